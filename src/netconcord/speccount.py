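"""Label-free spectral-counting quantification and differential testing.

Two samples (metastatic vs parental) are compared per protein.  Counts are
normalized to a common library size (the mean of the two totals), floored at
a minimum quantitative value of 1.0 so that proteins absent from one sample
still yield a finite fold change.  Significance comes from a two-sided
Fisher exact test on the raw integer counts against the library totals,
corrected by the Benjamini-Hochberg step-up procedure.  Fold changes use the
floored normalized values; the exact test always sees raw integers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .differential import DifferentialSet, select_differential

__all__ = [
    "read_count_table",
    "quantify",
    "fisher_test",
    "stepup_correct",
    "test_counts",
    "differential_proteins",
]

COUNT_COLUMNS = ("protein", "count_met", "count_par")
MIN_QUANT = 1.0


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with header (protein, count_met, count_par)."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    return validate_count_table(tab)


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(COUNT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty count table")
    table = table.copy()
    table["protein"] = table["protein"].astype(str).str.strip().str.upper()
    if table["protein"].duplicated().any():
        # multiple runs per protein: pool by summation before testing
        table = table.groupby("protein", as_index=False)[
            ["count_met", "count_par"]].sum()
    for col in ("count_met", "count_par"):
        vals = table[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{col}: spectral counts must be integers")
            table[col] = np.round(vals).astype(np.int64)
        if (table[col] < 0).any():
            raise ValueError(f"{col}: negative counts")
    for col in ("count_met", "count_par"):
        if table[col].sum() == 0:
            raise ValueError(f"{col}: all-zero sample")
    return table


def quantify(table: pd.DataFrame) -> pd.DataFrame:
    """Normalized quantitative values and fold changes (no p-values yet).

    Each sample's counts are scaled so its total equals the mean library
    size across the two samples, then floored at 1.0.  The fold change is
    metastatic / parental on the floored values.
    """
    table = validate_count_table(table)
    tot_met = table["count_met"].sum()
    tot_par = table["count_par"].sum()
    target = (tot_met + tot_par) / 2.0
    q_met = np.maximum(table["count_met"] * (target / tot_met), MIN_QUANT)
    q_par = np.maximum(table["count_par"] * (target / tot_par), MIN_QUANT)
    out = table.copy()
    out["qvalue_met"] = q_met
    out["qvalue_par"] = q_par
    out["fold_change"] = q_met / q_par
    return out


def fisher_test(protein_counts: tuple[int, int],
                library_totals: tuple[int, int]) -> float:
    """Two-sided Fisher exact p on [count, total - count] x sample.

    Two-sided by summing the probabilities of every 2x2 table (at fixed
    margins) no more likely than the observed one.
    """
    (a, b), (na, nb) = protein_counts, library_totals
    if na <= 0 or nb <= 0:
        raise ValueError("library totals must be positive")
    if a > na or b > nb:
        raise ValueError("protein count exceeds its library total")
    if a < 0 or b < 0:
        raise ValueError("negative counts")
    _, p = fisher_exact([[a, na - a], [b, nb - b]], alternative="two-sided")
    return float(p)


def stepup_correct(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def test_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Full per-protein quantification: fold changes, Fisher p, BH-adjusted p."""
    quant = quantify(table)
    tot_met = int(quant["count_met"].sum())
    tot_par = int(quant["count_par"].sum())
    quant["pvalue"] = [
        fisher_test((int(a), int(b)), (tot_met, tot_par))
        for a, b in zip(quant["count_met"], quant["count_par"])
    ]
    quant["p_adj"] = stepup_correct(quant["pvalue"])
    return quant


def differential_proteins(quant: pd.DataFrame, p_max: float = 0.05,
                          fc_min: float = 2.0,
                          model: str = "model") -> DifferentialSet:
    """Differential calls on corrected p and fold change (same rule shape as
    the expression layer, with the corrected p in place of the raw p)."""
    if "p_adj" not in quant.columns:
        raise ValueError("quant table lacks 'p_adj'; run test_counts first")
    if "fold_change" not in quant.columns:
        raise ValueError("quant table lacks 'fold_change'")
    stats = pd.DataFrame({
        "feature": quant["protein"],
        "log2fc": np.log2(quant["fold_change"].to_numpy(dtype=float)),
        "pvalue": quant["p_adj"],
    })
    return select_differential(stats, p_max=p_max, fc_min=fc_min, model=model)
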