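"""Reverse phase protein array (RPPA) validation analysis.

The RPPA panel probes a fixed set of proteins with (possibly several)
antibodies each.  The analysis collapses antibodies to one value per
protein (largest absolute log2 difference), calls up-regulation with a
strict log2 > 0.3 threshold (linear fold 2**0.3 = 1.23), and asks whether a
pathway's proteins are up-regulated more often than expected on the panel
via an upper-tail hypergeometric test:

    P(X >= k),  X ~ Hypergeom(N, K, n)

with N panel proteins, K up-regulated on the panel, n pathway proteins on
the panel, and k up-regulated pathway proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "HypergeomInput",
    "read_rppa_table",
    "collapse_antibodies",
    "call_upregulated",
    "pathway_hypergeom_test",
    "panel_summary",
]

RPPA_COLUMNS = ("antibody", "protein", "log2diff")

UP_THRESHOLD = 0.3


@dataclass(frozen=True)
class HypergeomInput:
    """Counts for the pathway up-regulation test.

    k: up-regulated proteins in the pathway;  K: up-regulated on the panel;
    m: not-up in the pathway;                 M: not-up on the panel;
    n: all pathway proteins on the panel;     N: all panel proteins.
    """

    k: int
    K: int
    m: int
    M: int
    n: int
    N: int

    def __post_init__(self) -> None:
        for fname, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"negative count: {fname} = {v}")
        if self.n != self.k + self.m:
            raise ValueError(f"violated identity n = k + m "
                             f"({self.n} != {self.k} + {self.m})")
        if self.N != self.K + self.M:
            raise ValueError(f"violated identity N = K + M "
                             f"({self.N} != {self.K} + {self.M})")
        if self.k > min(self.K, self.n):
            raise ValueError(f"violated identity k <= min(K, n) "
                             f"({self.k} > min({self.K}, {self.n}))")
        if self.n > self.N:
            raise ValueError(f"violated identity n <= N ({self.n} > {self.N})")


def read_rppa_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with header (antibody, protein, log2diff)."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    return validate_rppa_table(tab)


def validate_rppa_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(RPPA_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"RPPA table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty RPPA table")
    table = table.copy()
    table["antibody"] = table["antibody"].astype(str).str.strip()
    table["protein"] = table["protein"].astype(str).str.strip().str.upper()
    if table["antibody"].duplicated().any():
        raise ValueError("each antibody must map to exactly one protein")
    if not np.isfinite(table["log2diff"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite log2diff values")
    return table


def collapse_antibodies(table: pd.DataFrame) -> pd.DataFrame:
    """One row per protein: the antibody with the largest |log2diff|.

    Ties are broken by antibody name (ascending) for reproducibility.
    """
    table = validate_rppa_table(table)
    tab = table.assign(_abs=table["log2diff"].abs())
    tab = tab.sort_values(["protein", "_abs", "antibody"],
                          ascending=[True, False, True], kind="stable")
    out = tab.drop_duplicates("protein", keep="first")
    return out.drop(columns="_abs").reset_index(drop=True)[
        ["protein", "antibody", "log2diff"]]


def call_upregulated(values: pd.DataFrame | pd.Series,
                     threshold: float = UP_THRESHOLD
                     ) -> tuple[set[str], float]:
    """Proteins with log2 difference strictly above ``threshold``.

    Accepts the collapsed table (protein, log2diff) or a Series indexed by
    protein.  Returns the up-set and the equivalent linear fold 2**threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(values, pd.DataFrame):
        series = values.set_index("protein")["log2diff"]
    else:
        series = values
    up = set(series.index[series > threshold])
    return up, float(2.0 ** threshold)


def pathway_hypergeom_test(inp: HypergeomInput) -> float:
    """Upper-tail p = sum_{i>=k} C(K,i) C(M,n-i) / C(N,n), clipped to [0,1]."""
    p = float(hypergeom.sf(inp.k - 1, inp.N, inp.K, inp.n))
    return min(max(p, 0.0), 1.0)


def panel_summary(panel_proteins: Iterable[str], pathway_proteins: Iterable[str],
                  up_proteins: Iterable[str],
                  threshold: float = UP_THRESHOLD) -> dict:
    """Counts, percentages and the enrichment p-value for one panel/pathway.

    Percentages are reported to one decimal: the up-regulated fraction inside
    the pathway (k/n) against the panel background fraction (K/N).
    """
    panel = {str(p).strip().upper() for p in panel_proteins}
    pathway = {str(p).strip().upper() for p in pathway_proteins} & panel
    up = {str(p).strip().upper() for p in up_proteins} & panel
    inp = HypergeomInput(
        k=len(up & pathway), K=len(up),
        m=len(pathway - up), M=len(panel - up),
        n=len(pathway), N=len(panel),
    )
    return {
        "counts": asdict(inp),
        "pct_up_in_pathway": round(100.0 * inp.k / inp.n, 1) if inp.n else 0.0,
        "pct_up_on_panel": round(100.0 * inp.K / inp.N, 1) if inp.N else 0.0,
        "up_threshold_log2": threshold,
        "up_threshold_fold": round(float(2.0 ** threshold), 2),
        "pvalue": pathway_hypergeom_test(inp),
    }
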