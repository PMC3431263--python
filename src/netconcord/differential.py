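"""Threshold-based differential selection, panel filtering and sequon scanning.

Differential calls use the study-standard joint rule: raw (or corrected)
p-value below ``p_max`` and an absolute linear fold change of at least
``fc_min`` between the metastatic and parental classes.  The same rule shape
applies to every omic layer (expression arrays, spectral counts), so it
lives here once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialSet",
    "read_feature_stats",
    "select_differential",
    "subset_panel",
    "scan_sequons",
    "scan_fasta",
]

STATS_COLUMNS = ("feature", "log2fc", "pvalue")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DifferentialSet:
    """Up/down feature calls for one model (metastatic vs parental)."""

    model: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(
                f"{self.model}: up and down sets overlap: "
                f"{sorted(self.up & self.down)[:5]}")

    @property
    def all(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def _normalize_features(features: Iterable[str]) -> list[str]:
    return [str(f).strip().upper() for f in features]


def validate_feature_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a (feature, log2fc, pvalue) table."""
    missing = set(STATS_COLUMNS) - set(stats.columns)
    if missing:
        raise ValueError(f"feature stats missing columns: {sorted(missing)}")
    if len(stats) == 0:
        raise ValueError("empty feature stats table")
    stats = stats.copy()
    stats["feature"] = _normalize_features(stats["feature"])
    dup = stats["feature"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate features: {sorted(stats.loc[dup, 'feature'])[:5]}")
    bad = ~np.isfinite(stats["log2fc"].to_numpy(dtype=float))
    if bad.any():
        raise ValueError(
            f"non-finite log2fc for: {sorted(stats.loc[bad, 'feature'])[:5]}")
    p = stats["pvalue"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats


def read_feature_stats(path: str | Path) -> pd.DataFrame:
    """Read a TSV with header columns (feature, log2fc, pvalue)."""
    stats = pd.read_csv(path, sep="\t", comment="#")
    return validate_feature_stats(stats)


def select_differential(stats: pd.DataFrame, p_max: float = 0.05,
                        fc_min: float = 2.0, model: str = "model",
                        inclusive_fold: bool = True) -> DifferentialSet:
    """Call up/down features by p-value and linear fold-change thresholds.

    up:   p < p_max and 2**log2fc  >= fc_min
    down: p < p_max and 2**-log2fc >= fc_min

    ``inclusive_fold=False`` switches the fold comparison to strict (>),
    covering the ambiguity between "2-fold or greater" and "greater than
    2-fold" phrasings of the same protocol.
    """
    if not fc_min > 1:
        raise ValueError("fc_min must exceed 1")
    stats = validate_feature_stats(stats)
    log2_cut = np.log2(fc_min)
    lfc = stats["log2fc"].to_numpy(dtype=float)
    p = stats["pvalue"].to_numpy(dtype=float)
    if inclusive_fold:
        up_mask = (p < p_max) & (lfc >= log2_cut)
        down_mask = (p < p_max) & (-lfc >= log2_cut)
    else:
        up_mask = (p < p_max) & (lfc > log2_cut)
        down_mask = (p < p_max) & (-lfc > log2_cut)
    feats = stats["feature"].to_numpy()
    return DifferentialSet(model=model,
                           up=frozenset(feats[up_mask]),
                           down=frozenset(feats[down_mask]))


def subset_panel(stats: pd.DataFrame, panel: Sequence[str]) -> pd.DataFrame:
    """Restrict a stats table to a fixed feature panel, in panel order.

    Emulates restricting genome-wide expression to a curated panel (e.g. a
    glycogene list).  Returns an empty table with a warning if nothing
    overlaps.
    """
    panel_norm = _normalize_features(panel)
    if not panel_norm:
        raise ValueError("empty panel")
    stats = validate_feature_stats(stats)
    by_feature = stats.set_index("feature")
    present = [f for f in dict.fromkeys(panel_norm) if f in by_feature.index]
    if not present:
        logger.warning("panel of %d features has zero overlap with stats table",
                       len(panel_norm))
        return stats.iloc[0:0].copy()
    return by_feature.loc[present].reset_index()[list(stats.columns)]


_SEQUON = re.compile(r"N(?=[A-Z][ST])")
_SEQUON_NO_PRO = re.compile(r"N(?=[^P][ST])")


def scan_sequons(seq: str, exclude_proline: bool = False) -> list[int]:
    """1-based positions of N-glycosylation sequons (Asn-Xaa-Ser/Thr).

    Overlapping sequons are all reported.  ``exclude_proline`` drops motifs
    with proline at Xaa (a site rarely glycosylated in practice); the default
    enumerates the literal Asn-Xaa-Ser/Thr rule.
    """
    s = seq.strip().upper()
    for i, aa in enumerate(s):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"invalid amino acid {aa!r} at position {i + 1}")
    pattern = _SEQUON_NO_PRO if exclude_proline else _SEQUON
    return [m.start() + 1 for m in pattern.finditer(s)]


def scan_fasta(path: str | Path,
               exclude_proline: bool = False) -> dict[str, list[int]]:
    """Sequon positions for every record of a FASTA file."""
    from Bio import SeqIO

    out: dict[str, list[int]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = scan_sequons(str(rec.seq), exclude_proline=exclude_proline)
    return out
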