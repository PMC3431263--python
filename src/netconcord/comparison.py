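"""Cross-model concordance statistics.

Concordance quantifies how much two isogenic metastatic models agree:
common differential features divided by the per-category minimum of the two
models' set sizes, as a half-up-rounded integer percentage.  The overall
figure pools the up and down categories: common features over the sum of
the per-category minima.  Using per-category minima makes the statistic
symmetric in model order and never exceeds 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

from .differential import DifferentialSet

__all__ = [
    "ConcordanceReport",
    "category_pct",
    "overall_concordance",
    "compare_sets",
]


def _round_half_up_pct(numer: int, denom: int) -> int:
    if denom <= 0:
        raise ValueError("zero denominator in concordance percentage")
    pct = Decimal(100) * Decimal(numer) / Decimal(denom)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConcordanceReport:
    model_a: str
    model_b: str
    common_up: int
    common_down: int
    denom_up: int
    denom_down: int
    category_pct_up: int
    category_pct_down: int
    overall_pct: int

    def __post_init__(self) -> None:
        if self.common_up > self.denom_up or self.common_down > self.denom_down:
            raise ValueError("common counts exceed per-category minima")
        if not 0 <= self.overall_pct <= 100:
            raise ValueError("overall_pct outside [0, 100]")

    def to_dict(self) -> dict:
        return asdict(self)


def category_pct(common: int, a_size: int, b_size: int) -> int:
    """Percentage of common features relative to the smaller model's set."""
    denom = min(a_size, b_size)
    if denom == 0:
        raise ValueError("category percentage undefined: smaller set is empty")
    if common > denom:
        raise ValueError("common count exceeds the smaller set size")
    return _round_half_up_pct(common, denom)


def overall_concordance(common_up: int, common_down: int, a_up: int,
                        a_down: int, b_up: int, b_down: int) -> int:
    """Overall concordance pooling both regulation categories.

    100 * (common_up + common_down) / (min(a_up, b_up) + min(a_down, b_down)),
    half-up rounded to an integer percent.
    """
    denom = min(a_up, b_up) + min(a_down, b_down)
    if denom == 0:
        raise ValueError("overall concordance undefined: empty denominators")
    for c, lim in ((common_up, min(a_up, b_up)), (common_down, min(a_down, b_down))):
        if c > lim:
            raise ValueError("common count exceeds per-category minimum")
    return _round_half_up_pct(common_up + common_down, denom)


def compare_sets(a: DifferentialSet, b: DifferentialSet) -> ConcordanceReport:
    """Concordance report from two models' up/down differential sets."""
    common_up = len(a.up & b.up)
    common_down = len(a.down & b.down)
    denom_up = min(len(a.up), len(b.up))
    denom_down = min(len(a.down), len(b.down))
    pct_up = category_pct(common_up, len(a.up), len(b.up)) if denom_up else 0
    pct_down = (category_pct(common_down, len(a.down), len(b.down))
                if denom_down else 0)
    if denom_up + denom_down:
        overall = _round_half_up_pct(common_up + common_down,
                                     denom_up + denom_down)
    else:
        overall = 0
    return ConcordanceReport(
        model_a=a.model, model_b=b.model,
        common_up=common_up, common_down=common_down,
        denom_up=denom_up, denom_down=denom_down,
        category_pct_up=pct_up, category_pct_down=pct_down,
        overall_pct=overall,
    )
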