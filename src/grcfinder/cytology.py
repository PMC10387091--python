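"""GRC physical size from meiotic-spread measurements.

In pachytene spreads the 29 largest A chromosomes of a cell are measured
in micrometres and paired, by rank, with the 29 largest chromosome sizes
(bp) of a reference karyotype.  Chromosome length in micrometres scales as
a power law of size in bp, so within each cell an ordinary least-squares
regression of log(bp) on log(um) converts the measured GRC length to base
pairs.  The unpaired (univalent) GRC is measured 1.5x too long relative to
bivalents, so its length is divided by 1.5 before conversion.  Variation
among individuals is tested with a one-way ANOVA on the per-cell estimates
plus Tukey's HSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SpreadCell",
    "ReferenceKaryotype",
    "CellEstimate",
    "AnovaResult",
    "N_CHROMOSOMES",
    "cell_regression",
    "size_summary",
    "anova_tukey",
]

N_CHROMOSOMES = 29


@dataclass
class SpreadCell:
    cell_id: str
    individual: str
    species: str
    lengths_um: tuple[float, ...]  # the 29 largest A-chromosome lengths
    grc_length_um: float

    def __post_init__(self) -> None:
        if len(self.lengths_um) != N_CHROMOSOMES:
            raise ValueError(
                f"cell {self.cell_id}: need {N_CHROMOSOMES} chromosome lengths, "
                f"got {len(self.lengths_um)}"
            )
        if any(x <= 0 for x in self.lengths_um) or self.grc_length_um <= 0:
            raise ValueError(f"cell {self.cell_id}: non-positive length")


@dataclass
class ReferenceKaryotype:
    sizes_bp: tuple[float, ...]  # the 29 largest chromosomes, descending

    def __post_init__(self) -> None:
        if len(self.sizes_bp) != N_CHROMOSOMES:
            raise ValueError(f"need {N_CHROMOSOMES} reference sizes")
        if any(x <= 0 for x in self.sizes_bp):
            raise ValueError("non-positive reference size")
        if list(self.sizes_bp) != sorted(self.sizes_bp, reverse=True):
            raise ValueError("reference sizes must be in descending order")


@dataclass
class CellEstimate:
    cell_id: str
    individual: str
    grc_bp: float
    slope: float
    intercept: float
    r_squared: float


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    # (group_a, group_b, mean difference, Tukey p)
    tukey: list[tuple[str, str, float, float]]

    @property
    def df_total(self) -> int:
        return self.df_between + self.df_within


def cell_regression(
    cell: SpreadCell, ref: ReferenceKaryotype, univalent_divisor: float = 1.5
) -> CellEstimate:
    """Per-cell log-log regression and GRC size conversion.

    The i-th longest measured chromosome is paired with the i-th largest
    reference size; log(bp) is regressed on log(um) by OLS, and the GRC
    estimate is exp(intercept + slope * log(grc_um / divisor)).  The
    result is invariant to the micrometre unit scale and to the log base.
    """
    um = np.sort(np.asarray(cell.lengths_um, dtype=float))[::-1]
    bp = np.asarray(ref.sizes_bp, dtype=float)
    x = np.log(um)
    y = np.log(bp)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    grc_bp = math.exp(intercept + slope * math.log(cell.grc_length_um / univalent_divisor))
    return CellEstimate(
        cell_id=cell.cell_id,
        individual=cell.individual,
        grc_bp=grc_bp,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
    )


def size_summary(
    estimates: Sequence[CellEstimate],
) -> tuple[dict[str, float], tuple[float, float]]:
    """Per-individual mean GRC size and the range of individual means."""
    by_individual: dict[str, list[float]] = {}
    for est in estimates:
        by_individual.setdefault(est.individual, []).append(est.grc_bp)
    means = {ind: float(np.mean(v)) for ind, v in by_individual.items()}
    values = list(means.values())
    return means, (min(values), max(values))


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from sums of squares, plus Tukey HSD on group means."""
    names = sorted(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    if len(data) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(d) < 2 for d in data):
        raise ValueError("every group needs >= 2 observations")
    n_total = sum(len(d) for d in data)
    grand = np.concatenate(data).mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    df_between = len(data) - 1
    df_within = n_total - len(data)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = math.inf if ms_between > 0 else 0.0
    else:
        f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within)) if math.isfinite(f) else 0.0
    hsd = stats.tukey_hsd(*data)
    tukey = []
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            tukey.append(
                (
                    names[i],
                    names[j],
                    float(data[i].mean() - data[j].mean()),
                    float(hsd.pvalue[i, j]),
                )
            )
    return AnovaResult(
        f_statistic=float(f),
        p_value=p,
        df_between=df_between,
        df_within=df_within,
        tukey=tukey,
    )
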