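"""Group-level statistics for the two-group (control vs epileptic) study.

Unpaired t-tests on partial-saturation estimates, Spearman rank correlation
for structural measures, and the summed hippocampal cell-loss score.  The
cell-loss scale runs 0–4 per subregion (4 = no neuronal loss, 0 = complete
loss) over CA1, CA3, CA3c and the dentate hilus, so the summed score spans
0–16.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnimalRecord",
    "GroupComparison",
    "RankCorrelation",
    "total_cell_loss_score",
    "compare_groups",
    "rank_correlation",
]

SUBREGIONS = ("CA1", "CA3", "CA3c", "hilus")


@dataclass
class AnimalRecord:
    """Per-animal measurements entering the group statistics."""

    animal_id: str
    group: str                      # "control" | "epileptic"
    b_max: dict = field(default_factory=dict)       # roi -> pmol/ml
    inv_kd_vr: dict = field(default_factory=dict)   # roi -> ml/pmol
    hippocampal_volume: float | None = None          # voxel count
    cell_loss: dict = field(default_factory=dict)    # subregion -> score 0-4
    seizure_frequency: float | None = None           # per 5 days

    def __post_init__(self) -> None:
        for region, score in self.cell_loss.items():
            if not 0 <= score <= 4:
                raise ValueError(f"cell-loss score for {region} outside [0, 4]")
        if self.hippocampal_volume is not None and self.hippocampal_volume < 0:
            raise ValueError("volume must be non-negative")


def total_cell_loss_score(record: AnimalRecord) -> float:
    """Sum the four subregion cell-loss scores (0 = complete loss, 16 = none).

    All four subregions must be scored; the sum is order-independent.
    """
    missing = [r for r in SUBREGIONS if r not in record.cell_loss]
    if missing:
        raise ValueError(f"missing subregion scores: {missing}")
    return float(sum(record.cell_loss[r] for r in SUBREGIONS))


@dataclass
class GroupComparison:
    measure: str
    t: float
    p: float
    df: float
    group_means: dict
    group_sems: dict
    group_ns: dict
    significance: str     # "significant" | "trend" | "ns"
    equal_var: bool


def _significance_label(p: float) -> str:
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "trend"
    return "ns"


def compare_groups(records, measure, equal_var: bool = True) -> GroupComparison:
    """Two-sided unpaired t-test between the two groups of ``records``.

    ``measure`` is either a callable mapping a record to a float or a
    ``(attribute, roi)`` pair such as ``("b_max", "hippocampus")``.  Equal
    variances are pooled by default; pass ``equal_var=False`` for Welch.
    """
    if callable(measure):
        extract, name = measure, getattr(measure, "__name__", "measure")
    else:
        attr, roi = measure
        extract = lambda r: getattr(r, attr)[roi]  # noqa: E731
        name = f"{attr}[{roi}]"
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.group, []).append(float(extract(r)))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(groups)}")
    (ga, xs), (gb, ys) = sorted(groups.items())
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each group needs at least 2 animals")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.std(ddof=1) == 0 and ys.std(ddof=1) == 0 and xs.mean() == ys.mean():
        t, p, df = 0.0, 1.0, len(xs) + len(ys) - 2
    else:
        res = sps.ttest_ind(xs, ys, equal_var=equal_var)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return GroupComparison(
        measure=name, t=t, p=p, df=df,
        group_means={ga: float(xs.mean()), gb: float(ys.mean())},
        group_sems={ga: float(sps.sem(xs)), gb: float(sps.sem(ys))},
        group_ns={ga: len(xs), gb: len(ys)},
        significance=_significance_label(p), equal_var=equal_var)


@dataclass
class RankCorrelation:
    rho: float
    r_squared: float     # rho², matching how rank correlations are reported
    p: float
    n: int
    p_method: str        # "exact-permutation" | "asymptotic"


#: below this n the two-sided p-value is computed by exhaustive enumeration
_EXACT_P_MAX_N = 8


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)   # mid-ranks for ties
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def rank_correlation(x, y) -> RankCorrelation:
    """Spearman rank correlation with mid-rank ties.

    For n ≤ 8 the two-sided p-value is exact, from exhaustive enumeration of
    the rank permutations; beyond that the usual asymptotic approximation is
    used.  A constant series leaves the correlation undefined and is
    rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant series")
    rho = _spearman_rho(x, y)
    n = int(x.size)
    if n <= _EXACT_P_MAX_N:
        ry = sps.rankdata(y)
        rx = sps.rankdata(x)
        count = total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p, method = count / total, "exact-permutation"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "asymptotic"
    return RankCorrelation(rho=rho, r_squared=rho * rho, p=float(p), n=n,
                           p_method=method)
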