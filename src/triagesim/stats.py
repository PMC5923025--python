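"""Statistical comparison layer across assessment time points.

Part A (procedure-derived endpoints such as accuracy, sensitivity,
over-/under-triage and time requirement) is compared between sessions with a
one-way ANOVA followed by Bonferroni-adjusted pairwise post-hoc tests.
Because procedures are clustered within providers, the default unit of
analysis is the per-provider rate; raw procedure-level values can be passed
explicitly.  Part B (provider-level performance score and pass indicator) is
compared with paired tests: paired t for the score, Wilcoxon signed-rank
(Pratt zero handling) for the binary pass indicator, plus a Shapiro-Wilk
normality check.  Alpha defaults to 0.05.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestKind",
    "Direction",
    "ComparisonResult",
    "anova_bonferroni",
    "compare_procedure_level",
    "compare_provider_level",
    "normality_check",
]

ALPHA = 0.05


class TestKind(enum.Enum):
    ANOVA_BONFERRONI = "A"
    PAIRED_T = "T"
    WILCOXON = "W"


class Direction(enum.Enum):
    DECLINE = "decline"
    IMPROVEMENT = "improvement"
    NONE = "none"


@dataclass(frozen=True)
class ComparisonResult:
    endpoint: str
    pair: tuple[str, str]            # (later, earlier) time-point labels
    test: TestKind
    p_value: float
    direction: Direction
    significant: bool
    statistic: float = float("nan")
    note: str = ""

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value {self.p_value} outside [0, 1]")


def _direction(later_mean: float, earlier_mean: float, higher_is_better: bool) -> Direction:
    if math.isclose(later_mean, earlier_mean, abs_tol=1e-12):
        return Direction.NONE
    better = later_mean > earlier_mean
    if not higher_is_better:
        better = not better
    return Direction.IMPROVEMENT if better else Direction.DECLINE


def anova_bonferroni(
    groups: Mapping[str, Sequence[float]],
    endpoint: str = "",
    alpha: float = ALPHA,
    higher_is_better: bool = True,
) -> tuple[float, list[ComparisonResult]]:
    """Omnibus one-way ANOVA plus all pairwise Bonferroni-adjusted t tests.

    Returns ``(omnibus_p, pairwise_results)``.  Pairwise p values are raw
    two-sample t-test p values multiplied by the number of comparisons and
    capped at 1.  Direction is judged from the group means with the later
    time point first in each pair.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], float) for k in labels]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 non-missing values")
    omnibus = sps.f_oneway(*arrays)
    pairs = list(combinations(range(len(labels)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        if np.allclose(arrays[i], arrays[i][0]) and np.allclose(arrays[j], arrays[j][0]) and np.isclose(arrays[i][0], arrays[j][0]):
            p_adj, stat, note = 1.0, float("nan"), "identical constant groups"
        else:
            t = sps.ttest_ind(arrays[j], arrays[i])
            p_adj = min(1.0, float(t.pvalue) * m)
            stat, note = float(t.statistic), ""
        out.append(
            ComparisonResult(
                endpoint=endpoint,
                pair=(labels[j], labels[i]),
                test=TestKind.ANOVA_BONFERRONI,
                p_value=p_adj,
                direction=_direction(
                    float(np.mean(arrays[j])), float(np.mean(arrays[i])), higher_is_better
                ),
                significant=p_adj < alpha,
                statistic=stat,
                note=note,
            )
        )
    return float(omnibus.pvalue), out


# Endpoints where a larger value means better triage (used for the
# improvement/decline arrow); error rates and times are better when smaller.
HIGHER_IS_BETTER = {
    "accuracy": True,
    "sensitivity": True,
    "specificity": True,
    "under_rate": False,
    "critical_under_rate": False,
    "over_rate": False,
    "critical_over_rate": False,
    "airway_accuracy": True,
    "bleeding_accuracy": True,
    "time_s": False,
    "weighted_time_s": False,
}


def compare_procedure_level(
    endpoint_values: Mapping[str, Mapping[str, Sequence[float]]],
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Compare Part A endpoints across sessions.

    ``endpoint_values`` maps endpoint name -> {session label -> values}
    (per-provider rates by default upstream).  Only pairwise post-hoc
    results are returned; the omnibus p is available via
    :func:`anova_bonferroni` directly.
    """
    results: list[ComparisonResult] = []
    for endpoint, groups in endpoint_values.items():
        _, pairwise = anova_bonferroni(
            groups, endpoint, alpha, HIGHER_IS_BETTER.get(endpoint, True)
        )
        results.extend(pairwise)
    return results


def compare_provider_level(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    pair: tuple[str, str] = ("later", "earlier"),
    pass_threshold: float = 90.0,
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Paired Part B comparison of two sessions.

    ``scores_a``/``scores_b`` map provider id -> performance score for the
    later and earlier session; providers present in only one session are
    dropped (their count is noted on the result).  Returns the paired t on
    the scores and the Wilcoxon signed-rank test on the pass indicators.
    """
    common = sorted(set(scores_a) & set(scores_b))
    dropped = len(set(scores_a) ^ set(scores_b))
    if len(common) < 2:
        raise ValueError("need >= 2 providers matched across both sessions")
    a = np.array([scores_a[p] for p in common], float)
    b = np.array([scores_b[p] for p in common], float)
    note = f"{len(common)} matched, {dropped} unmatched dropped"

    if np.allclose(a, b):
        t_p, t_stat, t_note = float("nan"), float("nan"), note + "; identical paired values"
    else:
        t = sps.ttest_rel(a, b)
        t_p, t_stat, t_note = float(t.pvalue), float(t.statistic), note
    results = [
        ComparisonResult(
            endpoint="performance_score",
            pair=pair,
            test=TestKind.PAIRED_T,
            p_value=t_p,
            direction=_direction(float(a.mean()), float(b.mean()), True),
            significant=(not math.isnan(t_p)) and t_p < alpha,
            statistic=t_stat,
            note=t_note,
        )
    ]

    pa = (a >= pass_threshold).astype(float)
    pb = (b >= pass_threshold).astype(float)
    diff = pa - pb
    if np.all(diff == 0):
        w_p, w_stat, w_note = float("nan"), float("nan"), note + "; identical pass indicators"
    else:
        w = sps.wilcoxon(pa, pb, zero_method="pratt")
        w_p, w_stat, w_note = float(w.pvalue), float(w.statistic), note
    results.append(
        ComparisonResult(
            endpoint="pass_rate",
            pair=pair,
            test=TestKind.WILCOXON,
            p_value=w_p,
            direction=_direction(float(pa.mean()), float(pb.mean()), True),
            significant=(not math.isnan(w_p)) and w_p < alpha,
            statistic=w_stat,
            note=w_note,
        )
    )
    return results


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W statistic, p value)."""
    arr = np.asarray(values, float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 3:
        raise ValueError("Shapiro-Wilk needs >= 3 values")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)
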