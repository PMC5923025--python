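"""Endpoints of the triage study: error taxonomy, diagnostic metrics for
red-category detection, intervention-decision accuracy, the 10-item triage
performance score, pass rate, team qualification probability, and the
category-weighted time requirement.

The five error classes (OK / OVER / UNDER / CRITICAL_OVER / CRITICAL_UNDER)
partition the 16 possible (assigned, expected) category pairs: any non-red
patient triaged red is a critical over-triage, any red patient triaged
non-red is a critical under-triage, and the remaining off-diagonal cells are
plain over-/under-triage by urgency order RED > YELLOW > GREEN > DEAD.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .engine import TriageCategory

__all__ = [
    "ErrorClass",
    "MetricSet",
    "Proportion",
    "PerformanceSheet",
    "LEADER_CRITERIA",
    "ASSISTANT_CRITERIA",
    "classify_error",
    "confusion",
    "compute_metrics",
    "score_performance",
    "sheets_from_records",
    "session_scores",
    "pass_rate",
    "team_pass_probability",
    "weighted_time",
]


class ErrorClass(enum.Enum):
    OK = "OK"
    OVER = "OVER"
    UNDER = "UNDER"
    CRITICAL_OVER = "CRITICAL_OVER"
    CRITICAL_UNDER = "CRITICAL_UNDER"


def classify_error(assigned: TriageCategory, expected: TriageCategory) -> ErrorClass:
    """Classify one triage outcome against the consented standard solution."""
    if assigned is expected:
        return ErrorClass.OK
    if assigned is TriageCategory.RED:
        return ErrorClass.CRITICAL_OVER
    if expected is TriageCategory.RED:
        return ErrorClass.CRITICAL_UNDER
    if assigned.urgency > expected.urgency:
        return ErrorClass.OVER
    return ErrorClass.UNDER


# Checklist items.  The leader makes the clinical decisions (6 items per
# procedure), the assistant documents and announces the algorithm steps
# (4 items per procedure); 10 items in total, one point each.
LEADER_CRITERIA = (
    "role_behavior",
    "communication",
    "bleeding_indication",
    "airway_indication",
    "triage_category",
    "labeling",
)
ASSISTANT_CRITERIA = (
    "role_behavior",
    "communication",
    "algorithm_compliance",
    "documentation",
)


@dataclass(frozen=True)
class Proportion:
    """A proportion with its Wilson 95% CI; NaN-valued when undefined."""

    value: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def _wilson(k: int, n: int) -> Proportion:
    if n == 0:
        return Proportion(float("nan"), float("nan"), float("nan"), 0)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return Proportion(k / n, float(lo), float(hi), n)


def _t_mean_ci(x: np.ndarray) -> tuple[float, float, float]:
    m = float(np.mean(x))
    if len(x) < 2:
        return m, float("nan"), float("nan")
    half = sps.t.ppf(0.975, len(x) - 1) * sps.sem(x)
    return m, m - float(half), m + float(half)


@dataclass(frozen=True)
class MetricSet:
    """Procedure-level endpoint estimates for one record set."""

    n: int
    accuracy: Proportion
    under_rate: Proportion
    critical_under_rate: Proportion
    over_rate: Proportion
    critical_over_rate: Proportion
    sensitivity: Proportion      # red detected among expected-red
    specificity: Proportion      # non-red kept non-red
    airway_accuracy: Proportion
    bleeding_accuracy: Proportion
    mean_time_s: tuple[float, float, float] | None = None
    weighted_time_s: tuple[float, float, float] | None = None


_CATS = [c.value for c in TriageCategory]


def _records_frame(records: Iterable) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of TriageRecord-like objects."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        rows.append(
            {
                "assigned": getattr(r.assigned, "value", r.assigned),
                "ground_truth": getattr(r.ground_truth, "value", r.ground_truth),
                "airway_correct": getattr(r, "airway_correct", None),
                "bleeding_correct": getattr(r, "bleeding_correct", None),
                "time_s": getattr(r, "time_s", None),
            }
        )
    return pd.DataFrame(rows)


def confusion(records: Iterable) -> pd.DataFrame:
    """4x4 table of counts, rows = assigned, columns = expected category."""
    df = _records_frame(records)
    tab = pd.crosstab(df["assigned"], df["ground_truth"])
    return tab.reindex(index=_CATS, columns=_CATS, fill_value=0)


def compute_metrics(
    records: Iterable,
    time_weights: Mapping[TriageCategory, float] | None = None,
) -> MetricSet:
    """Compute every procedure-level endpoint on a record set.

    Sensitivity/specificity are for red-category patients (all non-red
    categories as negatives).  With no expected-red (or no expected-non-red)
    records the corresponding estimate is returned as NaN rather than 0.
    Airway/bleeding accuracy are the fractions of procedures whose performed
    intervention decision matched the indicated one.
    """
    df = _records_frame(records)
    n = len(df)
    if n == 0:
        raise ValueError("cannot compute metrics on an empty record set")
    assigned = df["assigned"].astype(str)
    expected = df["ground_truth"].astype(str)
    err = np.array(
        [classify_error(TriageCategory(a), TriageCategory(e)).value
         for a, e in zip(assigned, expected)]
    )
    counts = {c.value: int((err == c.value).sum()) for c in ErrorClass}

    exp_red = expected == "RED"
    as_red = assigned == "RED"
    sens = _wilson(int((exp_red & as_red).sum()), int(exp_red.sum()))
    spec = _wilson(int((~exp_red & ~as_red).sum()), int((~exp_red).sum()))

    def _bool_prop(col: str) -> Proportion:
        if col not in df or df[col].isna().all():
            return Proportion(float("nan"), float("nan"), float("nan"), 0)
        s = df[col].dropna().astype(bool)
        return _wilson(int(s.sum()), len(s))

    mean_time = None
    wtime = None
    if "time_s" in df and df["time_s"].notna().any():
        t = df["time_s"].dropna().to_numpy(float)
        mean_time = _t_mean_ci(t)
        weights = time_weights if time_weights is not None else DEFAULT_TIME_WEIGHTS
        wtime = _weighted_time_ci(df, weights)

    return MetricSet(
        n=n,
        accuracy=_wilson(counts["OK"], n),
        under_rate=_wilson(counts["UNDER"], n),
        critical_under_rate=_wilson(counts["CRITICAL_UNDER"], n),
        over_rate=_wilson(counts["OVER"], n),
        critical_over_rate=_wilson(counts["CRITICAL_OVER"], n),
        sensitivity=sens,
        specificity=spec,
        airway_accuracy=_bool_prop("airway_correct"),
        bleeding_accuracy=_bool_prop("bleeding_correct"),
        mean_time_s=mean_time,
        weighted_time_s=wtime,
    )


def provider_averaged_metrics(records: pd.DataFrame, by: str = "leader_id") -> pd.DataFrame:
    """Per-provider endpoint rates (one row per provider).

    The pooled-procedure estimates of :func:`compute_metrics` and the mean of
    these per-provider rates generally differ when providers contribute
    unequal procedure counts; both views are offered.
    """
    out = []
    for pid, grp in records.groupby(by):
        m = compute_metrics(grp)
        out.append(
            {
                by: pid,
                "n": m.n,
                "accuracy": m.accuracy.value,
                "sensitivity": m.sensitivity.value,
                "specificity": m.specificity.value,
                "under_rate": m.under_rate.value,
                "critical_under_rate": m.critical_under_rate.value,
                "over_rate": m.over_rate.value,
                "critical_over_rate": m.critical_over_rate.value,
                "airway_accuracy": m.airway_accuracy.value,
                "bleeding_accuracy": m.bleeding_accuracy.value,
                "time_s": float("nan") if m.mean_time_s is None else m.mean_time_s[0],
                "weighted_time_s": float("nan")
                if m.weighted_time_s is None
                else m.weighted_time_s[0],
            }
        )
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Performance score


@dataclass
class PerformanceSheet:
    """Checklist outcomes for one provider over one assessment session.

    ``rows`` holds one entry per triage procedure performed by the provider:
    ``("LEADER", {criterion: bool})`` with the 6 leader items, or
    ``("ASSISTANT", {criterion: bool})`` with the 4 assistant items.
    A regular session has 10 rows in each role (role switch after ten
    patients), for a maximum score of 10*6 + 10*4 = 100.
    """

    provider_id: str
    rows: list[tuple[str, dict[str, bool]]] = field(default_factory=list)

    def add(self, role: str, criteria: Mapping[str, bool]) -> None:
        want = LEADER_CRITERIA if role == "LEADER" else ASSISTANT_CRITERIA
        if set(criteria) != set(want):
            raise ValueError(
                f"{role} row needs exactly criteria {want}, got {sorted(criteria)}"
            )
        self.rows.append((role, dict(criteria)))

    @property
    def max_points(self) -> int:
        return sum(6 if role == "LEADER" else 4 for role, _ in self.rows)


def score_performance(sheet: PerformanceSheet, rescale: bool = False) -> float:
    """Sum of fulfilled checklist items (one point each).

    A full 20-procedure sheet (10 per role) scores in 0..100.  Sheets with
    other role coverage are flagged via ``PerformanceSheet.coverage_ok`` by
    the caller's inspection of row counts; the raw sum is still returned,
    rescaled to the 100-point range only when ``rescale`` is requested.
    """
    raw = sum(sum(crit.values()) for _, crit in sheet.rows)
    if rescale and sheet.max_points not in (0, 100):
        return 100.0 * raw / sheet.max_points
    return float(raw)


def coverage_ok(sheet: PerformanceSheet) -> bool:
    """True when the sheet has the regular 10 leader + 10 assistant rows."""
    n_lead = sum(1 for role, _ in sheet.rows if role == "LEADER")
    n_asst = len(sheet.rows) - n_lead
    return n_lead == 10 and n_asst == 10


def sheets_from_records(records: Iterable) -> dict[str, PerformanceSheet]:
    """Assemble one performance sheet per provider from triage records.

    Each record credits its leader with the six leader items and its
    assistant with the four assistant items; over a regular 20-procedure
    session with a role switch after ten patients every provider ends up
    with 10 rows in each role.
    """
    sheets: dict[str, PerformanceSheet] = {}

    def sheet(pid: str) -> PerformanceSheet:
        if pid not in sheets:
            sheets[pid] = PerformanceSheet(provider_id=pid)
        return sheets[pid]

    for r in records:
        crit = r.criteria
        sheet(r.leader_id).add(
            "LEADER", {c: crit[f"leader_{c}"] for c in LEADER_CRITERIA}
        )
        sheet(r.assistant_id).add(
            "ASSISTANT", {c: crit[f"assistant_{c}"] for c in ASSISTANT_CRITERIA}
        )
    return sheets


def session_scores(records: Iterable) -> dict[str, float]:
    """Per-provider performance score for one session's records."""
    return {
        pid: score_performance(sh) for pid, sh in sheets_from_records(records).items()
    }


def pass_rate(scores: Sequence[float], threshold: float = 90.0) -> Proportion:
    """Fraction of providers scoring at or above the qualification threshold."""
    if len(scores) == 0:
        raise ValueError("pass_rate of an empty score list is undefined")
    k = int(sum(s >= threshold for s in scores))
    return _wilson(k, len(scores))


def team_pass_probability(p: float, k: int = 2) -> float:
    """P(at least one of k independent members qualifies) = 1 - (1-p)^k."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if k < 1:
        raise ValueError("team size must be >= 1")
    return 1.0 - (1.0 - p) ** k


# --------------------------------------------------------------------------
# Weighted time requirement

# Idealized MCI casualty mix used to re-weight the per-category mean times
# (red and yellow vignettes are over-represented in the training pool for
# didactic reasons): 20% red, 20% yellow, 60% green, no dead fraction.
DEFAULT_TIME_WEIGHTS: dict[TriageCategory, float] = {
    TriageCategory.RED: 0.2,
    TriageCategory.YELLOW: 0.2,
    TriageCategory.GREEN: 0.6,
    TriageCategory.DEAD: 0.0,
}


def weighted_time(
    mean_time_by_category: Mapping[TriageCategory, float],
    weights: Mapping[TriageCategory, float] | None = None,
) -> float:
    """Weighted mean triage time over an idealized category distribution."""
    w = DEFAULT_TIME_WEIGHTS if weights is None else weights
    total = sum(w.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"weights sum to {total}, expected 1")
    out = 0.0
    for cat, wc in w.items():
        if wc == 0.0:
            continue
        if cat not in mean_time_by_category or mean_time_by_category[cat] is None:
            raise ValueError(f"no mean time for weighted category {cat.value}")
        out += wc * mean_time_by_category[cat]
    return out


def _weighted_time_ci(df: pd.DataFrame, weights: Mapping[TriageCategory, float]):
    """Weighted mean with a delta-method 95% CI over category strata."""
    means: dict[TriageCategory, float] = {}
    var = 0.0
    for cat, wc in weights.items():
        if wc == 0.0:
            continue
        t = df.loc[df["assigned"] == cat.value, "time_s"].dropna().to_numpy(float)
        if len(t) == 0:
            return None  # weighted category absent from this record set
        means[cat] = float(np.mean(t))
        if len(t) > 1:
            var += wc**2 * float(np.var(t, ddof=1)) / len(t)
    m = weighted_time(means, weights)
    half = 1.959963984540054 * math.sqrt(var)
    return m, m - half, m + half
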