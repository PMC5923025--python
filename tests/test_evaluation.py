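"""Error taxonomy, diagnostic metrics, performance score, pass rate, team
qualification probability and weighted time."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triagesim import (
    TriageCategory,
    classify_error,
    compute_metrics,
    confusion,
    pass_rate,
    score_performance,
    team_pass_probability,
    weighted_time,
)
from triagesim.evaluation import (
    ASSISTANT_CRITERIA,
    LEADER_CRITERIA,
    ErrorClass,
    PerformanceSheet,
    coverage_ok,
    provider_averaged_metrics,
)

R, Y, G, D = (TriageCategory.RED, TriageCategory.YELLOW,
              TriageCategory.GREEN, TriageCategory.DEAD)
OK, OV, UN, CO, CU = (ErrorClass.OK, ErrorClass.OVER, ErrorClass.UNDER,
                      ErrorClass.CRITICAL_OVER, ErrorClass.CRITICAL_UNDER)

# The full error table, rows = triaged as, columns = expected (R, Y, G, D).
ERROR_TABLE = {
    R: {R: OK, Y: CO, G: CO, D: CO},
    Y: {R: CU, Y: OK, G: OV, D: OV},
    G: {R: CU, Y: UN, G: OK, D: OV},
    D: {R: CU, Y: UN, G: UN, D: OK},
}


def test_error_table_all_sixteen_cells():
    for assigned, row in ERROR_TABLE.items():
        for expected, want in row.items():
            assert classify_error(assigned, expected) is want


@given(
    st.lists(
        st.tuples(st.sampled_from(list(TriageCategory)), st.sampled_from(list(TriageCategory))),
        min_size=1,
        max_size=60,
    )
)
@settings(max_examples=200, derandomize=True)
def test_error_classes_partition_every_record_set(pairs):
    """accuracy + the four error-class rates account for every record."""
    classes = [classify_error(a, e) for a, e in pairs]
    counts = {c: classes.count(c) for c in ErrorClass}
    assert sum(counts.values()) == len(pairs)
    # critical iff exactly one side is RED
    for (a, e), c in zip(pairs, classes):
        assert ((a is R) ^ (e is R)) == (c in (CO, CU))


def _frame(pairs, **extra):
    df = pd.DataFrame(
        {"assigned": [a.value for a, _ in pairs], "ground_truth": [e.value for _, e in pairs]}
    )
    for k, v in extra.items():
        df[k] = v
    return df


def test_confusion_counts_sum_to_n(pool):
    pairs = [(v.ground_truth, v.ground_truth) for v in pool]
    tab = confusion(_frame(pairs))
    assert int(tab.to_numpy().sum()) == len(pool)
    assert int(np.trace(tab.to_numpy())) == len(pool)


def test_sensitivity_example():
    # 8 of 10 expected-RED assigned RED -> sensitivity 0.8
    pairs = [(R, R)] * 8 + [(G, R)] * 2
    m = compute_metrics(_frame(pairs))
    assert m.sensitivity.value == pytest.approx(0.8)
    assert m.specificity.defined is False  # no expected non-red records


def test_all_ok_records():
    pairs = [(c, c) for c in TriageCategory] * 5
    m = compute_metrics(_frame(pairs))
    assert m.accuracy.value == 1.0
    for rate in (m.under_rate, m.over_rate, m.critical_under_rate, m.critical_over_rate):
        assert rate.value == 0.0


def test_metrics_match_brute_force_on_random_tables():
    """Oracle equivalence on random confusion tables: sensitivity,
    specificity, accuracy and all four error rates recounted by hand."""
    rng = np.random.default_rng(17)
    cats = list(TriageCategory)
    for _ in range(50):
        n = int(rng.integers(5, 80))
        pairs = [(cats[rng.integers(4)], cats[rng.integers(4)]) for _ in range(n)]
        rng.shuffle(pairs)
        m = compute_metrics(_frame(pairs))
        exp_red = [p for p in pairs if p[1] is R]
        non_red = [p for p in pairs if p[1] is not R]
        if exp_red:
            assert m.sensitivity.value == pytest.approx(
                sum(a is R for a, _ in exp_red) / len(exp_red)
            )
        if non_red:
            assert m.specificity.value == pytest.approx(
                sum(a is not R for a, _ in non_red) / len(non_red)
            )
        assert m.accuracy.value == pytest.approx(sum(a is e for a, e in pairs) / n)
        rates = (m.accuracy.value + m.under_rate.value + m.over_rate.value
                 + m.critical_under_rate.value + m.critical_over_rate.value)
        assert rates == pytest.approx(1.0)


def test_intervention_accuracy_and_times():
    pairs = [(R, R)] * 4 + [(G, G)] * 4
    df = _frame(
        pairs,
        airway_correct=[True, True, False, True] * 2,
        bleeding_correct=[True] * 8,
        time_s=[50.0, 40.0, 50.0, 40.0, 20.0, 20.0, 20.0, 20.0],
    )
    m = compute_metrics(df)
    assert m.airway_accuracy.value == pytest.approx(0.75)
    assert m.bleeding_accuracy.value == pytest.approx(1.0)
    assert m.mean_time_s[0] == pytest.approx(32.5)


def test_empty_records_rejected():
    with pytest.raises(ValueError):
        compute_metrics(pd.DataFrame(columns=["assigned", "ground_truth"]))


def test_provider_averaged_vs_pooled_differ_under_imbalance():
    # one provider with 1 record (wrong), one with 9 (all right):
    # pooled accuracy 0.9, provider-averaged 0.5
    pairs = [(Y, R)] + [(R, R)] * 9
    df = _frame(pairs, leader_id=["p1"] + ["p2"] * 9)
    per = provider_averaged_metrics(df)
    assert per["accuracy"].mean() == pytest.approx(0.5)
    assert compute_metrics(df).accuracy.value == pytest.approx(0.9)


# ------------------------------------------------------------------ score


def _sheet(n_lead=10, n_asst=10, lead_val=True, asst_val=True):
    sh = PerformanceSheet(provider_id="P")
    for _ in range(n_lead):
        sh.add("LEADER", {c: lead_val for c in LEADER_CRITERIA})
    for _ in range(n_asst):
        sh.add("ASSISTANT", {c: asst_val for c in ASSISTANT_CRITERIA})
    return sh


def test_score_checklist_shape():
    assert len(LEADER_CRITERIA) == 6 and len(ASSISTANT_CRITERIA) == 4
    sh = _sheet()
    assert sh.max_points == 100 and coverage_ok(sh)


def test_score_examples():
    assert score_performance(_sheet()) == 100.0
    assert score_performance(_sheet(lead_val=False, asst_val=False)) == 0.0
    assert score_performance(_sheet(asst_val=False)) == 60.0  # perfect leader rows only


def test_irregular_coverage_flagged_and_rescaled_on_request():
    sh = _sheet(n_lead=5, n_asst=5)  # 5*6 + 5*4 = 50 possible
    assert not coverage_ok(sh)
    assert score_performance(sh) == 50.0
    assert score_performance(sh, rescale=True) == pytest.approx(100.0)


def test_sheet_rejects_wrong_criteria():
    sh = PerformanceSheet(provider_id="P")
    with pytest.raises(ValueError):
        sh.add("LEADER", {c: True for c in ASSISTANT_CRITERIA})


def test_pass_rate_examples():
    assert pass_rate([100.0] * 5).value == 1.0
    assert pass_rate([95.0, 85.0]).value == 0.5
    assert pass_rate([90.0]).value == 1.0  # threshold is inclusive
    with pytest.raises(ValueError):
        pass_rate([])


# ------------------------------------------------------------ team probability


def test_team_pass_probability_examples():
    assert team_pass_probability(0.7, 2) == pytest.approx(0.91)
    assert team_pass_probability(1.0) == 1.0
    assert team_pass_probability(0.0) == 0.0
    with pytest.raises(ValueError):
        team_pass_probability(1.5)


@given(st.floats(0.01, 0.98), st.integers(1, 6))
@settings(derandomize=True)
def test_team_pass_probability_monotone(p, k):
    assert team_pass_probability(p + 0.01, k) > team_pass_probability(p, k)
    assert team_pass_probability(p, k + 1) > team_pass_probability(p, k)


# ------------------------------------------------------------- weighted time


def test_weighted_time_examples():
    means = {R: 50.0, Y: 40.0, G: 20.0, D: 10.0}
    assert weighted_time(means) == pytest.approx(30.0)
    assert weighted_time({c: 30.0 for c in TriageCategory}) == pytest.approx(30.0)
    with pytest.raises(ValueError, match="GREEN"):
        weighted_time({R: 50.0, Y: 40.0, D: 10.0})
    with pytest.raises(ValueError, match="sum"):
        weighted_time(means, {R: 0.5, Y: 0.2, G: 0.2, D: 0.0})


@given(st.lists(st.floats(1.0, 100.0), min_size=4, max_size=4))
@settings(derandomize=True)
def test_weighted_time_within_bounds(ts):
    means = dict(zip([R, Y, G, D], ts))
    wt = weighted_time(means)
    weighted = [means[c] for c in (R, Y, G)]  # DEAD has zero weight
    assert min(weighted) - 1e-9 <= wt <= max(weighted) + 1e-9


def test_dead_mean_not_required():
    assert weighted_time({R: 10.0, Y: 10.0, G: 10.0}) == pytest.approx(10.0)
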