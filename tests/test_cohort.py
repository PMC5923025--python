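"""Synthetic cohort: vignette pool, skill decay/re-training dynamics, and
procedure/session/study simulation."""

import math
from collections import Counter

import numpy as np
import pytest

from conftest import make_provider
from triagesim import (
    StudyConfig,
    TriageCategory,
    draw_session_vignettes,
    generate_vignette_pool,
    session_scores,
    simulate_procedure,
    simulate_session,
    simulate_study,
    skill_at,
)
from triagesim.cohort import SKILLS, ProviderProfile, SkillState
from triagesim.engine import load_tree
from triagesim.evaluation import ErrorClass
from triagesim.io import records_to_frame

MINI = load_tree("""
name: mini
root: walk
findings:
  can_walk: {type: bool}
nodes:
  - id: walk
    finding: can_walk
    edges:
      - {when: true, category: GREEN}
      - {when: false, category: RED}
""")


# ------------------------------------------------------------------ pool


def test_pool_mix_and_reproducibility(asav_tree):
    mix = {TriageCategory.RED: 0.35, TriageCategory.YELLOW: 0.35,
           TriageCategory.GREEN: 0.25, TriageCategory.DEAD: 0.05}
    p1 = generate_vignette_pool(40, mix, asav_tree, seed=9)
    p2 = generate_vignette_pool(40, mix, asav_tree, seed=9)
    assert len(p1) == 40
    assert [v.findings for v in p1] == [v.findings for v in p2]
    assert [v.ground_truth for v in p1] == [v.ground_truth for v in p2]
    counts = Counter(v.ground_truth for v in p1)
    assert counts[TriageCategory.RED] + counts[TriageCategory.YELLOW] > counts[TriageCategory.GREEN]


def test_point_mass_green_pool_is_walkable(asav_tree):
    (v,) = generate_vignette_pool(1, {TriageCategory.GREEN: 1.0}, asav_tree, seed=3)
    assert v.ground_truth is TriageCategory.GREEN
    assert v.findings["can_walk"] is True


def test_unreachable_category_raises():
    with pytest.raises(RuntimeError, match="not reached"):
        generate_vignette_pool(1, {TriageCategory.DEAD: 1.0}, MINI, seed=0, max_attempts=200)


def test_bad_mix_rejected(asav_tree):
    with pytest.raises(ValueError, match="sums to"):
        generate_vignette_pool(4, {TriageCategory.RED: 0.5}, asav_tree, seed=0)


def test_session_draw(pool):
    sel = draw_session_vignettes(pool, 20, seed=4)
    assert len(sel) == 20 and len({v.id for v in sel}) == 20
    assert draw_session_vignettes(pool, 20, seed=4) == sel
    full = draw_session_vignettes(pool, len(pool), seed=4)
    assert sorted(v.id for v in full) == sorted(v.id for v in pool)
    with pytest.raises(ValueError):
        draw_session_vignettes(pool, len(pool) + 1, seed=4)


# ------------------------------------------------------------------ skills


def test_skill_decay_closed_form():
    # rate chosen analytically so that p(14.6 months) = 0.75
    rate = math.log((0.9 - 0.5) / (0.75 - 0.5)) / 14.6
    prof = make_provider("P", 0.9, floor=0.5, decay_rate=rate)
    assert skill_at(prof, 0.0).p["categorization_step"] == pytest.approx(0.9)
    assert skill_at(prof, 14.6).p["categorization_step"] == pytest.approx(0.75)


def test_zero_rate_constant_skills():
    prof = make_provider("P", 0.8, floor=0.5, decay_rate=0.0)
    assert skill_at(prof, 36.0).p == skill_at(prof, 0.0).p


def test_retrain_resets_above_initial_level():
    prof = make_provider("P", 0.9, floor=0.5, decay_rate=0.05, retrain_gain=0.02)
    prof.training_history.append((12.0, "RETRAIN"))
    before = skill_at(prof, 11.9).p["labeling"]
    after = skill_at(prof, 12.0).p["labeling"]
    assert before < 0.9
    assert after == pytest.approx(0.92)
    assert skill_at(prof, 20.0).p["labeling"] < after


def test_floor_bounds_skills():
    prof = make_provider("P", 0.9, floor=0.6, decay_rate=5.0)
    assert skill_at(prof, 1000.0).p["documentation"] == pytest.approx(0.6)


def test_invalid_skill_state_rejected():
    with pytest.raises(ValueError):
        SkillState.uniform(1.2)
    with pytest.raises(ValueError):
        SkillState.uniform(0.4, floor=0.5)


# ------------------------------------------------------------------ procedures


def test_perfect_provider_procedure(perfect_team, pool, asav_tree):
    a, b = perfect_team
    for i, v in enumerate(pool[:10]):
        r = simulate_procedure(a, b, v, asav_tree, seed=i)
        assert r.assigned is v.ground_truth
        assert r.error is ErrorClass.OK
        assert all(r.criteria.values())
        assert r.interventions_performed == v.indicated_interventions
        assert r.time_s > 0
        if v.ground_truth is TriageCategory.GREEN:
            assert r.tag_applied is None
        else:
            assert r.tag_applied is not None


def test_zero_skill_always_misassigns():
    """Forced wrong branch: p_categorization = 0 on a two-leaf tree flips
    every assignment."""
    from triagesim.cohort import Vignette

    a = make_provider("A", 0.5, floor=0.0)
    a.skill.p["categorization_step"] = 0.0
    b = make_provider("B", 0.9, floor=0.5)
    green = Vignette(id="g", findings={"can_walk": True},
                     ground_truth=TriageCategory.GREEN,
                     indicated_interventions=frozenset())
    for i in range(50):
        r = simulate_procedure(a, b, green, MINI, seed=i)
        assert r.assigned is TriageCategory.RED


def test_under_bias_shifts_errors_downward(pool, asav_tree):
    """With a strong under-triage bias, wrong assignments of RED vignettes
    land on less urgent categories more often than with bias off."""
    a = make_provider("A", 0.5, floor=0.0)
    a.skill.p["categorization_step"] = 0.0
    b = make_provider("B", 0.9, floor=0.5)
    red = next(v for v in pool if v.ground_truth is TriageCategory.RED)
    rng = np.random.default_rng(11)
    biased = [simulate_procedure(a, b, red, asav_tree, seed=rng, under_bias=50.0) for _ in range(200)]
    under = sum(r.error is ErrorClass.CRITICAL_UNDER for r in biased)
    assert under / 200 > 0.9


def test_role_swap_gives_both_members_both_roles(perfect_team, pool, asav_tree):
    a, b = perfect_team
    res = simulate_session([(a, b)], pool, seed=5, tree=asav_tree)
    assert res.n_procedures == 20
    lead_counts = Counter(r.leader_id for r in res.records)
    assert lead_counts == {"A": 10, "B": 10}
    # every record has the full 10-item checklist
    assert all(len(r.criteria) == 10 for r in res.records)
    assert session_scores(res.records) == {"A": 100.0, "B": 100.0}


# ------------------------------------------------------------------ study level


def test_monotone_decay_of_session_accuracy(pool, asav_tree):
    """Without re-training, Monte-Carlo accuracy is non-increasing in month
    (>= 1000 procedures per time point)."""
    rng = np.random.default_rng(21)
    prof_a = make_provider("A", 0.95, floor=0.55, decay_rate=0.05)
    prof_b = make_provider("B", 0.95, floor=0.55, decay_rate=0.05)
    accs = []
    for month in (0.0, 12.0, 24.0):
        ok = 0
        for _ in range(1000):
            v = pool[int(rng.integers(len(pool)))]
            r = simulate_procedure(prof_a, prof_b, v, asav_tree, month, rng)
            ok += r.assigned is r.ground_truth
        accs.append(ok / 1000)
    assert accs[0] > accs[1] > accs[2] - 0.02  # strict early drop, noise-tolerant tail
    assert accs[0] - accs[2] > 0.05


def test_parameter_recovery(pool, asav_tree):
    """Observed accuracy estimates p_categorization within its binomial CI."""
    rng = np.random.default_rng(31)
    for p in (0.9, 0.75):
        a = make_provider("A", max(p, 0.5), floor=0.3)
        a.skill.p["categorization_step"] = p
        b = make_provider("B", 0.9, floor=0.5)
        ok = sum(
            simulate_procedure(a, b, pool[int(rng.integers(len(pool)))], asav_tree, 0.0, rng).criteria[
                "leader_triage_category"
            ]
            for _ in range(1000)
        )
        assert abs(ok / 1000 - p) < 1.96 * math.sqrt(p * (1 - p) / 1000)


def test_study_reproducibility_and_inclusion():
    cfg = StudyConfig(roster_size=12, retention=[0.7, 0.9])
    s1 = simulate_study(cfg, 42)
    s2 = simulate_study(cfg, 42)
    f1 = records_to_frame(s1.all_records())
    f2 = records_to_frame(s2.all_records())
    assert f1.equals(f2)
    assert s1.pass_rates == s2.pass_rates
    # inclusion rule: baseline attendance plus at least one follow-up
    baseline = set(s1.sessions[0].roster)
    later = set(s1.sessions[1].roster) | set(s1.sessions[2].roster)
    assert s1.included_providers == baseline & later
    assert s1.n2 == len(s1.included_providers)
    assert s1.n1 <= sum(s.n_procedures for s in s1.sessions)
    # every included record involves an included provider
    for sess in s1.sessions:
        for r in s1.included_records(sess):
            assert {r.leader_id, r.assistant_id} & s1.included_providers


def test_stop_rule_flags_low_pass_rate():
    cfg = StudyConfig(roster_size=10, skill_base_p=0.80, skill_jitter_sd=0.0,
                      qualification_offset={}, retention=[1.0, 1.0],
                      retrain_before_session=None)
    study = simulate_study(cfg, 7)
    assert study.stop_rule_triggered["s1"]  # score ~80 << 90 threshold


def test_perfect_study_limit():
    cfg = StudyConfig(roster_size=8, skill_base_p=1.0, skill_jitter_sd=0.0,
                      qualification_offset={}, skill_decay_rate=0.0,
                      skill_floor=0.0, retention=[1.0, 1.0])
    study = simulate_study(cfg, 3)
    assert all(pr == 1.0 for pr in study.pass_rates.values())
    assert all(r.error is ErrorClass.OK for r in study.all_records())
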