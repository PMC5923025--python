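"""Synthetic cohort generator and session simulator for dummy-based
primary-triage assessment studies.

The module emulates the moving parts of a longitudinal triage-training
study: a pool of written patient vignettes with a consented ground-truth
category, two-person provider teams that swap leader/assistant roles halfway
through a 20-patient session, per-provider skill reliabilities that decay
exponentially over the months since training and recover after a brief
re-training lecture, and the roster attrition between yearly assessments.

Skill model
-----------
Each provider carries a correct-execution probability ``p_s`` for every
checklist skill.  Between training events the probability relaxes toward a
floor::

    p_s(t) = floor + (p_base - floor) * exp(-rate * (t - t_train))

A re-training event resets the base level to the post-initial level plus a
(possibly positive) ``retrain_gain``.

Categorization errors are simulated as one error event per procedure with
probability ``1 - p_categorization``, localized at a uniformly weighted node
of the true decision path: the leader takes a wrong branch there and follows
the algorithm faithfully afterwards.  Wrong branches whose continuation
happens to reach the true category are excluded, so the procedure-level
categorization accuracy equals ``p_categorization`` exactly and the
parameter is identifiable from observed accuracy.  An optional
``under_bias`` weights wrong branches that end in a less urgent category,
reproducing the under-triage excess seen in START-family field data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Any, Iterable, Mapping, Sequence

import numpy as np

from . import evaluation
from .engine import (
    DecisionTree,
    Intervention,
    TriageCategory,
    TriageDecision,
    apply_algorithm,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io import StudyConfig

__all__ = [
    "SKILLS",
    "Vignette",
    "SkillState",
    "ProviderProfile",
    "TriageRecord",
    "SessionResult",
    "StudyDataset",
    "TimeModel",
    "generate_vignette_pool",
    "draw_session_vignettes",
    "skill_at",
    "simulate_procedure",
    "simulate_session",
    "simulate_study",
]

SKILLS = (
    "categorization_step",
    "airway_indication",
    "bleeding_indication",
    "documentation",
    "labeling",
    "role_behavior",
    "communication",
    "algorithm_compliance",
)

QUALIFICATIONS = ("paramedic", "EMT", "other")
EMPLOYMENTS = ("professional", "volunteer")

DEFAULT_CATEGORY_MIX = {
    # red and yellow over-represented for didactic reasons
    TriageCategory.RED: 0.35,
    TriageCategory.YELLOW: 0.35,
    TriageCategory.GREEN: 0.25,
    TriageCategory.DEAD: 0.05,
}


# --------------------------------------------------------------------------
# Data containers


@dataclass(frozen=True)
class Vignette:
    """One simulated patient: a dummy description card.

    ``findings`` holds the vital data the algorithm tests plus descriptive
    context (age, sex, pain level); ``ground_truth`` is the consented
    standard-solution category, by construction the category the reference
    tree assigns.
    """

    id: str
    findings: dict[str, Any]
    ground_truth: TriageCategory
    indicated_interventions: frozenset[Intervention]


@dataclass(frozen=True)
class SkillState:
    """Per-skill correct-execution probabilities and their dynamics."""

    p: dict[str, float]
    decay_rate: float = 0.0      # per month
    floor: float = 0.5
    retrain_gain: float = 0.0

    def __post_init__(self):
        for s, v in self.p.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"skill {s}: probability {v} outside [0, 1]")
            if v < self.floor - 1e-12:
                raise ValueError(f"skill {s}: level {v} below floor {self.floor}")
        if self.decay_rate < 0:
            raise ValueError("decay rate must be >= 0")

    @classmethod
    def uniform(cls, p: float, **kw) -> "SkillState":
        return cls(p={s: p for s in SKILLS}, **kw)


@dataclass
class ProviderProfile:
    id: str
    qualification: str = "paramedic"
    employment: str = "professional"
    skill: SkillState = field(default_factory=lambda: SkillState.uniform(0.9))
    training_history: list[tuple[float, str]] = field(default_factory=lambda: [(0.0, "INITIAL")])

    def __post_init__(self):
        if self.qualification not in QUALIFICATIONS:
            raise ValueError(f"unknown qualification {self.qualification!r}")
        if self.employment not in EMPLOYMENTS:
            raise ValueError(f"unknown employment {self.employment!r}")


@dataclass
class TriageRecord:
    """One triage procedure as observed by the study assistants."""

    vignette_id: str
    team_id: str
    leader_id: str
    assistant_id: str
    ground_truth: TriageCategory
    assigned: TriageCategory
    error: evaluation.ErrorClass
    interventions_indicated: frozenset[Intervention]
    interventions_performed: frozenset[Intervention]
    airway_correct: bool
    bleeding_correct: bool
    tag_applied: str | None
    time_s: float
    criteria: dict[str, bool]
    months_since_training: float = 0.0
    session: str = ""

    def __post_init__(self):
        if self.time_s <= 0:
            raise ValueError("time_s must be positive")
        want = {f"leader_{c}" for c in evaluation.LEADER_CRITERIA} | {
            f"assistant_{c}" for c in evaluation.ASSISTANT_CRITERIA
        }
        if set(self.criteria) != want:
            raise ValueError("criteria keys must be exactly the 6 leader + 4 assistant items")


@dataclass
class SessionResult:
    label: str
    month: float
    records: list[TriageRecord]
    roster: list[str]                      # provider ids present
    teams: list[tuple[str, str]]

    @property
    def n_procedures(self) -> int:
        return len(self.records)


@dataclass
class StudyDataset:
    sessions: list[SessionResult]
    providers: dict[str, ProviderProfile]
    pool: list[Vignette]
    included_providers: set[str]
    pass_rates: dict[str, float]
    stop_rule_triggered: dict[str, bool]
    config: Any = None

    def all_records(self) -> list[TriageRecord]:
        return [r for s in self.sessions for r in s.records]

    def included_records(self, session: SessionResult) -> list[TriageRecord]:
        """Apply the inclusion rule: keep a triage run only if at least one
        team member took part in the baseline and in a follow-up session."""
        return [
            r
            for r in session.records
            if r.leader_id in self.included_providers
            or r.assistant_id in self.included_providers
        ]

    @property
    def n1(self) -> int:
        return sum(len(self.included_records(s)) for s in self.sessions)

    @property
    def n2(self) -> int:
        return len(self.included_providers)


# --------------------------------------------------------------------------
# Vignette pool


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_findings(tree: DecisionTree, rng: np.random.Generator) -> dict[str, Any]:
    """Draw one complete findings map uniformly over the declared domains,
    plus descriptive card context the algorithm does not test."""
    f: dict[str, Any] = {}
    for key, dom in tree.findings.items():
        if dom.kind == "bool":
            f[key] = bool(rng.random() < 0.5)
        elif dom.kind == "enum":
            f[key] = dom.values[rng.integers(len(dom.values))]
        else:
            f[key] = int(rng.integers(dom.lo, dom.hi + 1))
    f["age"] = int(rng.integers(5, 91))
    f["sex"] = "f" if rng.random() < 0.5 else "m"
    f["pain_level"] = int(rng.integers(0, 11))
    return f


def generate_vignette_pool(
    n: int = 40,
    category_mix: Mapping[TriageCategory, float] | None = None,
    tree: DecisionTree | None = None,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 10_000,
) -> list[Vignette]:
    """Build a pool of ``n`` vignettes whose ground-truth categories follow
    ``category_mix`` (red/yellow over-represented by default).

    Findings are rejection-sampled until the reference tree reproduces the
    target category, so the stored ground truth is consistent with the
    algorithm by construction.
    """
    if tree is None:
        from .engine import load_bundled_tree

        tree = load_bundled_tree("asav")
    mix = dict(DEFAULT_CATEGORY_MIX if category_mix is None else category_mix)
    total = sum(mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"category mix sums to {total}, expected 1")
    rng = _as_rng(seed)
    cats = list(mix)
    targets = [cats[i] for i in rng.choice(len(cats), size=n, p=[mix[c] for c in cats])]
    pool: list[Vignette] = []
    for i, target in enumerate(targets):
        for _ in range(max_attempts):
            findings = _sample_findings(tree, rng)
            decision = apply_algorithm(findings, tree)
            if decision.category is target:
                pool.append(
                    Vignette(
                        id=f"V{i + 1:03d}",
                        findings=findings,
                        ground_truth=target,
                        indicated_interventions=decision.interventions,
                    )
                )
                break
        else:
            raise RuntimeError(
                f"category {target.value} not reached in {max_attempts} attempts; "
                f"unreachable under tree {tree.name!r}?"
            )
    return pool


def draw_session_vignettes(
    pool: Sequence[Vignette], k: int = 20, seed: int | np.random.Generator = 0
) -> list[Vignette]:
    """Select ``k`` distinct vignettes uniformly without replacement, in
    random order (the study's random-number-table draw)."""
    if k > len(pool):
        raise ValueError(f"cannot draw {k} from a pool of {len(pool)}")
    rng = _as_rng(seed)
    idx = rng.permutation(len(pool))[:k]
    return [pool[i] for i in idx]


# --------------------------------------------------------------------------
# Skill dynamics


def skill_at(profile: ProviderProfile, month: float) -> SkillState:
    """Skill state at ``month``, decayed from the most recent training event."""
    events = sorted(profile.training_history)
    past = [(m, e) for m, e in events if m <= month + 1e-9]
    if not past:
        raise ValueError(f"provider {profile.id}: no training event before month {month}")
    t_train, kind = past[-1]
    base_state = profile.skill
    if kind == "RETRAIN":
        base = {
            s: min(1.0, max(base_state.floor, p + base_state.retrain_gain))
            for s, p in base_state.p.items()
        }
    else:
        base = dict(base_state.p)
    dt = month - t_train
    decayed = {
        s: base_state.floor + (b - base_state.floor) * math.exp(-base_state.decay_rate * dt)
        for s, b in base.items()
    }
    return replace(base_state, p=decayed)


# --------------------------------------------------------------------------
# Procedure simulation


@dataclass(frozen=True)
class TimeModel:
    """Per-category lognormal triage durations (seconds, walking time
    between dummies folded in).  Red/yellow patients take longer than green
    and dead ones.  The two simulated interventions are just placed on the
    dummy, so they add no time by default."""

    mean_s: Mapping[TriageCategory, float] = field(
        default_factory=lambda: {
            TriageCategory.RED: 45.0,
            TriageCategory.YELLOW: 40.0,
            TriageCategory.GREEN: 20.0,
            TriageCategory.DEAD: 15.0,
        }
    )
    sigma: float = 0.35          # log-scale sd
    intervention_s: float = 0.0  # added per performed intervention

    def draw(self, category: TriageCategory, n_interventions: int, rng: np.random.Generator) -> float:
        m = self.mean_s[category]
        mu = math.log(m) - self.sigma**2 / 2.0
        return float(rng.lognormal(mu, self.sigma)) + self.intervention_s * n_interventions


DEFAULT_TIME_MODEL = TimeModel()


def _continue_walk(tree: DecisionTree, start: str, findings: Mapping[str, Any]) -> TriageCategory:
    """Faithful walk from an interior node to a leaf category."""
    nid = start
    while True:
        node = tree.nodes[nid]
        edge = next(e for e in node.edges if e.predicate(findings[node.finding_key]))
        if edge.category is not None:
            return edge.category
        nid = edge.next_node


def _wrong_branch_outcomes(
    tree: DecisionTree, vignette: Vignette, true_path: Sequence[str]
) -> list[TriageCategory]:
    """Final category of every single wrong-branch deviation from the true
    path (one candidate per off-path edge, in path order)."""
    out = []
    for nid in true_path:
        node = tree.nodes[nid]
        value = vignette.findings[node.finding_key]
        for e in node.edges:
            if e.predicate(value):
                continue
            if e.category is not None:
                out.append(e.category)
            else:
                out.append(_continue_walk(tree, e.next_node, vignette.findings))
    return out


def simulate_procedure(
    leader: ProviderProfile,
    assistant: ProviderProfile,
    vignette: Vignette,
    tree: DecisionTree,
    month: float = 0.0,
    seed: int | np.random.Generator = 0,
    time_model: TimeModel = DEFAULT_TIME_MODEL,
    under_bias: float = 1.0,
    team_id: str = "T1",
    session: str = "",
) -> TriageRecord:
    """Simulate one triage procedure of a two-person team.

    ``under_bias`` >= 0 multiplies the weight of wrong branches ending in a
    less urgent category than the truth (0 = never under-triage on error,
    1 = unbiased).
    """
    rng = _as_rng(seed)
    lskill = skill_at(leader, month).p
    askill = skill_at(assistant, month).p
    truth = apply_algorithm(vignette, tree)

    # --- category assignment: at most one localized wrong branch
    assigned = truth.category
    if rng.random() >= lskill["categorization_step"]:
        outcomes = _wrong_branch_outcomes(tree, vignette, truth.path)
        candidates = [c for c in outcomes if c is not truth.category]
        if candidates:
            w = np.array(
                [1.0 + under_bias if c.urgency < truth.category.urgency else 1.0 for c in candidates]
            )
            assigned = candidates[rng.choice(len(candidates), p=w / w.sum())]

    # --- intervention decisions
    indicated = vignette.indicated_interventions
    performed = set()
    airway_ok = rng.random() < lskill["airway_indication"]
    if airway_ok == (Intervention.OROPHARYNGEAL_TUBE in indicated):
        performed.add(Intervention.OROPHARYNGEAL_TUBE)
    bleeding_ok = rng.random() < lskill["bleeding_indication"]
    if bleeding_ok == (Intervention.BLEEDING_CONTROL in indicated):
        performed.add(Intervention.BLEEDING_CONTROL)

    # --- tagging (green patients carry no tag)
    labeling_ok = bool(rng.random() < lskill["labeling"])
    correct_tag = TriageDecision.tag_for(assigned)
    if labeling_ok:
        tag = correct_tag
    else:
        tag = "red" if correct_tag is None else None  # spurious tag / forgot tag

    criteria = {
        "leader_role_behavior": bool(rng.random() < lskill["role_behavior"]),
        "leader_communication": bool(rng.random() < lskill["communication"]),
        "leader_bleeding_indication": bool(bleeding_ok),
        "leader_airway_indication": bool(airway_ok),
        "leader_triage_category": assigned is truth.category,
        "leader_labeling": labeling_ok,
        "assistant_role_behavior": bool(rng.random() < askill["role_behavior"]),
        "assistant_communication": bool(rng.random() < askill["communication"]),
        "assistant_algorithm_compliance": bool(rng.random() < askill["algorithm_compliance"]),
        "assistant_documentation": bool(rng.random() < askill["documentation"]),
    }

    return TriageRecord(
        vignette_id=vignette.id,
        team_id=team_id,
        leader_id=leader.id,
        assistant_id=assistant.id,
        ground_truth=vignette.ground_truth,
        assigned=assigned,
        error=evaluation.classify_error(assigned, vignette.ground_truth),
        interventions_indicated=frozenset(indicated),
        interventions_performed=frozenset(performed),
        airway_correct=bool(airway_ok),
        bleeding_correct=bool(bleeding_ok),
        tag_applied=tag,
        time_s=time_model.draw(assigned, len(performed), rng),
        criteria=criteria,
        months_since_training=month,
        session=session,
    )


def simulate_session(
    teams: Sequence[tuple[ProviderProfile, ProviderProfile]],
    pool: Sequence[Vignette],
    month: float = 0.0,
    seed: int | np.random.Generator = 0,
    k: int = 20,
    tree: DecisionTree | None = None,
    time_model: TimeModel = DEFAULT_TIME_MODEL,
    under_bias: float = 1.0,
    label: str = "session",
) -> SessionResult:
    """Run one assessment session: each team triages the same ``k`` drawn
    vignettes; team members swap leader/assistant roles after ``k // 2``
    patients, so both accumulate 10 leader and 10 assistant ratings."""
    if tree is None:
        from .engine import load_bundled_tree

        tree = load_bundled_tree("asav")
    rng = _as_rng(seed)
    vigs = draw_session_vignettes(pool, k, rng)
    half = k // 2
    records: list[TriageRecord] = []
    roster: list[str] = []
    team_ids = []
    for ti, (a, b) in enumerate(teams):
        tid = f"{label}-T{ti + 1:02d}"
        team_ids.append((a.id, b.id))
        roster.extend([a.id, b.id])
        for j, v in enumerate(vigs):
            lead, asst = (a, b) if j < half else (b, a)
            records.append(
                simulate_procedure(
                    lead, asst, v, tree, month, rng, time_model, under_bias, tid, label
                )
            )
    return SessionResult(label=label, month=month, records=records, roster=roster, teams=team_ids)


# --------------------------------------------------------------------------
# Full longitudinal study


def _allocate_categories(n: int, mix: Mapping[str, float], rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder allocation of n items to strata."""
    keys = list(mix)
    raw = {k: n * mix[k] for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    rem = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:rem]:
        counts[k] += 1
    out = [k for k in keys for _ in range(counts[k])]
    rng.shuffle(out)
    return out


def _make_roster(cfg: "StudyConfig", rng: np.random.Generator) -> dict[str, ProviderProfile]:
    quals = _allocate_categories(cfg.roster_size, cfg.qualification_mix, rng)
    emps = _allocate_categories(cfg.roster_size, cfg.employment_mix, rng)
    providers = {}
    for i in range(cfg.roster_size):
        pid = f"P{i + 1:03d}"
        base = cfg.skill_base_p + cfg.qualification_offset.get(quals[i], 0.0)
        p = {
            s: float(np.clip(base + rng.normal(0.0, cfg.skill_jitter_sd), cfg.skill_floor, 1.0))
            for s in SKILLS
        }
        providers[pid] = ProviderProfile(
            id=pid,
            qualification=quals[i],
            employment=emps[i],
            skill=SkillState(
                p=p,
                decay_rate=cfg.skill_decay_rate,
                floor=cfg.skill_floor,
                retrain_gain=cfg.retrain_gain,
            ),
            training_history=[(cfg.session_months[0], "INITIAL")],
        )
    return providers


def simulate_study(config: "StudyConfig", seed: int) -> StudyDataset:
    """Simulate the whole longitudinal study under one master seed.

    Sessions run at the configured months with Bernoulli roster retention
    between them; a re-training event is granted to the providers attending
    the configured re-training session.  After each session the pass rate
    (score >= pass threshold) is checked against the early-stopping
    threshold.  The inclusion rule for analysis (at least one team member
    present at baseline and a follow-up) is recorded on the returned
    dataset, which exposes N1 (procedures) and N2 (providers).
    """
    from .io import StudyConfig  # noqa: F401  (documented concrete type)

    ss = np.random.SeedSequence(seed)
    pool_rng, roster_rng, *session_rngs = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(config.session_months))
    ]
    tree = config.load_tree()
    pool = generate_vignette_pool(
        config.pool_size, config.category_mix_typed(), tree, pool_rng
    )
    providers = _make_roster(config, roster_rng)
    time_model = config.time_model()

    attendance: list[list[str]] = [list(providers)]
    for i, retention in enumerate(config.retention):
        prev = attendance[-1]
        keep = [pid for pid in prev if roster_rng.random() < retention]
        attendance.append(keep)
    attendance = attendance[: len(config.session_months)]

    if config.retrain_before_session is not None:
        m = config.session_months[config.retrain_before_session]
        for pid in attendance[config.retrain_before_session]:
            providers[pid].training_history.append((m, "RETRAIN"))

    sessions: list[SessionResult] = []
    pass_rates: dict[str, float] = {}
    stop_flags: dict[str, bool] = {}
    labels = [f"s{i + 1}" for i in range(len(config.session_months))]
    for i, (month, label, rng) in enumerate(zip(config.session_months, labels, session_rngs)):
        present = list(attendance[i])
        rng.shuffle(present)
        teams = [
            (providers[present[2 * t]], providers[present[2 * t + 1]])
            for t in range(len(present) // 2)
        ]
        res = simulate_session(
            teams,
            pool,
            month,
            rng,
            k=config.session_draw,
            tree=tree,
            time_model=time_model,
            under_bias=config.under_bias,
            label=label,
        )
        sessions.append(res)
        scores = evaluation.session_scores(res.records)
        if scores:
            pr = evaluation.pass_rate(list(scores.values()), config.pass_threshold).value
            pass_rates[label] = pr
            stop_flags[label] = pr < config.stop_threshold
    baseline = set(sessions[0].roster)
    later = set().union(*(s.roster for s in sessions[1:])) if len(sessions) > 1 else set()
    included = baseline & later
    return StudyDataset(
        sessions=sessions,
        providers=providers,
        pool=pool,
        included_providers=included,
        pass_rates=pass_rates,
        stop_rule_triggered=stop_flags,
        config=config,
    )
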