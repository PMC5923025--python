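"""CSV readers/writers, study configuration and report rendering.

All artifacts are plain CSV so that a study dataset can be audited by eye,
mirroring the paper-and-clipboard workflow of a dummy-based triage study.
Schemas:

``records.csv``  — one row per triage procedure (see ``RECORD_COLUMNS``);
                   categories serialized as RED/YELLOW/GREEN/DEAD,
                   interventions as ``|``-joined codes, checklist outcomes as
                   ``crit_<role>_<item>`` booleans.
``vignettes.csv``— one row per vignette; the findings map is stored as a
                   JSON object in ``findings_json``.
``roster.csv``   — one row per provider with qualification, employment and
                   session attendance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .cohort import (
    ProviderProfile,
    StudyDataset,
    TimeModel,
    TriageRecord,
    Vignette,
)
from .engine import DecisionTree, Intervention, TriageCategory, load_bundled_tree, load_tree

log = logging.getLogger("triagesim")

__all__ = [
    "StudyConfig",
    "read_records",
    "write_records",
    "records_to_frame",
    "write_vignettes",
    "read_vignettes",
    "write_roster",
    "write_study",
    "RECORD_COLUMNS",
]


# --------------------------------------------------------------------------
# Study configuration


@dataclass
class StudyConfig:
    """All knobs of a simulated longitudinal triage study.

    Defaults describe the emulated study: a 40-vignette pool with red and
    yellow over-represented, 20 vignettes drawn per session, a 33-provider
    roster thinning to ~22 and ~19 at the follow-ups, assessments at 0,
    14.6 and 25.1 months with a brief re-training immediately before the
    third, a 90-point qualification threshold and a 70% pass-rate stop rule.
    """

    tree: str = "asav"
    session_months: list[float] = field(default_factory=lambda: [0.0, 14.6, 25.1])
    pool_size: int = 40
    category_mix: dict[str, float] = field(
        default_factory=lambda: {"RED": 0.35, "YELLOW": 0.35, "GREEN": 0.25, "DEAD": 0.05}
    )
    session_draw: int = 20
    roster_size: int = 33
    qualification_mix: dict[str, float] = field(
        default_factory=lambda: {"paramedic": 0.576, "EMT": 0.121, "other": 0.303}
    )
    employment_mix: dict[str, float] = field(
        default_factory=lambda: {"professional": 0.727, "volunteer": 0.273}
    )
    retention: list[float] = field(default_factory=lambda: [0.667, 0.864])
    skill_base_p: float = 0.93
    qualification_offset: dict[str, float] = field(
        default_factory=lambda: {"paramedic": 0.003, "EMT": -0.002, "other": -0.008}
    )
    skill_jitter_sd: float = 0.015
    skill_decay_rate: float = 0.0148   # per month
    skill_floor: float = 0.75
    retrain_gain: float = 0.005
    retrain_before_session: int | None = 2
    pass_threshold: float = 90.0
    stop_threshold: float = 0.70
    time_mean_s: dict[str, float] = field(
        default_factory=lambda: {"RED": 45.0, "YELLOW": 40.0, "GREEN": 20.0, "DEAD": 15.0}
    )
    time_sigma: float = 0.35
    intervention_time_s: float = 0.0
    time_weights: dict[str, float] = field(
        default_factory=lambda: {"RED": 0.2, "YELLOW": 0.2, "GREEN": 0.6, "DEAD": 0.0}
    )
    under_bias: float = 1.0
    alpha: float = 0.05
    seed: int = 17

    def __post_init__(self):
        if not 0 < self.pass_threshold <= 100:
            raise ValueError("pass threshold must be in (0, 100]")
        if not 0 < self.stop_threshold <= 1:
            raise ValueError("stop-rule threshold must be in (0, 1]")
        if self.retrain_before_session is not None and not (
            0 <= self.retrain_before_session < len(self.session_months)
        ):
            raise ValueError("retrain_before_session out of range")
        if len(self.retention) < len(self.session_months) - 1:
            raise ValueError("need a retention probability per follow-up session")

    # -- typed views -------------------------------------------------------

    def load_tree(self) -> DecisionTree:
        p = Path(self.tree)
        if p.suffix in (".yaml", ".yml"):
            if not p.exists():
                raise FileNotFoundError(f"tree config {self.tree!r} does not exist")
            return load_tree(p.read_text())
        return load_bundled_tree(self.tree)

    def category_mix_typed(self) -> dict[TriageCategory, float]:
        return {TriageCategory(k): v for k, v in self.category_mix.items()}

    def time_model(self) -> TimeModel:
        return TimeModel(
            mean_s={TriageCategory(k): v for k, v in self.time_mean_s.items()},
            sigma=self.time_sigma,
            intervention_s=self.intervention_time_s,
        )

    def time_weights_typed(self) -> dict[TriageCategory, float]:
        return {TriageCategory(k): v for k, v in self.time_weights.items()}

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown study-config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# --------------------------------------------------------------------------
# Records CSV

_CRIT_COLUMNS = [f"crit_leader_{c}" for c in evaluation.LEADER_CRITERIA] + [
    f"crit_assistant_{c}" for c in evaluation.ASSISTANT_CRITERIA
]

RECORD_COLUMNS = [
    "session",
    "months_since_training",
    "vignette_id",
    "team_id",
    "leader_id",
    "assistant_id",
    "ground_truth",
    "assigned",
    "error",
    "interventions_indicated",
    "interventions_performed",
    "airway_correct",
    "bleeding_correct",
    "tag_applied",
    "time_s",
    *_CRIT_COLUMNS,
]

_CAT_TOKENS = {c.value for c in TriageCategory}


def _join_iv(ivs: Iterable[Intervention]) -> str:
    return "|".join(sorted(i.value for i in ivs))


def _split_iv(s: Any) -> frozenset[Intervention]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return frozenset()
    return frozenset(Intervention(tok) for tok in str(s).split("|"))


def records_to_frame(records: Iterable[TriageRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "session": r.session,
            "months_since_training": r.months_since_training,
            "vignette_id": r.vignette_id,
            "team_id": r.team_id,
            "leader_id": r.leader_id,
            "assistant_id": r.assistant_id,
            "ground_truth": r.ground_truth.value,
            "assigned": r.assigned.value,
            "error": r.error.value,
            "interventions_indicated": _join_iv(r.interventions_indicated),
            "interventions_performed": _join_iv(r.interventions_performed),
            "airway_correct": r.airway_correct,
            "bleeding_correct": r.bleeding_correct,
            "tag_applied": "" if r.tag_applied is None else r.tag_applied,
            "time_s": r.time_s,
        }
        for c in _CRIT_COLUMNS:
            row[c] = r.criteria[c[len("crit_"):]]
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Iterable[TriageRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records(path: str | Path) -> list[TriageRecord]:
    """Read a records CSV back into :class:`TriageRecord` objects.

    ``write_records`` followed by ``read_records`` is the identity on the
    record schema.  A malformed category token raises with the offending
    line number (header = line 1).
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[], float_precision="round_trip")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file {path}: missing columns {sorted(missing)}")
    out: list[TriageRecord] = []
    for i, row in df.iterrows():
        line = i + 2
        for col in ("ground_truth", "assigned"):
            if row[col] not in _CAT_TOKENS:
                raise ValueError(
                    f"{path}:{line}: bad triage category {row[col]!r} in column {col!r}"
                )
        criteria = {c[len("crit_"):]: _to_bool(row[c]) for c in _CRIT_COLUMNS}
        out.append(
            TriageRecord(
                vignette_id=str(row["vignette_id"]),
                team_id=str(row["team_id"]),
                leader_id=str(row["leader_id"]),
                assistant_id=str(row["assistant_id"]),
                ground_truth=TriageCategory(row["ground_truth"]),
                assigned=TriageCategory(row["assigned"]),
                error=evaluation.ErrorClass(row["error"]),
                interventions_indicated=_split_iv(row["interventions_indicated"]),
                interventions_performed=_split_iv(row["interventions_performed"]),
                airway_correct=_to_bool(row["airway_correct"]),
                bleeding_correct=_to_bool(row["bleeding_correct"]),
                tag_applied=None if row["tag_applied"] == "" else str(row["tag_applied"]),
                time_s=float(row["time_s"]),
                criteria=criteria,
                months_since_training=float(row["months_since_training"]),
                session=str(row["session"]),
            )
        )
    return out


def _to_bool(v: Any) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1")


# --------------------------------------------------------------------------
# Vignettes / roster CSV


def write_vignettes(pool: Iterable[Vignette], path: str | Path) -> None:
    rows = [
        {
            "id": v.id,
            "ground_truth": v.ground_truth.value,
            "indicated_interventions": _join_iv(v.indicated_interventions),
            "findings_json": json.dumps(v.findings, sort_keys=True),
        }
        for v in pool
    ]
    pd.DataFrame(rows, columns=["id", "ground_truth", "indicated_interventions", "findings_json"]).to_csv(
        path, index=False
    )


def read_vignettes(path: str | Path) -> list[Vignette]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    out = []
    for i, row in df.iterrows():
        if row["ground_truth"] not in _CAT_TOKENS:
            raise ValueError(f"{path}:{i + 2}: bad triage category {row['ground_truth']!r}")
        out.append(
            Vignette(
                id=str(row["id"]),
                findings=json.loads(row["findings_json"]),
                ground_truth=TriageCategory(row["ground_truth"]),
                indicated_interventions=_split_iv(row["indicated_interventions"]),
            )
        )
    return out


def write_roster(
    providers: Mapping[str, ProviderProfile],
    attendance: Mapping[str, list[str]],
    path: str | Path,
) -> None:
    rows = []
    for pid, p in providers.items():
        row = {
            "id": pid,
            "qualification": p.qualification,
            "employment": p.employment,
            "training_history": ";".join(f"{m}:{e}" for m, e in p.training_history),
        }
        for label, present in attendance.items():
            row[f"attended_{label}"] = pid in present
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_study(study: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write vignettes.csv, records.csv, roster.csv and summary.json for a
    simulated study; records carry an ``included`` flag for the Part A
    inclusion rule."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vignettes": out / "vignettes.csv",
        "records": out / "records.csv",
        "roster": out / "roster.csv",
        "summary": out / "summary.json",
    }
    write_vignettes(study.pool, paths["vignettes"])
    frames = []
    for s in study.sessions:
        f = records_to_frame(s.records)
        included = {id(r) for r in study.included_records(s)}
        f["included"] = [id(r) in included for r in s.records]
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(paths["records"], index=False)
    write_roster(study.providers, {s.label: s.roster for s in study.sessions}, paths["roster"])
    summary = {
        "n1": study.n1,
        "n2": study.n2,
        "pass_rates": study.pass_rates,
        "stop_rule_triggered": study.stop_rule_triggered,
        "session_months": [s.month for s in study.sessions],
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    return paths
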