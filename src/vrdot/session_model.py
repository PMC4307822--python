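"""Domain types, invariants, and tabular I/O for ADL session cohorts.

The central object is a :class:`CohortDataset`: a set of subjects, each
carrying demographics, per-visit neuropsychological / functional scale
scores and raw psychomotor measurements, and per-visit session event logs
from a simulated fire-evacuation drill.  A :class:`ProtocolSpec` fixes the
canonical order in which the drill's activities should be completed; the
scoring layer compares each :class:`SessionLog` against it.

Two interchangeable on-disk representations are supported:

* a single JSON document per cohort, and
* a CSV bundle of four files (``subjects.csv``, ``visits.csv``,
  ``sessions.csv``, ``events.csv``) joined by ids, which keeps event
  sequences lossless without a single ragged wide table.

Timestamps are seconds from session start, stored with millisecond
precision.  Visits are indexed 1, 2, 3 (annual assessments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

GROUPS = ("control", "aMCI", "mildAD")

#: per-visit scale / psychomotor columns (all floats; walk_steps integral)
VISIT_MEASURES = (
    "mmse",
    "bristol_adl",
    "blessed_adl",
    "gds",
    "ravlt_delayed",
    "faq",
    "tmt_a_s",
    "tmt_b_s",
    "digit_symbol",
    "walk_time_s",
    "walk_steps",
    "taps_dominant_15s",
    "taps_nondominant_15s",
    "grip_kg",
)


class SchemaError(ValueError):
    """A file does not conform to the documented cohort schema."""


class ValidationError(ValueError):
    """A domain invariant is violated; names the offending entity/field."""

    def __init__(self, message: str, subject_id: str | None = None, field: str | None = None):
        self.subject_id = subject_id
        self.field = field
        where = f" [subject={subject_id}]" if subject_id else ""
        super().__init__(message + where)


@dataclass(frozen=True)
class ProtocolSpec:
    """Canonical activity list of one evacuation scenario.

    ``activities`` lists activity ids in the order a fully competent
    participant would complete them; order errors are measured against it.
    """

    scenario_id: int
    activities: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "activities", tuple(self.activities))
        if not 1 <= self.scenario_id <= 6:
            raise ValidationError(f"scenario_id must be in 1..6, got {self.scenario_id}")
        if not self.activities:
            raise ValidationError("protocol must list at least one activity")
        if len(set(self.activities)) != len(self.activities):
            raise ValidationError("protocol activity_ids must be unique")

    def index_of(self, activity_id: str) -> int:
        return self.activities.index(activity_id)


#: default 8-step evacuation protocol.  The concrete activity list is a
#: package choice: the drill requires prioritising and sequencing subroutines
#: (size up the fire, call for help, secure the flat, get out), and eight
#: steps give the order-error metric room to vary.
DEFAULT_PROTOCOL = ProtocolSpec(
    scenario_id=2,
    activities=(
        "assess_fire",
        "call_emergency",
        "alert_neighbors",
        "gather_essentials",
        "close_doors",
        "avoid_smoke",
        "locate_exit",
        "evacuate_building",
    ),
)


@dataclass(frozen=True)
class ActivityEvent:
    """One performance of one activity inside a session.

    ``attempts`` counts tries within this single performance; repeating the
    whole activity later is a new event with the same ``activity_id``.
    """

    activity_id: str
    start_s: float
    end_s: float
    attempts: int = 1
    completed: bool = True

    def __post_init__(self):
        if self.start_s < 0:
            raise ValidationError(f"event {self.activity_id}: start_s < 0")
        if self.end_s < self.start_s:
            raise ValidationError(
                f"event {self.activity_id}: end_s ({self.end_s}) < start_s ({self.start_s})"
            )
        if self.attempts < 1:
            raise ValidationError(f"event {self.activity_id}: attempts must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SessionLog:
    """One subject-visit's event sequence in one scenario."""

    subject_id: str
    visit_year: int
    scenario_id: int
    events: tuple[ActivityEvent, ...]
    total_duration_s: float

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if self.visit_year not in (1, 2, 3):
            raise ValidationError(
                f"visit_year must be 1, 2 or 3, got {self.visit_year}", self.subject_id
            )
        if self.total_duration_s <= 0:
            raise ValidationError("total_duration_s must be > 0", self.subject_id)
        for ev in self.events:
            if ev.end_s > self.total_duration_s + 1e-9:
                raise ValidationError(
                    f"event {ev.activity_id} ends at {ev.end_s}s, beyond session "
                    f"duration {self.total_duration_s}s",
                    self.subject_id,
                )


@dataclass(frozen=True)
class ErrorCounts:
    """The four error counts the penalty weights k1..k4 act on."""

    omissions: int
    repetitions: int
    order_errors: int
    extra_attempts: int

    def __post_init__(self):
        for name in ("omissions", "repetitions", "order_errors", "extra_attempts"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.omissions, self.repetitions, self.order_errors, self.extra_attempts)


@dataclass(frozen=True)
class ScoreParams:
    """Non-negative penalty weights (k1: omission, k2: repetition,
    k3: order error, k4: extra attempt)."""

    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.k1, self.k2, self.k3, self.k4)


@dataclass(frozen=True)
class FunctionalScore:
    """Efficacy ratio (fraction of session time on protocol activities)
    and the penalty-adjusted functional index on a 0-100 scale
    (higher = better function)."""

    reff: float
    fi: float

    def __post_init__(self):
        if not 0.0 <= self.reff <= 1.0:
            raise ValidationError(f"reff must lie in [0,1], got {self.reff}")
        if not 0.0 <= self.fi <= 100.0 + 1e-9:
            raise ValidationError(f"fi must lie in [0,100], got {self.fi}")


@dataclass
class SubjectRecord:
    """One participant: demographics, per-visit measures, sessions, outcome."""

    subject_id: str
    group: str
    age: float
    sex: str  # "M" / "F"
    education_years: float
    knee_heel_cm: float
    visits: dict[int, dict[str, float]] = field(default_factory=dict)
    sessions: list[SessionLog] = field(default_factory=list)
    converted_to_ad: Optional[bool] = None  # aMCI only
    dropout: bool = False

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(
                f"group must be one of {GROUPS}, got {self.group!r}", self.subject_id, "group"
            )
        for year, meas in self.visits.items():
            if year not in (1, 2, 3):
                raise ValidationError(f"visit year {year} out of range", self.subject_id)
            mmse = meas.get("mmse")
            if mmse is not None and not 0 <= mmse <= 30:
                raise ValidationError(
                    f"MMSE in [0,30] violated (value {mmse})", self.subject_id, "mmse"
                )
            steps = meas.get("walk_steps")
            if steps is not None and steps < 1:
                raise ValidationError("walk_steps >= 1 violated", self.subject_id, "walk_steps")
        for s in self.sessions:
            if s.subject_id != self.subject_id:
                raise ValidationError(
                    f"session subject_id {s.subject_id!r} mismatch", self.subject_id
                )

    def session_for(self, visit_year: int) -> Optional[SessionLog]:
        for s in self.sessions:
            if s.visit_year == visit_year:
                return s
        return None

    @property
    def completed_visits(self) -> list[int]:
        return sorted(self.visits)


@dataclass
class CohortDataset:
    """A validated cohort plus its protocol and provenance note."""

    subjects: list[SubjectRecord]
    protocol: ProtocolSpec = DEFAULT_PROTOCOL
    provenance: str = ""

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject_ids: {dup}")

    def __len__(self) -> int:
        return len(self.subjects)

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


# ---------------------------------------------------------------------------
# validation


def validate_session(session: SessionLog, protocol: ProtocolSpec) -> list[str]:
    """Return a list of human-readable violation descriptors (empty if clean).

    Violations are returned, never raised: the loader uses this to name
    problems, and callers may choose to tolerate some.
    """
    violations: list[str] = []
    known = set(protocol.activities)
    for ev in session.events:
        if ev.activity_id not in known:
            violations.append(f"unknown activity {ev.activity_id!r}")
    # overlapping performances of the same activity
    by_act: dict[str, list[ActivityEvent]] = {}
    for ev in session.events:
        by_act.setdefault(ev.activity_id, []).append(ev)
    for act, evs in by_act.items():
        evs = sorted(evs, key=lambda e: (e.start_s, e.end_s))
        for a, b in zip(evs, evs[1:]):
            if b.start_s < a.end_s - 1e-9:
                violations.append(
                    f"overlapping events for activity {act!r} "
                    f"([{a.start_s},{a.end_s}] vs [{b.start_s},{b.end_s}])"
                )
    for ev in session.events:
        if ev.end_s > session.total_duration_s + 1e-9:
            violations.append(f"event {ev.activity_id!r} extends past session end")
    return violations


# ---------------------------------------------------------------------------
# JSON serialisation


def _round3(x: float) -> float:
    return round(float(x), 3)


def _event_to_dict(ev: ActivityEvent) -> dict:
    return {
        "activity_id": ev.activity_id,
        "start_s": _round3(ev.start_s),
        "end_s": _round3(ev.end_s),
        "attempts": ev.attempts,
        "completed": ev.completed,
    }


def _session_to_dict(s: SessionLog) -> dict:
    return {
        "subject_id": s.subject_id,
        "visit_year": s.visit_year,
        "scenario_id": s.scenario_id,
        "total_duration_s": _round3(s.total_duration_s),
        "events": [_event_to_dict(e) for e in s.events],
    }


def cohort_to_dict(cohort: CohortDataset) -> dict:
    return {
        "provenance": cohort.provenance,
        "protocol": {
            "scenario_id": cohort.protocol.scenario_id,
            "activities": list(cohort.protocol.activities),
        },
        "subjects": [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "education_years": s.education_years,
                "knee_heel_cm": s.knee_heel_cm,
                "converted_to_ad": s.converted_to_ad,
                "dropout": s.dropout,
                "visits": {str(y): dict(m) for y, m in sorted(s.visits.items())},
                "sessions": [_session_to_dict(x) for x in s.sessions],
            }
            for s in cohort.subjects
        ],
    }


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise SchemaError(f"missing required field {key!r} in {ctx}")
    return d[key]


def cohort_from_dict(doc: dict) -> CohortDataset:
    proto = _require(doc, "protocol", "cohort document")
    protocol = ProtocolSpec(
        scenario_id=int(_require(proto, "scenario_id", "protocol")),
        activities=tuple(_require(proto, "activities", "protocol")),
    )
    subjects = []
    for sd in _require(doc, "subjects", "cohort document"):
        sid = _require(sd, "subject_id", "subject")
        sessions = []
        for ss in sd.get("sessions", []):
            events = tuple(
                ActivityEvent(
                    activity_id=_require(ed, "activity_id", f"event of {sid}"),
                    start_s=float(_require(ed, "start_s", f"event of {sid}")),
                    end_s=float(_require(ed, "end_s", f"event of {sid}")),
                    attempts=int(ed.get("attempts", 1)),
                    completed=bool(ed.get("completed", True)),
                )
                for ed in ss.get("events", [])
            )
            sessions.append(
                SessionLog(
                    subject_id=sid,
                    visit_year=int(_require(ss, "visit_year", f"session of {sid}")),
                    scenario_id=int(ss.get("scenario_id", protocol.scenario_id)),
                    events=events,
                    total_duration_s=float(_require(ss, "total_duration_s", f"session of {sid}")),
                )
            )
        visits = {
            int(y): {k: (float(v) if v is not None else None) for k, v in meas.items()}
            for y, meas in sd.get("visits", {}).items()
        }
        conv = sd.get("converted_to_ad")
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=_require(sd, "group", f"subject {sid}"),
                age=float(_require(sd, "age", f"subject {sid}")),
                sex=str(sd.get("sex", "")),
                education_years=float(sd.get("education_years", float("nan"))),
                knee_heel_cm=float(sd.get("knee_heel_cm", 50.0)),
                visits=visits,
                sessions=sessions,
                converted_to_ad=None if conv is None else bool(conv),
                dropout=bool(sd.get("dropout", False)),
            )
        )
    return CohortDataset(
        subjects=subjects, protocol=protocol, provenance=str(doc.get("provenance", ""))
    )


# ---------------------------------------------------------------------------
# CSV bundle serialisation

_CSV_FILES = ("subjects.csv", "visits.csv", "sessions.csv", "events.csv")


def _cohort_to_frames(cohort: CohortDataset) -> dict[str, pd.DataFrame]:
    subj_rows, visit_rows, sess_rows, ev_rows = [], [], [], []
    for s in cohort.subjects:
        subj_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "education_years": s.education_years,
                "knee_heel_cm": s.knee_heel_cm,
                "converted_to_ad": "" if s.converted_to_ad is None else int(s.converted_to_ad),
                "dropout": int(s.dropout),
            }
        )
        for year, meas in sorted(s.visits.items()):
            row = {"subject_id": s.subject_id, "visit_year": year}
            row.update({k: meas.get(k) for k in VISIT_MEASURES})
            visit_rows.append(row)
        for i, sess in enumerate(s.sessions):
            sess_id = f"{s.subject_id}_y{sess.visit_year}"
            sess_rows.append(
                {
                    "session_id": sess_id,
                    "subject_id": s.subject_id,
                    "visit_year": sess.visit_year,
                    "scenario_id": sess.scenario_id,
                    "total_duration_s": _round3(sess.total_duration_s),
                }
            )
            for j, ev in enumerate(sess.events):
                ev_rows.append(
                    {
                        "session_id": sess_id,
                        "event_index": j,
                        "activity_id": ev.activity_id,
                        "start_s": _round3(ev.start_s),
                        "end_s": _round3(ev.end_s),
                        "attempts": ev.attempts,
                        "completed": int(ev.completed),
                    }
                )
    return {
        "subjects.csv": pd.DataFrame(
            subj_rows,
            columns=[
                "subject_id", "group", "age", "sex", "education_years",
                "knee_heel_cm", "converted_to_ad", "dropout",
            ],
        ),
        "visits.csv": pd.DataFrame(
            visit_rows, columns=["subject_id", "visit_year", *VISIT_MEASURES]
        ),
        "sessions.csv": pd.DataFrame(
            sess_rows,
            columns=["session_id", "subject_id", "visit_year", "scenario_id", "total_duration_s"],
        ),
        "events.csv": pd.DataFrame(
            ev_rows,
            columns=[
                "session_id", "event_index", "activity_id",
                "start_s", "end_s", "attempts", "completed",
            ],
        ),
    }


def _cohort_from_frames(
    frames: dict[str, pd.DataFrame], protocol: ProtocolSpec, provenance: str
) -> CohortDataset:
    subs = frames["subjects.csv"]
    visits = frames["visits.csv"]
    sess = frames["sessions.csv"]
    events = frames["events.csv"]
    for fname, df, cols in [
        ("subjects.csv", subs, ["subject_id", "group", "age"]),
        ("visits.csv", visits, ["subject_id", "visit_year"]),
        ("sessions.csv", sess, ["session_id", "subject_id", "visit_year", "total_duration_s"]),
        ("events.csv", events, ["session_id", "activity_id", "start_s", "end_s"]),
    ]:
        for c in cols:
            if c not in df.columns:
                raise SchemaError(f"missing required column {c!r} in {fname}")
    ev_by_sess = dict(tuple(events.groupby("session_id", sort=False))) if len(events) else {}
    subjects = []
    for _, row in subs.iterrows():
        sid = str(row["subject_id"])
        svis = visits[visits["subject_id"] == sid]
        vdict = {}
        for _, vr in svis.iterrows():
            meas = {}
            for k in VISIT_MEASURES:
                if k in svis.columns and pd.notna(vr[k]):
                    meas[k] = float(vr[k])
            vdict[int(vr["visit_year"])] = meas
        slist = []
        ssess = sess[sess["subject_id"] == sid]
        for _, sr in ssess.iterrows():
            sevs = ev_by_sess.get(sr["session_id"])
            evs: tuple[ActivityEvent, ...] = ()
            if sevs is not None:
                sevs = sevs.sort_values("event_index")
                evs = tuple(
                    ActivityEvent(
                        activity_id=str(er["activity_id"]),
                        start_s=float(er["start_s"]),
                        end_s=float(er["end_s"]),
                        attempts=int(er["attempts"]),
                        completed=bool(int(er["completed"])),
                    )
                    for _, er in sevs.iterrows()
                )
            slist.append(
                SessionLog(
                    subject_id=sid,
                    visit_year=int(sr["visit_year"]),
                    scenario_id=int(sr["scenario_id"]),
                    events=evs,
                    total_duration_s=float(sr["total_duration_s"]),
                )
            )
        conv = row["converted_to_ad"]
        conv_val = None if (pd.isna(conv) or conv == "") else bool(int(conv))
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education_years=float(row["education_years"]),
                knee_heel_cm=float(row["knee_heel_cm"]),
                visits=vdict,
                sessions=slist,
                converted_to_ad=conv_val,
                dropout=bool(int(row["dropout"])),
            )
        )
    return CohortDataset(subjects=subjects, protocol=protocol, provenance=provenance)


# ---------------------------------------------------------------------------
# public I/O


def write_cohort(cohort: CohortDataset, path: str | Path, format: str = "json") -> None:
    """Write a cohort to ``path``.

    ``format="json"``: one document at ``path``.  ``format="csv-bundle"``:
    ``path`` is a directory receiving the four CSV files plus a small
    ``meta.json`` holding the protocol and provenance.  Writes are
    deterministic: the same cohort always produces identical bytes.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(cohort_to_dict(cohort), indent=1, sort_keys=True) + "\n")
    elif format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        frames = _cohort_to_frames(cohort)
        for fname, df in frames.items():
            df.to_csv(path / fname, index=False)
        meta = {
            "provenance": cohort.provenance,
            "protocol": {
                "scenario_id": cohort.protocol.scenario_id,
                "activities": list(cohort.protocol.activities),
            },
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_cohort(path: str | Path, format: str = "json") -> CohortDataset:
    """Load and fully validate a cohort written by :func:`write_cohort`."""
    path = Path(path)
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise SchemaError(f"{path} is not valid JSON: {e}") from e
        return cohort_from_dict(doc)
    if format == "csv-bundle":
        frames = {}
        for fname in _CSV_FILES:
            fpath = path / fname
            if not fpath.exists():
                raise SchemaError(f"missing required file {fname} in bundle {path}")
            frames[fname] = pd.read_csv(fpath)
        meta = json.loads((path / "meta.json").read_text())
        protocol = ProtocolSpec(
            scenario_id=int(meta["protocol"]["scenario_id"]),
            activities=tuple(meta["protocol"]["activities"]),
        )
        return _cohort_from_frames(frames, protocol, str(meta.get("provenance", "")))
    raise ValueError(f"unknown format {format!r}")
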