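"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from vrdot.session_model import (
    ActivityEvent,
    CohortDataset,
    ProtocolSpec,
    SessionLog,
    SubjectRecord,
)


@pytest.fixture
def protocol5() -> ProtocolSpec:
    return ProtocolSpec(scenario_id=1, activities=("A", "B", "C", "D", "E"))


def make_session(subject_id, events, total=None, visit_year=1, scenario_id=1):
    """Build a SessionLog from (activity, start, end[, attempts[, completed]]) tuples."""
    evs = []
    for e in events:
        act, start, end = e[0], e[1], e[2]
        attempts = e[3] if len(e) > 3 else 1
        completed = e[4] if len(e) > 4 else True
        evs.append(ActivityEvent(act, float(start), float(end), attempts, completed))
    if total is None:
        total = max((ev.end_s for ev in evs), default=10.0)
    return SessionLog(subject_id, visit_year, scenario_id, tuple(evs), float(total))


@pytest.fixture
def tiny_cohort(protocol5) -> CohortDataset:
    """Three subjects, one per group, 1-3 visits each."""
    subjects = []
    for i, (group, years) in enumerate(
        [("control", (1, 2, 3)), ("aMCI", (1, 2, 3)), ("mildAD", (1,))]
    ):
        sid = f"s{i + 1}"
        sessions = [
            make_session(
                sid,
                [("A", 0, 10), ("B", 12, 20), ("C", 22, 30), ("D", 31, 40), ("E", 41, 50)],
                total=60 + 5 * y,
                visit_year=y,
            )
            for y in years
        ]
        visits = {
            y: {
                "mmse": 28.0 - 2 * i - 0.5 * (y - 1),
                "bristol_adl": 5.0 + 2 * i + 0.5 * (y - 1),
                "blessed_adl": 2.0 + i,
                "ravlt_delayed": 7.0 - 2 * i,
                "walk_time_s": 5.0 + i,
                "walk_steps": 8.0,
                "taps_dominant_15s": 57.0 - 3 * i,
                "taps_nondominant_15s": 54.0,
                "grip_kg": 30.0 - 2 * i,
            }
            for y in years
        }
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                age=70.0 + i,
                sex="M" if i % 2 == 0 else "F",
                education_years=12.0 + i,
                knee_heel_cm=48.0 + i,
                visits=visits,
                sessions=sessions,
                converted_to_ad=(True if group == "aMCI" else None),
                dropout=(group == "mildAD"),
            )
        )
    return CohortDataset(subjects=subjects, protocol=protocol5, provenance="fixture")


# --------------------------------------------------------------------------
# independent oracles


def brute_force_lis(seq) -> int:
    """Longest strictly increasing subsequence by exhaustive enumeration."""
    best = 0
    n = len(seq)
    for r in range(n, 0, -1):
        for idx in combinations(range(n), r):
            vals = [seq[i] for i in idx]
            if all(a < b for a, b in zip(vals, vals[1:])):
                return r
    return best


def brute_force_auc(pos, neg) -> float:
    """Mann-Whitney probability by exhaustive pairwise comparison."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_counts(session: SessionLog, protocol: ProtocolSpec):
    """Independent re-derivation of (O, R, W, A) by direct definition."""
    completed = [e for e in session.events if e.completed]
    per_act = {}
    for e in sorted(completed, key=lambda e: (e.end_s, e.start_s)):
        per_act.setdefault(e.activity_id, []).append(e)
    O = sum(1 for a in protocol.activities if a not in per_act)
    R = sum(len(v) - 1 for v in per_act.values())
    firsts = sorted((v[0] for v in per_act.values()), key=lambda e: (e.end_s, e.start_s))
    order = [protocol.activities.index(e.activity_id) for e in firsts]
    W = len(order) - brute_force_lis(order)
    A = sum(v[0].attempts - 1 for v in per_act.values())
    return (O, R, W, A)
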