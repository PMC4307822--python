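"""Session scoring: error extraction, efficacy ratio, functional index.

A session is scored against the protocol's canonical activity order.  Four
error counts are extracted:

* **O** — omissions: protocol activities never completed in the session;
* **R** — repetitions: completed performances beyond the first, per activity;
* **W** — order errors: the longest-increasing-subsequence deficit of the
  first-completion order mapped onto protocol indices (equivalently, the
  minimum number of activities one must delete to restore protocol order);
* **A** — extra attempts: attempts beyond the first on each activity's first
  completed performance (retries inside later repetitions are already
  penalised through R).

The efficacy ratio ``REff`` is the fraction of session time spent on
protocol activities.  The functional index adjusts it by a rational penalty::

    FI = 100 * REff / (1 + k1*O + k2*R + k3*W + k4*A)

which reduces to ``100*REff`` at zero errors, stays in [0, 100], and is
monotone decreasing in every error count — the properties the calibration
procedure relies on.  Higher FI means better function.  The penalty form is
a single replaceable strategy (:func:`penalised_index`).
"""

from __future__ import annotations

import bisect
from typing import Sequence

import pandas as pd

from .session_model import (
    CohortDataset,
    ErrorCounts,
    FunctionalScore,
    ProtocolSpec,
    ScoreParams,
    SessionLog,
    ValidationError,
    validate_session,
)


def longest_increasing_subsequence(seq: Sequence[int]) -> int:
    """Length of the longest strictly increasing subsequence (patience sort)."""
    tails: list[int] = []
    for x in seq:
        i = bisect.bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def _first_completions(session: SessionLog) -> list:
    """First completed event per activity, in order of completion time."""
    first: dict[str, object] = {}
    for ev in sorted(session.events, key=lambda e: (e.end_s, e.start_s)):
        if ev.completed and ev.activity_id not in first:
            first[ev.activity_id] = ev
    return sorted(first.values(), key=lambda e: (e.end_s, e.start_s))


def count_errors(session: SessionLog, protocol: ProtocolSpec) -> ErrorCounts:
    """Extract the four error counts of a session against the protocol.

    Raises :class:`ValidationError` if the session fails
    :func:`~vrdot.session_model.validate_session`.
    """
    violations = validate_session(session, protocol)
    if violations:
        raise ValidationError(
            f"invalid session ({'; '.join(violations)})", session.subject_id
        )
    completed_by_act: dict[str, int] = {}
    for ev in session.events:
        if ev.completed:
            completed_by_act[ev.activity_id] = completed_by_act.get(ev.activity_id, 0) + 1

    omissions = sum(1 for a in protocol.activities if completed_by_act.get(a, 0) == 0)
    repetitions = sum(max(n - 1, 0) for n in completed_by_act.values())

    firsts = _first_completions(session)
    order = [protocol.index_of(ev.activity_id) for ev in firsts]
    order_errors = len(order) - longest_increasing_subsequence(order)

    extra_attempts = sum(ev.attempts - 1 for ev in firsts)
    return ErrorCounts(omissions, repetitions, order_errors, extra_attempts)


def _union_length(intervals: list[tuple[float, float]]) -> float:
    """Total length of the union of closed intervals."""
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total = 0.0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return total + (cur_hi - cur_lo)


def efficacy_ratio(session: SessionLog, protocol: ProtocolSpec) -> float:
    """Fraction of total session time spent performing protocol activities.

    Overlapping intervals of the same activity are unioned before summing;
    the result is clamped to [0, 1].
    """
    if session.total_duration_s <= 0:
        raise ValidationError("total_duration_s must be > 0", session.subject_id)
    known = set(protocol.activities)
    by_act: dict[str, list[tuple[float, float]]] = {}
    for ev in session.events:
        if ev.activity_id in known:
            by_act.setdefault(ev.activity_id, []).append((ev.start_s, ev.end_s))
    active = sum(_union_length(iv) for iv in by_act.values())
    return min(max(active / session.total_duration_s, 0.0), 1.0)


def penalised_index(reff: float, counts: ErrorCounts, params: ScoreParams) -> float:
    """Rational-penalty functional index on the 0-100 scale."""
    k1, k2, k3, k4 = params.as_tuple()
    o, r, w, a = counts.as_tuple()
    return 100.0 * reff / (1.0 + k1 * o + k2 * r + k3 * w + k4 * a)


def functional_index(
    session: SessionLog, protocol: ProtocolSpec, params: ScoreParams
) -> FunctionalScore:
    """Score one session: (efficacy ratio, penalty-adjusted index)."""
    reff = efficacy_ratio(session, protocol)
    counts = count_errors(session, protocol)
    return FunctionalScore(reff=reff, fi=penalised_index(reff, counts, params))


def score_cohort(cohort: CohortDataset, params: ScoreParams) -> pd.DataFrame:
    """Score every subject-visit session in a cohort.

    Returns a tidy frame with columns ``subject_id, visit_year, reff, fi``
    plus the raw error counts, one row per session, deterministic order
    (subject order of the cohort, then visit year).
    """
    rows = []
    for subj in cohort.subjects:
        for sess in sorted(subj.sessions, key=lambda s: s.visit_year):
            try:
                counts = count_errors(sess, cohort.protocol)
                reff = efficacy_ratio(sess, cohort.protocol)
            except ValidationError as e:
                raise ValidationError(
                    f"scoring failed for visit {sess.visit_year}: {e}", subj.subject_id
                ) from e
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "visit_year": sess.visit_year,
                    "reff": reff,
                    "fi": penalised_index(reff, counts, params),
                    "omissions": counts.omissions,
                    "repetitions": counts.repetitions,
                    "order_errors": counts.order_errors,
                    "extra_attempts": counts.extra_attempts,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "visit_year", "reff", "fi",
            "omissions", "repetitions", "order_errors", "extra_attempts",
        ],
    )
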