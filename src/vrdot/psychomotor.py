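"""Derived psychomotor metrics: gait speed, stride length, tapping rate,
grip, and the 50-cm knee-heel normalisation.

The walk course is 4.6 m; tapping trials last 15 s.  Gait speed and stride
length can be normalised to a reference lower-leg (knee-heel) length of
50 cm by multiplicative scaling, removing stature effects before group
comparison.  The normalisation is the identity at 50 cm and is
scale-equivariant, so it can be applied before or after unit conversion.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .session_model import CohortDataset

WALK_COURSE_M = 4.6
TAP_DURATION_S = 15.0
REFERENCE_KNEE_HEEL_CM = 50.0


class DomainError(ValueError):
    """Input outside the metric's domain (e.g. non-positive time)."""


def gait_speed(time_s: float, distance_m: float = WALK_COURSE_M) -> float:
    """Usual-pace walking speed in m/s over a timed course."""
    if time_s <= 0:
        raise DomainError(f"walk time must be > 0 s, got {time_s}")
    return distance_m / time_s


def stride_length(steps: float, distance_m: float = WALK_COURSE_M) -> float:
    """Mean stride length in m: distance walked over number of steps."""
    if steps < 1:
        raise DomainError(f"steps must be >= 1, got {steps}")
    return distance_m / steps


def knee_heel_adjust(value: float, knee_heel_cm: float) -> float:
    """Normalise a gait quantity to the 50-cm reference knee-heel length."""
    if knee_heel_cm <= 0:
        raise DomainError(f"knee-heel length must be > 0 cm, got {knee_heel_cm}")
    return value * (REFERENCE_KNEE_HEEL_CM / knee_heel_cm)


def tapping_rate(n_taps: float, duration_s: float = TAP_DURATION_S) -> float:
    """Finger-tapping rate in taps/second."""
    if duration_s <= 0:
        raise DomainError(f"duration must be > 0 s, got {duration_s}")
    if n_taps < 0:
        raise DomainError(f"tap count must be >= 0, got {n_taps}")
    return n_taps / duration_s


def grip_best(attempts: Iterable[float]) -> float:
    """Best of up to 3 dynamometer attempts (kg), dominant hand."""
    vals = [v for v in attempts if v is not None and not np.isnan(v)]
    if not vals or len(vals) > 3:
        raise DomainError("grip strength needs 1-3 recorded attempts")
    return max(vals)


#: derived-metric columns emitted by :func:`derive_metrics`
DERIVED_COLUMNS = (
    "gait_speed_ms", "stride_length_m",
    "gait_speed_adj", "stride_length_adj",
    "tap_rate_dom", "tap_rate_nondom", "grip_kg",
)


def derive_metrics(cohort: CohortDataset, adjust: str = "apply") -> pd.DataFrame:
    """Compute derived psychomotor metrics for every subject-visit.

    ``adjust`` controls the knee-heel normalisation of gait speed and
    stride length: ``"apply"`` always normalises, ``"skip"`` never does,
    ``"auto"`` applies it only if the knee-heel covariate relates to gait
    speed at the 10% level across the cohort (tested by OLS on the pooled
    baseline rows).  Adjusted values are emitted alongside the raw ones;
    downstream models use the ``*_adj`` columns by default.
    """
    if adjust not in ("apply", "skip", "auto"):
        raise ValueError("adjust must be one of 'apply', 'skip', 'auto'")
    rows = []
    for subj in cohort.subjects:
        for year, meas in sorted(subj.visits.items()):
            row: dict = {"subject_id": subj.subject_id, "visit_year": year}
            wt, ws = meas.get("walk_time_s"), meas.get("walk_steps")
            row["gait_speed_ms"] = gait_speed(wt) if wt else np.nan
            row["stride_length_m"] = stride_length(ws) if ws else np.nan
            td, tn = meas.get("taps_dominant_15s"), meas.get("taps_nondominant_15s")
            row["tap_rate_dom"] = tapping_rate(td) if td is not None else np.nan
            row["tap_rate_nondom"] = tapping_rate(tn) if tn is not None else np.nan
            row["grip_kg"] = meas.get("grip_kg", np.nan)
            row["knee_heel_cm"] = subj.knee_heel_cm
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df

    do_adjust = adjust == "apply"
    if adjust == "auto":
        do_adjust = _knee_heel_significant(df)
    if do_adjust:
        factor = REFERENCE_KNEE_HEEL_CM / df["knee_heel_cm"]
        df["gait_speed_adj"] = df["gait_speed_ms"] * factor
        df["stride_length_adj"] = df["stride_length_m"] * factor
    else:
        df["gait_speed_adj"] = df["gait_speed_ms"]
        df["stride_length_adj"] = df["stride_length_m"]
    return df.drop(columns=["knee_heel_cm"])


def _knee_heel_significant(df: pd.DataFrame, alpha: float = 0.10) -> bool:
    """Does knee-heel length predict gait speed at the ``alpha`` level?"""
    import statsmodels.api as sm

    base = df[df["visit_year"] == df["visit_year"].min()]
    sub = base[["gait_speed_ms", "knee_heel_cm"]].dropna()
    if len(sub) < 10:
        return False
    X = sm.add_constant(sub["knee_heel_cm"].to_numpy())
    fit = sm.OLS(sub["gait_speed_ms"].to_numpy(), X).fit()
    return bool(fit.pvalues[1] < alpha)
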