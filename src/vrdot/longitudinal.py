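"""Annual rates of change over visits 1-3.

The random-intercept/random-slope model for a measure y of subject i at
visit time t (years since baseline, 0/1/2) is::

    y_it = (b0 + u0i) + (b1 + u1i) * t + e_it

It is estimated by a transparent two-stage procedure: ordinary least
squares per subject (the within-subject fit is saturated or near-saturated
with 2-3 visits), followed by precision-weighted pooling with
empirical-Bayes-style shrinkage of each subject's slope toward its group
mean.  With balanced visits this two-stage estimator of the mean slope
coincides with the mixed-model generalised-least-squares estimator; a hook
(`reml_backend`) allows swapping in a full REML fit via statsmodels
MixedLM for unbalanced designs.

Slopes are reported in measure units per year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .session_model import CohortDataset


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class TrajectoryFit:
    """Per-subject OLS line through (visit_year, value) points."""

    subject_id: str
    measure: str
    intercept: float  # value at visit year 1
    slope: float  # units per year
    n_visits: int
    residual_sd: float
    slope_se: float  # OLS SE of the slope; 0 for a saturated 2-point fit


@dataclass
class PooledSlopes:
    """Pooled slope estimates for one measure across subjects."""

    measure: str
    mean_slope: float
    se: float
    group_means: dict[str, float]
    subject_slopes: pd.DataFrame  # subject_id, group, slope, shrunken_slope
    between_sd: float  # estimated SD of true subject slopes


def fit_subject_trajectory(
    series: Sequence[tuple[int, float]], subject_id: str = "", measure: str = ""
) -> TrajectoryFit:
    """OLS line through a subject's (visit_year, value) points.

    Time is coded internally as years since visit 1; the reported intercept
    is the fitted value at visit 1.
    """
    pts = [(int(t), float(v)) for t, v in series if v is not None and not np.isnan(v)]
    years = sorted({t for t, _ in pts})
    if len(pts) < 2 or len(years) < 2:
        raise DomainError("need >= 2 visits at >= 2 distinct years for a slope")
    t = np.array([p[0] - 1 for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    n = len(t)
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    if sxx == 0:
        raise DomainError("identical visit years: degenerate design")
    slope = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * tbar)
    resid = y - (intercept + slope * t)
    if n > 2:
        s2 = float(np.sum(resid**2) / (n - 2))
    else:
        s2 = 0.0
    return TrajectoryFit(
        subject_id=subject_id,
        measure=measure,
        intercept=intercept,
        slope=slope,
        n_visits=n,
        residual_sd=float(np.sqrt(s2)),
        slope_se=float(np.sqrt(s2 / sxx)),
    )


def pool_slopes(
    fits: Sequence[TrajectoryFit], groups: Mapping[str, str] | None = None
) -> PooledSlopes:
    """Pool per-subject slopes: overall/group means, SE, and shrinkage.

    The between-subject slope variance tau^2 is estimated by moments
    (variance of raw slopes minus mean squared within-subject SE, floored
    at 0).  Each subject's slope is shrunk toward its group mean with
    weight w_i = tau^2 / (tau^2 + se_i^2) — full trust in exact
    (zero-residual) fits, heavy shrinkage of noisy ones.  Shrinkage never
    moves a slope past its group mean.
    """
    if not fits:
        raise DomainError("no trajectory fits to pool")
    measures = {f.measure for f in fits}
    if len(measures) > 1:
        raise DomainError(f"fits mix measures: {sorted(measures)}")
    groups = groups or {}
    slopes = np.array([f.slope for f in fits])
    ses = np.array([f.slope_se for f in fits])
    n = len(slopes)
    mean_slope = float(slopes.mean())
    se = float(slopes.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")

    if n >= 2:
        tau2 = max(float(slopes.var(ddof=1)) - float(np.mean(ses**2)), 0.0)
    else:
        tau2 = 0.0

    glab = [groups.get(f.subject_id, "all") for f in fits]
    df = pd.DataFrame(
        {"subject_id": [f.subject_id for f in fits], "group": glab, "slope": slopes, "se": ses}
    )
    gmeans = df.groupby("group")["slope"].mean().to_dict()
    denom = tau2 + ses**2
    with np.errstate(invalid="ignore"):
        w = np.where(denom > 0, tau2 / np.where(denom > 0, denom, 1.0), 1.0)
    gm = df["group"].map(gmeans).to_numpy()
    df["shrunken_slope"] = gm + w * (slopes - gm)
    df = df.drop(columns=["se"])
    return PooledSlopes(
        measure=next(iter(measures)),
        mean_slope=mean_slope,
        se=se,
        group_means={k: float(v) for k, v in gmeans.items()},
        subject_slopes=df,
        between_sd=float(np.sqrt(tau2)),
    )


def rate_of_change_features(
    long_values: pd.DataFrame,
    measures: Sequence[str] | None = None,
    slopes: str = "raw",
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Baseline value and annual slope per subject for each measure.

    ``long_values`` is a tidy frame with columns ``subject_id, visit_year``
    plus one column per measure (e.g. the merged output of scoring,
    psychomotor derivation and the visit scales; see
    :func:`measurement_table`).  For every requested measure the output
    carries ``<measure>_baseline`` (the year-1 value) and
    ``<measure>_slope`` (units/year; NaN for subjects with one usable
    visit).  ``slopes="shrunken"`` replaces raw OLS slopes with their
    group-shrunken counterparts.
    """
    if slopes not in ("raw", "shrunken"):
        raise ValueError("slopes must be 'raw' or 'shrunken'")
    required = {"subject_id", "visit_year"}
    if not required <= set(long_values.columns):
        raise DomainError("long_values needs subject_id and visit_year columns")
    if measures is None:
        measures = [c for c in long_values.columns if c not in required]
    out = pd.DataFrame({"subject_id": long_values["subject_id"].unique()})
    for m in measures:
        if m not in long_values.columns:
            raise DomainError(f"measure {m!r} not present in long_values")
        base, slope_map, fits = {}, {}, []
        for sid, sub in long_values.groupby("subject_id", sort=False):
            sub = sub.dropna(subset=[m])
            b = sub.loc[sub["visit_year"] == 1, m]
            base[sid] = float(b.iloc[0]) if len(b) else np.nan
            pts = list(zip(sub["visit_year"], sub[m]))
            if len({t for t, _ in pts}) >= 2:
                fit = fit_subject_trajectory(pts, subject_id=sid, measure=m)
                fits.append(fit)
                slope_map[sid] = fit.slope
            else:
                slope_map[sid] = np.nan
        if slopes == "shrunken" and len(fits) >= 2:
            pooled = pool_slopes(fits, groups=groups)
            shr = dict(
                zip(pooled.subject_slopes["subject_id"], pooled.subject_slopes["shrunken_slope"])
            )
            slope_map.update(shr)
        out[f"{m}_baseline"] = out["subject_id"].map(base)
        out[f"{m}_slope"] = out["subject_id"].map(slope_map)
    return out


def measurement_table(
    cohort: CohortDataset,
    scores: pd.DataFrame | None = None,
    derived: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge visit scales, session scores and derived psychomotor metrics
    into one tidy (subject_id, visit_year, measure...) frame."""
    rows = []
    for subj in cohort.subjects:
        for year, meas in sorted(subj.visits.items()):
            row = {"subject_id": subj.subject_id, "visit_year": year}
            row.update(meas)
            rows.append(row)
    df = pd.DataFrame(rows)
    for extra in (scores, derived):
        if extra is not None:
            df = df.merge(extra, on=["subject_id", "visit_year"], how="left")
    return df
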