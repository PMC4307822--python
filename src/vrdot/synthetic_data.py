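"""Synthetic three-group cohort generator.

Emulates the statistical structure the analysis pipeline assumes: three
diagnostic groups (healthy controls, amnestic MCI, mild Alzheimer-type
dementia) with annual visits over three years; scale and psychomotor
baselines drawn from truncated normals anchored to the study cohort's
published group means/SDs; group-dependent session error processes;
per-subject linear decline trajectories induced by random
intercepts/slopes; and conversion-to-dementia labels for the aMCI group
driven by each subject's realised efficacy-ratio slope.

The generator is built to be the scorer's inverse: error counts
(O, R, W, A) are drawn first and the session event log is then constructed
so that :func:`vrdot.scoring.count_errors` recovers those counts exactly —

* omissions: O activities are simply never performed;
* order errors: the performed activities are sequenced as the W largest
  protocol indices in decreasing order followed by the rest in increasing
  order, a permutation whose longest-increasing-subsequence deficit is
  exactly W;
* repetitions and extra attempts are layered on without disturbing the
  first-completion order.

The target efficacy ratio is likewise realised exactly by sizing the idle
(non-activity) time.  Timing noise is log-normal.

Everything is driven by a single integer seed through
``numpy.random.default_rng``; identical seeds give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .session_model import (
    DEFAULT_PROTOCOL,
    GROUPS,
    ActivityEvent,
    CohortDataset,
    ProtocolSpec,
    SessionLog,
    SubjectRecord,
    ValidationError,
)

# (mean, sd, lower bound, upper bound) per measure, per group — baselines
# anchored to the published cohort tables (controls / aMCI / mild AD).
_SCALE_ANCHORS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "mmse": {
        "control": (29.1, 1.0, 0, 30),
        "aMCI": (26.1, 1.8, 0, 30),
        "mildAD": (23.4, 2.0, 0, 30),
    },
    "ravlt_delayed": {
        "control": (7.4, 3.7, 0, 15),
        "aMCI": (2.9, 3.3, 0, 15),
        "mildAD": (0.7, 1.6, 0, 15),
    },
    "gds": {
        "control": (4.59, 4.1, 0, 15),
        "aMCI": (5.49, 5.76, 0, 15),
        "mildAD": (5.29, 4.45, 0, 15),
    },
    "faq": {
        "control": (0.1, 0.6, 0, 30),
        "aMCI": (3.8, 4.4, 0, 30),
        "mildAD": (12.7, 6.7, 0, 30),
    },
    "tmt_a_s": {
        "control": (36.3, 13.0, 10, 300),
        "aMCI": (44.2, 21.7, 10, 300),
        "mildAD": (64.8, 34.5, 10, 300),
    },
    "tmt_b_s": {
        "control": (89.3, 44.3, 20, 400),
        "aMCI": (130.8, 73.2, 20, 400),
        "mildAD": (200.5, 86.6, 20, 400),
    },
    "digit_symbol": {
        "control": (45.8, 10.2, 0, 93),
        "aMCI": (37.0, 11.1, 0, 93),
        "mildAD": (27.6, 12.5, 0, 93),
    },
    "bristol_adl": {
        "control": (4.46, 0.5, 0, 60),
        "aMCI": (5.59, 0.9, 0, 60),
        "mildAD": (10.59, 0.9, 0, 60),
    },
    "blessed_adl": {
        "control": (1.85, 0.27, 0, 17),
        "aMCI": (2.38, 0.56, 0, 17),
        "mildAD": (4.38, 0.56, 0, 17),
    },
}

# annual decline (mean, sd), units/year; sign follows the scale direction
# (cognitive scores fall, disability scales rise).
_SCALE_SLOPES: dict[str, dict[str, tuple[float, float]]] = {
    "mmse": {"control": (-0.1, 0.2), "aMCI": (-0.7, 0.5), "mildAD": (-1.6, 0.8)},
    "ravlt_delayed": {"control": (-0.05, 0.2), "aMCI": (-0.4, 0.4), "mildAD": (-0.2, 0.3)},
    "gds": {"control": (0.0, 0.3), "aMCI": (0.2, 0.4), "mildAD": (0.3, 0.5)},
    "faq": {"control": (0.05, 0.2), "aMCI": (0.8, 0.8), "mildAD": (2.0, 1.2)},
    "tmt_a_s": {"control": (0.5, 1.5), "aMCI": (2.5, 3.0), "mildAD": (6.0, 5.0)},
    "tmt_b_s": {"control": (1.5, 4.0), "aMCI": (8.0, 8.0), "mildAD": (18.0, 12.0)},
    "digit_symbol": {"control": (-0.3, 0.8), "aMCI": (-1.5, 1.2), "mildAD": (-3.0, 1.8)},
    "bristol_adl": {"control": (0.05, 0.1), "aMCI": (0.5, 0.4), "mildAD": (1.3, 0.7)},
    "blessed_adl": {"control": (0.02, 0.05), "aMCI": (0.2, 0.2), "mildAD": (0.6, 0.3)},
}

#: within-subject visit-to-visit measurement noise SD, as a fraction of the
#: group baseline SD (kept small so trajectories are clearly linear).
_NOISE_FRACTION = 0.25


@dataclass
class GroupConfig:
    """Generating distributions for one diagnostic group.

    ``error_rates`` are the Poisson means (lambda_O, lambda_R, lambda_W,
    lambda_A) at baseline; ``error_growth`` multiplies them by
    (1 + growth * years-since-baseline).  ``reff_mean/sd`` and
    ``reff_slope_mean/sd`` parameterise the efficacy-ratio level and its
    annual drift.  ``conversion_intercept/beta`` define the logistic
    conversion model on the realised efficacy-ratio slope (aMCI only).
    """

    n: int
    age_mean: float
    age_sd: float
    male_fraction: float
    education_mean: float
    education_sd: float
    error_rates: tuple[float, float, float, float]
    error_growth: float
    reff_mean: float
    reff_sd: float
    reff_slope_mean: float
    reff_slope_sd: float
    gait_speed_mean: float
    gait_speed_sd: float
    stride_mean: float = 0.58
    stride_sd: float = 0.07
    tap_dom_mean: float = 3.8
    tap_dom_sd: float = 0.8
    tap_nondom_mean: float = 3.6
    tap_nondom_sd: float = 0.67
    gait_slope_mean: float = -0.01
    gait_slope_sd: float = 0.01
    tap_slope_mean: float = -0.02
    tap_slope_sd: float = 0.03
    activity_duration_mean_s: float = 22.0
    activity_duration_sigma: float = 0.35  # log-normal shape
    conversion_intercept: float = -3.0
    conversion_beta: float = -60.0

    def __post_init__(self):
        if self.n < 0:
            raise ValidationError("group size must be >= 0")
        if any(r < 0 for r in self.error_rates):
            raise ValidationError("error rates must be >= 0")
        if self.reff_sd < 0 or self.age_sd < 0:
            raise ValidationError("sds must be >= 0")


@dataclass
class CohortConfig:
    """Whole-cohort generating configuration.

    Group sizes are *completer* counts; the generator enrols
    round(n / (1 - dropout)) subjects per group and marks the surplus as
    baseline-only dropouts, so both the enrolled and completed cohort
    sizes land on their configured values exactly.
    """

    groups: dict[str, GroupConfig]
    n_visits: int = 3
    dropout: float = 0.116
    protocol: ProtocolSpec = field(default_factory=lambda: DEFAULT_PROTOCOL)

    def __post_init__(self):
        if set(self.groups) != set(GROUPS):
            raise ValidationError(f"groups must be exactly {GROUPS}, got {set(self.groups)}")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must lie in [0, 1)")


def default_config() -> CohortConfig:
    """Study-anchored defaults: 72/65/68 completers, 11.6% dropout,
    published scale means/SDs, error rates ordered control < aMCI < mild AD."""
    return CohortConfig(
        groups={
            "control": GroupConfig(
                n=72, age_mean=72.63, age_sd=5.06, male_fraction=0.38,
                education_mean=16.1, education_sd=2.9,
                error_rates=(0.05, 0.1, 0.05, 0.1), error_growth=0.10,
                reff_mean=0.88, reff_sd=0.05,
                reff_slope_mean=-0.005, reff_slope_sd=0.004,
                gait_speed_mean=0.96, gait_speed_sd=0.23,
            ),
            "aMCI": GroupConfig(
                n=65, age_mean=72.78, age_sd=6.21, male_fraction=0.43,
                education_mean=15.7, education_sd=3.0,
                error_rates=(0.8, 0.9, 0.8, 1.0), error_growth=0.25,
                reff_mean=0.68, reff_sd=0.07,
                reff_slope_mean=-0.035, reff_slope_sd=0.018,
                gait_speed_mean=0.91, gait_speed_sd=0.24,
                tap_dom_mean=3.77, tap_nondom_mean=3.61,
                gait_slope_mean=-0.025, tap_slope_mean=-0.05,
                conversion_intercept=-5.7, conversion_beta=-140.0,
            ),
            "mildAD": GroupConfig(
                n=68, age_mean=72.58, age_sd=6.21, male_fraction=0.46,
                education_mean=14.6, education_sd=3.2,
                error_rates=(1.8, 1.8, 1.6, 2.2), error_growth=0.40,
                reff_mean=0.55, reff_sd=0.08,
                reff_slope_mean=-0.05, reff_slope_sd=0.02,
                gait_speed_mean=0.86, gait_speed_sd=0.20,
                tap_dom_mean=3.74, tap_nondom_mean=3.58,
                gait_slope_mean=-0.04, tap_slope_mean=-0.08,
            ),
        },
    )


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        return np.full(size, float(mean)) if size else float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _order_with_lis_deficit(indices: np.ndarray, w: int) -> np.ndarray:
    """Permutation of sorted ``indices`` whose LIS deficit is exactly ``w``.

    Place the ``w`` largest elements first in decreasing order, then the
    rest in increasing order.  Every front element exceeds every tail
    element, so the LIS is the tail (length m - w) for w < m, and 1 for
    w = m - 1.
    """
    s = np.sort(indices)
    m = len(s)
    if w == 0:
        return s
    if not 0 < w <= m - 1:
        raise ValueError(f"order-error count {w} infeasible for {m} activities")
    return np.concatenate([s[m - w:][::-1], s[: m - w]])


def generate_session(
    subject_id: str,
    visit_year: int,
    counts: tuple[int, int, int, int],
    reff_target: float,
    protocol: ProtocolSpec,
    rng: np.random.Generator,
    duration_mean_s: float = 22.0,
    duration_sigma: float = 0.35,
) -> SessionLog:
    """Construct an event log that scores back to ``counts`` exactly and has
    efficacy ratio ``reff_target`` (up to millisecond rounding).

    Infeasible draws are capped: W <= performed - 1, and R/A require at
    least one performed activity.
    """
    n_act = len(protocol.activities)
    o, r, w, a = counts
    o = min(o, n_act)
    m = n_act - o
    if m == 0:
        r = w = a = 0
    else:
        w = min(w, m - 1)
    if not 0 < reff_target <= 1:
        raise ValueError("reff_target must lie in (0, 1]")

    performed_idx = np.sort(rng.choice(n_act, size=m, replace=False)) if m else np.array([], int)
    order = _order_with_lis_deficit(performed_idx, w)

    # first completions in the constructed order
    events_spec: list[tuple[str, int]] = []  # (activity_id, attempts)
    attempt_extra = rng.multinomial(a, np.full(m, 1.0 / m)) if m and a else np.zeros(m, int)
    for j, idx in enumerate(order):
        events_spec.append((protocol.activities[idx], 1 + int(attempt_extra[j])))
    # repetitions appended after all first completions: first-completion
    # order (and thus W) is untouched; each adds one completed performance
    if m and r:
        rep_choices = rng.choice(order, size=r, replace=True)
        for idx in rep_choices:
            events_spec.append((protocol.activities[idx], 1))

    durations = np.exp(
        rng.normal(math.log(duration_mean_s), duration_sigma, size=len(events_spec))
    )
    active = float(durations.sum()) if len(events_spec) else 0.0
    if active == 0.0:
        # nothing performed: a session of idle wandering
        total = float(np.exp(rng.normal(math.log(duration_mean_s * n_act), duration_sigma)))
        return SessionLog(subject_id, visit_year, protocol.scenario_id, (), round(total, 3))
    total = active / reff_target
    idle = total - active
    gaps = rng.dirichlet(np.ones(len(events_spec) + 1)) * idle if idle > 0 else np.zeros(
        len(events_spec) + 1
    )
    events = []
    t = gaps[0]
    for i, (act, attempts) in enumerate(events_spec):
        start, end = t, t + durations[i]
        events.append(
            ActivityEvent(
                activity_id=act,
                start_s=round(start, 3),
                end_s=round(end, 3),
                attempts=attempts,
                completed=True,
            )
        )
        t = end + gaps[i + 1]
    total = max(round(total, 3), round(events[-1].end_s, 3))
    return SessionLog(subject_id, visit_year, protocol.scenario_id, tuple(events), total)


def _draw_counts(rng, rates: tuple[float, ...], growth: float, year: int,
                 n_act: int) -> tuple[int, int, int, int]:
    factor = 1.0 + growth * (year - 1)
    lam = np.asarray(rates) * factor
    o = int(min(rng.poisson(lam[0]), n_act - 1))  # keep >= 1 activity performed
    m = n_act - o
    r = int(rng.poisson(lam[1]))
    w = int(min(rng.poisson(lam[2]), m - 1)) if m > 1 else 0
    a = int(rng.poisson(lam[3]))
    return o, r, w, a


def _subject_visits(rng, gcfg: GroupConfig, group: str, n_visits: int, sex: str):
    """Per-visit measure dict for one subject: truncated-normal baselines,
    linear per-subject slopes, small visit noise, instrument bounds."""
    visits: dict[int, dict[str, float]] = {y: {} for y in range(1, n_visits + 1)}
    for scale, anchors in _SCALE_ANCHORS.items():
        mean, sd, lo, hi = anchors[group]
        base = float(_truncnorm(rng, mean, sd, lo, hi))
        smean, ssd = _SCALE_SLOPES[scale][group]
        slope = float(rng.normal(smean, ssd))
        for y in visits:
            v = base + slope * (y - 1) + rng.normal(0, sd * _NOISE_FRACTION)
            visits[y][scale] = float(np.clip(v, lo, hi))
    # psychomotor raws: gait speed / stride drive walk time and steps
    gait0 = float(_truncnorm(rng, gcfg.gait_speed_mean, gcfg.gait_speed_sd, 0.3, 1.8))
    stride0 = float(_truncnorm(rng, gcfg.stride_mean, gcfg.stride_sd, 0.3, 0.9))
    gait_slope = float(rng.normal(gcfg.gait_slope_mean, gcfg.gait_slope_sd))
    tap0 = float(_truncnorm(rng, gcfg.tap_dom_mean, gcfg.tap_dom_sd, 1.0, 7.0))
    tapn0 = float(_truncnorm(rng, gcfg.tap_nondom_mean, gcfg.tap_nondom_sd, 1.0, 7.0))
    tap_slope = float(rng.normal(gcfg.tap_slope_mean, gcfg.tap_slope_sd))
    grip_mean = 32.0 if sex == "M" else 20.0
    grip0 = float(_truncnorm(rng, grip_mean, 6.0, 5.0, 60.0))
    for y in visits:
        t = y - 1
        gait = max(gait0 + gait_slope * t + rng.normal(0, 0.03), 0.2)
        stride = max(stride0 + 0.3 * gait_slope * t + rng.normal(0, 0.01), 0.25)
        visits[y]["walk_time_s"] = round(4.6 / gait, 1)
        visits[y]["walk_steps"] = float(max(int(round(4.6 / stride)), 1))
        tap = max(tap0 + tap_slope * t + rng.normal(0, 0.08), 0.5)
        tapn = max(tapn0 + tap_slope * t + rng.normal(0, 0.08), 0.5)
        visits[y]["taps_dominant_15s"] = float(int(round(tap * 15)))
        visits[y]["taps_nondominant_15s"] = float(int(round(tapn * 15)))
        visits[y]["grip_kg"] = round(max(grip0 - 0.4 * t + rng.normal(0, 0.8), 2.0), 1)
    return visits


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortDataset:
    """Generate a full cohort, reproducibly from ``seed``.

    Each group enrols round(n / (1 - dropout)) subjects; dropouts (chosen
    at random) carry baseline data only.  aMCI conversion labels are drawn
    from the configured logistic model in the subject's realised
    efficacy-ratio slope.
    """
    config = config or default_config()
    rng = np.random.default_rng(seed)
    protocol = config.protocol
    n_act = len(protocol.activities)
    subjects = []
    for group in GROUPS:
        gcfg = config.groups[group]
        n_enrol = int(round(gcfg.n / (1.0 - config.dropout))) if config.dropout else gcfg.n
        n_drop = n_enrol - gcfg.n
        drop_ids = set(rng.choice(n_enrol, size=n_drop, replace=False)) if n_drop else set()
        for i in range(n_enrol):
            sid = f"{group}_{i + 1:03d}"
            dropout = i in drop_ids
            n_vis = 1 if dropout else config.n_visits
            sex = "M" if rng.random() < gcfg.male_fraction else "F"
            age = float(_truncnorm(rng, gcfg.age_mean, gcfg.age_sd, 60, 95))
            edu = float(_truncnorm(rng, gcfg.education_mean, gcfg.education_sd, 4, 24))
            knee_heel = float(_truncnorm(rng, 50.0, 3.0, 40, 60))
            visits = _subject_visits(rng, gcfg, group, n_vis, sex)

            reff0 = float(np.clip(rng.normal(gcfg.reff_mean, gcfg.reff_sd), 0.05, 0.99))
            reff_slope = float(rng.normal(gcfg.reff_slope_mean, gcfg.reff_slope_sd))
            sessions = []
            for y in range(1, n_vis + 1):
                counts = _draw_counts(rng, gcfg.error_rates, gcfg.error_growth, y, n_act)
                reff_y = float(np.clip(reff0 + reff_slope * (y - 1), 0.05, 0.99))
                sessions.append(
                    generate_session(
                        sid, y, counts, reff_y, protocol, rng,
                        duration_mean_s=gcfg.activity_duration_mean_s,
                        duration_sigma=gcfg.activity_duration_sigma,
                    )
                )
            converted = None
            if group == "aMCI" and not dropout:
                lp = gcfg.conversion_intercept + gcfg.conversion_beta * reff_slope
                converted = bool(rng.random() < 1.0 / (1.0 + math.exp(-lp)))
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    age=round(age, 1),
                    sex=sex,
                    education_years=round(edu, 1),
                    knee_heel_cm=round(knee_heel, 1),
                    visits=visits,
                    sessions=sessions,
                    converted_to_ad=converted,
                    dropout=dropout,
                )
            )
    return CohortDataset(
        subjects=subjects,
        protocol=protocol,
        provenance=f"synthetic cohort, seed={seed}",
    )


def make_pilot(config: CohortConfig | None = None, seed: int = 0) -> CohortDataset:
    """Single-visit pilot cohort (25 controls / 26 aMCI / 24 mild AD) for
    calibration experiments; pilot group mean ages 73.7 / 74.2 / 76.7."""
    config = config or default_config()
    pilot_groups = {}
    for group, (n, age_m, age_sd) in {
        "control": (25, 73.7, 4.0),
        "aMCI": (26, 74.2, 2.0),
        "mildAD": (24, 76.7, 3.0),
    }.items():
        pilot_groups[group] = replace(
            config.groups[group], n=n, age_mean=age_m, age_sd=age_sd
        )
    pcfg = CohortConfig(groups=pilot_groups, n_visits=1, dropout=0.0,
                        protocol=config.protocol)
    cohort = generate_cohort(pcfg, seed=seed)
    cohort.provenance = f"synthetic pilot, seed={seed}"
    return cohort


def make_recovery_pilot(
    true_k: tuple[float, float, float, float],
    n: int = 75,
    seed: int = 7,
    protocol: ProtocolSpec = DEFAULT_PROTOCOL,
    mmse_noise_sd: float = 0.1,
    iadl_noise_sd: float = 0.14,
) -> CohortDataset:
    """Parameter-recovery fixture: a single-visit pilot whose MMSE and
    Bristol scores are noisy monotone functions of the functional index
    computed with ``true_k``.

    Error counts are drawn independently across the four types
    (Poisson(1), order errors capped by feasibility) and the efficacy
    ratio uniformly on (0.35, 0.95).  Keeping the penalty term
    k·x mostly below 1 keeps the index near-linear in the weights, so
    rank correlations identify both the direction *and* the magnitude of
    the weight vector symmetrically; recovery calibrations on this
    fixture should use tight thresholds (|rho| >= 0.99) so the accepted
    region localises around ``true_k``.  Synthetic by construction; not a
    claim about any real pilot sample.
    """
    from .scoring import count_errors, efficacy_ratio, penalised_index
    from .session_model import ErrorCounts, ScoreParams

    rng = np.random.default_rng(seed)
    params = ScoreParams(*true_k)
    n_act = len(protocol.activities)
    subjects = []
    fis = []
    for i in range(n):
        o = int(min(rng.poisson(1.0), n_act - 1))
        m = n_act - o
        r = int(rng.poisson(1.0))
        w = int(min(rng.poisson(1.0), m - 1)) if m > 1 else 0
        a = int(rng.poisson(1.0))
        reff = float(rng.uniform(0.35, 0.95))
        sid = f"pilot_{i + 1:03d}"
        sess = generate_session(sid, 1, (o, r, w, a), reff, protocol, rng)
        fi = penalised_index(
            efficacy_ratio(sess, protocol), count_errors(sess, protocol), params
        )
        fis.append(fi)
        subjects.append((sid, sess))
    fis = np.asarray(fis)
    span = np.ptp(fis) or 1.0
    z = (fis - fis.min()) / span
    mmse = np.clip(18.0 + 12.0 * z + rng.normal(0, mmse_noise_sd, n), 0, 30)
    bristol = np.clip(20.0 - 16.0 * z + rng.normal(0, iadl_noise_sd, n), 0, 60)
    records = [
        SubjectRecord(
            subject_id=sid,
            group="control",
            age=73.0,
            sex="F",
            education_years=14.0,
            knee_heel_cm=50.0,
            visits={1: {"mmse": float(mmse[i]), "bristol_adl": float(bristol[i])}},
            sessions=[sess],
        )
        for i, (sid, sess) in enumerate(subjects)
    ]
    return CohortDataset(
        subjects=records,
        protocol=protocol,
        provenance=f"synthetic recovery pilot, true_k={tuple(true_k)}, seed={seed}",
    )
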