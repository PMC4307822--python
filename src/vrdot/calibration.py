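"""Two-step pilot calibration of the penalty weights (k1, k2, k3, k4).

Step 1 evaluates every candidate weight set on a regular grid: the pilot
cohort's baseline sessions are scored with the candidate, and the Spearman
correlation of the resulting functional index with MMSE (expected strongly
positive — higher index, better cognition) and with an informant IADL
scale (expected strongly negative — higher index, less disability) is
computed.  Step 2 accepts every candidate meeting both correlation
thresholds and takes the componentwise mean of the accepted sets as the
final weights.

"Strong" correlation has no canonical numeric value; the thresholds
default to |rho| >= 0.6 and are configuration, never hard-coded.  The grid
(rather than continuous optimisation) keeps the procedure exactly
reproducible and mirrors evaluation of discrete candidate sets.

The grid evaluation is vectorised: with per-subject efficacy ratios r_i
and error-count vectors x_i fixed, the candidate index is
100 r_i / (1 + k·x_i) for every k at once, and Spearman rho is the Pearson
correlation of midranks, computed chunkwise over candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import count_errors, efficacy_ratio
from .session_model import CohortDataset, ScoreParams


class CalibrationError(RuntimeError):
    """No candidate met the acceptance thresholds; carries the best seen."""

    def __init__(self, message: str, best: ScoreParams, rho_mmse: float, rho_iadl: float):
        super().__init__(
            f"{message} (best candidate {best.as_tuple()}: "
            f"rho_mmse={rho_mmse:.3f}, rho_iadl={rho_iadl:.3f})"
        )
        self.best = best
        self.best_rhos = (rho_mmse, rho_iadl)


class DomainError(ValueError):
    pass


def _grid_axis(value) -> tuple[float, float, float]:
    lo, hi, step = value
    if not (lo <= hi and step > 0):
        raise ValueError("grid requires min <= max and step > 0")
    return float(lo), float(hi), float(step)


@dataclass
class CalibrationConfig:
    """Grid bounds/step (shared across the four weights, or a 4-sequence of
    (min, max, step) triples), correlation thresholds, and which scale
    column plays the IADL role."""

    grid_min: float = 0.0
    grid_max: float = 1.0
    grid_step: float = 0.05
    rho_mmse_min: float = 0.6
    rho_iadl_max: float = -0.6
    iadl_scale: str = "bristol_adl"
    per_k: Sequence[tuple[float, float, float]] | None = None

    def axes(self) -> list[np.ndarray]:
        if self.per_k is not None:
            triples = [_grid_axis(t) for t in self.per_k]
        else:
            triples = [_grid_axis((self.grid_min, self.grid_max, self.grid_step))] * 4
        axes = []
        for lo, hi, step in triples:
            n = int(round((hi - lo) / step)) + 1
            axes.append(np.round(lo + step * np.arange(n), 10))
        return axes



@dataclass
class CalibrationResult:
    """Accepted candidates, their componentwise mean, and per-candidate
    correlation diagnostics."""

    accepted: list[ScoreParams]
    final: ScoreParams
    diagnostics: pd.DataFrame = field(repr=False)  # k1..k4, rho_mmse, rho_iadl, accepted

    def summary(self) -> pd.DataFrame:
        acc = self.diagnostics[self.diagnostics["accepted"]]
        return pd.DataFrame(
            {
                "final": self.final.as_tuple(),
                "accepted_min": acc[["k1", "k2", "k3", "k4"]].min().to_numpy(),
                "accepted_max": acc[["k1", "k2", "k3", "k4"]].max().to_numpy(),
            },
            index=["k1", "k2", "k3", "k4"],
        )


def _pilot_arrays(pilot: CohortDataset, iadl_scale: str):
    """Baseline efficacy ratios, error-count matrix, MMSE and IADL vectors."""
    reff, X, mmse, iadl = [], [], [], []
    for subj in pilot.subjects:
        sess = subj.session_for(1)
        if sess is None or 1 not in subj.visits:
            continue
        meas = subj.visits[1]
        if meas.get("mmse") is None or meas.get(iadl_scale) is None:
            continue
        reff.append(efficacy_ratio(sess, pilot.protocol))
        X.append(count_errors(sess, pilot.protocol).as_tuple())
        mmse.append(meas["mmse"])
        iadl.append(meas[iadl_scale])
    if len(reff) < 3:
        raise DomainError(
            f"need >= 3 pilot subjects with baseline session, MMSE and {iadl_scale}"
        )
    return (np.array(reff), np.array(X, dtype=float),
            np.array(mmse, dtype=float), np.array(iadl, dtype=float))


def _rank_corr_matrix(fi: np.ndarray, target_ranks: np.ndarray) -> np.ndarray:
    """Spearman rho of each column of ``fi`` (n x K) against fixed ranks."""
    rf = stats.rankdata(fi, axis=0)
    rf = rf - rf.mean(axis=0, keepdims=True)
    t = target_ranks - target_ranks.mean()
    denom = np.sqrt((rf**2).sum(axis=0) * (t**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rf * t[:, None]).sum(axis=0) / denom
    return rho


def evaluate_candidates(
    candidates: np.ndarray, pilot: CohortDataset, config: CalibrationConfig,
    chunk: int = 20000,
) -> pd.DataFrame:
    """Spearman (rho_mmse, rho_iadl) of the candidate-scored baseline index
    for every row of ``candidates`` (K x 4).  Order-preserving and
    order-independent: each candidate is evaluated in isolation."""
    reff, X, mmse, iadl = _pilot_arrays(pilot, config.iadl_scale)
    if np.ptp(mmse) == 0 or np.ptp(iadl) == 0:
        raise DomainError("constant MMSE or IADL: correlations undefined")
    rm = stats.rankdata(mmse)
    ri = stats.rankdata(iadl)
    cands = np.atleast_2d(np.asarray(candidates, dtype=float))
    rho_m = np.empty(len(cands))
    rho_i = np.empty(len(cands))
    for start in range(0, len(cands), chunk):
        kk = cands[start:start + chunk]
        denom = 1.0 + X @ kk.T  # (n, K)
        fi = 100.0 * reff[:, None] / denom
        # a constant index column (constant reff at k=0) yields rho = NaN
        rho_m[start:start + chunk] = _rank_corr_matrix(fi, rm)
        rho_i[start:start + chunk] = _rank_corr_matrix(fi, ri)
    df = pd.DataFrame(cands, columns=["k1", "k2", "k3", "k4"])
    df["rho_mmse"] = rho_m
    df["rho_iadl"] = rho_i
    return df


def evaluate_candidate(
    params: ScoreParams, pilot: CohortDataset, config: CalibrationConfig | None = None
) -> tuple[float, float]:
    """(rho_mmse, rho_iadl) for a single candidate weight set."""
    config = config or CalibrationConfig()
    df = evaluate_candidates(np.array([params.as_tuple()]), pilot, config)
    rm, ri = float(df["rho_mmse"].iloc[0]), float(df["rho_iadl"].iloc[0])
    if np.isnan(rm) or np.isnan(ri):
        raise DomainError("functional index is constant across the pilot: rho undefined")
    return rm, ri


def calibrate(
    pilot: CohortDataset, config: CalibrationConfig | None = None
) -> CalibrationResult:
    """Full-grid calibration: evaluate every grid point, accept those with
    rho_mmse >= ``rho_mmse_min`` and rho_iadl <= ``rho_iadl_max``, return
    the componentwise mean of the accepted sets."""
    config = config or CalibrationConfig()
    axes = config.axes()
    grids = np.meshgrid(*axes, indexing="ij")
    cands = np.column_stack([g.ravel() for g in grids])
    diag = evaluate_candidates(cands, pilot, config)
    diag["accepted"] = (diag["rho_mmse"] >= config.rho_mmse_min) & (
        diag["rho_iadl"] <= config.rho_iadl_max
    )
    acc = diag[diag["accepted"]]
    if acc.empty:
        score = diag["rho_mmse"] - diag["rho_iadl"]  # most-positive / most-negative combo
        best = diag.loc[score.idxmax()]
        raise CalibrationError(
            "no candidate met both correlation thresholds",
            ScoreParams(best["k1"], best["k2"], best["k3"], best["k4"]),
            float(best["rho_mmse"]),
            float(best["rho_iadl"]),
        )
    accepted = [
        ScoreParams(r.k1, r.k2, r.k3, r.k4) for r in acc.itertuples(index=False)
    ]
    final = ScoreParams(*[float(acc[c].mean()) for c in ("k1", "k2", "k3", "k4")])
    return CalibrationResult(accepted=accepted, final=final, diagnostics=diag)
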