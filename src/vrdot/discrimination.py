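"""Correlation and ROC machinery for the screening battery.

Spearman and partial Spearman correlations, ROC curves with Mann-Whitney
AUC (ties get half credit), stratified-bootstrap confidence intervals,
Youden-optimal cutoffs, and confusion-matrix metrics.

Score direction is always explicit: for impairment screening, MMSE and the
functional index are *lower-is-positive* (lower values indicate the
impaired class), informant ADL scales are *higher-is-positive*.  Nothing
is inferred from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

DIRECTIONS = ("higher-is-positive", "lower-is-positive")


class DomainError(ValueError):
    pass


class UndefinedCorrelationError(DomainError):
    """A correlation is undefined (constant input)."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")


@dataclass
class ROCResult:
    """ROC curve over all distinct score thresholds plus its AUC.

    ``thresholds`` are in original score units, sorted ascending;
    ``sens[i]``/``spec[i]`` are achieved when calling positive every score
    at or beyond ``thresholds[i]`` in the positive direction.  The raw
    ``scores``/``labels`` are retained so cutoff reports and bootstrap CIs
    can be computed from the same sample.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    direction: str
    positive_label: object
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class CutoffReport:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float  # NaN when no predicted positives
    npv: float  # NaN when no predicted negatives

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise DomainError("expected a 1-D numeric vector")
    return a


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties; two-sided p from
    the t approximation with n-2 degrees of freedom."""
    xa, ya = _as_1d(x), _as_1d(y)
    if len(xa) != len(ya):
        raise DomainError("x and y must have equal length")
    if len(xa) < 3:
        raise DomainError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = stats.spearmanr(xa, ya)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue), n=len(xa))


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates,
    covariate_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (mid-ranks), x and y are residualised
    on the ranked covariates by OLS, and the residuals are correlated.  The
    two-sided p uses a t statistic with n - 2 - q degrees of freedom, q the
    number of covariates.
    """
    xa, ya = _as_1d(x), _as_1d(y)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, q = len(xa), Z.shape[1]
    if len(ya) != n or Z.shape[0] != n:
        raise DomainError("x, y and covariates must have equal length")
    if n <= q + 2:
        raise DomainError(f"need n > q + 2 (n={n}, q={q})")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")

    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rz = np.column_stack([stats.rankdata(Z[:, j]) for j in range(q)])
    # drop covariates made constant by ranking (no information)
    keep = np.ptp(rz, axis=0) > 0
    rz = rz[:, keep]
    design = np.column_stack([np.ones(n), rz])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DomainError("collinear covariates: degenerate design")
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    if np.allclose(ex, 0) or np.allclose(ey, 0):
        raise UndefinedCorrelationError(
            "residuals vanish: a variable is an exact function of the covariates"
        )
    rho = float(np.corrcoef(ex, ey)[0, 1])
    rho = max(min(rho, 1.0), -1.0)
    df = n - 2 - q
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(rho=rho, p_value=float(p), n=n, covariates=tuple(covariate_names))


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction not in DIRECTIONS:
        raise DomainError(f"direction must be one of {DIRECTIONS}")
    return scores if direction == "higher-is-positive" else -scores


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + 0.5 P(pos = neg), via midranks."""
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    n1, n0 = len(pos), len(neg)
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve(scores, labels, positive_label, direction: str) -> ROCResult:
    """ROC curve and Mann-Whitney AUC for a binary screening problem.

    ``sens``/``spec`` are evaluated at every distinct score value used as a
    cutoff (inclusive in the positive direction).  Requires both classes.
    """
    s = _as_1d(scores)
    lab = np.asarray(labels)
    if len(s) != len(lab):
        raise DomainError("scores and labels must have equal length")
    y = lab == positive_label
    if y.all() or not y.any():
        raise DomainError("both classes must be present")
    o = _oriented(s, direction)
    pos, neg = o[y], o[~y]
    auc = _mann_whitney_auc(pos, neg)

    thresholds = np.unique(s)
    ot = _oriented(thresholds, direction)
    order = np.argsort(ot)
    thresholds, ot = thresholds[order], ot[order]
    # positive call: oriented score >= oriented threshold
    sens = np.array([(pos >= t).mean() for t in ot])
    spec = np.array([(neg < t).mean() for t in ot])
    return ROCResult(
        thresholds=thresholds, sens=sens, spec=spec, auc=auc,
        direction=direction, positive_label=positive_label,
        scores=s, labels=lab,
    )


def auc_ci(
    roc: ROCResult, n_boot: int = 2000, seed: int | None = None, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling within each class.

    Stratified resampling keeps both class sizes fixed; the interval is
    stored back onto ``roc`` and returned.
    """
    y = roc.labels == roc.positive_label
    o = _oriented(roc.scores, roc.direction)
    pos, neg = o[y], o[~y]
    if len(pos) < 2 or len(neg) < 2:
        raise DomainError("need at least 2 members per class for a bootstrap CI")
    rng = np.random.default_rng(seed)
    n1, n0 = len(pos), len(neg)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, n1, n1)]
        bn = neg[rng.integers(0, n0, n0)]
        aucs[b] = _mann_whitney_auc(bp, bn)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    roc.ci_low, roc.ci_high = float(lo), float(hi)
    return float(lo), float(hi)


def confusion_metrics(scores, labels, cutoff: float, direction: str,
                      positive_label=True) -> CutoffReport:
    """Sensitivity, specificity, PPV and NPV at a fixed cutoff (inclusive in
    the positive direction).  Empty predicted cells yield NaN predictive
    values rather than an exception."""
    s = _as_1d(scores)
    lab = np.asarray(labels)
    y = lab == positive_label
    if y.all() or not y.any():
        raise DomainError("both classes must be present")
    o = _oriented(s, direction)
    oc = cutoff if direction == "higher-is-positive" else -cutoff
    pred = o >= oc
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return CutoffReport(cutoff=float(cutoff), sensitivity=sens, specificity=spec,
                        ppv=ppv, npv=npv)


def optimal_cutoff(roc: ROCResult, criterion: str = "youden") -> CutoffReport:
    """Cutoff maximising Youden's J = sens + spec - 1 over the ROC's
    thresholds; ties broken toward higher specificity."""
    if criterion != "youden":
        raise ValueError(f"unknown criterion {criterion!r}")
    j = roc.sens + roc.spec - 1.0
    best = max(range(len(j)), key=lambda i: (j[i], roc.spec[i]))
    return confusion_metrics(
        roc.scores, roc.labels, float(roc.thresholds[best]), roc.direction,
        positive_label=roc.positive_label,
    )
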