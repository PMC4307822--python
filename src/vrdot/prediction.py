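"""Conversion-to-dementia modelling: logistic regression with odds
ratios, Nagelkerke pseudo-R², classification rate, and backward stepwise
selection.

Maximum-likelihood fitting is delegated to statsmodels' ``Logit``
(Newton-Raphson); this module adds the screening-battery layer on top:
odds-ratio confidence intervals, Nagelkerke's rescaled likelihood-ratio
R², percent correctly classified, perfect-separation flagging with an
optional Firth-style (Jeffreys-penalised) fallback, and the stepwise
procedure with forced-in covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class DomainError(ValueError):
    pass


class DegenerateDesignError(DomainError):
    pass


@dataclass
class LogisticFit:
    """Results of a fitted binary logistic model.

    ``params`` etc. are indexed by predictor name; ``const`` is the
    intercept.  ``separation`` flags (quasi-)complete separation: the MLE
    does not exist and coefficients are reported at the stopping point (or
    from the Firth-penalised fit if requested).
    """

    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    llnull: float
    n: int
    separation: bool = False
    penalty: str = "none"
    _exog_names: tuple[str, ...] = field(default=(), repr=False)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params.drop("const"))

    def odds_ratio_ci(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        b = self.params.drop("const")
        se = self.bse.drop("const")
        return pd.DataFrame(
            {"or": np.exp(b), "ci_low": np.exp(b - z * se), "ci_high": np.exp(b + z * se)}
        )

    @property
    def nagelkerke_r2(self) -> float:
        return nagelkerke_r2(self)

    def predict_proba(self, X) -> np.ndarray:
        Xd = _design(X, self.predictors)
        return expit(Xd.to_numpy() @ self.params.reindex(Xd.columns).to_numpy())

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, Wald p, OR with 95% CI."""
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        )
        ors = self.odds_ratio_ci()
        return tab.join(ors)


def _design(X, predictors: tuple[str, ...] | None = None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        Xd = X.copy()
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = predictors or tuple(f"x{i + 1}" for i in range(arr.shape[1]))
        Xd = pd.DataFrame(arr, columns=list(names))
    if predictors is not None:
        Xd = Xd[list(predictors)]
    Xd.insert(0, "const", 1.0)
    return Xd


def _detect_separation(p: np.ndarray, y: np.ndarray) -> bool:
    """Fitted probabilities essentially 0/1 on every observation."""
    return bool(np.all(np.abs(p - y) < 1e-6)) and len(p) > 0


def _firth_fit(Xd: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Firth-penalised logistic regression (Jeffreys-prior score correction).

    Newton iterations on the modified score U*(b) = U(b) + X' (h .* (1/2 - p)),
    h the hat-diagonal of the weighted design.  Guarantees finite estimates
    under separation.
    """
    n, k = Xd.shape
    b = np.zeros(k)
    for _ in range(max_iter):
        eta = Xd @ b
        p = expit(eta)
        w = p * (1 - p)
        XtW = Xd.T * w
        info = XtW @ Xd
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as e:
            raise DegenerateDesignError("singular information matrix") from e
        h = np.einsum("ij,jk,ik->i", Xd, info_inv, Xd * w[:, None])
        score = Xd.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        b = b + step
        if np.linalg.norm(score) < tol:
            break
    eta = Xd @ b
    p = expit(eta)
    w = p * (1 - p)
    info = (Xd.T * w) @ Xd
    cov = np.linalg.inv(info)
    llf = float(np.sum(y * np.log(np.clip(p, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - p, 1e-12, 1))))
    return b, np.sqrt(np.diag(cov)), llf


def fit_logistic(X, y, predictors: tuple[str, ...] | None = None,
                 penalty: str = "none") -> LogisticFit:
    """Fit a binary logistic regression by maximum likelihood.

    ``X`` is a DataFrame (column names become predictor names) or 2-D
    array; an intercept is always added.  ``penalty="firth"`` applies the
    Jeffreys-prior correction, keeping estimates finite under separation.
    Perfect separation under the plain MLE is flagged on the result rather
    than raised.
    """
    Xd = _design(X, predictors)
    ya = np.asarray(y, dtype=float).ravel()
    if len(ya) != len(Xd):
        raise DomainError("X and y must have equal length")
    if not set(np.unique(ya)) <= {0.0, 1.0}:
        raise DomainError("y must be binary 0/1")
    if ya.min() == ya.max():
        raise DomainError("y must contain both classes")
    if len(ya) <= Xd.shape[1]:
        raise DomainError(f"need n > number of parameters ({Xd.shape[1]})")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise DegenerateDesignError("rank-deficient predictor matrix")

    names = tuple(c for c in Xd.columns if c != "const")
    prevalence = ya.mean()
    llnull = float(
        len(ya) * (prevalence * np.log(prevalence) + (1 - prevalence) * np.log(1 - prevalence))
    )

    if penalty == "firth":
        b, se, llf = _firth_fit(Xd.to_numpy(), ya)
        params = pd.Series(b, index=Xd.columns)
        bse = pd.Series(se, index=Xd.columns)
        from scipy.stats import norm

        zs = params / bse
        pvals = pd.Series(2 * norm.sf(np.abs(zs)), index=Xd.columns)
        sep = _detect_separation(expit(Xd.to_numpy() @ b), ya)
        return LogisticFit(names, params, bse, pvals, llf, llnull, len(ya),
                           separation=sep, penalty="firth")
    if penalty != "none":
        raise ValueError(f"unknown penalty {penalty!r}")

    model = sm.Logit(ya, Xd)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-10)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            separation = True
    p = np.asarray(res.predict())
    if _detect_separation(p, ya):
        separation = True
    return LogisticFit(
        predictors=names,
        params=pd.Series(np.asarray(res.params), index=Xd.columns),
        bse=pd.Series(np.asarray(res.bse), index=Xd.columns),
        pvalues=pd.Series(np.asarray(res.pvalues), index=Xd.columns),
        llf=float(res.llf),
        llnull=llnull,
        n=len(ya),
        separation=separation,
    )


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke's rescaled R²: [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)]."""
    if fit.llnull is None or np.isnan(fit.llnull):
        raise DomainError("null model log-likelihood unavailable")
    n = fit.n
    cs = 1.0 - np.exp(2.0 * (fit.llnull - fit.llf) / n)
    denom = 1.0 - np.exp(2.0 * fit.llnull / n)
    if denom <= 0:
        return 0.0
    return float(min(max(cs / denom, 0.0), 1.0))


def classify(fit: LogisticFit, X, y=None, threshold: float = 0.5):
    """Predicted labels at a probability threshold; with ``y`` also the
    percent correctly classified (0-100)."""
    p = fit.predict_proba(X)
    labels = (p >= threshold).astype(int)
    if y is None:
        return labels, None
    ya = np.asarray(y, dtype=float).ravel()
    return labels, float(100.0 * np.mean(labels == ya))


def backward_stepwise(
    X: pd.DataFrame,
    y,
    p_keep: float = 0.10,
    forced_in: tuple[str, ...] = (),
    penalty: str = "none",
) -> tuple[tuple[str, ...], LogisticFit]:
    """Backward elimination on Wald p-values.

    Starting from the full model, repeatedly drop the eligible predictor
    with the largest p >= ``p_keep`` (ties broken toward the later column)
    and refit, until every remaining eligible predictor has p < ``p_keep``.
    ``forced_in`` covariates are never removed.  Deterministic given the
    input column order.
    """
    if not isinstance(X, pd.DataFrame):
        raise DomainError("backward_stepwise requires a named DataFrame")
    missing = set(forced_in) - set(X.columns)
    if missing:
        raise DomainError(f"forced_in predictors not in X: {sorted(missing)}")
    current = list(X.columns)
    fit = fit_logistic(X[current], y, penalty=penalty)
    while True:
        eligible = [c for c in current if c not in forced_in]
        if not eligible:
            break
        pv = fit.pvalues.reindex(eligible)
        worst_p = np.nanmax(pv.to_numpy())
        if np.isnan(worst_p) or worst_p < p_keep:
            break
        # later column wins ties
        worst = [c for c in eligible if pv[c] == worst_p][-1]
        current.remove(worst)
        if current:
            fit = fit_logistic(X[current], y, penalty=penalty)
        else:
            fit = _intercept_only(y)
            break
    return tuple(current), fit


def _intercept_only(y) -> LogisticFit:
    ya = np.asarray(y, dtype=float).ravel()
    prev = ya.mean()
    ll = float(len(ya) * (prev * np.log(prev) + (1 - prev) * np.log(1 - prev)))
    b0 = float(np.log(prev / (1 - prev)))
    se = float(1.0 / np.sqrt(len(ya) * prev * (1 - prev)))
    return LogisticFit(
        predictors=(),
        params=pd.Series({"const": b0}),
        bse=pd.Series({"const": se}),
        pvalues=pd.Series({"const": np.nan}),
        llf=ll,
        llnull=ll,
        n=len(ya),
    )
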