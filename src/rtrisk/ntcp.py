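"""Lyman-Kutcher-Burman NTCP model and model-performance metrics.

The LKB model with the volume parameter fixed at n = 1 reduces the organ's
dose distribution to a single dosimetric factor x (here a percent-volume
metric such as IV40, the ipsilateral-lung volume receiving >= 40 Gy) and
maps it to a complication probability through the probit dose-response

    NTCP(x) = Phi(t),    t = (x - TV50) / (m * TV50),

where TV50 is the factor value giving a 50% complication probability (in
the factor's own units) and m is the dimensionless slope parameter.
Parameters are estimated by maximising the Bernoulli log-likelihood of the
observed complication indicators; 95% confidence intervals come from the
profile likelihood (chi-square cutoff of 3.84 on twice the log-likelihood
drop).

:class:`LKBModel` follows the scikit-learn estimator protocol: construct,
``fit(x, y)``, then ``predict_proba``; fitted attributes carry a trailing
underscore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "lkb_probability",
    "invert_lkb",
    "LKBModel",
    "fit_lkb",
    "auc",
    "hosmer_lemeshow",
    "scaled_brier",
    "calibration_slope",
    "ValidationReport",
    "validate_predictions",
]

_PCLIP = 1e-12
_CHI2_95_1DF = float(stats.chi2.ppf(0.95, df=1))  # 3.841...


def lkb_probability(x, tv50: float, m: float):
    """LKB complication probability Phi((x - TV50) / (m * TV50)).

    Strictly increasing in ``x`` and exactly 0.5 at ``x = TV50``.  Accepts
    scalars or arrays.
    """
    if tv50 <= 0 or m <= 0:
        raise ValueError("LKB model requires TV50 > 0 and m > 0")
    t = (np.asarray(x, dtype=float) - tv50) / (m * tv50)
    out = stats.norm.cdf(t)
    return float(out) if np.isscalar(x) else out


def invert_lkb(p, tv50: float, m: float):
    """Factor value at which the LKB model predicts probability ``p``.

    Closed form ``x = TV50 * (1 + m * Phi^{-1}(p))``; exact inverse of
    :func:`lkb_probability`.
    """
    if tv50 <= 0 or m <= 0:
        raise ValueError("LKB model requires TV50 > 0 and m > 0")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    out = tv50 * (1.0 + m * stats.norm.ppf(p_arr))
    return float(out) if np.isscalar(p) else out


def _neg_loglik(params, x, y):
    tv50, m = params
    p = lkb_probability(x, tv50, m)
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    return -float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


class LKBModel(BaseEstimator):
    """Probit (LKB, n = 1) dose-response model fit by maximum likelihood.

    Parameters
    ----------
    factor_name:
        Label of the dosimetric factor the model operates on (bookkeeping
        only; e.g. ``"IV40"``).
    tv50, m:
        Optional fixed parameters.  When both are given the model can
        predict without fitting.
    n_starts:
        Number of seeded multi-start points for the bounded quasi-Newton
        optimisation.
    ci:
        Whether :meth:`fit` computes 95% profile-likelihood intervals.
    random_state:
        Seed for the start-point draw.

    Attributes (after ``fit``)
    --------------------------
    tv50_, m_ : point estimates.
    loglik_ : maximised log-likelihood.
    ci_tv50_, ci_m_ : 95% profile-likelihood intervals.
    n_events_ : number of positive outcomes in the fit data.
    converged_ : True when at least one start converged.
    """

    def __init__(self, factor_name: str = "IV40", tv50: float | None = None,
                 m: float | None = None, n_starts: int = 6, ci: bool = True,
                 random_state: int | None = 0):
        self.factor_name = factor_name
        self.tv50 = tv50
        self.m = m
        self.n_starts = n_starts
        self.ci = ci
        self.random_state = random_state

    # -- prediction -----------------------------------------------------
    def _params(self):
        if hasattr(self, "tv50_"):
            return self.tv50_, self.m_
        if self.tv50 is not None and self.m is not None:
            return self.tv50, self.m
        check_is_fitted(self, "tv50_")

    def predict_proba(self, x):
        """Complication probability for factor values ``x``."""
        tv50, m = self._params()
        return lkb_probability(np.asarray(x, dtype=float).ravel(), tv50, m)

    def predict(self, x, threshold: float = 0.5):
        return (self.predict_proba(x) >= threshold).astype(int)

    def invert(self, p):
        """Factor value yielding complication probability ``p``."""
        tv50, m = self._params()
        return invert_lkb(p, tv50, m)

    # -- fitting --------------------------------------------------------
    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y).ravel().astype(float)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary")
        n_events = int(y.sum())
        if n_events == 0 or n_events == y.size:
            raise ValueError("need at least one event and one non-event")
        if np.ptp(x) == 0:
            raise ValueError("all factor values identical: TV50 unidentifiable")

        xmax = float(np.max(x))
        bounds = [(1e-6, 10.0 * xmax), (0.01, 10.0)]
        rng = np.random.default_rng(self.random_state)
        starts = [(np.median(x) if np.median(x) > 0 else 0.5 * xmax, 0.5)]
        while len(starts) < self.n_starts:
            starts.append(
                (rng.uniform(0.05 * xmax, 3.0 * xmax), 10 ** rng.uniform(-1.5, 0.7))
            )

        best, best_val = None, np.inf
        for s in starts:
            res = optimize.minimize(
                _neg_loglik, np.asarray(s), args=(x, y), method="L-BFGS-B",
                bounds=bounds, options={"maxiter": 500, "ftol": 1e-12},
            )
            if res.fun < best_val:
                best, best_val = res, res.fun
        if best is None or not np.isfinite(best_val):
            raise RuntimeError("LKB fit failed to converge from all starts")
        self.tv50_, self.m_ = float(best.x[0]), float(best.x[1])
        self.loglik_ = -best_val
        self.n_events_ = n_events
        self.converged_ = bool(best.success)
        if self.tv50_ >= 0.999 * bounds[0][1] or self.m_ >= 0.999 * bounds[1][1]:
            warnings.warn(
                "LKB fit hit a parameter bound; data may be separated",
                RuntimeWarning,
            )
        if self.ci:
            self.ci_tv50_ = self._profile_ci(0, x, y, bounds)
            self.ci_m_ = self._profile_ci(1, x, y, bounds)
        return self

    def _profile_deviance(self, idx, value, x, y, bounds):
        """2*(lnL_hat - max over the other parameter at fixed value)."""
        other = 1 - idx
        def nll(v):
            params = [0.0, 0.0]
            params[idx] = value
            params[other] = v
            return _neg_loglik(params, x, y)
        res = optimize.minimize_scalar(
            nll, bounds=bounds[other], method="bounded",
            options={"xatol": 1e-10},
        )
        return 2.0 * (res.fun + self.loglik_)

    def _profile_ci(self, idx, x, y, bounds, level_dev: float = _CHI2_95_1DF):
        est = (self.tv50_, self.m_)[idx]
        lo_b, hi_b = bounds[idx]
        f = lambda v: self._profile_deviance(idx, v, x, y, bounds) - level_dev

        def edge(direction: int) -> float:
            """Expand from the estimate until the deviance crosses 3.84."""
            limit = hi_b if direction > 0 else max(lo_b, 1e-9)
            step = 0.1 * est
            v = est + direction * step
            while (v < limit) if direction > 0 else (v > limit):
                if f(v) > 0:
                    a, b = (est, v) if direction > 0 else (v, est)
                    return float(optimize.brentq(f, a, b, xtol=1e-8))
                step *= 1.6
                v += direction * step
            if f(limit) > 0:
                a, b = (est, limit) if direction > 0 else (limit, est)
                return float(optimize.brentq(f, a, b, xtol=1e-8))
            return limit  # profile never crosses: CI open at the bound

        return (edge(-1), edge(+1))


@dataclass
class FitResult:
    """Point estimates, likelihood and profile CIs from :func:`fit_lkb`."""

    factor_name: str
    tv50: float
    m: float
    loglik: float
    ci_tv50: tuple[float, float]
    ci_m: tuple[float, float]
    n_events: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "factor": self.factor_name,
            "tv50": self.tv50,
            "m": self.m,
            "loglik": self.loglik,
            "ci_tv50": list(self.ci_tv50),
            "ci_m": list(self.ci_m),
            "n_events": self.n_events,
            "converged": self.converged,
        }


def fit_lkb(x, y, factor_name: str = "IV40", ci: bool = True,
            random_state: int | None = 0) -> FitResult:
    """Functional wrapper around :class:`LKBModel`'s maximum-likelihood fit."""
    est = LKBModel(factor_name=factor_name, ci=ci, random_state=random_state).fit(x, y)
    return FitResult(
        factor_name=factor_name, tv50=est.tv50_, m=est.m_, loglik=est.loglik_,
        ci_tv50=getattr(est, "ci_tv50_", (np.nan, np.nan)),
        ci_m=getattr(est, "ci_m_", (np.nan, np.nan)),
        n_events=est.n_events_, converged=est.converged_,
    )


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

def auc(pred, y) -> float:
    """Area under the ROC curve (Mann-Whitney, half credit for ties)."""
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both outcome classes")
    return float(roc_auc_score(y, np.asarray(pred, dtype=float).ravel()))


def hosmer_lemeshow(pred, y, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test on risk-quantile groups.

    Predictions are cut at quantiles of predicted risk (ties kept in one
    group; empty groups dropped).  The statistic is
    ``sum (O_g - E_g)^2 / (E_g (1 - E_g / n_g))`` with ``df = G - 2`` and an
    upper-tail chi-square p-value.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if pred.size < 2 * groups:
        raise ValueError("need at least 2 observations per requested group")
    qs = np.quantile(pred, np.linspace(0, 1, groups + 1))
    qs = np.unique(qs)
    idx = np.clip(np.searchsorted(qs, pred, side="right") - 1, 0, qs.size - 2)
    stat = 0.0
    n_groups = 0
    for g in range(qs.size - 1):
        sel = idx == g
        n_g = int(sel.sum())
        if n_g == 0:
            continue
        obs = float(y[sel].sum())
        exp = float(pred[sel].sum())
        denom = exp * (1.0 - exp / n_g)
        if denom <= 0:
            if abs(obs - exp) > 1e-12:
                raise ValueError("group with zero expected variance but nonzero residual")
            n_groups += 1
            continue
        stat += (obs - exp) ** 2 / denom
        n_groups += 1
    df = max(n_groups - 2, 1)
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def scaled_brier(pred, y) -> float:
    """Scaled Brier score, 1 - BS / BS_ref with BS_ref = pbar(1 - pbar).

    0 for the constant event-rate predictor, 1 for perfect predictions.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    pbar = y.mean()
    bs_ref = pbar * (1.0 - pbar)
    if bs_ref == 0:
        raise ValueError("scaled Brier undefined for a single-class outcome")
    bs = float(np.mean((pred - y) ** 2))
    return 1.0 - bs / bs_ref


def calibration_slope(pred, y) -> tuple[float, float]:
    """Logistic recalibration of ``y`` on logit(pred): (slope, intercept)."""
    import statsmodels.api as sm

    pred = np.asarray(pred, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if np.any((pred <= 0) | (pred >= 1)):
        raise ValueError("predictions must lie strictly inside (0, 1)")
    lp = np.log(pred / (1 - pred))
    if np.ptp(lp) == 0:
        raise ValueError("constant predictions carry no calibration slope")
    X = sm.add_constant(lp)
    res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
    return float(res.params[1]), float(res.params[0])


@dataclass
class ValidationReport:
    """Discrimination and calibration summary for fitted NTCP predictions."""

    auc: float
    hl_stat: float
    hl_df: int
    hl_p: float
    scaled_brier: float
    calibration_slope: float
    calibration_intercept: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "hosmer_lemeshow": {"stat": self.hl_stat, "df": self.hl_df, "p": self.hl_p},
            "scaled_brier": self.scaled_brier,
            "calibration_slope": self.calibration_slope,
            "calibration_intercept": self.calibration_intercept,
        }


def validate_predictions(pred, y, hl_groups: int = 10) -> ValidationReport:
    """Compute AUC, Hosmer-Lemeshow, scaled Brier and calibration slope."""
    stat, df, p = hosmer_lemeshow(pred, y, groups=hl_groups)
    slope, intercept = calibration_slope(pred, y)
    return ValidationReport(
        auc=auc(pred, y), hl_stat=stat, hl_df=df, hl_p=p,
        scaled_brier=scaled_brier(pred, y),
        calibration_slope=slope, calibration_intercept=intercept,
    )
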