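"""Propensity-score estimation and 1:1 caliper matching without replacement.

Treatment modality in an observational radiotherapy cohort is confounded
with baseline covariates (age, stage, nodal irradiation, chemotherapy).
The remedy implemented here is the standard one: model the probability of
receiving the comparison modality given the covariates with a logistic
regression (the propensity score), then pair each treated patient with the
nearest unmatched control on the logit of that score, refusing pairs
farther apart than a caliper of 0.2 times the pooled standard deviation of
the logit scores.  Balance before and after matching is summarised with
standardised mean differences and two-sided tests.

:class:`PropensityMatcher` is the estimator-style entry point; the
module-level functions expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "SeparationError",
    "PropensityModel",
    "MatchResult",
    "fit_propensity",
    "match_caliper",
    "balance_diagnostics",
    "PropensityMatcher",
    "DEFAULT_COVARIATES",
]

#: Matching covariates: age (continuous), AJCC stage (ordinal 1-3),
#: supraclavicular irradiation and chemotherapy (binary).
DEFAULT_COVARIATES = ("age", "ajcc", "scf", "chemo")


class SeparationError(RuntimeError):
    """A covariate perfectly predicts the treatment arm."""


@dataclass
class PropensityModel:
    """Fitted logistic propensity model and per-patient scores."""

    covariates: list[str]
    coef: pd.Series                  # includes "const"
    propensity: pd.Series            # P(arm = treated_label | covariates)
    logit: pd.Series
    treated_label: str

    def __post_init__(self) -> None:
        p = self.propensity.to_numpy()
        if np.any((p <= 0) | (p >= 1)) or not np.all(np.isfinite(self.logit)):
            raise ValueError("propensity scores must lie strictly inside (0, 1)")


@dataclass
class MatchResult:
    """1:1 pairs with caliper bookkeeping.

    Each patient id appears in at most one pair and every pair's logit
    distance is within the caliper (checked on construction).
    """

    pairs: list[tuple[str, str, float]]   # (treated id, control id, |logit diff|)
    caliper: float
    unmatched_treated: list[str] = field(default_factory=list)
    unmatched_control: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        t = [a for a, _, _ in self.pairs]
        c = [b for _, b, _ in self.pairs]
        if len(set(t)) != len(t) or len(set(c)) != len(c):
            raise ValueError("an id is reused across pairs")
        if any(d > self.caliper + 1e-12 for _, _, d in self.pairs):
            raise ValueError("pair distance exceeds the caliper")

    @property
    def matched_ids(self) -> list[str]:
        return [a for a, _, _ in self.pairs] + [b for _, b, _ in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id", "distance"])


def _check_separation(X: pd.DataFrame, treated: np.ndarray) -> None:
    for col in X.columns:
        a = X.loc[treated, col]
        b = X.loc[~treated, col]
        if a.min() > b.max() or b.min() > a.max():
            raise SeparationError(f"covariate {col!r} perfectly separates the arms")


def fit_propensity(df: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                   arm_col: str = "modality", treated_label: str = "IMRT") -> PropensityModel:
    """Fit P(arm = ``treated_label`` | covariates) by Newton-type ML.

    ``df`` is a cohort covariate frame (see ``cohort_to_dataframe``); every
    patient receives a propensity score and its logit.  Perfect separation
    by any single covariate raises :class:`SeparationError` naming it.
    """
    covariates = list(covariates)
    arms = df[arm_col]
    if arms.nunique() != 2:
        raise ValueError("propensity fitting needs exactly two arms")
    treated = (arms == treated_label).to_numpy()
    if treated.sum() < 2 or (~treated).sum() < 2:
        raise ValueError("need at least two patients per arm")
    X = df[covariates].astype(float)
    _check_separation(X, treated)
    Xc = sm.add_constant(X)
    try:
        res = sm.Logit(treated.astype(float), Xc).fit(
            disp=0, method="newton", maxiter=200, tol=1e-10
        )
    except Exception as exc:  # statsmodels raises on detected separation too
        raise SeparationError(f"propensity fit failed: {exc}") from exc
    if np.max(np.abs(res.params[1:])) > 30:
        raise SeparationError("propensity coefficients diverged (quasi-separation)")
    p = pd.Series(res.predict(Xc), index=df.index).clip(1e-12, 1 - 1e-12)
    return PropensityModel(
        covariates=covariates,
        coef=pd.Series(res.params, index=Xc.columns),
        propensity=p,
        logit=np.log(p / (1 - p)),
        treated_label=treated_label,
    )


def match_caliper(logit: pd.Series, arms: pd.Series, treated_label: str = "IMRT",
                  caliper_mult: float = 0.2, seed: int | None = 0) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the logit propensity.

    The caliper is ``caliper_mult`` times the standard deviation of the
    logit scores over the pooled cohort.  Treated units are processed in
    descending propensity order; each takes its nearest unused control
    within the caliper.  Distance ties break on smaller control id, with a
    seeded shuffle only among exactly tied ids.
    """
    if caliper_mult <= 0:
        raise ValueError("caliper_mult must be positive")
    treated_mask = arms == treated_label
    if treated_mask.sum() == 0 or (~treated_mask).sum() == 0:
        raise ValueError("both arms must be non-empty")
    caliper = caliper_mult * float(np.std(logit.to_numpy(), ddof=1))

    controls = logit[~treated_mask].sort_index()
    available = dict(controls.items())
    pairs: list[tuple[str, str, float]] = []
    unmatched_t: list[str] = []
    order = logit[treated_mask].sort_values(ascending=False, kind="stable")
    for tid, tlogit in order.items():
        if not available:
            unmatched_t.append(tid)
            continue
        ids = list(available)
        dists = np.abs(np.asarray([available[c] for c in ids]) - tlogit)
        best = float(dists.min())
        if best > caliper:
            unmatched_t.append(tid)
            continue
        tied = sorted(c for c, d in zip(ids, dists) if d == best)
        cid = tied[0]
        pairs.append((tid, cid, best))
        del available[cid]
    return MatchResult(
        pairs=pairs, caliper=caliper,
        unmatched_treated=unmatched_t,
        unmatched_control=sorted(available),
        seed=seed,
    )


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardised mean difference with the pooled-variance denominator."""
    va, vb = np.var(a, ddof=1) if a.size > 1 else 0.0, np.var(b, ddof=1) if b.size > 1 else 0.0
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0:
        return 0.0 if np.mean(a) == np.mean(b) else np.inf
    return float((np.mean(a) - np.mean(b)) / denom)


def _p_value(a: np.ndarray, b: np.ndarray, binary: bool) -> float:
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    if binary:
        table = np.array(
            [[np.sum(a == 1), np.sum(a == 0)], [np.sum(b == 1), np.sum(b == 0)]]
        )
        if np.any(table.sum(axis=0) == 0):
            return 1.0
        return float(stats.chi2_contingency(table, correction=False).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def balance_diagnostics(df: pd.DataFrame, match: MatchResult,
                        covariates=DEFAULT_COVARIATES, arm_col: str = "modality",
                        treated_label: str = "IMRT") -> pd.DataFrame:
    """Pre/post-match SMD and p-value per covariate.

    Raises on an empty pair list rather than reporting vacuous balance.
    """
    if not match.pairs:
        raise ValueError("no matched pairs: balance diagnostics undefined")
    treated = df[arm_col] == treated_label
    t_ids = [a for a, _, _ in match.pairs]
    c_ids = [b for _, b, _ in match.pairs]
    rows = []
    for cov in covariates:
        col = df[cov].astype(float)
        a_pre, b_pre = col[treated].to_numpy(), col[~treated].to_numpy()
        a_post, b_post = col.loc[t_ids].to_numpy(), col.loc[c_ids].to_numpy()
        binary = set(np.unique(col)) <= {0.0, 1.0}
        rows.append(
            {
                "covariate": cov,
                "smd_pre": _smd(a_pre, b_pre),
                "smd_post": _smd(a_post, b_post),
                "p_pre": _p_value(a_pre, b_pre, binary),
                "p_post": _p_value(a_post, b_post, binary),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


class PropensityMatcher(BaseEstimator):
    """Propensity fit plus caliper matching as one estimator.

    ``fit(df)`` expects a cohort covariate DataFrame carrying the arm
    column; fitted attributes: ``model_`` (:class:`PropensityModel`),
    ``match_`` (:class:`MatchResult`), ``balance_`` (diagnostics frame).
    """

    def __init__(self, covariates=DEFAULT_COVARIATES, arm_col: str = "modality",
                 treated_label: str = "IMRT", caliper_mult: float = 0.2,
                 random_state: int | None = 0):
        self.covariates = covariates
        self.arm_col = arm_col
        self.treated_label = treated_label
        self.caliper_mult = caliper_mult
        self.random_state = random_state

    def fit(self, df: pd.DataFrame, y=None):
        self.model_ = fit_propensity(
            df, self.covariates, self.arm_col, self.treated_label
        )
        self.match_ = match_caliper(
            self.model_.logit, df[self.arm_col], self.treated_label,
            self.caliper_mult, self.random_state,
        )
        self.balance_ = balance_diagnostics(
            df, self.match_, self.covariates, self.arm_col, self.treated_label
        )
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        """Restrict a cohort frame to the matched patients."""
        return df.loc[self.match_.matched_ids]
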