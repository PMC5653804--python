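"""Secondary-cancer risk: risk-equivalent dose, OED and excess absolute risk.

The mechanistic carcinoma-induction model used here weights each dose level
by a cell-kill/repopulation response before averaging over the organ.  For
a dose bin receiving total dose ``D`` (delivered in fractions of ``d`` Gy),
with fractionation-corrected cell-kill parameter

    alpha' = alpha * (1 + d / (alpha/beta ratio)),

the risk-equivalent dose (RED) of the full model is

    RED(D) = exp(-alpha' D) / (alpha' R)
             * [1 - 2R + R^2 exp(alpha' D)
                - (1 - R)^2 exp(-(alpha' R / (1 - R)) D)],

where ``R`` in [0, 1] is the repopulation/repair parameter.  The limits
``R -> 0`` (bell-shaped, full cell kill) and ``R -> 1`` (plateau, full
repopulation) have closed forms and are used near the boundary.  RED has
slope 1 at the origin, so the organ-equivalent dose (OED) — the
volume-weighted average of RED over the differential DVH — reduces to the
mean dose when the response is linear.

The excess absolute risk (EAR, excess cancer cases per 10,000 person-years)
scales the OED by an organ-specific slope ``beta_ear`` defined for exposure
at age 30 and attainment at age 70, modified for other ages by

    mu(age_x, age_a) = exp(gamma_e (age_x - 30) + gamma_a ln(age_a / 70)).

Organ parameter values are inputs loaded from a YAML/CSV config; the
packaged template ``organ_params_synthetic.yaml`` carries synthetic
placeholder values for testing and must be replaced with published fits
for real analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import Patient
from .dvh import DVH, to_differential

__all__ = [
    "OrganRiskParams",
    "load_organ_params",
    "load_synthetic_organ_params",
    "fraction_dose",
    "red_full",
    "oed",
    "ear",
    "accumulated_ear",
    "cohort_scr",
]

# Switch to the closed-form R-limits within this distance of the boundary.
# The general expression differs from the limit by O(eps * RED) at the
# switch point, so a 1e-7 window keeps the jump below 1e-5 Gy for any
# realistic plateau value while staying far from catastrophic cancellation.
_R_EDGE = 1e-7


@dataclass
class OrganRiskParams:
    """Carcinoma-induction model constants for one organ.

    ``alpha`` in 1/Gy; ``R`` dimensionless in [0, 1]; ``beta_ear`` in
    excess cases per 10,000 PY per Gy at the reference ages (30/70);
    ``gamma_e``/``gamma_a`` dimensionless age modifiers; ``alpha_beta``
    the fractionation-sensitivity ratio in Gy.
    """

    organ: str
    alpha: float
    R: float
    beta_ear: float
    gamma_e: float
    gamma_a: float
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R must lie in [0, 1]")
        if self.alpha_beta <= 0:
            raise ValueError("alpha/beta ratio must be positive")


def load_organ_params(source) -> dict[str, OrganRiskParams]:
    """Load per-organ parameters from a YAML mapping or an open stream."""
    if isinstance(source, dict):
        raw = source
    elif isinstance(source, (str, bytes)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    out = {}
    for organ, vals in raw.items():
        if organ.startswith("_"):
            continue
        out[organ] = OrganRiskParams(organ=organ, **vals)
    return out


def load_synthetic_organ_params() -> dict[str, OrganRiskParams]:
    """Packaged synthetic parameter template (testing/demo only)."""
    with resources.files("rtrisk.data").joinpath(
        "organ_params_synthetic.yaml"
    ).open() as fh:
        return load_organ_params(fh)


def fraction_dose(D, n_fractions: int):
    """Dose per fraction at a DVH bin, assuming a uniform fraction pattern."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be at least 1")
    return np.asarray(D, dtype=float) / n_fractions if not np.isscalar(D) else float(D) / n_fractions


def _alpha_prime(d, p: OrganRiskParams):
    """Fractionation-corrected cell kill: alpha (1 + d / (alpha/beta))."""
    ap = p.alpha * (1.0 + np.asarray(d, dtype=float) / p.alpha_beta)
    if np.any(ap <= 0):
        raise ValueError("alpha' must be positive")
    return ap


def red_full(D, d, p: OrganRiskParams):
    """Risk-equivalent dose of the full carcinoma model, in Gy.

    ``D`` total dose at the bin, ``d`` the corresponding dose per fraction.
    Vectorised over ``D``/``d``.  Near the ``R`` boundaries the closed-form
    bell (R=0) and plateau (R=1) limits are evaluated instead of the
    general expression, which is 0/0 there.
    """
    D = np.asarray(D, dtype=float)
    scalar = D.ndim == 0
    D = np.atleast_1d(D)
    ap = np.atleast_1d(_alpha_prime(d, p))
    if np.any(D < 0):
        raise ValueError("dose must be non-negative")
    R = p.R
    if R <= _R_EDGE:
        out = D * np.exp(-ap * D)
    elif R >= 1.0 - _R_EDGE:
        out = (1.0 - np.exp(-ap * D)) / ap
    else:
        out = (
            np.exp(-ap * D) / (ap * R)
            * (
                1.0
                - 2.0 * R
                + R**2 * np.exp(ap * D)
                - (1.0 - R) ** 2 * np.exp(-(ap * R / (1.0 - R)) * D)
            )
        )
    out = np.clip(out, 0.0, None)
    out[D == 0.0] = 0.0  # the bracket vanishes identically at zero dose
    return float(out[0]) if scalar else out


def oed(dvh: DVH, p: OrganRiskParams, n_fractions: int = 30) -> float:
    """Organ-equivalent dose: volume-weighted mean RED over the DVH.

    Uses the differential representation with bin-midpoint doses; weights
    are the bin volume fractions (summing to 1).
    """
    dd = to_differential(dvh)
    w = dd.values / 100.0
    mid = 0.5 * (dd.bin_edges[:-1] + dd.bin_edges[1:])
    d = fraction_dose(mid, n_fractions)
    return float(np.sum(w * red_full(mid, d, p)))


def ear(oed_value: float, p: OrganRiskParams, age_x: float, age_a: float = 70.0) -> float:
    """Excess absolute risk per 10,000 person-years at the given ages."""
    if age_x <= 0 or age_a <= 0:
        raise ValueError("ages must be positive")
    if age_a < age_x:
        raise ValueError("attained age must be at least the exposure age")
    mu = np.exp(p.gamma_e * (age_x - 30.0) + p.gamma_a * np.log(age_a / 70.0))
    return float(p.beta_ear * oed_value * mu)


def accumulated_ear(oed_value: float, p: OrganRiskParams, age_x: float,
                    age_stop: float = 70.0, latency: float = 0.0) -> float:
    """Sum of yearly EARs over attained ages from exposure (+latency) to 70.

    One definition of a lifetime-accumulated excess risk; the point value
    at the stop age is available directly from :func:`ear`.
    """
    start = int(np.ceil(age_x + latency))
    if start > age_stop:
        return 0.0
    ages = np.arange(start, int(age_stop) + 1, dtype=float)
    return float(sum(ear(oed_value, p, age_x, a) for a in ages))


def cohort_scr(cohort: list[Patient], params: dict[str, OrganRiskParams],
               n_fractions: int = 30, age_a: float = 70.0,
               age_cutoff: float = 65.0, test: str = "ranksum"):
    """Per-patient OED/EAR for every parameterised organ, plus arm contrast.

    Patients older than ``age_cutoff`` at treatment are excluded.  Returns
    ``(results, comparison)``: a long DataFrame of per-patient values and a
    per-organ frame of arm means, SDs and a two-sided p-value (rank-sum by
    default, Welch t-test with ``test="ttest"``).
    """
    eligible = [p for p in cohort if p.age <= age_cutoff]
    if not eligible:
        raise ValueError("no patients at or below the age cutoff")
    rows = []
    for pat in eligible:
        for organ, d in pat.dvhs.items():
            if organ not in params:
                warnings.warn(f"no risk parameters for organ {organ!r}; skipped")
                continue
            o = oed(d, params[organ], n_fractions)
            rows.append(
                {
                    "id": pat.id,
                    "modality": pat.modality,
                    "organ": organ,
                    "age_x": pat.age,
                    "age_a": age_a,
                    "oed": o,
                    "ear": ear(o, params[organ], pat.age, age_a),
                }
            )
    results = pd.DataFrame(rows)
    if results.empty:
        raise ValueError("no organ had risk parameters")

    comp_rows = []
    for organ, grp in results.groupby("organ"):
        arms = sorted(grp["modality"].unique())
        row: dict = {"organ": organ}
        for metric in ("oed", "ear"):
            for arm in arms:
                v = grp.loc[grp["modality"] == arm, metric]
                row[f"{metric}_mean_{arm}"] = float(v.mean())
                row[f"{metric}_sd_{arm}"] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
            if len(arms) == 2:
                a = grp.loc[grp["modality"] == arms[0], metric].to_numpy()
                b = grp.loc[grp["modality"] == arms[1], metric].to_numpy()
                if np.array_equal(np.sort(a), np.sort(b)):
                    pv = 1.0
                elif test == "ranksum":
                    pv = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                elif test == "ttest":
                    pv = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                else:
                    raise ValueError("test must be 'ranksum' or 'ttest'")
                row[f"{metric}_p"] = pv
        comp_rows.append(row)
    comparison = pd.DataFrame(comp_rows).set_index("organ")
    return results, comparison
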