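"""Patient cohorts: data model, baseline fixture, and synthetic generation.

Real per-patient radiotherapy records (covariates, treatment modality,
pneumonitis grade, per-organ DVHs) are rarely shareable, so this module
provides two sources of cohorts:

* a packaged fixture with the matched 32:32 IMRT/VMAT baseline table
  (category counts per arm), expandable into a covariate-level cohort for
  event accounting and table-one reproduction; and
* a parametric synthetic generator with a known dose-response ground truth,
  which gives every downstream stage (matching, factor selection, NTCP
  fitting, secondary-cancer risk) a testable input.

The generator draws covariates from configurable marginals, assigns the
treatment modality through a logistic model on those covariates (creating
realistic pre-matching imbalance), builds per-organ cumulative DVHs from a
modality-dependent sigmoid shape family, and draws the pneumonitis outcome
from a Lyman-Kutcher-Burman model on a chosen dosimetric factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import DVH, dosimetric_vector, mean_dose, read_dvh_file, v_at, write_dvh_file

__all__ = [
    "ORGANS",
    "Patient",
    "OrganShape",
    "SynthConfig",
    "generate_cohort",
    "load_table1_fixture",
    "matched_fixture_cohort",
    "table_one",
    "count_rp_events",
    "factor_value",
    "factor_matrix",
    "cohort_to_dataframe",
    "write_cohort",
    "read_cohort",
]

#: The six organs at risk carried by generated cohorts.
ORGANS = (
    "ipsilateral_lung",
    "contralateral_lung",
    "contralateral_breast",
    "spinal_cord",
    "liver",
    "stomach",
)

MODALITIES = ("IMRT", "VMAT")


@dataclass
class Patient:
    """One treated patient: baseline covariates, outcome and dosimetry.

    ``rp_grade`` is the chest-CT density-change grade (0 none, 1 linear
    streaks, 2 moderate opacity, 3 complete opacity); the modelling
    endpoint downstream is grade >= 1.
    """

    id: str
    age: float
    ajcc: int          # AJCC stage 1-3, ordinal
    t_stage: int       # 1-4
    n_stage: int       # 0-3
    scf: bool          # supraclavicular fossa irradiated
    chemo: bool        # concurrent chemotherapy
    modality: str      # "IMRT" | "VMAT"
    rp_grade: int      # 0-3
    dvhs: dict[str, DVH] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.rp_grade not in (0, 1, 2, 3):
            raise ValueError("rp_grade must be 0-3")


# ---------------------------------------------------------------------------
# packaged matched-cohort fixture
# ---------------------------------------------------------------------------

def load_table1_fixture() -> dict:
    """Raw matched-cohort baseline counts shipped with the package."""
    with resources.files("rtrisk.data").joinpath("table1_matched.json").open() as fh:
        return json.load(fh)

_AGE_BIN_REP = {"<=40": 35.0, "41-50": 45.0, "51-60": 55.0, ">61": 65.0}


def matched_fixture_cohort() -> list[Patient]:
    """Expand the packaged matched baseline counts into 64 patients.

    Each arm's categorical marginals are reproduced exactly; the joint
    distribution across covariates is not known from the counts, so
    covariates are expanded independently in deterministic order.  Ages take
    the representative value of their bin.  No DVHs are attached: the
    fixture supports event accounting and baseline tabulation, not
    dosimetric analysis.
    """
    fx = load_table1_fixture()
    cohort: list[Patient] = []
    for arm, counts in fx["arms"].items():
        n = counts["n"]

        def expand(table: dict, cast=lambda v: v) -> list:
            seq: list = []
            for key, cnt in table.items():
                seq.extend([cast(key)] * cnt)
            if len(seq) != n:
                raise ValueError(f"fixture counts for {arm} do not sum to {n}")
            return seq

        ages = expand(counts["age_bins"], lambda k: _AGE_BIN_REP[k])
        scf = expand(counts["scf"], lambda k: k == "yes")
        ajcc = expand(counts["ajcc"], int)
        t_st = expand(counts["t_stage"], int)
        n_st = expand(counts["n_stage"], int)
        chemo = expand(counts["chemo"], lambda k: k == "yes")
        rp = expand(counts["rp_grade"], int)
        for i in range(n):
            cohort.append(
                Patient(
                    id=f"{arm}-{i:03d}",
                    age=ages[i],
                    ajcc=ajcc[i],
                    t_stage=t_st[i],
                    n_stage=n_st[i],
                    scf=scf[i],
                    chemo=chemo[i],
                    modality=arm,
                    rp_grade=rp[i],
                )
            )
    return cohort


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

@dataclass
class OrganShape:
    """Sigmoid cumulative-DVH shape family for one organ.

    The cumulative curve is a decreasing logistic in dose, renormalised to
    100% at 0 Gy and 0% at ``max_dose``:

        V(x) = 100 * (S(x) - S(Dmax)) / (S(0) - S(Dmax)),
        S(x) = 1 / (1 + exp((x - loc) / scale)).

    ``loc`` shifts the curve's shoulder (per-modality mean, patient-level
    jitter ``loc_sd``); ``scale`` controls the fall-off width.
    """

    loc: dict[str, float]
    scale: float
    loc_sd: float = 2.0
    scale_sd: float = 0.5
    max_dose: float = 63.0


@dataclass
class LungBandModel:
    """Band-mass model for the ipsilateral-lung DVH.

    The differential DVH is drawn as independent lognormal masses around a
    modality-dependent template over 5-Gy dose bands (a large unirradiated
    /low-dose bulk, a decaying bath, and a high-dose shoulder near the
    prescription), then normalised to 100% and spread uniformly over 1-Gy
    bins.  Independent band-level variation reflects anatomy- and
    plan-driven heterogeneity and gives every V_x candidate metric its own
    information content, so the dose-response ground truth on one band
    boundary is identifiable.
    """

    #: mean masses for bands 0-5, 5-10, ..., 35-40 Gy (shared template)
    low_template: tuple[float, ...] = (40.0, 12.0, 8.0, 6.0, 5.0, 4.0, 3.5, 3.0)
    #: mean masses for bands 40-45, ..., 55-60, 60-63 Gy per modality
    high_template: dict = field(
        default_factory=lambda: {
            "IMRT": (3.6, 3.6, 3.6, 3.6, 1.4),
            "VMAT": (2.448, 2.448, 2.448, 2.448, 0.952),
        }
    )
    #: VMAT's partial arcs expose a smaller low-dose bath
    bath_scale: dict = field(default_factory=lambda: {"IMRT": 1.0, "VMAT": 0.8})
    sigma: float = 0.9       # lognormal sd of band masses
    sigma_bulk: float = 0.3  # the unirradiated bulk varies less
    max_dose: float = 63.0


def _default_organ_shapes() -> dict[str, OrganShape]:
    # VMAT spreads slightly more low dose to the contralateral lung and
    # breast; the cord/liver/stomach see low doses under both techniques.
    return {
        "contralateral_lung": OrganShape(
            loc={"IMRT": 1.0, "VMAT": 3.0}, scale=3.0, loc_sd=1.5,
            scale_sd=0.5, max_dose=30.0,
        ),
        "contralateral_breast": OrganShape(
            loc={"IMRT": 1.0, "VMAT": 3.5}, scale=3.5, loc_sd=1.5,
            scale_sd=0.5, max_dose=35.0,
        ),
        "spinal_cord": OrganShape(
            loc={"IMRT": 4.0, "VMAT": 3.0}, scale=4.0, loc_sd=1.5,
            scale_sd=0.5, max_dose=45.0,
        ),
        "liver": OrganShape(
            loc={"IMRT": 2.0, "VMAT": 2.0}, scale=4.0, loc_sd=1.5,
            scale_sd=0.5, max_dose=40.0,
        ),
        "stomach": OrganShape(
            loc={"IMRT": 1.5, "VMAT": 1.5}, scale=3.0, loc_sd=1.0,
            scale_sd=0.5, max_dose=35.0,
        ),
    }


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort generator.

    Covariate marginals default to the pooled unmatched baseline of the
    90-patient cohort the generator emulates; the treatment-assignment
    coefficients reproduce its pre-matching imbalance (VMAT patients
    younger, lower stage, less supraclavicular irradiation and
    chemotherapy).  ``confounding`` scales the assignment coefficients:
    0 gives a randomised cohort.
    """

    n_per_arm: int = 32
    seed: int | None = None

    # covariate marginals (pooled unmatched cohort)
    age_mean: float = 52.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (25.0, 80.0)
    ajcc_probs: tuple[float, ...] = (0.59, 0.17, 0.24)        # stages 1..3
    t_probs: tuple[float, ...] = (0.49, 0.44, 0.05, 0.02)     # T1..T4
    n_probs: tuple[float, ...] = (0.57, 0.22, 0.10, 0.11)     # N0..N3
    scf_p: float = 0.41
    chemo_p: float = 0.57

    # logistic treatment assignment: logit P(VMAT) = intercept + coeffs . z
    confounding: float = 1.0
    assign_intercept: float = 0.8
    assign_coefs: dict = field(
        default_factory=lambda: {
            "age": -0.30,    # per decade above 52
            "ajcc": -0.50,   # per stage above 2
            "scf": -1.00,
            "chemo": -0.60,
        }
    )

    organ_shapes: dict[str, OrganShape] = field(default_factory=_default_organ_shapes)
    lung_bands: LungBandModel = field(default_factory=LungBandModel)
    n_dvh_bins: int = 64

    # ground-truth dose response for the pneumonitis outcome
    truth_factor: str = "IV40"
    truth_tv50: float = 15.07
    truth_m: float = 0.62
    grade_split: tuple[float, ...] = (20.0, 9.0, 2.0)  # grades 1:2:3 among events

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if self.truth_tv50 <= 0 or self.truth_m <= 0:
            raise ValueError("LKB ground truth requires TV50 > 0 and m > 0")
        for p in (*self.ajcc_probs, *self.t_probs, *self.n_probs,
                  self.scf_p, self.chemo_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def factor_value(p: Patient, factor: str, organ: str = "ipsilateral_lung") -> float:
    """Evaluate a named dosimetric factor (``MD`` or ``IV<x>``/``V<x>``)."""
    d = p.dvhs[organ]
    if factor == "MD":
        return mean_dose(d)
    name = factor.lstrip("IV") if factor.startswith(("IV", "V")) else None
    if name is None:
        raise ValueError(f"unknown dosimetric factor {factor!r}")
    return v_at(d, float(name))


def _make_lung_dvh(bands: LungBandModel, modality: str,
                   rng: np.random.Generator) -> DVH:
    low = np.asarray(bands.low_template, dtype=float).copy()
    low[1:] *= bands.bath_scale[modality]
    hi = np.asarray(bands.high_template[modality], dtype=float)
    # lognormal draws with mean equal to the template mass
    low_m = low * np.exp(
        bands.sigma * rng.standard_normal(low.size) - bands.sigma**2 / 2
    )
    low_m[0] = low[0] * np.exp(
        bands.sigma_bulk * rng.standard_normal() - bands.sigma_bulk**2 / 2
    )
    hi_m = hi * np.exp(bands.sigma * rng.standard_normal(hi.size) - bands.sigma**2 / 2)
    mass = np.concatenate([low_m, hi_m])
    mass = 100.0 * mass / mass.sum()

    band_edges = np.concatenate(
        [np.arange(0.0, 60.1, 5.0), [bands.max_dose]]
    )  # 0,5,...,60,63
    edges = np.arange(0.0, bands.max_dose + 0.5, 1.0)
    edges[-1] = bands.max_dose
    v = np.empty(edges.size - 1)
    for k in range(band_edges.size - 1):
        lo, hi_e = band_edges[k], band_edges[k + 1]
        sel = (edges[:-1] >= lo - 1e-9) & (edges[:-1] < hi_e - 1e-9)
        v[sel] = mass[k] / sel.sum()
    v *= 100.0 / v.sum()
    return DVH("ipsilateral_lung", "differential", edges, v)


def _make_dvh(organ: str, shape: OrganShape, modality: str, nbins: int,
              rng: np.random.Generator) -> DVH:
    loc = rng.normal(shape.loc[modality], shape.loc_sd)
    scale = max(1.0, rng.normal(shape.scale, shape.scale_sd))
    edges = np.linspace(0.0, shape.max_dose, nbins + 1)
    s = 1.0 / (1.0 + np.exp((edges - loc) / scale))
    v = 100.0 * (s - s[-1]) / (s[0] - s[-1])
    v[0], v[-1] = 100.0, 0.0
    return DVH(organ, "cumulative", edges, v)


def generate_cohort(cfg: SynthConfig, seed: int | None = None) -> list[Patient]:
    """Draw a reproducible synthetic cohort of ``2 * n_per_arm`` patients.

    Modality is assigned by the configured logistic model; arm sizes are
    therefore stochastic around the assignment probability rather than
    fixed.  The pneumonitis event indicator is Bernoulli with probability
    given by the LKB model on the ground-truth factor; event grades 1-3
    follow ``grade_split``.
    """
    from .ntcp import lkb_probability  # local import avoids a cycle

    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    n = 2 * cfg.n_per_arm
    lo, hi = cfg.age_range

    cohort: list[Patient] = []
    for i in range(n):
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), lo, hi))
        ajcc = int(rng.choice([1, 2, 3], p=np.asarray(cfg.ajcc_probs) / sum(cfg.ajcc_probs)))
        t_st = int(rng.choice([1, 2, 3, 4], p=np.asarray(cfg.t_probs) / sum(cfg.t_probs)))
        n_st = int(rng.choice([0, 1, 2, 3], p=np.asarray(cfg.n_probs) / sum(cfg.n_probs)))
        scf = bool(rng.random() < cfg.scf_p)
        chemo = bool(rng.random() < cfg.chemo_p)

        c = cfg.assign_coefs
        eta = cfg.assign_intercept + cfg.confounding * (
            c["age"] * (age - cfg.age_mean) / 10.0
            + c["ajcc"] * (ajcc - 2)
            + c["scf"] * scf
            + c["chemo"] * chemo
        )
        modality = "VMAT" if rng.random() < 1.0 / (1.0 + np.exp(-eta)) else "IMRT"

        dvhs = {"ipsilateral_lung": _make_lung_dvh(cfg.lung_bands, modality, rng)}
        for organ, shape in cfg.organ_shapes.items():
            dvhs[organ] = _make_dvh(organ, shape, modality, cfg.n_dvh_bins, rng)

        pat = Patient(
            id=f"P{i:04d}", age=age, ajcc=ajcc, t_stage=t_st, n_stage=n_st,
            scf=scf, chemo=chemo, modality=modality, rp_grade=0, dvhs=dvhs,
        )
        x = factor_value(pat, cfg.truth_factor)
        p_event = lkb_probability(x, cfg.truth_tv50, cfg.truth_m)
        if rng.random() < p_event:
            split = np.asarray(cfg.grade_split, dtype=float)
            pat.rp_grade = int(rng.choice([1, 2, 3], p=split / split.sum()))
        cohort.append(pat)
    return cohort


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

_CATEGORICALS = ("scf", "ajcc", "t_stage", "n_stage", "chemo", "rp_grade")


def cohort_to_dataframe(cohort: list[Patient]) -> pd.DataFrame:
    """Covariates/outcome as a DataFrame, one row per patient (no DVHs)."""
    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "age": [p.age for p in cohort],
            "ajcc": [p.ajcc for p in cohort],
            "t_stage": [p.t_stage for p in cohort],
            "n_stage": [p.n_stage for p in cohort],
            "scf": [int(p.scf) for p in cohort],
            "chemo": [int(p.chemo) for p in cohort],
            "modality": [p.modality for p in cohort],
            "rp_grade": [p.rp_grade for p in cohort],
        }
    ).set_index("id")


def factor_matrix(
    cohort: list[Patient],
    thresholds=tuple(float(x) for x in range(5, 55, 5)),
    organ: str = "ipsilateral_lung",
    prefix: str = "IV",
) -> pd.DataFrame:
    """Candidate dosimetric factor matrix (MD + V_x columns) for a cohort."""
    rows = {
        p.id: dosimetric_vector(p.dvhs[organ], tuple(thresholds), prefix=prefix)
        for p in cohort
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def table_one(cohort: list[Patient], grouping: str = "modality") -> pd.DataFrame:
    """Baseline characteristics by arm with between-arm tests.

    Categorical rows carry per-arm ``count (percent)`` and a chi-square
    p-value; the age row carries mean and range with a rank-sum p-value.
    """
    df = cohort_to_dataframe(cohort)
    groups = df[grouping].unique()
    if len(groups) < 2:
        raise ValueError("table_one needs at least two groups")
    groups = sorted(groups)
    rows = []
    arms = {g: df[df[grouping] == g] for g in groups}

    vals = [arms[g]["age"].to_numpy() for g in groups]
    try:
        p_age = float(stats.mannwhitneyu(*vals[:2], alternative="two-sided").pvalue)
    except ValueError:
        p_age = 1.0
    row = {"variable": "age", "level": "mean (range)"}
    for g in groups:
        a = arms[g]["age"]
        row[g] = f"{a.mean():.1f} ({a.min():.0f}-{a.max():.0f})"
    row["p"] = p_age
    rows.append(row)

    for var in _CATEGORICALS:
        levels = sorted(df[var].unique())
        table = np.array(
            [[int((arms[g][var] == lv).sum()) for g in groups] for lv in levels]
        )
        keep = table.sum(axis=1) > 0
        p_val = 1.0
        if keep.sum() >= 2:
            with np.errstate(invalid="ignore"):
                try:
                    p_val = float(stats.chi2_contingency(table[keep]).pvalue)
                except ValueError:
                    p_val = 1.0
        for j, lv in enumerate(levels):
            row = {"variable": var, "level": str(lv)}
            for k, g in enumerate(groups):
                n_g = len(arms[g])
                row[g] = f"{table[j, k]} ({100 * table[j, k] / n_g:.0f})"
            row["p"] = p_val if j == 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def count_rp_events(cohort: list[Patient], min_grade: int = 1) -> dict:
    """Count pneumonitis events (grade >= ``min_grade``), total and per arm."""
    n = len(cohort)
    by_arm: dict[str, int] = {}
    total = 0
    for p in cohort:
        hit = p.rp_grade >= min_grade
        by_arm[p.modality] = by_arm.get(p.modality, 0) + int(hit)
        total += int(hit)
    return {
        "n": n,
        "events": total,
        "by_arm": dict(sorted(by_arm.items())),
        "fraction": total / n if n else float("nan"),
    }


# ---------------------------------------------------------------------------
# cohort file I/O (cohort.csv + one DVH CSV per patient)
# ---------------------------------------------------------------------------

def write_cohort(directory, cohort: list[Patient]) -> None:
    """Write ``cohort.csv`` plus a ``dvh/`` sidecar directory of DVH CSVs."""
    directory = Path(directory)
    (directory / "dvh").mkdir(parents=True, exist_ok=True)
    cohort_to_dataframe(cohort).to_csv(directory / "cohort.csv")
    for p in cohort:
        if p.dvhs:
            write_dvh_file(str(directory / "dvh" / f"{p.id}.csv"), list(p.dvhs.values()))


def read_cohort(directory) -> list[Patient]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    df = pd.read_csv(directory / "cohort.csv", index_col="id")
    cohort = []
    for pid, row in df.iterrows():
        dvh_path = directory / "dvh" / f"{pid}.csv"
        dvhs = {}
        if dvh_path.exists():
            dvhs = {d.organ: d for d in read_dvh_file(str(dvh_path))}
        cohort.append(
            Patient(
                id=str(pid), age=float(row["age"]), ajcc=int(row["ajcc"]),
                t_stage=int(row["t_stage"]), n_stage=int(row["n_stage"]),
                scf=bool(row["scf"]), chemo=bool(row["chemo"]),
                modality=str(row["modality"]), rp_grade=int(row["rp_grade"]),
                dvhs=dvhs,
            )
        )
    return cohort
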