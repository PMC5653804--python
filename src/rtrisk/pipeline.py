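"""End-to-end workflow: cohort -> matching -> selection -> NTCP -> SCR.

``run_pipeline`` reproduces the full comparative analysis from either a
cohort directory on disk or a synthetic-generation config: propensity-match
the two modality arms, extract the candidate dosimetric factor matrix from
the matched patients' ipsilateral-lung DVHs, pick the dominant factor by
cross-validated LASSO, fit the LKB dose-response to the grade-1+
pneumonitis endpoint with profile-likelihood intervals and validation
metrics, and (when organ parameters are configured) compute per-organ
OED/EAR with an arm contrast.  All randomness fans out from one global
seed through fixed per-stage offsets so stages re-run identically in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scr as scr_mod
from .cohort import (
    SynthConfig, cohort_to_dataframe, count_rp_events, factor_matrix,
    generate_cohort, read_cohort, table_one, write_cohort,
)
from .matching import PropensityMatcher
from .ntcp import LKBModel, validate_predictions
from .selection import DominantFactorLasso

logger = logging.getLogger("rtrisk")

__all__ = ["RunConfig", "run_pipeline", "make_figures"]

# fixed per-stage seed offsets; kept small so seed + offset stays < 2**31
_STAGE_OFFSET = {"synth": 11, "match": 23, "select": 37, "ntcp": 51, "scr": 67}


@dataclass
class RunConfig:
    """Settings for one pipeline run (YAML-serialisable)."""

    outdir: str = "rtrisk_out"
    seed: int = 0
    cohort_dir: str | None = None          # read a cohort instead of synthesising
    n_per_arm: int = 32                    # synthesis size when cohort_dir is None
    covariates: tuple[str, ...] = ("age", "ajcc", "scf", "chemo")
    treated_label: str = "IMRT"
    caliper_mult: float = 0.2
    thresholds: tuple[float, ...] = tuple(float(x) for x in range(5, 55, 5))
    lasso_k: int = 10
    lasso_rule: str = "1se"
    lasso_loss: str = "deviance"
    organ_params: str | None = None        # YAML path; None skips the SCR stage
    use_synthetic_organ_params: bool = False
    n_fractions: int = 30
    age_attained: float = 70.0
    age_cutoff: float = 65.0
    scr_test: str = "ranksum"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + _STAGE_OFFSET[stage]) % (2**31 - 1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    Every table is also written under ``cfg.outdir``.  A missing organ
    parameter file only skips the secondary-cancer stage; the NTCP arm
    still completes (and vice versa: an NTCP failure does not block SCR).
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": dataclasses.asdict(cfg)}

    # ---- stage: cohort -------------------------------------------------
    if cfg.cohort_dir:
        cohort = read_cohort(cfg.cohort_dir)
        logger.info("loaded %d patients from %s", len(cohort), cfg.cohort_dir)
    else:
        scfg = SynthConfig(n_per_arm=cfg.n_per_arm)
        cohort = generate_cohort(scfg, seed=cfg.stage_seed("synth"))
        logger.info("synthesised %d patients", len(cohort))
        write_cohort(out / "cohort", cohort)
    df = cohort_to_dataframe(cohort)

    # ---- stage: matching ----------------------------------------------
    matcher = PropensityMatcher(
        covariates=cfg.covariates, treated_label=cfg.treated_label,
        caliper_mult=cfg.caliper_mult, random_state=cfg.stage_seed("match"),
    ).fit(df)
    matched_ids = matcher.match_.matched_ids
    matched = [p for p in cohort if p.id in set(matched_ids)]
    bundle["match"] = {
        "n_pairs": len(matcher.match_.pairs),
        "caliper": matcher.match_.caliper,
        "unmatched_treated": matcher.match_.unmatched_treated,
    }
    matcher.match_.to_frame().to_csv(out / "match.csv", index=False)
    matcher.balance_.to_csv(out / "balance.csv")
    t1 = table_one(matched)
    t1.to_csv(out / "table_one_matched.csv", index=False)
    bundle["events"] = count_rp_events(matched)
    logger.info("matched %d pairs; %d grade-1+ events",
                len(matcher.match_.pairs), bundle["events"]["events"])

    # ---- stage: factor selection + NTCP --------------------------------
    ntcp_error = None
    try:
        X = factor_matrix(matched, thresholds=cfg.thresholds)
        y = np.array([int(p.rp_grade >= 1) for p in matched])
        selector = DominantFactorLasso(
            k=cfg.lasso_k, rule=cfg.lasso_rule, loss=cfg.lasso_loss,
            random_state=cfg.stage_seed("select"),
        ).fit(X, y)
        factor = selector.dominant_factor_
        bundle["selection"] = {
            "dominant_factor": factor,
            "chosen_lambda": selector.lambda_,
            "ranking": selector.ranking_,
        }
        selector.path_.to_frame().to_csv(out / "lasso_path.csv", index=False)

        model = LKBModel(factor_name=factor,
                         random_state=cfg.stage_seed("ntcp")).fit(X[factor], y)
        pred = model.predict_proba(X[factor])
        report = validate_predictions(pred, y)
        bundle["ntcp"] = {
            "factor": factor,
            "tv50": model.tv50_,
            "m": model.m_,
            "loglik": model.loglik_,
            "ci_tv50": list(model.ci_tv50_),
            "ci_m": list(model.ci_m_),
            "n_events": model.n_events_,
            "validation": report.to_dict(),
        }
        with open(out / "ntcp_fit.json", "w") as fh:
            json.dump(bundle["ntcp"], fh, indent=2)
        grid = np.linspace(0.0, float(X[factor].max()) * 1.5, 200)
        pd.DataFrame({factor: grid, "ntcp": model.predict_proba(grid)}).to_csv(
            out / "dose_response.csv", index=False
        )
        bundle["_ntcp_scatter"] = pd.DataFrame(
            {"factor": X[factor].to_numpy(), "ntcp": pred, "event": y,
             "modality": [p.modality for p in matched]}
        )
    except Exception as exc:
        ntcp_error = f"NTCP stage failed: {exc}"
        logger.warning(ntcp_error)
        bundle["ntcp_error"] = ntcp_error

    # ---- stage: SCR ----------------------------------------------------
    params = None
    if cfg.use_synthetic_organ_params:
        params = scr_mod.load_synthetic_organ_params()
    elif cfg.organ_params:
        params = scr_mod.load_organ_params(cfg.organ_params)
    if params is None:
        logger.warning("no organ parameters configured; SCR stage skipped")
        bundle["scr_skipped"] = True
    else:
        try:
            results, comparison = scr_mod.cohort_scr(
                matched, params, n_fractions=cfg.n_fractions,
                age_a=cfg.age_attained, age_cutoff=cfg.age_cutoff,
                test=cfg.scr_test,
            )
            results.to_csv(out / "scr_results.csv", index=False)
            comparison.to_csv(out / "scr_comparison.csv")
            bundle["scr"] = {
                "n_eligible": int(results["id"].nunique()),
                "comparison": comparison.to_dict(orient="index"),
            }
            bundle["_scr_results"] = results
        except Exception as exc:
            logger.warning("SCR stage failed: %s", exc)
            bundle["scr_error"] = str(exc)

    if ntcp_error and "scr_error" in bundle:
        raise RuntimeError(f"both analysis arms failed: {ntcp_error}; {bundle['scr_error']}")

    bundle["_cohort"] = matched
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {k: v for k, v in bundle.items() if not k.startswith("_")},
            fh, indent=2, default=str,
        )
    return bundle


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def make_figures(bundle: dict, outdir=None) -> list[str]:
    """Render the standard figure set from a completed report bundle.

    Produces mean-DVH-by-arm, fitted dose-response with event markers,
    factor/NTCP scatter by arm, OED and EAR bar charts, and the
    NTCP-versus-EAR trend scatter.  Missing bundle components are named in
    the raised error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    missing = [k for k in ("config", "_cohort") if k not in bundle]
    if missing:
        raise ValueError(f"bundle is missing components: {missing}")
    out = Path(outdir or bundle["config"]["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    cohort = bundle["_cohort"]
    files: list[str] = []

    # mean ipsilateral-lung DVH per arm
    fig, ax = plt.subplots()
    arms = sorted({p.modality for p in cohort})
    if len(arms) < 2:
        warnings.warn("single-arm bundle: DVH plot degrades to one series")
    from .dvh import to_cumulative

    for arm in arms:
        vals = []
        for p in cohort:
            if p.modality == arm and "ipsilateral_lung" in p.dvhs:
                c = to_cumulative(p.dvhs["ipsilateral_lung"])
                vals.append(np.interp(np.linspace(0, 63, 100), c.bin_edges, c.values, right=0))
        if vals:
            ax.plot(np.linspace(0, 63, 100), np.mean(vals, axis=0), label=arm)
    ax.set_xlabel("Dose (Gy)"); ax.set_ylabel("Volume (%)"); ax.legend()
    ax.set_title("Mean ipsilateral-lung DVH by arm")
    f = out / "fig_mean_dvh.png"; fig.savefig(f, dpi=120); plt.close(fig); files.append(str(f))

    if "ntcp" in bundle and "_ntcp_scatter" in bundle:
        sc = bundle["_ntcp_scatter"]
        tv50, m = bundle["ntcp"]["tv50"], bundle["ntcp"]["m"]
        from .ntcp import lkb_probability
        grid = np.linspace(0, max(sc["factor"].max() * 1.4, tv50 * 1.6), 200)
        fig, ax = plt.subplots()
        ax.plot(grid, lkb_probability(grid, tv50, m), "k-")
        ax.plot(sc.loc[sc.event == 1, "factor"], np.full((sc.event == 1).sum(), 1.02), "|", color="C3")
        ax.plot(sc.loc[sc.event == 0, "factor"], np.full((sc.event == 0).sum(), -0.02), "|", color="C0")
        ax.set_xlabel(bundle["ntcp"]["factor"]); ax.set_ylabel("NTCP")
        ax.set_title(f"LKB fit: TV50={tv50:.2f}, m={m:.2f}")
        f = out / "fig_ntcp_curve.png"; fig.savefig(f, dpi=120); plt.close(fig); files.append(str(f))

        fig, ax = plt.subplots()
        for arm in arms:
            sel = sc["modality"] == arm
            ax.scatter(sc.loc[sel, "factor"], sc.loc[sel, "ntcp"], label=arm, alpha=0.7)
        ax.set_xlabel(bundle["ntcp"]["factor"]); ax.set_ylabel("NTCP"); ax.legend()
        f = out / "fig_factor_scatter.png"; fig.savefig(f, dpi=120); plt.close(fig); files.append(str(f))

    if "_scr_results" in bundle:
        res = bundle["_scr_results"]
        for metric, fname in (("oed", "fig_oed.png"), ("ear", "fig_ear.png")):
            piv = res.groupby(["organ", "modality"])[metric].agg(["mean", "std"]).unstack()
            fig, ax = plt.subplots(figsize=(8, 4))
            piv["mean"].plot.bar(yerr=piv["std"], ax=ax, capsize=3)
            ax.set_ylabel(metric.upper())
            fig.tight_layout()
            f = out / fname; fig.savefig(f, dpi=120); plt.close(fig); files.append(str(f))

        if "_ntcp_scatter" in bundle:
            sc = bundle["_ntcp_scatter"].copy()
            lung = res[res["organ"] == "ipsilateral_lung"].set_index("id")
            ids = [p.id for p in cohort]
            sc["id"] = ids[: len(sc)]
            merged = sc.set_index("id").join(lung[["ear"]], how="inner")
            fig, ax = plt.subplots()
            for arm in arms:
                sel = merged["modality"] == arm
                ax.scatter(merged.loc[sel, "ntcp"], merged.loc[sel, "ear"], label=arm, alpha=0.7)
            ax.set_xlabel("RP NTCP"); ax.set_ylabel("EAR (per 10,000 PY)"); ax.legend()
            f = out / "fig_ntcp_vs_ear.png"; fig.savefig(f, dpi=120); plt.close(fig); files.append(str(f))
    return files
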