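# rtrisk

Radiation-pneumonitis risk and secondary-cancer risk modelling for
breast-radiotherapy cohorts described by dose-volume histograms (DVHs).

Comparing two delivery techniques (fixed-field IMRT vs volumetric arcs,
VMAT) in an observational cohort raises two linked questions: which
dosimetric factor drives acute radiation pneumonitis (RP), and how do the
techniques trade off that acute risk against the long-term excess risk of
radiation-induced second cancers in nearby organs?  `rtrisk` implements
the full analysis chain for patient records of the form *baseline
covariates + treatment modality + CT-graded RP outcome + per-organ DVHs*:

1. **Propensity-score matching** — logistic model of modality on baseline
   covariates (age, AJCC stage, supraclavicular irradiation, chemotherapy);
   greedy 1:1 nearest-neighbour matching on the logit score without
   replacement, caliper 0.2 × SD(logit); balance diagnostics (standardised
   mean differences and two-sided tests).
2. **Dosimetric factor selection** — L1-penalised logistic regression
   (coordinate descent, 10-fold cross-validation, one-standard-error rule)
   over the candidate set {MD, IV5, IV10, …, IV50}, where IVx is the
   percent of ipsilateral-lung volume receiving ≥ x Gy and MD the mean
   lung dose.
3. **LKB NTCP fit** — Lyman–Kutcher–Burman probit dose-response with the
   volume parameter fixed at n = 1,

       NTCP(x) = Φ((x − TV50) / (m · TV50)),

   fit to the grade-1+ RP endpoint by maximum likelihood, with 95%
   profile-likelihood intervals (Δ2lnL = 3.84) and validation by AUC,
   Hosmer–Lemeshow test, scaled Brier score and calibration slope.
4. **Secondary-cancer risk** — Schneider-type full mechanistic carcinoma
   model: per-dose-bin risk-equivalent dose RED(D) with fractionation
   correction α′ = α(1 + d/(α/β)), α/β = 3 Gy; organ-equivalent dose
   OED = Σᵢ wᵢ·RED(Dᵢ) over the differential DVH; excess absolute risk
   EAR = β · OED · exp(γₑ(age_x − 30) + γₐ ln(age_a/70)) in excess cases
   per 10,000 person-years, with patients older than 65 at treatment
   excluded.

Because real patient records of this kind are restricted, the package
includes a first-class synthetic-cohort generator
(`rtrisk.cohort.SynthConfig` / `generate_cohort`) with known LKB ground
truth, plus the published matched baseline table as an in-package fixture
for event accounting.

## Worked example

```python
from rtrisk.pipeline import RunConfig, run_pipeline

cfg = RunConfig(outdir="out", seed=7, n_per_arm=150,
                use_synthetic_organ_params=True)
bundle = run_pipeline(cfg)
```

On this synthetic cohort (300 patients, LKB ground truth TV50 = 15.07,
m = 0.62 on IV40) the run prints/writes:

```
matched 111 pairs; 103 grade-1+ events   (IMRT 59, VMAT 44; caliper 0.170)
selection: dominant factor IV40, lambda = 0.0995
LKB fit:   TV50 = 15.17 (95% CI 13.74–16.78), m = 0.517 (95% CI 0.401–0.711)
validation: AUC 0.787, HL p 0.964, scaled Brier 0.257, calibration slope 0.995
SCR (synthetic organ parameters):
  ipsilateral lung  OED  IMRT 6.61 vs VMAT 6.25 Gy   (p = 0.002)
  ipsilateral lung  EAR  IMRT 55.1 vs VMAT 52.1 /10,000 PY (p = 0.005)
  contralateral breast EAR IMRT 26.9 vs VMAT 30.4 /10,000 PY (p < 0.001)
```

Reading: matching keeps the arms comparable; the selector recovers the
generating factor IV40; the refit TV50 is within 1% of the generating
value; and the arm contrast shows the expected trade-off — the arc
technique spares the ipsilateral lung (lower RP and lung OED/EAR) at the
cost of slightly more low dose to contralateral organs.  The inverse model
gives planning thresholds: `invert_lkb(0.25, 15.07, 0.62)` → 8.8% — keep
IV40 below ~8.8% to hold predicted RP risk under 25%.

The SCR organ parameters shipped with the package
(`rtrisk/data/organ_params_synthetic.yaml`) are synthetic placeholders;
replace them with published organ-specific fits for real analyses.

A CLI mirrors the library (`rtrisk synth | match | select | fit-ntcp |
scr | run | figures`); `rtrisk run --seed 7 --synthetic-params` performs
the pipeline above from a shell.

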