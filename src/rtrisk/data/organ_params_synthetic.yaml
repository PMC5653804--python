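# SYNTHETIC organ-risk parameter template.
#
# These values are placeholders with plausible orders of magnitude for the
# carcinoma-induction model (alpha in 1/Gy, R in [0,1], beta_ear in excess
# cases per 10,000 PY per Gy at reference ages 30/70, gamma_e and gamma_a
# dimensionless, alpha_beta in Gy).  They are NOT published organ fits:
# replace every entry with values from the epidemiological literature
# before drawing clinical conclusions.
_meta:
  synthetic: true

ipsilateral_lung:
  alpha: 0.04
  R: 0.8
  beta_ear: 8.0
  gamma_e: 0.002
  gamma_a: 4.0
  alpha_beta: 3.0
contralateral_lung:
  alpha: 0.04
  R: 0.8
  beta_ear: 8.0
  gamma_e: 0.002
  gamma_a: 4.0
  alpha_beta: 3.0
contralateral_breast:
  alpha: 0.06
  R: 0.5
  beta_ear: 10.0
  gamma_e: -0.01
  gamma_a: 2.0
  alpha_beta: 3.0
spinal_cord:
  alpha: 0.02
  R: 0.2
  beta_ear: 1.0
  gamma_e: 0.0
  gamma_a: 2.0
  alpha_beta: 3.0
liver:
  alpha: 0.03
  R: 0.5
  beta_ear: 2.0
  gamma_e: -0.02
  gamma_a: 3.0
  alpha_beta: 3.0
stomach:
  alpha: 0.05
  R: 0.5
  beta_ear: 3.0
  gamma_e: -0.01
  gamma_a: 2.0
  alpha_beta: 3.0
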