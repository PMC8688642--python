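# Default model configuration: NYC adult-smoker cohort, 2018 base year.
#
# Provenance of the numbers
# -------------------------
# * menthol_prevalence margins (25.6 / 83.8 / 59.8 by race/ethnicity,
#   44.1 / 59.3 by sex, 49% overall) are the published 2018 NYC survey
#   margins; the joint sex x race cells below are an independence
#   scaling of those margins (cell = race x sex / 0.49, clamped to 1),
#   because only the margins are published.  Edit the cells to override.
# * strata_weights and age_bands are derived from the same survey's
#   weighted counts.
# * risk-factor distributions, coefficients, the life table and the
#   cost block are SYNTHETIC plausible values: the underlying cohort
#   fits and expenditure figures are not published.  They are
#   calibrated only to coarse magnitudes (20-year cumulative MI
#   incidence among smokers in the 4-8% range; mean discounted 20-year
#   cost of order $40k per person).  Do not treat them as estimates.

population:
  n_default: 10000
  strata_weights:            # sex x race/ethnicity shares of adult smokers
    male:
      nl_white: 0.245422704
      nl_black: 0.181936909
      latino: 0.176507354
    female:
      nl_white: 0.160995792
      nl_black: 0.119349498
      latino: 0.115787743
  age_bands:                 # uniform within band; weights from survey counts
    - {lo: 18, hi: 25, weight: 0.075362}
    - {lo: 25, hi: 45, weight: 0.454744}
    - {lo: 45, hi: 65, weight: 0.388015}
    - {lo: 65, hi: 85, weight: 0.081879}
  risk_factors:              # independent parametric marginals (synthetic)
    bmi:   {family: lognormal, mean: 28.0, sd: 5.5, lo: 12, hi: 80}
    sbp:   {family: normal, mean: 124.0, sd: 14.0, lo: 70, hi: 260,
            age_slope: 0.45, age_ref: 45}
    ldl_c: {family: normal, mean: 116.0, sd: 30.0, lo: 20, hi: 400}
    hdl_c: {family: lognormal, mean: 51.0, sd: 14.0, lo: 10, hi: 150}
  diabetes_prevalence:
    male:
      nl_white: 0.10
      nl_black: 0.16
      latino: 0.17
    female:
      nl_white: 0.09
      nl_black: 0.17
      latino: 0.18
  menthol_prevalence:        # joint cells via independence scaling of margins
    male:
      nl_white: 0.2304
      nl_black: 0.7542
      latino: 0.5382
    female:
      nl_white: 0.309812
      nl_black: 1.0
      latino: 0.723702

coefficients:                # annual logistic transition models (synthetic)
  mi:
    alpha: -12.35
    betas:
      age: 0.065
      male: 0.45
      nl_black: 0.20
      latino: 0.05
      bmi: 0.020
      sbp: 0.012
      ldl_c: 0.006
      hdl_c: -0.020
      diabetes: 0.60
      current_smoker: 0.70
      former_smoker: 0.0
  stroke:
    alpha: -13.00
    betas:
      age: 0.072
      male: 0.20
      nl_black: 0.30
      latino: 0.10
      bmi: 0.012
      sbp: 0.016
      ldl_c: 0.003
      hdl_c: -0.012
      diabetes: 0.55
      current_smoker: 0.46
      former_smoker: 0.0
  cvd_death:
    alpha: -14.20
    betas:
      age: 0.085
      male: 0.35
      nl_black: 0.25
      latino: 0.08
      bmi: 0.015
      sbp: 0.012
      ldl_c: 0.004
      hdl_c: -0.015
      diabetes: 0.60
      current_smoker: 0.60
      former_smoker: 0.0

life_table:                  # annual non-CVD death probability (synthetic)
  male:
    - {lo: 18, hi: 30, q: 0.0015}
    - {lo: 30, hi: 40, q: 0.0022}
    - {lo: 40, hi: 50, q: 0.0042}
    - {lo: 50, hi: 60, q: 0.0085}
    - {lo: 60, hi: 70, q: 0.017}
    - {lo: 70, hi: 80, q: 0.038}
    - {lo: 80, hi: 90, q: 0.085}
    - {lo: 90, hi: 100, q: 0.18}
  female:
    - {lo: 18, hi: 30, q: 0.0009}
    - {lo: 30, hi: 40, q: 0.0014}
    - {lo: 40, hi: 50, q: 0.0028}
    - {lo: 50, hi: 60, q: 0.0060}
    - {lo: 60, hi: 70, q: 0.012}
    - {lo: 70, hi: 80, q: 0.027}
    - {lo: 80, hi: 90, q: 0.065}
    - {lo: 90, hi: 100, q: 0.15}

costs:                       # 2018 USD (synthetic placeholder magnitudes)
  discount_rate: 0.03
  base_year_index: 0
  background:                # annual background cost while alive
    - {lo: 18, hi: 35, cost: 1500}
    - {lo: 35, hi: 45, cost: 1900}
    - {lo: 45, hi: 55, cost: 2400}
    - {lo: 55, hi: 65, cost: 3000}
    - {lo: 65, hi: 75, cost: 4000}
    - {lo: 75, hi: 100, cost: 5200}
  mi_event_cost: 25000
  stroke_event_cost: 22000
  post_mi_annual_cost: 3600
  post_stroke_annual_cost: 4800

scenarios:
  - {name: status_quo, quit_proportion: 0.0, start_year_index: 0}
  - {name: menthol_ban, quit_proportion: 0.212, start_year_index: 0}

population_size: 880000      # adult smokers the per-person saving scales to
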