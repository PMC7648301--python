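# Framingham 2008 general cardiovascular disease risk (D'Agostino et al.,
# Circulation 2008; office-based lipid model).  10-year risk of total CVD.
version: "framingham/1.0"
age_window: [30, 74]
strata:
  female:
    baseline_survival: 0.95012
    mean_linear_predictor: 26.1931
    terms:
      - {features: [ln_age], coef: 2.32888}
      - {features: [ln_tc], coef: 1.20904}
      - {features: [ln_hdl], coef: -0.70833}
      - {features: [ln_sbp_untreated], coef: 2.76157}
      - {features: [ln_sbp_treated], coef: 2.82263}
      - {features: [smoker], coef: 0.52873}
      - {features: [diabetes], coef: 0.69154}
  male:
    baseline_survival: 0.88936
    mean_linear_predictor: 23.9802
    terms:
      - {features: [ln_age], coef: 3.06117}
      - {features: [ln_tc], coef: 1.12370}
      - {features: [ln_hdl], coef: -0.93263}
      - {features: [ln_sbp_untreated], coef: 1.93303}
      - {features: [ln_sbp_treated], coef: 1.99881}
      - {features: [smoker], coef: 0.65451}
      - {features: [diabetes], coef: 0.57367}
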