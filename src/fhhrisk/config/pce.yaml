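# Pooled cohort equations for 10-year hard-ASCVD risk (Goff et al.,
# 2013 ACC/AHA guideline, Appendix 7).  Race/sex-stratified; race strata
# outside {white, black} map to the white/other stratum.
version: "pce/1.0"
age_window: [40, 79]
strata:
  white_female:
    baseline_survival: 0.9665
    mean_linear_predictor: -29.18
    terms:
      - {features: [ln_age], coef: -29.799}
      - {features: [ln_age, ln_age], coef: 4.884}
      - {features: [ln_tc], coef: 13.540}
      - {features: [ln_age, ln_tc], coef: -3.114}
      - {features: [ln_hdl], coef: -13.578}
      - {features: [ln_age, ln_hdl], coef: 3.149}
      - {features: [ln_sbp_treated], coef: 2.019}
      - {features: [ln_sbp_untreated], coef: 1.957}
      - {features: [smoker], coef: 7.574}
      - {features: [ln_age, smoker], coef: -1.665}
      - {features: [diabetes], coef: 0.661}
  black_female:
    baseline_survival: 0.9533
    mean_linear_predictor: 86.61
    terms:
      - {features: [ln_age], coef: 17.114}
      - {features: [ln_tc], coef: 0.940}
      - {features: [ln_hdl], coef: -18.920}
      - {features: [ln_age, ln_hdl], coef: 4.475}
      - {features: [ln_sbp_treated], coef: 29.291}
      - {features: [ln_age, ln_sbp_treated], coef: -6.432}
      - {features: [ln_sbp_untreated], coef: 27.820}
      - {features: [ln_age, ln_sbp_untreated], coef: -6.087}
      - {features: [smoker], coef: 0.691}
      - {features: [diabetes], coef: 0.874}
  white_male:
    baseline_survival: 0.9144
    mean_linear_predictor: 61.18
    terms:
      - {features: [ln_age], coef: 12.344}
      - {features: [ln_tc], coef: 11.853}
      - {features: [ln_age, ln_tc], coef: -2.664}
      - {features: [ln_hdl], coef: -7.990}
      - {features: [ln_age, ln_hdl], coef: 1.769}
      - {features: [ln_sbp_treated], coef: 1.797}
      - {features: [ln_sbp_untreated], coef: 1.764}
      - {features: [smoker], coef: 7.837}
      - {features: [ln_age, smoker], coef: -1.795}
      - {features: [diabetes], coef: 0.658}
  black_male:
    baseline_survival: 0.8954
    mean_linear_predictor: 19.54
    terms:
      - {features: [ln_age], coef: 2.469}
      - {features: [ln_tc], coef: 0.302}
      - {features: [ln_hdl], coef: -0.307}
      - {features: [ln_sbp_treated], coef: 1.916}
      - {features: [ln_sbp_untreated], coef: 1.809}
      - {features: [smoker], coef: 0.549}
      - {features: [diabetes], coef: 0.645}
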