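# Reynolds risk score: 10-year cardiovascular risk incorporating hsCRP and
# parental MI before age 60.  Women: Ridker et al., JAMA 2007 (clinical
# model B; HbA1c term applies to diabetic women).  Men: Ridker et al.,
# Circulation 2008.  Coefficients are transcriptions from the published
# reports; mean_linear_predictor is the published centering constant.
version: "reynolds/1.0"
age_window: [45, 80]
strata:
  female:
    baseline_survival: 0.98634
    mean_linear_predictor: 22.325
    terms:
      - {features: [age], coef: 0.0799}
      - {features: [ln_sbp_untreated], coef: 3.137}
      - {features: [ln_sbp_treated], coef: 3.137}
      - {features: [ln_crp], coef: 0.180}
      - {features: [ln_tc], coef: 1.382}
      - {features: [ln_hdl], coef: -1.172}
      - {features: [hba1c_if_diabetic], coef: 0.134}
      - {features: [smoker], coef: 0.818}
      - {features: [fam_mi60], coef: 0.438}
  male:
    baseline_survival: 0.8990
    mean_linear_predictor: 33.097
    terms:
      - {features: [ln_age], coef: 4.385}
      - {features: [ln_sbp_untreated], coef: 2.607}
      - {features: [ln_sbp_treated], coef: 2.607}
      - {features: [ln_tc], coef: 0.963}
      - {features: [ln_hdl], coef: -0.772}
      - {features: [ln_crp], coef: 0.102}
      - {features: [smoker], coef: 0.405}
      - {features: [fam_mi60], coef: 0.541}
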