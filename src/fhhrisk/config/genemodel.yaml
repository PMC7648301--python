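# Two-gene autosomal-dominant breast/ovarian cancer susceptibility model.
#
# Allele frequencies and carrier penetrance anchors are implementer-sourced
# from the published BRCA risk-model literature:
#   - general-population allele frequencies: Parmigiani, Berry & Aguilar,
#     Am J Hum Genet 1998 (0.0006 BRCA1, 0.00022 BRCA2; BRCA2 raised to
#     0.0007 per later model releases)
#   - Ashkenazi founder-mutation frequencies: Struewing et al., NEJM 1997
#   - carrier penetrance: meta-analytic cumulative risks, Antoniou et al.,
#     Am J Hum Genet 2003 / Chen & Parmigiani, JCO 2007
#   - noncarrier baseline: SEER cumulative incidence
# Cumulative risks are anchors; the engine interpolates them monotonically
# to an annual age grid (0-110).
version: "genemodel/1.0"
genes:
  - name: BRCA1
    allele_frequency:
      general: 0.0006
      ashkenazi: 0.0060
  - name: BRCA2
    allele_frequency:
      general: 0.0007
      ashkenazi: 0.0060
penetrance:
  - curve: BRCA1
    cancer: breast_cancer
    sex: female
    cumulative_risk: {20: 0.0, 30: 0.036, 40: 0.19, 50: 0.40, 60: 0.55, 70: 0.65, 80: 0.70, 110: 0.72}
  - curve: BRCA1
    cancer: breast_cancer
    sex: male
    cumulative_risk: {20: 0.0, 50: 0.003, 70: 0.012, 110: 0.015}
  - curve: BRCA1
    cancer: ovarian_cancer
    sex: female
    cumulative_risk: {20: 0.0, 30: 0.01, 40: 0.04, 50: 0.16, 60: 0.32, 70: 0.40, 80: 0.44, 110: 0.45}
  - curve: BRCA1
    cancer: ovarian_cancer
    sex: male
    cumulative_risk: {110: 0.0}
  - curve: BRCA2
    cancer: breast_cancer
    sex: female
    cumulative_risk: {20: 0.0, 30: 0.02, 40: 0.12, 50: 0.28, 60: 0.42, 70: 0.52, 80: 0.58, 110: 0.60}
  - curve: BRCA2
    cancer: breast_cancer
    sex: male
    cumulative_risk: {20: 0.0, 50: 0.014, 70: 0.055, 110: 0.07}
  - curve: BRCA2
    cancer: ovarian_cancer
    sex: female
    cumulative_risk: {20: 0.0, 40: 0.01, 50: 0.04, 60: 0.09, 70: 0.14, 80: 0.17, 110: 0.18}
  - curve: BRCA2
    cancer: ovarian_cancer
    sex: male
    cumulative_risk: {110: 0.0}
  - curve: noncarrier
    cancer: breast_cancer
    sex: female
    cumulative_risk: {20: 0.0, 30: 0.0005, 40: 0.005, 50: 0.02, 60: 0.045, 70: 0.075, 80: 0.10, 90: 0.12, 110: 0.125}
  - curve: noncarrier
    cancer: breast_cancer
    sex: male
    cumulative_risk: {20: 0.0, 60: 0.0003, 80: 0.001, 110: 0.0013}
  - curve: noncarrier
    cancer: ovarian_cancer
    sex: female
    cumulative_risk: {20: 0.0, 40: 0.001, 50: 0.004, 60: 0.008, 70: 0.012, 80: 0.015, 110: 0.017}
  - curve: noncarrier
    cancer: ovarian_cancer
    sex: male
    cumulative_risk: {110: 0.0}
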