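# Default three-tier risk-management rule catalog (19 rules: the four
# hereditary cancer syndrome referrals are separate rules).
#
# Only two numeric criteria are fixed by the deployment this catalog
# mirrors: breast MRI at lifetime breast-cancer risk > 20% (strict), and
# ASCVD-linked prevention at 10-year risk >= 7.5% (inclusive).  The other
# predicates encode the cited guideline families (NCCN-style hereditary
# cancer patterns, USPSTF-style screening criteria) as editable defaults:
# the engine, not this exact clinical content, is the contract.
version: "rules/1.0"

monogenic:
  - id: hereditary_cardiac
    recommendation: Genetic counseling referral for hereditary cardiac syndromes
    citation: HRS/EHRA expert consensus on cardiac genetic testing
    when:
      any:
        - {agg: {condition: cardiomyopathy, degrees: [SELF, FDR, SDR]}, op: ">=", value: 1}
        - {agg: {condition: sudden_cardiac_death, degrees: [FDR, SDR], max_onset: 50}, op: ">=", value: 1}
        - {agg: {condition: marfan_syndrome, degrees: [SELF, FDR, SDR]}, op: ">=", value: 1}
  - id: hboc
    recommendation: Genetic counseling referral for hereditary breast and ovarian cancer syndrome
    citation: NCCN genetic/familial high-risk assessment, breast and ovarian
    when:
      any:
        - {agg: {condition: ovarian_cancer, degrees: [SELF, FDR, SDR]}, op: ">=", value: 1}
        - {agg: {condition: breast_cancer, degrees: [SELF, FDR, SDR], max_onset: 45}, op: ">=", value: 1}
        - {agg: {condition: breast_cancer, sex: male}, op: ">=", value: 1}
        - {agg: {condition: breast_cancer}, op: ">=", value: 3}
  - id: lynch
    recommendation: Genetic counseling referral for Lynch syndrome
    citation: NCCN genetic/familial high-risk assessment, colorectal
    when:
      any:
        - {agg: {condition: colon_cancer, degrees: [SELF, FDR, SDR], max_onset: 50}, op: ">=", value: 1}
        - all:
            - {agg: {condition: colon_cancer}, op: ">=", value: 2}
            - {agg: {condition: endometrial_cancer}, op: ">=", value: 1}
        - {agg: {condition: colon_cancer}, op: ">=", value: 3}
  - id: fap
    recommendation: Genetic counseling referral for familial adenomatous polyposis
    citation: NCCN genetic/familial high-risk assessment, colorectal
    when:
      any:
        - {agg: {condition: colorectal_polyps, degrees: [SELF, FDR, SDR]}, op: ">=", value: 1}
  - id: pten
    recommendation: Genetic counseling referral for PTEN hamartoma tumor syndrome
    citation: NCCN genetic/familial high-risk assessment, breast and ovarian
    when:
      all:
        - {agg: {condition: breast_cancer, degrees: [SELF, FDR], max_onset: 40}, op: ">=", value: 1}
        - {agg: {condition: thyroid_cancer, degrees: [SELF, FDR]}, op: ">=", value: 1}
  - id: thrombophilia
    recommendation: Genetic counseling for hereditary thrombophilia
    citation: EGAPP recommendation on FVL/prothrombin testing
    when:
      any:
        - {agg: {condition: venous_thromboembolism, degrees: [SELF], max_onset: 50}, op: ">=", value: 1}
        - {agg: {condition: venous_thromboembolism, degrees: [FDR]}, op: ">=", value: 2}
        - {agg: {condition: venous_thromboembolism, degrees: [FDR], max_onset: 50}, op: ">=", value: 1}
  - id: familial_hypercholesterolemia
    recommendation: Familial hypercholesterolemia testing
    citation: NLA familial hypercholesterolemia screening guidance
    when:
      any:
        - {var: profile.total_cholesterol, op: ">=", value: 310}
        - {agg: {condition: familial_hypercholesterolemia, degrees: [FDR]}, op: ">=", value: 1}
        - all:
            - {agg: {condition: coronary_artery_disease, degrees: [FDR], max_onset: 50}, op: ">=", value: 1}
            - {var: profile.total_cholesterol, op: ">=", value: 250}
  - id: hemochromatosis
    recommendation: Hemochromatosis iron studies and genetic testing
    citation: AASLD hemochromatosis practice guidance
    when:
      any:
        - {agg: {condition: hemochromatosis, degrees: [SELF, FDR]}, op: ">=", value: 1}
  - id: wilsons
    recommendation: Wilson's disease genetic testing
    citation: AASLD Wilson disease practice guidance
    when:
      any:
        - {agg: {condition: wilsons_disease, degrees: [SELF, FDR, SDR]}, op: ">=", value: 1}
  - id: alpha1_antitrypsin
    recommendation: Alpha-1 antitrypsin deficiency genetic testing
    citation: ATS/ERS alpha-1 antitrypsin deficiency statement
    when:
      any:
        - {agg: {condition: alpha1_antitrypsin_deficiency, degrees: [SELF, FDR]}, op: ">=", value: 1}

familial:
  - id: ovarian_screening_discussion
    recommendation: Discussion of ovarian cancer screening options
    citation: SGO clinical practice statement on ovarian cancer risk
    when:
      any:
        - {agg: {condition: ovarian_cancer, degrees: [FDR]}, op: ">=", value: 1}
  - id: breast_mri
    recommendation: Adjunct breast MRI screening starting at age 30
    citation: ACS guidelines for breast MRI as an adjunct to mammography
    when:
      all:
        - {var: score.tyrer_cuzick, op: ">", value: 20}
  - id: breast_chemoprevention
    recommendation: Discussion of breast cancer chemoprevention
    citation: USPSTF medications to reduce breast cancer risk
    when:
      all:
        - {var: score.gail, op: ">=", value: 1.67}
  - id: early_colonoscopy
    recommendation: Colonoscopy starting before age 50 and/or more frequently
    citation: US Multi-Society Task Force colorectal screening for family history
    when:
      any:
        - {agg: {condition: colon_cancer, degrees: [FDR], max_onset: 60}, op: ">=", value: 1}
        - {agg: {condition: colon_cancer, degrees: [FDR]}, op: ">=", value: 2}

common:
  - id: aspirin_stroke_prevention
    recommendation: Aspirin for primary stroke prevention
    citation: USPSTF aspirin for primary prevention
    when:
      all:
        - {var: profile.sex, op: "==", value: female}
        - {var: profile.age, op: ">=", value: 55}
        - {var: profile.age, op: "<=", value: 79}
        - {var: score.pce, op: ">=", value: 10}
  - id: diabetes_screening
    recommendation: Screening for type 2 diabetes
    citation: USPSTF / ADA screening for abnormal blood glucose
    when:
      all:
        - {var: profile.diabetes, op: "==", value: false}
        - any:
            - all:
                - {var: profile.age, op: ">=", value: 40}
                - {var: profile.age, op: "<=", value: 70}
                - {var: profile.bmi, op: ">=", value: 25}
            - {agg: {condition: type_2_diabetes, degrees: [FDR]}, op: ">=", value: 1}
  - id: aaa_screening
    recommendation: One-time abdominal aortic aneurysm ultrasound screening
    citation: USPSTF abdominal aortic aneurysm screening
    when:
      any:
        - all:
            - {var: profile.sex, op: "==", value: male}
            - {var: profile.age, op: ">=", value: 65}
            - {var: profile.age, op: "<=", value: 75}
            - {var: profile.smoker, op: "==", value: true}
        - all:
            - {var: profile.age, op: ">=", value: 65}
            - {var: profile.age, op: "<=", value: 75}
            - {agg: {condition: abdominal_aortic_aneurysm, degrees: [FDR]}, op: ">=", value: 1}
  - id: calcium_scoring_ct
    recommendation: Calcium-scoring CT for further cardiovascular risk stratification
    citation: ACC/AHA cholesterol guideline (statin-linked 10-year risk threshold)
    when:
      all:
        - {var: score.pce, op: ">=", value: 7.5}
  - id: lung_cancer_screening
    recommendation: Annual low-dose CT lung cancer screening
    citation: USPSTF lung cancer screening
    when:
      all:
        - {var: profile.age, op: ">=", value: 50}
        - {var: profile.age, op: "<=", value: 80}
        - {var: profile.pack_years, op: ">=", value: 20}
        - any:
            - {var: profile.smoker, op: "==", value: true}
            - {var: profile.years_since_quit_smoking, op: "<=", value: 15}
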