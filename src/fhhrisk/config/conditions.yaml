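# Default 27-condition catalog for risk assessment.
# A configurable stand-in list: common chronic diseases plus hereditary
# syndromes referenced by the decision-support rule catalog and the
# familial-clustering statistics.
version: "conditions/1.0"
conditions:
  - {code: breast_cancer, label: Breast cancer, category: cancer}
  - {code: ovarian_cancer, label: Ovarian cancer, category: cancer}
  - {code: colon_cancer, label: Colorectal cancer, category: cancer}
  - {code: colorectal_polyps, label: Colorectal polyposis (>10 adenomas), category: cancer}
  - {code: endometrial_cancer, label: Endometrial (uterine) cancer, category: cancer}
  - {code: prostate_cancer, label: Prostate cancer, category: cancer}
  - {code: pancreatic_cancer, label: Pancreatic cancer, category: cancer}
  - {code: gastric_cancer, label: Gastric cancer, category: cancer}
  - {code: lung_cancer, label: Lung cancer, category: cancer}
  - {code: melanoma, label: Melanoma, category: cancer}
  - {code: thyroid_cancer, label: Thyroid cancer, category: cancer}
  - {code: coronary_artery_disease, label: Coronary artery disease / myocardial infarction, category: cardiovascular}
  - {code: stroke, label: Stroke or TIA, category: cardiovascular}
  - {code: abdominal_aortic_aneurysm, label: Abdominal aortic aneurysm, category: cardiovascular}
  - {code: cardiomyopathy, label: Cardiomyopathy (hypertrophic or dilated), category: cardiovascular}
  - {code: sudden_cardiac_death, label: Sudden cardiac death / arrhythmia syndrome, category: cardiovascular}
  - {code: familial_hypercholesterolemia, label: Severe hypercholesterolemia, category: cardiovascular}
  - {code: venous_thromboembolism, label: Venous thromboembolism (DVT/PE), category: cardiovascular}
  - {code: type_1_diabetes, label: Type 1 diabetes mellitus, category: metabolic}
  - {code: type_2_diabetes, label: Type 2 diabetes mellitus, category: metabolic}
  - {code: hemochromatosis, label: Hereditary hemochromatosis, category: hereditary}
  - {code: wilsons_disease, label: Wilson's disease, category: hereditary}
  - {code: alpha1_antitrypsin_deficiency, label: Alpha-1 antitrypsin deficiency, category: hereditary}
  - {code: marfan_syndrome, label: Marfan syndrome, category: hereditary}
  - {code: thalassemia, label: Thalassemia, category: hereditary}
  - {code: asthma, label: Asthma, category: respiratory}
  - {code: copd, label: Chronic obstructive pulmonary disease, category: respiratory}
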