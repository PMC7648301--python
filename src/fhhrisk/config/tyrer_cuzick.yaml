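# Tyrer-Cuzick-style model configuration (single-hypothetical-locus form,
# after Tyrer, Duffy & Cuzick, Stat Med 2004).  The hypothetical dominant
# low-penetrance locus stands in for residual polygenic familial risk; its
# frequency follows the published model and its penetrance anchors give a
# moderate (~24% by age 80) carrier risk.  Hormonal relative risks are
# category summaries consistent with the published model's risk factors.
version: "tyrer_cuzick/1.0"
hypothetical_locus:
  name: LOWPEN
  allele_frequency: 0.113
  breast_cumulative_risk: {20: 0.0, 40: 0.03, 50: 0.08, 60: 0.14, 70: 0.20, 80: 0.24, 110: 0.26}
hormonal_rr:
  menarche: {lt12: 1.14, "12_13": 1.07, ge14: 1.00}
  first_birth: {lt20: 1.00, "20_24": 1.05, "25_29": 1.12, ge30: 1.25, nulliparous: 1.25}
  hrt: {never: 1.00, current: 1.40}
  bmi: {lt25: 1.00, "25_30": 1.10, ge30: 1.20}
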