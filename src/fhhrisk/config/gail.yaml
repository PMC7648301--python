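# Gail model coefficients and baseline hazards.
#
# Category relative risks: Gail et al., JNCI 1989 (as used by the NCI
# BCRAT).  Baseline breast-cancer incidence: SEER white 1983-87 composite
# rates and SEER black rates as adopted by BCRAT (annual hazards).
# Competing mortality: US non-breast-cancer death rates, same vintage.
# Attributable-risk adjustment (1 - AR): BCRAT white value 0.5788.
# Rates are approximate transcriptions for a deployable default; deployers
# may substitute refreshed tables without code changes.
version: "gail/1.0"
default_race: white
menarche_rr: {ge14: 1.000, "12_13": 1.099, lt12: 1.207}
biopsy_rr:
  under50: {"0": 1.000, "1": 1.698, "2plus": 2.882}
  over50: {"0": 1.000, "1": 1.273, "2plus": 1.620}
atypical_rr: {"yes": 1.82, "no": 0.93}
afb_fdr_rr:
  lt20: {"0": 1.000, "1": 2.607, "2plus": 6.798}
  "20_24": {"0": 1.244, "1": 2.681, "2plus": 5.775}
  25_29_or_nulliparous: {"0": 1.548, "1": 2.756, "2plus": 4.907}
  ge30: {"0": 1.927, "1": 2.834, "2plus": 4.169}
one_minus_ar:
  white: {under50: 0.5788, over50: 0.5788}
  black: {under50: 0.7294, over50: 0.7464}
# annual baseline breast-cancer hazard by 5-year age-band start (per woman-year)
incidence:
  white:
    20: 0.0000122
    25: 0.0000742
    30: 0.0002297
    35: 0.0005649
    40: 0.0011645
    45: 0.0019525
    50: 0.0026154
    55: 0.0030279
    60: 0.0036757
    65: 0.0042029
    70: 0.0043479
    75: 0.0043191
    80: 0.0041392
    85: 0.0038561
  black:
    20: 0.0000243
    25: 0.0001320
    30: 0.0002870
    35: 0.0006427
    40: 0.0012753
    45: 0.0018014
    50: 0.0021449
    55: 0.0025343
    60: 0.0028812
    65: 0.0031470
    70: 0.0033603
    75: 0.0033206
    80: 0.0031289
    85: 0.0028026
# annual competing (non-breast-cancer) mortality hazard
mortality:
  white:
    20: 0.0004412
    25: 0.0005254
    30: 0.0006746
    35: 0.0009092
    40: 0.0012534
    45: 0.0019570
    50: 0.0032984
    55: 0.0054622
    60: 0.0091035
    65: 0.0141854
    70: 0.0225935
    75: 0.0361146
    80: 0.0613626
    85: 0.1420663
  black:
    20: 0.0007425
    25: 0.0010692
    30: 0.0014835
    35: 0.0020536
    40: 0.0028357
    45: 0.0038968
    50: 0.0054080
    55: 0.0081124
    60: 0.0119765
    65: 0.0168014
    70: 0.0243667
    75: 0.0357674
    80: 0.0543363
    85: 0.1105420
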