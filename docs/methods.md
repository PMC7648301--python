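# Methods

This note documents the models, the parameters that matter, the design
choices that were genuinely open, and what the synthetic-data tests do and
do not demonstrate.

## Pedigree capture and expansion

Family histories arrive as relationship-coded records relative to one
proband. The vocabulary is a closed list (25 codes); each code fixes the
degree of relationship (first/second/third), the side of the family, and
in most cases the sex, so no inference is needed downstream. Validation
requires the six always-collected relatives (both parents, all four
grandparents), and the quality scorer evaluates the five elements of a
high-quality family history independently: relationship + sex, side of
family, vital status with the matching age (and cause of death), all
conditions carrying onset ages, and at least three generations
(generation indices are derived from the codes: proband 1, parents 2,
grandparents 3, children 0, grandchildren −1; the element counts distinct
indices).

Expansion to an explicit parent-linked graph inserts *placeholder
founders* wherever a relationship implies an unentered connector: an aunt
implies the grandparent couple (shared with the — possibly placeholder —
parent), a niece implies a sibling and partner, a cousin an aunt/uncle and
partner, a grandchild a child and partner. Because the interchange format
does not record *which* sibling a niece descends through, every such
relative gets its own connector couple; this is deliberate — guessing an
attachment would silently fabricate genetic relationships. Placeholders
carry `history_known = false` and therefore only contribute transmission
structure to the likelihood. Every individual ends up with either both
parents or neither (a lone entered parent is completed with a placeholder
partner). Half-siblings share exactly one parent with the proband.
Consanguinity is stored and reported but not modelled: the likelihood
engine refuses pedigrees whose marriage graph is not a tree.

## Mendelian carrier model

The gene model (YAML config) lists autosomal-dominant susceptibility
genes — by default BRCA1 and BRCA2 — each with an allele frequency per
ancestry stratum (general population ~6–7 × 10⁻⁴; Ashkenazi 6 × 10⁻³,
reflecting the founder mutations) and cumulative penetrance anchors for
breast and ovarian cancer by sex, interpolated monotonically (PCHIP) to an
annual grid from 0 to 110. Carrier anchors follow the meta-analytic
BRCA literature (e.g. BRCA1 female breast ~65% by 70); the noncarrier
baseline follows registry cumulative incidence. Male breast cancer uses
sex-specific curves (BRCA2 ≫ BRCA1 > baseline); ovarian penetrance is
zero for males.

Inference treats carriers as heterozygous when transmitting (the standard
rare-allele simplification: a carrier parent transmits with probability ½,
a noncarrier never), genes segregate independently, and the penetrance of
a multi-gene carrier class is the elementwise maximum of the single-gene
curves (the class has prior mass ~10⁻⁶; any reasonable combination rule
is inconsequential). Phenotype terms: annual penetrance increment at the
onset age for affected individuals, `F_G(censoring age)` when affected
with unknown onset, survival to the censoring age when unaffected,
and 1 for history-unknown individuals — keeping them in the graph
preserves transmission paths that dropping them would sever.

The posterior is computed by Elston–Stewart peeling implemented as
sum-product message passing over nuclear families, summing each child out
independently given the parents, so cost is linear in pedigree size and
polynomial in the genotype-class count (4 classes for two genes, 8 when
the Tyrer–Cuzick hypothetical locus is added). Individuals disconnected
from the counselee (a married-in relative with no children entered)
contribute their component's total probability as a scalar factor.
Degenerate input: if a phenotype is impossible under *every* genotype
class (an onset before the earliest penetrance anchor), that individual is
treated as uninformative rather than declaring the whole pedigree
impossible. The reported "pedigree likelihood" is
`P(phenotypes | counselee genotype)`, obtained by dividing the joint by
the counselee's structural (phenotype-free) genotype marginal; note that
under the heterozygote transmission simplification the structural marginal
of a deep descendant differs from the Hardy–Weinberg prior by O(p²) per
generation, which only matters for artificially common test alleles.

An independent exhaustive-enumeration oracle (summing the full joint over
all genotype assignments, with its own transmission arithmetic) verifies
the peeler to 10⁻⁹ on hundreds of seeded random pedigrees — 2-class
enumeration up to 12 members, 4-class up to 8.

Residual absolute risk over a horizon is the posterior mixture of
genotype-conditional risks `(F_G(a+h) − F_G(a)) / (1 − F_G(a))`; lifetime
horizons run to age 85 (configurable).

## The six calculators

All coefficient sets live in versioned YAML configs with source notes;
the code owns the functional forms, eligibility windows and the
missing-data contract. Scores are percentages rounded to two decimals.

- **Gail** (5-year breast cancer; women 35–85 without prior breast
  cancer). Category relative risks for menarche age, biopsies (age-band
  specific, with the atypical-hyperplasia multiplier applied only when
  biopsies exist) and the age-at-first-birth × affected-FDR interaction,
  from the published model; the affected-FDR count is computed from the
  pedigree by degree classification. Absolute risk composes the RR with
  race-stratified attributable-risk-adjusted incidence and competing
  mortality by closed-form integration over annual piecewise-constant
  hazards; a fine-grid trapezoidal oracle checks it in the tests. Unknown
  atypical-hyperplasia status multiplies by 1 (it is not a required
  input); parity must be resolvable (nulliparous flag or age at first
  birth).
- **Tyrer–Cuzick-style lifetime breast cancer** (women 20–85). The
  published model's single-hypothetical-locus form: the two-gene model is
  extended with one common (allele frequency 0.113), moderately penetrant
  (~24% by 80) dominant locus standing in for residual polygenic familial
  risk; the 8-class posterior comes from the same peeling engine.
  Hormonal/benign-disease relative risks (menarche, parity/age at first
  birth, HRT, BMI) apply to the non-genetic component as a power on the
  noncarrier survival. This is an explicit approximation of the commercial
  IBIS program (no full polygenotype, no competing mortality).
- **BRCA-model lifetime breast cancer**: the carrier posterior mixed into
  residual risk to 85, directly from the Mendelian module.
- **Framingham 2008 general CVD**, **Reynolds**, **pooled cohort
  equations**: the shared survival form `1 − S0^exp(L − L̄)` with
  sex-stratified (and, for the pooled cohort equations, race-stratified
  with interaction terms) coefficients. Configs express terms as products
  of named features (`ln_age`, `ln_tc`, `ln_sbp_treated/untreated`, …), so
  powers and interactions need no code. Reynolds requires hsCRP (and
  HbA1c for diabetic women) and uses parental myocardial infarction before
  60, derived from the pedigree when the profile does not state it —
  parents with known histories and no early coronary disease count as a
  negative; otherwise the input is missing and the score is
  `not_calculated`. Unlisted race strata map to the white/other stratum.
  Age windows: Framingham 30–74, Reynolds 45–80 (men from 50), PCE 40–79.
  The identity `risk = 1 − S0` at the stratum mean linear predictor is
  asserted exactly in the tests. Which Framingham variant the deployed
  platform used is not documented; the 2008 general-CVD form is the
  configured default and an explicit assumption.

Missing-data contract: each calculator declares its required inputs;
deleting any one flips that calculator (and only the dependent ones) to
`not_calculated` with the input named. Nothing is imputed.

## Rule engine

The catalog ships 19 rules in three tiers: ten monogenic referral rules
(hereditary cardiac syndromes; the four hereditary-cancer referrals —
HBOC, Lynch, FAP, PTEN — kept separate because they are reported
separately; thrombophilia; familial hypercholesterolemia; hemochromatosis;
Wilson's; alpha-1 antitrypsin), four familial rules (ovarian screening
discussion, breast MRI, breast chemoprevention, early/frequent
colonoscopy) and five common-tier rules (aspirin for stroke prevention,
diabetes screening, AAA screening, calcium-scoring CT, lung cancer
screening). Only two numeric criteria are fixed by the deployment this
mirrors — breast MRI at lifetime risk **> 20%** (strict) and ASCVD-linked
prevention at 10-year risk **≥ 7.5%** (inclusive); the remaining
predicates encode the cited guideline families as editable defaults. The
count of distinct "strategies" is ambiguous in the source material
(somewhere between 16 and 19 depending on how referrals are split); this
catalog documents its own count rather than resolving that.

The condition language allows only conjunction/disjunction/negation over
leaf comparisons of declared variables (`profile.*`, `score.*` in percent)
and one pedigree aggregate (`count_affected` with condition, degree, side,
sex and onset-bound filters) — no scripting, so a catalog is auditable and
unknown variables fail at load time, not evaluation time. Evaluation is
three-valued: missing inputs make a rule *not evaluable*, reported
distinctly from *not met*. Onset-unknown condition entries are excluded
from onset-bounded counts (they cannot certify "before age X"). Fired
rules carry evidence tuples whose replay re-satisfies the predicate;
boundary semantics are pinned per rule and tested at cutoff ± 0.01 (the
resolution of the two-decimal percent scores).

## Cohort statistics

Two clustering summaries per condition: *affected families* (share of
pedigrees with ≥ 1 affected member, proband included) and *within
family* (mean ± SD of the family-wise affected fraction across affected
families only; an empty denominator raises an explicit undefined-result
signal rather than returning a number). Family size includes the proband —
the source material does not state the denominator, so it is a documented,
configurable choice. Conditions count once per individual. PAM raw scores
(0–100) map to four activation levels at the published PAM-13 cut-points
(≤ 47.0 / ≤ 55.1 / ≤ 67.0 / above), inclusive on the lower level; the
alternative five-level scheme mentioned in some instruments is not
implemented because all quantities of interest use the four-level scale.

## Synthetic cohorts

The generator emulates a patient-entered primary-care FHH cohort. Family
structure: the seven always-present members plus extras (siblings,
children, aunts/uncles, nieces/nephews, cousins, grandchildren) sampled to
a target size drawn from a shifted gamma (mean 13.7, SD 7.9, clamped to
7–74); proband ages follow the study-population age mix; generational age
gaps are ≥ 15 years with a mean near 27; death is applied via a sampled
lifespan. Disease: per condition, a sporadic cumulative-incidence curve by
sex; optionally a dominant locus gene-dropped through the expanded graph
(founders from Hardy–Weinberg, transmission ½); and a family-level
log-normal frailty Z acting as `S(a|Z) = S(a)^Z` (default σ = 0.4) — the
simplest mechanism that reproduces the observed contrast between
affected-families and within-family proportions. Observation: histories
are unknown for distant relatives (known with probability 0.95 / 0.70 /
0.54 by degree), onsets recorded with probability 0.895, and labs masked
(lipids 65%, blood pressure 90%, hsCRP 4% — hsCRP rarity is what makes
the Reynolds score almost never calculable, as in practice). PAM scores
are normal (mean 70.8, SD 13.9) truncated to [0, 100]. Everything is
reproducible from one master seed via independent per-family child
streams, so family *i* is invariant to cohort size and generation order.
Truth tables (carrier labels, frailties) are emitted for recovery tests
and never read by the assessment pipeline.

What passing tests show — and do not. The generator shares its survival
machinery's *form* with the inference model but draws onsets by direct
inversion, independent of the peeling code; carrier-recovery tests
therefore check the estimator, not a tautology. They do not establish
calibration on real populations: real FHH data have reporting error,
correlated missingness, non-random family sizes and ascertainment effects
the generator does not model.

## Problem sizes and numerics

The default test and reproduction runs use cohorts of 40–500 families and
enumeration oracles up to 12 members (2 genotype classes) or 8 members
(4 classes) — sizes at which exhaustive enumeration is a trustworthy
independent check while the full suite stays fast. Tolerances: peeling vs
enumeration 10⁻⁹ absolute; posterior normalisation 10⁻⁹; reference
identities exact at double precision; stochastic checks use seeded draws
with binomial 99–99.9% intervals or pre-registered margins (carrier vs
noncarrier mean posterior separation 0.05). Ages are rounded to integer
grid years; risks are clamped to [0, 1] before percent rounding.

## Known limitations

- Inbreeding loops, identical-twin genotype collapsing and X-linked or
  recessive inheritance are unsupported (loops are detected and refused).
- The Tyrer–Cuzick implementation is the published simplification, not the
  commercial program; scores should not be compared to IBIS output at the
  individual level.
- Coefficient tables are transcriptions for a deployable default and may
  lag current registry rates; they are data, not code, and carry source
  notes in each YAML.
- The rule catalog encodes guideline families as defaults; deployments are
  expected to review and edit the clinical content. The engine — loading,
  validation, three-valued evaluation, evidence replay — is the tested
  contract.
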