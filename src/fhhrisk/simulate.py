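"""Seeded generator of realistic family-health-history cohorts.

Every family always contains the proband, both parents and all four
grandparents (the required relatives); additional siblings, children,
aunts/uncles, nieces/nephews, cousins and grandchildren are sampled to
reach a target family size drawn from a long-tailed distribution (mean
about 14, support 7-74).  Ages are generated with coherent generational
gaps (a parent is at least 15 years older than any child).

Disease is generated from a survival model per condition:

- a *sporadic* cumulative incidence curve by age and sex;
- optionally an autosomal-dominant susceptibility locus (allele frequency
  plus a carrier penetrance curve) gene-dropped through the expanded
  pedigree graph, producing high-risk subfamilies;
- a family-level shared-environment frailty: a log-normal multiplier Z on
  the cumulative hazard, S(a | Z) = S(a)^Z, inducing familial clustering
  beyond the locus.

Observed data are then masked the way self-reported histories are: distant
relatives' histories are unknown with increasing probability by degree,
ages of onset are dropped at random, and labs (especially hsCRP) are
frequently unavailable in the proband's risk-factor profile.

Everything is reproducible from the master seed; each family uses an
independent child stream of the seed sequence, so families are identical
regardless of generation order or cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import yaml

from .genemodel import AGES, _interp_cdf
from .graph import PedigreeGraph, entered_ids, expand_to_graph
from .pedigree import (
    ConditionEntry,
    Degree,
    Pedigree,
    ProbandRecord,
    RelativeRecord,
    Sex,
    classify_degree,
)
from .profiles import RiskFactorProfile


@dataclass
class DominantLocus:
    allele_frequency: float
    carrier_cumulative_incidence: dict[float, float]

    def carrier_prob(self) -> float:
        f = self.allele_frequency
        return 2 * f * (1 - f) + f * f


@dataclass
class SimCondition:
    """Sporadic incidence (by sex) and optional dominant locus for one condition."""

    sporadic: dict[str, dict[float, float]]  # sex -> age -> cumulative incidence
    locus: Optional[DominantLocus] = None


def _default_conditions() -> dict[str, SimCondition]:
    return {
        "breast_cancer": SimCondition(
            sporadic={
                "female": {30: 0.0005, 40: 0.005, 50: 0.02, 60: 0.045, 70: 0.075, 80: 0.10, 110: 0.125},
                "male": {60: 0.0003, 80: 0.001, 110: 0.0013},
            },
            # allele frequency enriched over the population value so carrier
            # subfamilies appear at cohort sizes of a few hundred
            locus=DominantLocus(
                allele_frequency=0.006,
                carrier_cumulative_incidence={30: 0.036, 40: 0.19, 50: 0.40, 60: 0.55, 70: 0.65, 80: 0.70, 110: 0.72},
            ),
        ),
        "ovarian_cancer": SimCondition(
            sporadic={"female": {50: 0.004, 70: 0.012, 110: 0.017}, "male": {110: 0.0}},
        ),
        "colon_cancer": SimCondition(
            sporadic={"female": {50: 0.004, 70: 0.025, 110: 0.05}, "male": {50: 0.005, 70: 0.03, 110: 0.06}},
        ),
        "coronary_artery_disease": SimCondition(
            sporadic={"female": {50: 0.02, 70: 0.12, 110: 0.25}, "male": {50: 0.05, 70: 0.20, 110: 0.35}},
        ),
        "type_2_diabetes": SimCondition(
            sporadic={"female": {40: 0.04, 60: 0.13, 110: 0.25}, "male": {40: 0.05, 60: 0.15, 110: 0.28}},
        ),
        "asthma": SimCondition(
            sporadic={"female": {10: 0.06, 20: 0.08, 110: 0.10}, "male": {10: 0.07, 20: 0.09, 110: 0.11}},
        ),
        "marfan_syndrome": SimCondition(
            # very rare sporadically; nearly fully penetrant dominant locus ->
            # strong within-family clustering with few affected families
            sporadic={"female": {110: 0.0002}, "male": {110: 0.0002}},
            locus=DominantLocus(
                allele_frequency=0.001,
                carrier_cumulative_incidence={10: 0.40, 20: 0.70, 40: 0.90, 110: 0.95},
            ),
        ),
    }


@dataclass
class SimulationParams:
    """Study-like cohort generation settings (defaults emulate a
    primary-care FHH cohort: family sizes with mean ~13.7 and range 7-74,
    history known for ~95% of FDRs / 70% of SDRs / 54% of TDRs, onset
    recorded for ~89.5% of condition entries, hsCRP rarely available)."""

    n_families: int = 100
    family_size_mean: float = 13.7
    family_size_sd: float = 7.9
    family_size_min: int = 7
    family_size_max: int = 74
    conditions: dict[str, SimCondition] = dc_field(default_factory=_default_conditions)
    shared_env_sd: float = 0.4
    history_known_prob: dict[str, float] = dc_field(
        default_factory=lambda: {"FDR": 0.95, "SDR": 0.70, "TDR": 0.54}
    )
    onset_recorded_prob: float = 0.895
    lab_availability: dict[str, float] = dc_field(
        default_factory=lambda: {"lipids": 0.65, "bp": 0.90, "hscrp": 0.04}
    )
    pam_mean: float = 70.8
    pam_sd: float = 13.9

    def validate(self) -> None:
        for name, p in [("onset_recorded_prob", self.onset_recorded_prob)] + [
            (f"history_known[{k}]", v) for k, v in self.history_known_prob.items()
        ] + [(f"lab_availability[{k}]", v) for k, v in self.lab_availability.items()]:
            if not (0 <= p <= 1):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.shared_env_sd < 0:
            raise ValueError("shared_env_sd must be nonnegative")
        if not (1 <= self.family_size_min <= self.family_size_max):
            raise ValueError("invalid family size bounds")

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        conds = d.pop("conditions", None)
        params = cls(**d)
        if conds is not None:
            params.conditions = {}
            for name, spec in conds.items():
                locus = spec.get("locus")
                params.conditions[name] = SimCondition(
                    sporadic={
                        s: {float(a): float(v) for a, v in t.items()}
                        for s, t in spec["sporadic"].items()
                    },
                    locus=DominantLocus(
                        allele_frequency=float(locus["allele_frequency"]),
                        carrier_cumulative_incidence={
                            float(a): float(v)
                            for a, v in locus["carrier_cumulative_incidence"].items()
                        },
                    )
                    if locus
                    else None,
                )
        params.validate()
        return params


# --------------------------------------------------------------------------
# family structure

_EXTRA_CODES = [
    ("sister", 0.14), ("brother", 0.14),
    ("daughter", 0.11), ("son", 0.11),
    ("maternal aunt", 0.07), ("maternal uncle", 0.07),
    ("paternal aunt", 0.07), ("paternal uncle", 0.07),
    ("niece", 0.05), ("nephew", 0.05),
    ("maternal cousin", 0.03), ("paternal cousin", 0.03),
    ("granddaughter", 0.03), ("grandson", 0.03),
]


def _sample_family_size(params: SimulationParams, rng: np.random.Generator) -> int:
    # shifted gamma reproduces the long right tail above the minimum of 7
    excess_mean = params.family_size_mean - params.family_size_min
    if excess_mean <= 0 or params.family_size_sd <= 0:
        return params.family_size_min
    shape = (excess_mean / params.family_size_sd) ** 2
    scale = params.family_size_sd**2 / excess_mean
    size = params.family_size_min + rng.gamma(shape, scale)
    return int(np.clip(round(size), params.family_size_min, params.family_size_max))


def _vital(age_raw: float, rng: np.random.Generator) -> dict:
    lifespan = float(np.clip(rng.normal(80, 10), 40, 110))
    if age_raw >= lifespan:
        return {"alive": False, "age_at_death": round(lifespan, 1), "cause_of_death": "natural causes"}
    return {"alive": True, "current_age": round(max(age_raw, 0.0), 1)}


def sample_family_structure(
    params: SimulationParams, rng: np.random.Generator
) -> Pedigree:
    """Pedigree skeleton: required relatives plus sampled extras, coherent ages."""
    proband_age = float(rng.choice([rng.uniform(25, 50), rng.uniform(50, 60), rng.uniform(60, 66), rng.uniform(66, 88)], p=[0.28, 0.24, 0.16, 0.32]))
    proband_sex = Sex.FEMALE if rng.random() < 0.69 else Sex.MALE
    gap = lambda: 15 + rng.gamma(6, 2)  # parent-child age gap, mean ~27
    mother_age = proband_age + gap()
    father_age = proband_age + gap()
    records: list[RelativeRecord] = []

    def add(code: str, age_raw: float, sex: Sex | None = None) -> None:
        kwargs = dict(relation_code=code, **_vital(age_raw, rng))
        if sex is not None:
            kwargs["sex"] = sex
        records.append(RelativeRecord(**kwargs))

    mgm_age, mgf_age = mother_age + gap(), mother_age + gap()
    pgm_age, pgf_age = father_age + gap(), father_age + gap()
    add("mother", mother_age)
    add("father", father_age)
    add("maternal grandmother", mgm_age)
    add("maternal grandfather", mgf_age)
    add("paternal grandmother", pgm_age)
    add("paternal grandfather", pgf_age)

    target = _sample_family_size(params, rng)
    codes = [c for c, _ in _EXTRA_CODES]
    weights = np.array([w for _, w in _EXTRA_CODES])
    weights /= weights.sum()
    while len(records) + 1 < target:
        code = str(rng.choice(codes, p=weights))
        if code in ("sister", "brother"):
            # keep at least the 15-year generational gap below both parents
            age = min(proband_age + rng.uniform(-12, 12), mother_age - 16, father_age - 16)
        elif code in ("daughter", "son"):
            if proband_age < 35:
                continue
            age = proband_age - gap()
        elif code in ("granddaughter", "grandson"):
            if proband_age < 55:
                continue
            age = proband_age - gap() - gap()
        elif code in ("niece", "nephew"):
            age = proband_age - gap() + rng.uniform(-5, 5)
        elif "cousin" in code:
            age = proband_age + rng.uniform(-15, 15)
            sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
            if age < 0:
                continue
            records.append(
                RelativeRecord(relation_code=code, sex=sex, **_vital(age, rng))
            )
            continue
        else:  # aunt/uncle: sibling of a parent, below that side's grandparents
            if "maternal" in code:
                cap = min(mgm_age, mgf_age) - 16
                age = min(mother_age + rng.uniform(-10, 10), cap)
            else:
                cap = min(pgm_age, pgf_age) - 16
                age = min(father_age + rng.uniform(-10, 10), cap)
        if age < 0:
            continue
        add(code, age)

    proband = ProbandRecord(
        relation_code="self",
        sex=proband_sex,
        alive=True,
        current_age=round(proband_age, 1),
        ashkenazi=bool(rng.random() < 0.04),
    )
    return Pedigree(proband=proband, relatives=records)


# --------------------------------------------------------------------------
# gene dropping and phenotypes

def drop_genotypes(
    graph: PedigreeGraph, locus: DominantLocus, rng: np.random.Generator
) -> dict[str, bool]:
    """Founder carriers from Hardy-Weinberg, non-founders by transmission."""
    import networkx as nx

    carrier: dict[str, bool] = {}
    order = list(nx.topological_sort(graph.digraph()))
    p_carrier = locus.carrier_prob()
    for iid in order:
        ind = graph.individuals[iid]
        if ind.is_founder:
            carrier[iid] = bool(rng.random() < p_carrier)
        else:
            p_not = 1.0
            for pid in (ind.mother, ind.father):
                if carrier[pid]:
                    p_not *= 0.5
            carrier[iid] = bool(rng.random() < 1.0 - p_not)
    return carrier


def _sample_onset(
    F: np.ndarray, frailty: float, rng: np.random.Generator
) -> Optional[float]:
    """Onset age under S(a|Z) = S(a)^Z, or None if never affected."""
    Fz = 1.0 - np.power(1.0 - F, frailty)
    u = rng.random()
    if u >= Fz[-1]:
        return None
    return float(np.searchsorted(Fz, u, side="right"))


@dataclass
class FamilyTruth:
    family_index: int
    frailty: dict[str, float]
    carriers: dict[str, dict[str, bool]]  # condition -> individual id -> carrier


def assign_phenotypes(
    pedigree: Pedigree,
    graph: PedigreeGraph,
    params: SimulationParams,
    rng: np.random.Generator,
    family_index: int = 0,
) -> FamilyTruth:
    """Sample condition onsets into the pedigree records (in place) and
    return the latent truth (carrier labels, frailties)."""
    ids = entered_ids(pedigree)
    truth = FamilyTruth(family_index=family_index, frailty={}, carriers={})
    for cond, spec in params.conditions.items():
        frailty = float(np.exp(rng.normal(0.0, params.shared_env_sd)))
        truth.frailty[cond] = frailty
        carriers: dict[str, bool] = {}
        if spec.locus is not None:
            carriers = drop_genotypes(graph, spec.locus, rng)
            carrier_F = _interp_cdf(spec.locus.carrier_cumulative_incidence)
        truth.carriers[cond] = {
            iid: carriers.get(iid, False) for iid, _ in ids
        }
        sporadic_F = {
            sex: _interp_cdf(anchors) for sex, anchors in spec.sporadic.items()
        }
        for iid, rec in ids:
            if rec.sex == Sex.UNKNOWN or rec.sex.value not in sporadic_F:
                continue
            cens = rec.censoring_age
            if cens is None:
                continue
            F = carrier_F if carriers.get(iid, False) else sporadic_F[rec.sex.value]
            onset = _sample_onset(F, frailty, rng)
            if onset is not None and onset <= cens:
                rec.conditions.append(
                    ConditionEntry(condition_code=cond, age_of_onset=onset)
                )
    return truth


def apply_missingness(
    pedigree: Pedigree, params: SimulationParams, rng: np.random.Generator
) -> None:
    """History-known masks by degree and onset-recorded masks, in place."""
    for rec in pedigree.relatives:
        deg = classify_degree(rec.relation_code)
        if deg == Degree.SELF:
            continue
        p_known = params.history_known_prob.get(deg.value, 1.0)
        if rng.random() >= p_known:
            rec.history_known = False
            rec.conditions = []
            continue
        for cond in rec.conditions:
            if rng.random() >= params.onset_recorded_prob:
                cond.age_of_onset = None
    for cond in pedigree.proband.conditions:
        if rng.random() >= params.onset_recorded_prob:
            cond.age_of_onset = None


def sample_profile(
    pedigree: Pedigree, params: SimulationParams, rng: np.random.Generator
) -> RiskFactorProfile:
    """Personal risk factors for the proband, with lab-availability masks."""
    pr = pedigree.proband
    labs = params.lab_availability
    have_lipids = rng.random() < labs.get("lipids", 1.0)
    have_bp = rng.random() < labs.get("bp", 1.0)
    have_crp = rng.random() < labs.get("hscrp", 1.0)
    smoker = bool(rng.random() < 0.15)
    diabetic = bool(rng.random() < 0.10)
    nullip = bool(rng.random() < 0.15)
    return RiskFactorProfile(
        age=float(np.clip(pr.current_age or 50, 18, 120)),
        sex=pr.sex,
        race_ethnicity=str(rng.choice(["white", "black", "other"], p=[0.85, 0.08, 0.07])),
        menarche_age=float(np.clip(round(rng.normal(12.8, 1.5)), 9, 17)) if pr.sex == Sex.FEMALE else None,
        nulliparous=nullip if pr.sex == Sex.FEMALE else None,
        age_first_live_birth=None if nullip or pr.sex != Sex.FEMALE else float(np.clip(round(rng.normal(26, 5)), 15, min(45, (pr.current_age or 50)))),
        breast_biopsy_count=int(rng.choice([0, 1, 2], p=[0.82, 0.13, 0.05])) if pr.sex == Sex.FEMALE else None,
        atypical_hyperplasia=bool(rng.random() < 0.1) if pr.sex == Sex.FEMALE else None,
        hrt_use=bool(rng.random() < 0.1) if pr.sex == Sex.FEMALE else None,
        height_cm=float(np.clip(rng.normal(163 if pr.sex == Sex.FEMALE else 177, 7), 140, 210)),
        weight_kg=float(np.clip(rng.normal(75, 16), 40, 180)),
        systolic_bp=float(np.clip(rng.normal(126, 16), 90, 220)) if have_bp else None,
        treated_hypertension=bool(rng.random() < 0.25) if have_bp else None,
        total_cholesterol=float(np.clip(rng.normal(200, 35), 100, 400)) if have_lipids else None,
        hdl=float(np.clip(rng.normal(55, 14), 20, 120)) if have_lipids else None,
        smoker=smoker,
        pack_years=float(np.clip(rng.gamma(2, 10), 0, 120)) if smoker else 0.0,
        years_since_quit_smoking=None,
        diabetes=diabetic,
        hba1c=float(np.clip(rng.normal(7.2, 1.0), 5.5, 13)) if diabetic else None,
        hscrp=float(np.clip(rng.lognormal(0.5, 0.8), 0.1, 20)) if have_crp else None,
    )


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    profile: RiskFactorProfile
    pam_score: float
    truth: FamilyTruth


def simulate_cohort(params: SimulationParams, seed: int) -> list[SimulatedFamily]:
    """Generate a full cohort; family *i* is a deterministic function of
    (seed, i) via independent seed-sequence child streams."""
    params.validate()
    streams = np.random.SeedSequence(seed).spawn(params.n_families)
    out: list[SimulatedFamily] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        ped = sample_family_structure(params, rng)
        graph = expand_to_graph(ped)
        truth = assign_phenotypes(ped, graph, params, rng, family_index=i)
        apply_missingness(ped, params, rng)
        profile = sample_profile(ped, params, rng)
        pam = float(np.clip(rng.normal(params.pam_mean, params.pam_sd), 0, 100))
        # revalidate after in-place edits
        ped = Pedigree.model_validate(ped.model_dump())
        out.append(SimulatedFamily(pedigree=ped, profile=profile, pam_score=pam, truth=truth))
    return out


def truth_table(cohort: list[SimulatedFamily]):
    """Tidy truth table (one row per individual x locus condition)."""
    import pandas as pd

    rows = []
    for fam in cohort:
        for cond, carr in fam.truth.carriers.items():
            for iid, is_carrier in carr.items():
                rows.append(
                    {
                        "family_index": fam.truth.family_index,
                        "individual_id": iid,
                        "condition": cond,
                        "carrier": is_carrier,
                        "frailty": fam.truth.frailty[cond],
                    }
                )
    return pd.DataFrame(rows)
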