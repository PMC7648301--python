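"""Shared fixtures: toy gene models, pedigree builders, random pedigree graphs."""

from __future__ import annotations

import json

import numpy as np
import pytest

from fhhrisk.genemodel import GeneModel, _interp_cdf
from fhhrisk.graph import Individual, PedigreeGraph
from fhhrisk.pedigree import Pedigree, Sex, parse_pedigree
from fhhrisk.profiles import RiskFactorProfile


def make_pedigree(relatives: list[dict], proband: dict | None = None) -> Pedigree:
    doc = {
        "proband": {
            "relation_code": "self",
            "sex": "female",
            "alive": True,
            "current_age": 45,
            **(proband or {}),
        },
        "relatives": relatives,
    }
    return parse_pedigree(json.dumps(doc))


def required_six(**overrides) -> list[dict]:
    """Mother, father and four grandparents with plain vital data."""
    base = [
        {"relation_code": "mother", "alive": True, "current_age": 70},
        {"relation_code": "father", "alive": True, "current_age": 72},
        {"relation_code": "maternal grandmother", "alive": False, "age_at_death": 82,
         "cause_of_death": "stroke"},
        {"relation_code": "maternal grandfather", "alive": False, "age_at_death": 79,
         "cause_of_death": "heart disease"},
        {"relation_code": "paternal grandmother", "alive": False, "age_at_death": 88,
         "cause_of_death": "old age"},
        {"relation_code": "paternal grandfather", "alive": False, "age_at_death": 70,
         "cause_of_death": "cancer"},
    ]
    for rec in base:
        rec.update(overrides.get(rec["relation_code"], {}))
    return base


@pytest.fixture
def required_pedigree() -> Pedigree:
    return make_pedigree(required_six())


@pytest.fixture
def single_gene_model() -> GeneModel:
    """One-gene dominant toy model: 2 genotype classes, one modelled cancer."""
    carrier = _interp_cdf({20: 0.0, 40: 0.25, 60: 0.55, 80: 0.75, 110: 0.80})
    base = _interp_cdf({20: 0.0, 40: 0.01, 60: 0.04, 80: 0.09, 110: 0.11})
    cdf = {}
    for sex in ("female", "male"):
        cdf[("G", "breast_cancer", sex)] = carrier
        cdf[("noncarrier", "breast_cancer", sex)] = base
    model = GeneModel(
        genes=["G"],
        frequencies={"G": {"general": 0.05}},
        cdf=cdf,
        cancers=["breast_cancer"],
        version="toy-single/1",
    )
    model.validate()
    return model


@pytest.fixture
def flat_gene_model() -> GeneModel:
    """Carrier and noncarrier penetrance identical: phenotypes carry no signal."""
    curve = _interp_cdf({20: 0.0, 60: 0.10, 110: 0.15})
    cdf = {}
    for sex in ("female", "male"):
        cdf[("G", "breast_cancer", sex)] = curve
        cdf[("noncarrier", "breast_cancer", sex)] = curve
    model = GeneModel(
        genes=["G"],
        frequencies={"G": {"general": 0.10}},
        cdf=cdf,
        cancers=["breast_cancer"],
        version="toy-flat/1",
    )
    model.validate()
    return model


def _rand_sex(rng: np.random.Generator) -> Sex:
    return Sex.FEMALE if rng.random() < 0.5 else Sex.MALE


def random_pedigree_graph(
    rng: np.random.Generator,
    max_size: int = 12,
    p_affected_bias: float = 0.35,
) -> PedigreeGraph:
    """Random loop-free pedigree with phenotypes for oracle comparisons.

    Grows nuclear families: starts from a founder couple, then repeatedly
    marries an existing member to a new founder and adds children, so the
    marriage graph stays a tree.
    """
    n = int(rng.integers(3, max_size + 1))
    people: dict[str, Individual] = {}
    counter = [0]

    def new_person(sex: Sex, mother=None, father=None) -> Individual:
        counter[0] += 1
        ind = Individual(id=f"p{counter[0]}", sex=sex, mother=mother, father=father)
        people[ind.id] = ind
        return ind

    mom = new_person(Sex.FEMALE)
    dad = new_person(Sex.MALE)
    kids = [new_person(_rand_sex(rng), mom.id, dad.id)]
    while len(people) < n:
        if rng.random() < 0.5 and kids:
            # marry a random childless existing member to a new founder
            pivot = people[str(rng.choice([k.id for k in kids]))]
            spouse = new_person(Sex.MALE if pivot.sex == Sex.FEMALE else Sex.FEMALE)
            if len(people) < n:
                m, f = (pivot, spouse) if pivot.sex == Sex.FEMALE else (spouse, pivot)
                kid = new_person(_rand_sex(rng), m.id, f.id)
                kids.append(kid)
        else:
            kids.append(new_person(_rand_sex(rng), mom.id, dad.id))
    for ind in people.values():
        age = float(rng.integers(25, 85))
        ind.censoring_age = age
        if rng.random() < 0.15:
            ind.history_known = False
        elif rng.random() < p_affected_bias:
            onset = float(rng.integers(25, int(age) + 1))
            ind.affected["breast_cancer"] = onset if rng.random() < 0.9 else None
    counselee = str(rng.choice(sorted(people)))
    return PedigreeGraph(individuals=people, proband_id=counselee)


# ---------------------------------------------------------------------------
# independent exhaustive-enumeration oracle for the Mendelian posterior

def _oracle_phenotype(ind: Individual, model: GeneModel, class_idx: int) -> float:
    if not ind.history_known or ind.sex == Sex.UNKNOWN:
        return 1.0
    lik = 1.0
    for cancer in model.cancers:
        F = model.class_cdf(class_idx, cancer, ind.sex.value)
        if cancer in ind.affected:
            onset = ind.affected[cancer]
            if onset is not None:
                a = int(round(onset))
                lik *= F[a] - F[a - 1] if a >= 1 else F[0]
            else:
                t = int(round(ind.censoring_age)) if ind.censoring_age is not None else len(F) - 1
                lik *= F[t]
        elif ind.censoring_age is not None:
            lik *= 1.0 - F[int(round(ind.censoring_age))]
    return lik


def _oracle_transmission(model: GeneModel, child: int, mom: int, dad: int) -> float:
    # per-gene first-principles transmission: carrier parent transmits w.p. 1/2
    K = len(model.genes)
    p = 1.0
    for g in range(K):
        cg = (child >> (K - 1 - g)) & 1
        mg = (mom >> (K - 1 - g)) & 1
        dg = (dad >> (K - 1 - g)) & 1
        p_not = (0.5 if mg else 1.0) * (0.5 if dg else 1.0)
        p *= (1.0 - p_not) if cg else p_not
    return p


def enumeration_joint(
    g: PedigreeGraph, model: GeneModel, counselee: str, stratum: str = "general",
    with_phenotypes: bool = True,
) -> np.ndarray:
    """Brute-force P(data, G_counselee=k) by summing over all assignments."""
    ids = sorted(g.individuals)
    idx = {iid: i for i, iid in enumerate(ids)}
    C = model.n_classes
    n = len(ids)
    prior = model.genotype_prior(stratum)
    phen = np.ones((n, C))
    if with_phenotypes:
        for iid in ids:
            for k in range(C):
                phen[idx[iid], k] = _oracle_phenotype(g.individuals[iid], model, k)
    grids = np.meshgrid(*[np.arange(C)] * n, indexing="ij")
    assign = np.stack([a.ravel() for a in grids], axis=1)  # (C^n, n)
    logp = np.ones(assign.shape[0])
    T = np.zeros((C, C, C))
    for c in range(C):
        for m in range(C):
            for f in range(C):
                T[c, m, f] = _oracle_transmission(model, c, m, f)
    for iid in ids:
        i = idx[iid]
        ind = g.individuals[iid]
        if ind.is_founder:
            logp = logp * prior[assign[:, i]]
        else:
            logp = logp * T[assign[:, i], assign[:, idx[ind.mother]], assign[:, idx[ind.father]]]
        logp = logp * phen[i, assign[:, i]]
    out = np.zeros(C)
    ci = idx[counselee]
    for k in range(C):
        out[k] = logp[assign[:, ci] == k].sum()
    return out


def enumeration_posterior(g, model, counselee, stratum="general") -> np.ndarray:
    joint = enumeration_joint(g, model, counselee, stratum)
    return joint / joint.sum()


def enumeration_likelihood(g, model, counselee, stratum="general") -> np.ndarray:
    joint = enumeration_joint(g, model, counselee, stratum)
    prior = enumeration_joint(g, model, counselee, stratum, with_phenotypes=False)
    return joint / prior


@pytest.fixture
def full_profile() -> RiskFactorProfile:
    return RiskFactorProfile(
        age=52,
        sex=Sex.FEMALE,
        race_ethnicity="white",
        menarche_age=12,
        nulliparous=False,
        age_first_live_birth=27,
        breast_biopsy_count=1,
        atypical_hyperplasia=False,
        hrt_use=False,
        height_cm=165,
        weight_kg=70,
        systolic_bp=128,
        treated_hypertension=False,
        total_cholesterol=205,
        hdl=52,
        smoker=False,
        pack_years=0.0,
        diabetes=False,
        hscrp=1.8,
    )
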