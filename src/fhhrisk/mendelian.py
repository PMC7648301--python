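"""Exact Bayesian carrier inference on loop-free pedigrees.

The pedigree and genotypes form a Bayesian network: founder genotypes are
drawn from the ancestry-stratum prior, children from the Mendelian
transmission kernel, and each individual's phenotype (affected at an onset
age, or unaffected to a censoring age) depends only on their own genotype.
Because the marriage graph of an outbred pedigree is a tree, the exact
genotype posterior of the counselee is obtained by peeling (Elston-Stewart):
a sum-product recursion over nuclear families that sums each child out
independently given the parental genotypes, so cost is linear in pedigree
size and quadratic-ish in the (small) genotype-class count.

Phenotype likelihood terms per individual and genotype class G:

- affected at onset age a: the annual penetrance increment F_G(a) - F_G(a-1);
- affected, onset unknown: F_G(censoring age) (ever affected by then);
- unaffected for a modelled cancer to censoring age t: 1 - F_G(t);
- history unknown (or placeholder founder): 1 — the individual still
  contributes transmission structure but no phenotype information.

Multiple modelled cancers multiply (conditional independence given
genotype).  Conditions outside the gene model's cancer list are ignored
here; they are handled by the rule engine, not the Mendelian likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genemodel import AGE_MAX, GeneModel
from .graph import Individual, PedigreeGraph
from .pedigree import Sex


class LoopError(ValueError):
    """Pedigree contains an inbreeding loop; peeling unsupported."""


@dataclass
class GenotypePosterior:
    """Posterior over joint genotype classes for the counselee."""

    labels: list[str]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.probabilities.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"posterior does not normalise (sum={total})")

    def prob(self, label: str) -> float:
        return float(self.probabilities[self.labels.index(label)])

    @property
    def carrier_probability(self) -> float:
        """Probability of carrying at least one modelled mutation."""
        return float(
            sum(p for lab, p in zip(self.labels, self.probabilities) if lab != "noncarrier")
        )

    def as_dict(self) -> dict[str, float]:
        return {lab: float(p) for lab, p in zip(self.labels, self.probabilities)}


@dataclass
class AbsoluteRisk:
    """Absolute probability of a condition over a horizon, in [0, 1]."""

    condition: str
    horizon_years: float
    probability: float


def _clip_age(a: float) -> int:
    return int(np.clip(round(a), 0, AGE_MAX))


def phenotype_likelihood(ind: Individual, model: GeneModel) -> np.ndarray:
    """Per-genotype-class likelihood of one individual's phenotype."""
    C = model.n_classes
    out = np.ones(C)
    if not ind.history_known or ind.sex == Sex.UNKNOWN:
        return out
    sex = ind.sex.value
    cens = ind.censoring_age
    for cancer in model.cancers:
        if cancer in ind.affected:
            onset = ind.affected[cancer]
            for k in range(C):
                F = model.class_cdf(k, cancer, sex)
                if onset is not None:
                    a = _clip_age(onset)
                    out[k] *= F[a] - F[a - 1] if a >= 1 else F[0]
                else:
                    t = _clip_age(cens) if cens is not None else AGE_MAX
                    out[k] *= F[t]
        elif cens is not None:
            t = _clip_age(cens)
            for k in range(C):
                out[k] *= 1.0 - model.class_cdf(k, cancer, sex)[t]
        # no censoring age and unaffected: no information
    if not out.any():
        # the model assigns zero density under every genotype (e.g. an onset
        # before the earliest penetrance anchor): treat as uninformative
        # rather than declaring the pedigree impossible
        return np.ones(C)
    return out


class _Peeler:
    def __init__(self, g: PedigreeGraph, model: GeneModel, stratum: str, flat: bool = False):
        if g.has_loops():
            raise LoopError("pedigree contains loops; exact peeling unsupported")
        self.g = g
        self.model = model
        self.prior = model.genotype_prior(stratum)
        self.T = model.transmission()
        self.C = model.n_classes
        if flat:
            self.phen = {i: np.ones(self.C) for i in g.individuals}
        else:
            self.phen = {
                i: phenotype_likelihood(ind, model) for i, ind in g.individuals.items()
            }
        self.fams = g.nuclear_families()
        self.parent_fam: dict[str, int] = {}
        self.spouse_fams: dict[str, list[int]] = {i: [] for i in g.individuals}
        for idx, (m, f, kids) in enumerate(self.fams):
            self.spouse_fams[m].append(idx)
            self.spouse_fams[f].append(idx)
            for k in kids:
                self.parent_fam[k] = idx

    def joint(self, counselee: str) -> np.ndarray:
        """P(all phenotypes, G_counselee = g) for each class g.

        Individuals not connected to the counselee (e.g. a married-in
        relative with no children entered) contribute a scalar factor:
        the total probability of their own component.
        """
        v = self._down(counselee, exclude=None)
        for root in self._component_roots(counselee):
            v = v * self._down(root, exclude=None).sum()
        return v

    def _component_roots(self, counselee: str) -> list[str]:
        import networkx as nx

        ug = nx.Graph()
        ug.add_nodes_from(self.g.individuals)
        for m, f, kids in self.fams:
            for a in [f, *kids]:
                ug.add_edge(m, a)
            for k in kids:
                ug.add_edge(f, k)
        reached = nx.node_connected_component(ug, counselee)
        roots = []
        for comp in nx.connected_components(ug):
            if comp is not reached and counselee not in comp:
                roots.append(min(comp))
        return sorted(roots)

    def _down(self, i: str, exclude: int | None) -> np.ndarray:
        v = self.phen[i].copy()
        if i in self.parent_fam:
            if self.parent_fam[i] != exclude:
                v *= self._family_to_child(self.parent_fam[i], i)
        else:
            v *= self.prior
        for fidx in self.spouse_fams[i]:
            if fidx != exclude:
                v *= self._family_to_parent(fidx, i)
        return v

    def _child_sums(self, fidx: int, skip: str | None) -> np.ndarray:
        """prod over children c != skip of sum_gc T[gc,gm,gf]*down(c), as (C, C)."""
        _, _, kids = self.fams[fidx]
        out = np.ones((self.C, self.C))
        for c in kids:
            if c == skip:
                continue
            cv = self._down(c, exclude=fidx)
            out *= np.einsum("cmf,c->mf", self.T, cv)
        return out

    def _family_to_parent(self, fidx: int, pivot: str) -> np.ndarray:
        m, f, _ = self.fams[fidx]
        spouse = f if pivot == m else m
        sv = self._down(spouse, exclude=fidx)
        ks = self._child_sums(fidx, skip=None)
        if pivot == m:
            return ks @ sv  # sum over gf
        return ks.T @ sv  # pivot is father: sum over gm

    def _family_to_child(self, fidx: int, pivot: str) -> np.ndarray:
        m, f, _ = self.fams[fidx]
        mv = self._down(m, exclude=fidx)
        fv = self._down(f, exclude=fidx)
        ks = self._child_sums(fidx, skip=pivot)
        pair = np.outer(mv, fv) * ks  # (gm, gf)
        return np.einsum("cmf,mf->c", self.T, pair)


def structural_prior(g: PedigreeGraph, model: GeneModel, counselee: str, stratum: str = "general") -> np.ndarray:
    """Marginal genotype distribution of *counselee* with no phenotype data."""
    v = _Peeler(g, model, stratum, flat=True).joint(counselee)
    return v / v.sum()


def pedigree_likelihood(
    g: PedigreeGraph,
    model: GeneModel,
    counselee: str | None = None,
    stratum: str = "general",
) -> np.ndarray:
    """P(all phenotypes | counselee genotype class), one value per class."""
    counselee = counselee or g.proband_id
    joint = _Peeler(g, model, stratum).joint(counselee)
    prior = _Peeler(g, model, stratum, flat=True).joint(counselee)
    return joint / prior


def carrier_posterior(
    g: PedigreeGraph,
    model: GeneModel,
    counselee: str | None = None,
    stratum: str = "general",
) -> GenotypePosterior:
    """Posterior over the counselee's joint genotype classes given the pedigree."""
    counselee = counselee or g.proband_id
    joint = _Peeler(g, model, stratum).joint(counselee)
    total = joint.sum()
    if total <= 0:
        raise ValueError("pedigree has zero likelihood under the gene model")
    return GenotypePosterior(labels=model.class_labels, probabilities=joint / total)


def future_cancer_risk(
    posterior: GenotypePosterior,
    model: GeneModel,
    cancer: str,
    sex: str,
    current_age: float,
    horizon: float,
) -> AbsoluteRisk:
    """Posterior-mixture residual risk of *cancer* over the next *horizon* years.

    For each genotype class G the conditional risk given being unaffected at
    the current age is (F_G(a + h) - F_G(a)) / (1 - F_G(a)); the classes are
    mixed by their posterior weights.
    """
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    a = _clip_age(current_age)
    b = _clip_age(current_age + horizon)
    risk = 0.0
    for k, w in enumerate(posterior.probabilities):
        F = model.class_cdf(k, cancer, sex)
        denom = 1.0 - F[a]
        if denom > 0:
            risk += float(w) * (F[b] - F[a]) / denom
    return AbsoluteRisk(condition=cancer, horizon_years=float(horizon), probability=risk)


def lifetime_risk(
    posterior: GenotypePosterior,
    model: GeneModel,
    cancer: str,
    sex: str,
    current_age: float,
    to_age: float = 85.0,
) -> AbsoluteRisk:
    """Residual risk from the current age to *to_age* (default 85)."""
    horizon = max(0.0, to_age - current_age)
    risk = future_cancer_risk(posterior, model, cancer, sex, current_age, horizon)
    return AbsoluteRisk(condition=cancer, horizon_years=horizon, probability=risk.probability)
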