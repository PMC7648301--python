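"""Mendelian gene model: allele frequencies and age-indexed penetrance.

The model describes a small set of rare autosomal-dominant susceptibility
genes (default BRCA1 and BRCA2), each with an allele frequency per ancestry
stratum and a cumulative penetrance curve (probability of each modelled
cancer by age, by sex) for carriers, plus a shared noncarrier baseline
curve.  Curves are entered in config as anchors at selected ages and are
interpolated to an annual grid with a monotone (PCHIP) interpolant.

Carriers are treated as heterozygous when transmitting (the standard
rare-allele simplification): a carrier parent passes the mutation with
probability 1/2, a noncarrier never does.  Joint genotype classes are the
2^K carrier patterns over the K genes; the penetrance of a multi-gene
carrier class is the elementwise maximum of the single-gene carrier curves.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

AGE_MAX = 110
AGES = np.arange(0, AGE_MAX + 1)


class GeneModelError(ValueError):
    pass


def _interp_cdf(anchors: dict[float, float]) -> np.ndarray:
    pts = sorted(anchors.items())
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    if xs[0] > 0:
        xs, ys = [0.0] + xs, [0.0] + ys
    if xs[-1] < AGE_MAX:
        xs, ys = xs + [float(AGE_MAX)], ys + [ys[-1]]
    if any(b < a for a, b in zip(ys, ys[1:])):
        raise GeneModelError("penetrance anchors must be nondecreasing in age")
    if not (0 <= ys[0] and ys[-1] <= 1):
        raise GeneModelError("penetrance must lie in [0, 1]")
    return np.clip(PchipInterpolator(xs, ys)(AGES), 0.0, 1.0)


@dataclass
class GeneModel:
    """Allele frequencies + penetrance curves on an annual age grid."""

    genes: list[str]
    frequencies: dict[str, dict[str, float]]  # gene -> stratum -> allele freq
    # (curve_name, cancer, sex) -> cumulative risk over AGES;
    # curve_name is a gene name or "noncarrier"
    cdf: dict[tuple[str, str, str], np.ndarray]
    cancers: list[str]
    version: str = "unversioned"
    _class_cdf_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_classes(self) -> int:
        return 2 ** len(self.genes)

    @property
    def class_labels(self) -> list[str]:
        out = []
        for pattern in self._patterns():
            carried = [g for g, c in zip(self.genes, pattern) if c]
            out.append("+".join(carried) if carried else "noncarrier")
        return out

    def _patterns(self) -> list[tuple[int, ...]]:
        return list(itertools.product((0, 1), repeat=len(self.genes)))

    def strata(self) -> list[str]:
        return sorted(next(iter(self.frequencies.values())))

    def carrier_prob(self, gene: str, stratum: str) -> float:
        """Hardy-Weinberg carrier probability 2f(1-f) + f^2."""
        try:
            f = self.frequencies[gene][stratum]
        except KeyError as exc:
            raise GeneModelError(f"unknown gene/stratum {gene!r}/{stratum!r}") from exc
        return 2 * f * (1 - f) + f * f

    def genotype_prior(self, stratum: str) -> np.ndarray:
        """Founder prior over joint genotype classes (genes independent)."""
        ps = [self.carrier_prob(g, stratum) for g in self.genes]
        prior = np.empty(self.n_classes)
        for k, pattern in enumerate(self._patterns()):
            prior[k] = float(
                np.prod([p if c else 1 - p for p, c in zip(ps, pattern)])
            )
        return prior

    def class_cdf(self, class_idx: int, cancer: str, sex: str) -> np.ndarray:
        """Cumulative penetrance of *cancer* for genotype class, by sex."""
        key = (class_idx, cancer, sex)
        if key not in self._class_cdf_cache:
            pattern = self._patterns()[class_idx]
            carried = [g for g, c in zip(self.genes, pattern) if c]
            if not carried:
                curve = self.cdf[("noncarrier", cancer, sex)]
            else:
                curve = np.max(
                    [self.cdf[(g, cancer, sex)] for g in carried], axis=0
                )
            self._class_cdf_cache[key] = curve
        return self._class_cdf_cache[key]

    def transmission(self) -> np.ndarray:
        """T[child, mother, father] over joint classes.

        Per gene: a carrier parent transmits with probability 1/2, a
        noncarrier parent never; genes segregate independently.
        """
        C = self.n_classes
        pats = self._patterns()
        T = np.ones((C, C, C))
        for ci, cp in enumerate(pats):
            for mi, mp in enumerate(pats):
                for fi, fp in enumerate(pats):
                    p = 1.0
                    for cg, mg, fg in zip(cp, mp, fp):
                        q_not = (0.5 if mg else 1.0) * (0.5 if fg else 1.0)
                        p *= (1 - q_not) if cg else q_not
                    T[ci, mi, fi] = p
        return T

    def validate(self) -> None:
        for (name, cancer, sex), curve in self.cdf.items():
            if np.any(np.diff(curve) < -1e-12):
                raise GeneModelError(f"curve {name}/{cancer}/{sex} not nondecreasing")
            if name != "noncarrier":
                base = self.cdf.get(("noncarrier", cancer, sex))
                if base is not None and np.any(curve < base - 1e-9):
                    raise GeneModelError(
                        f"carrier curve {name}/{cancer}/{sex} below noncarrier baseline"
                    )
        for gene, strata in self.frequencies.items():
            for stratum, f in strata.items():
                if not (0 <= f <= 0.5):
                    raise GeneModelError(f"allele frequency {gene}/{stratum}={f} outside [0, 0.5]")


def load_gene_model(path_or_stream) -> GeneModel:
    if hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            data = yaml.safe_load(fh)
    genes = [g["name"] for g in data["genes"]]
    freqs = {g["name"]: {k: float(v) for k, v in g["allele_frequency"].items()} for g in data["genes"]}
    cancers = sorted({c["cancer"] for c in data["penetrance"]})
    cdf: dict[tuple[str, str, str], np.ndarray] = {}
    for entry in data["penetrance"]:
        key = (entry["curve"], entry["cancer"], entry["sex"])
        cdf[key] = _interp_cdf({float(a): float(v) for a, v in entry["cumulative_risk"].items()})
    for cancer in cancers:
        for sex in ("female", "male"):
            for curve in ["noncarrier"] + genes:
                if (curve, cancer, sex) not in cdf:
                    raise GeneModelError(f"missing penetrance curve {curve}/{cancer}/{sex}")
    model = GeneModel(
        genes=genes,
        frequencies=freqs,
        cdf=cdf,
        cancers=cancers,
        version=str(data.get("version", "unversioned")),
    )
    model.validate()
    return model


def default_gene_model() -> GeneModel:
    ref = importlib.resources.files("fhhrisk.config").joinpath("genemodel.yaml")
    with ref.open() as fh:
        return load_gene_model(fh)
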