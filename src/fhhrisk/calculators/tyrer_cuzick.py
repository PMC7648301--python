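"""Tyrer-Cuzick-style lifetime breast-cancer risk (single-hypothetical-locus form).

The published model combines a Mendelian segregation component — BRCA1/2
plus one hypothetical common, low-penetrance dominant susceptibility locus
standing in for residual polygenic familial risk — with personal hormonal
and benign-disease relative risks.  This implementation:

1. extends the two-gene model with the hypothetical locus (frequency and
   penetrance from ``config/tyrer_cuzick.yaml``) and computes the
   counselee's genotype-class posterior by pedigree peeling;
2. computes each class's residual breast-cancer risk to age 85;
3. applies the product of hormonal relative risks (age at menarche,
   parity / age at first birth, HRT use, BMI) to the *non-genetic*
   component only, as a power on the noncarrier survival:
   risk_nc' = 1 - (1 - risk_nc)^RR;
4. mixes the class risks by their posterior weights.

This is a documented simplification of the commercial IBIS program: the
hypothetical locus replaces IBIS's full polygenotype, and competing
mortality is not modelled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import yaml

from ..genemodel import GeneModel, _interp_cdf, default_gene_model
from ..graph import PedigreeGraph
from ..mendelian import carrier_posterior
from ..pedigree import Sex
from ..profiles import Horizon, RiskFactorProfile, RiskScore, computed, not_calculated

BREAST = "breast_cancer"
LIFETIME_TO_AGE = 85.0


@dataclass
class TCConfig:
    locus_name: str
    allele_frequency: float
    penetrance_anchors: dict[float, float]  # female breast cancer, carrier
    menarche_rr: dict[str, float]
    first_birth_rr: dict[str, float]
    hrt_rr: dict[str, float]
    bmi_rr: dict[str, float]
    version: str = "unversioned"


def load_tc_config(stream=None) -> TCConfig:
    if stream is None:
        ref = importlib.resources.files("fhhrisk.config").joinpath("tyrer_cuzick.yaml")
        stream = ref.open()
    with stream:
        d = yaml.safe_load(stream)
    loc = d["hypothetical_locus"]
    return TCConfig(
        locus_name=loc.get("name", "LOWPEN"),
        allele_frequency=float(loc["allele_frequency"]),
        penetrance_anchors={float(a): float(v) for a, v in loc["breast_cumulative_risk"].items()},
        menarche_rr=d["hormonal_rr"]["menarche"],
        first_birth_rr=d["hormonal_rr"]["first_birth"],
        hrt_rr=d["hormonal_rr"]["hrt"],
        bmi_rr=d["hormonal_rr"]["bmi"],
        version=str(d.get("version", "unversioned")),
    )


def extended_gene_model(base: GeneModel | None = None, cfg: TCConfig | None = None) -> GeneModel:
    """Base gene model plus the hypothetical low-penetrance locus."""
    base = base or default_gene_model()
    cfg = cfg or load_tc_config()
    genes = base.genes + [cfg.locus_name]
    freqs = dict(base.frequencies)
    freqs[cfg.locus_name] = {s: cfg.allele_frequency for s in base.strata()}
    cdf = dict(base.cdf)
    cdf[(cfg.locus_name, BREAST, "female")] = _interp_cdf(cfg.penetrance_anchors)
    # the hypothetical locus is breast-specific; other curves equal baseline
    for cancer in base.cancers:
        for sex in ("female", "male"):
            key = (cfg.locus_name, cancer, sex)
            if key not in cdf:
                cdf[key] = base.cdf[("noncarrier", cancer, sex)]
    model = GeneModel(genes=genes, frequencies=freqs, cdf=cdf, cancers=base.cancers,
                      version=f"{base.version}+{cfg.version}")
    model.validate()
    return model


def hormonal_relative_risk(profile: RiskFactorProfile, cfg: TCConfig) -> float:
    rr = 1.0
    m = profile.menarche_age
    rr *= cfg.menarche_rr["lt12" if m < 12 else ("12_13" if m < 14 else "ge14")]
    if profile.nulliparous or (profile.age_first_live_birth is None):
        rr *= cfg.first_birth_rr["nulliparous"]
    else:
        a = profile.age_first_live_birth
        rr *= cfg.first_birth_rr["lt20" if a < 20 else ("20_24" if a < 25 else ("25_29" if a < 30 else "ge30"))]
    rr *= cfg.hrt_rr["current" if profile.hrt_use else "never"]
    bmi = profile.bmi
    rr *= cfg.bmi_rr["ge30" if bmi >= 30 else ("25_30" if bmi >= 25 else "lt25")]
    return rr


def required_missing(profile: RiskFactorProfile) -> list[str]:
    missing = []
    if profile.menarche_age is None:
        missing.append("menarche_age")
    if profile.nulliparous is None and profile.age_first_live_birth is None:
        missing.append("age_first_live_birth")
    if profile.hrt_use is None:
        missing.append("hrt_use")
    if profile.height_cm is None:
        missing.append("height_cm")
    if profile.weight_kg is None:
        missing.append("weight_kg")
    return missing


def tyrer_cuzick_lifetime_risk(
    profile: RiskFactorProfile,
    graph: PedigreeGraph,
    base_model: GeneModel | None = None,
    cfg: TCConfig | None = None,
    stratum: str = "general",
) -> RiskScore:
    """Lifetime (to 85) breast-cancer risk as a percent score."""
    cfg = cfg or load_tc_config()
    if profile.sex != Sex.FEMALE or profile.breast_cancer_history or not (20 <= profile.age <= LIFETIME_TO_AGE):
        return not_calculated("tyrer_cuzick", Horizon.LIFETIME, ["eligibility"])
    missing = required_missing(profile)
    if missing:
        return not_calculated("tyrer_cuzick", Horizon.LIFETIME, missing)
    model = extended_gene_model(base_model, cfg)
    post = carrier_posterior(graph, model, stratum=stratum)
    rr = hormonal_relative_risk(profile, cfg)
    total = 0.0
    for k, (label, w) in enumerate(zip(post.labels, post.probabilities)):
        base_risk = _class_lifetime_risk(model, k, profile.age)
        if label == "noncarrier":
            base_risk = 1.0 - (1.0 - base_risk) ** rr
        total += float(w) * base_risk
    return computed("tyrer_cuzick", Horizon.LIFETIME, total)


def _class_lifetime_risk(model: GeneModel, class_idx: int, age: float) -> float:
    from ..genemodel import AGE_MAX
    import numpy as np

    F = model.class_cdf(class_idx, BREAST, "female")
    a = int(np.clip(round(age), 0, AGE_MAX))
    b = int(np.clip(round(LIFETIME_TO_AGE), 0, AGE_MAX))
    denom = 1.0 - F[a]
    return (F[b] - F[a]) / denom if denom > 0 else 0.0
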