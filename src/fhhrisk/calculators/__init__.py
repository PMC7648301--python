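"""The six validated risk calculators behind a uniform contract.

``eligibility`` decides which calculators apply to a proband (published
age/sex windows); ``run_all`` executes every applicable calculator and
returns a :class:`~fhhrisk.profiles.RiskScore` per calculator id, with
``not_calculated`` + named missing inputs whenever a required input is
absent (never an imputed number).
"""

from __future__ import annotations

from ..genemodel import GeneModel, default_gene_model
from ..graph import PedigreeGraph
from ..mendelian import carrier_posterior, lifetime_risk
from ..pedigree import Pedigree, Sex
from ..profiles import (
    CALCULATOR_IDS,
    Horizon,
    RiskFactorProfile,
    RiskScore,
    computed,
    not_calculated,
)
from .cvd import framingham_cvd_risk, load_cvd_config, pce_ascvd_risk, reynolds_risk
from .gail import gail_absolute_risk, gail_relative_risk
from .tyrer_cuzick import tyrer_cuzick_lifetime_risk

__all__ = [
    "eligibility",
    "run_all",
    "gail_absolute_risk",
    "gail_relative_risk",
    "tyrer_cuzick_lifetime_risk",
    "brcapro_lifetime_risk",
    "framingham_cvd_risk",
    "reynolds_risk",
    "pce_ascvd_risk",
]

# published eligibility windows (age lo, age hi)
_WINDOWS = {
    "gail": (35.0, 85.0),
    "tyrer_cuzick": (20.0, 85.0),
    "brcapro": (20.0, 85.0),
    "framingham": (30.0, 74.0),
    "reynolds": (45.0, 80.0),
    "pce": (40.0, 79.0),
}
_BREAST_CALCS = ("gail", "tyrer_cuzick", "brcapro")


def eligibility(profile: RiskFactorProfile) -> set[str]:
    """Calculator ids applicable to this proband (deterministic).

    Breast models: women in the model's age window without a prior breast
    cancer.  CVD models: either sex within the published age window (the
    Reynolds window for men starts at 50).
    """
    out: set[str] = set()
    for calc, (lo, hi) in _WINDOWS.items():
        if not (lo <= profile.age <= hi):
            continue
        if calc in _BREAST_CALCS:
            if profile.sex == Sex.FEMALE and not profile.breast_cancer_history:
                out.add(calc)
        elif calc == "reynolds":
            if profile.sex == Sex.FEMALE or (profile.sex == Sex.MALE and profile.age >= 50):
                out.add(calc)
        elif profile.sex != Sex.UNKNOWN:
            out.add(calc)
    return out


def brcapro_lifetime_risk(
    profile: RiskFactorProfile,
    graph: PedigreeGraph,
    model: GeneModel | None = None,
    stratum: str = "general",
) -> RiskScore:
    """Lifetime (to 85) breast-cancer risk from the Mendelian carrier posterior."""
    if profile.sex != Sex.FEMALE or profile.breast_cancer_history:
        return not_calculated("brcapro", Horizon.LIFETIME, ["eligibility"])
    model = model or default_gene_model()
    post = carrier_posterior(graph, model, stratum=stratum)
    risk = lifetime_risk(post, model, "breast_cancer", "female", profile.age)
    return computed("brcapro", Horizon.LIFETIME, risk.probability)


def run_all(
    profile: RiskFactorProfile,
    pedigree: Pedigree,
    graph: PedigreeGraph | None = None,
    gene_model: GeneModel | None = None,
    ashkenazi: bool = False,
) -> dict[str, RiskScore]:
    """Run every calculator; ineligible ones report not_calculated."""
    from ..graph import expand_to_graph

    if graph is None:
        graph = expand_to_graph(pedigree)
    stratum = "ashkenazi" if (ashkenazi or pedigree.proband.ashkenazi) else "general"
    eligible = eligibility(profile)
    scores: dict[str, RiskScore] = {}
    for calc in CALCULATOR_IDS:
        if calc not in eligible:
            horizon = {
                "gail": Horizon.FIVE_YEAR,
                "tyrer_cuzick": Horizon.LIFETIME,
                "brcapro": Horizon.LIFETIME,
            }.get(calc, Horizon.TEN_YEAR)
            scores[calc] = not_calculated(calc, horizon, ["eligibility"])
            continue
        if calc == "gail":
            scores[calc] = gail_absolute_risk(profile, pedigree)
        elif calc == "tyrer_cuzick":
            scores[calc] = tyrer_cuzick_lifetime_risk(profile, graph, gene_model, stratum=stratum)
        elif calc == "brcapro":
            scores[calc] = brcapro_lifetime_risk(profile, graph, gene_model, stratum)
        elif calc == "framingham":
            scores[calc] = framingham_cvd_risk(profile, pedigree)
        elif calc == "reynolds":
            scores[calc] = reynolds_risk(profile, pedigree)
        elif calc == "pce":
            scores[calc] = pce_ascvd_risk(profile, pedigree)
    return scores
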