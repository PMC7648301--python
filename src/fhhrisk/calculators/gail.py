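"""Gail model: 5-year absolute breast-cancer risk.

The model multiplies category relative risks for age at menarche, number
of breast biopsies (with an atypical-hyperplasia multiplier), and the age
at first live birth x number of affected first-degree relatives
interaction, then composes the relative risk with race-stratified,
attributable-risk-adjusted baseline breast-cancer incidence and competing
(non-breast-cancer) mortality to get an absolute probability over the
projection interval.

The biopsy relative risk is age-band specific (under / over 50), so the
projection uses the pre-50 relative risk for person-years before age 50
and the post-50 one after.  With piecewise-constant annual hazards the
integral has a closed form per year:

    P = sum_j  w_j * [1 - exp(-(r_j h1_j + h2_j))] * S_j,
    w_j = r_j h1_j / (r_j h1_j + h2_j),
    S_j = survival (breast-cancer-free and alive) to the start of year j.

Coefficients, hazards and attributable-risk factors live in
``config/gail.yaml`` with source notes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from ..pedigree import Degree, Pedigree, Sex
from ..profiles import Horizon, RiskFactorProfile, RiskScore, computed, not_calculated

BREAST = "breast_cancer"


@dataclass
class GailConfig:
    menarche_rr: dict[str, float]          # category -> RR
    biopsy_rr: dict[str, dict[str, float]]  # age band -> category -> RR
    atypical_rr: dict[str, float]
    afb_fdr_rr: dict[str, dict[str, float]]  # age-at-first-birth cat -> FDR cat -> RR
    incidence: dict[str, dict[int, float]]   # race -> age-band start -> annual hazard
    mortality: dict[str, dict[int, float]]
    one_minus_ar: dict[str, dict[str, float]]  # race -> {under50, over50}
    default_race: str = "white"
    version: str = "unversioned"


def load_gail_config(stream=None) -> GailConfig:
    if stream is None:
        ref = importlib.resources.files("fhhrisk.config").joinpath("gail.yaml")
        stream = ref.open()
    with stream:
        d = yaml.safe_load(stream)
    return GailConfig(
        menarche_rr=d["menarche_rr"],
        biopsy_rr=d["biopsy_rr"],
        atypical_rr=d["atypical_rr"],
        afb_fdr_rr=d["afb_fdr_rr"],
        incidence={r: {int(k): float(v) for k, v in t.items()} for r, t in d["incidence"].items()},
        mortality={r: {int(k): float(v) for k, v in t.items()} for r, t in d["mortality"].items()},
        one_minus_ar=d["one_minus_ar"],
        default_race=d.get("default_race", "white"),
        version=str(d.get("version", "unversioned")),
    )


def _menarche_cat(age: float) -> str:
    if age < 12:
        return "lt12"
    if age < 14:
        return "12_13"
    return "ge14"


def _biopsy_cat(n: int) -> str:
    if n == 0:
        return "0"
    return "1" if n == 1 else "2plus"


def _afb_cat(nulliparous: bool, age: float | None) -> str:
    if nulliparous or age is None:
        return "25_29_or_nulliparous"
    if age < 20:
        return "lt20"
    if age < 25:
        return "20_24"
    if age < 30:
        return "25_29_or_nulliparous"
    return "ge30"


def _fdr_cat(n: int) -> str:
    if n == 0:
        return "0"
    return "1" if n == 1 else "2plus"


def fdr_breast_cancer_count(pedigree: Pedigree) -> int:
    """Number of first-degree relatives with breast cancer."""
    return sum(
        1
        for r in pedigree.relatives
        if r.degree == Degree.FDR and r.has_condition(BREAST)
    )


def required_missing(profile: RiskFactorProfile) -> list[str]:
    missing = []
    if profile.menarche_age is None:
        missing.append("menarche_age")
    if profile.nulliparous is None and profile.age_first_live_birth is None:
        missing.append("age_first_live_birth")
    if profile.breast_biopsy_count is None:
        missing.append("breast_biopsy_count")
    return missing


def gail_relative_risk(
    profile: RiskFactorProfile,
    fdr_count: int,
    config: GailConfig | None = None,
    age_band: str = "under50",
) -> float:
    """Product of category relative risks for one age band.

    Reference categories (menarche >= 14, no biopsies, first birth < 20,
    no affected FDR) give exactly 1.0.
    """
    cfg = config or load_gail_config()
    missing = required_missing(profile)
    if missing:
        raise ValueError(f"missing Gail inputs: {missing}")
    rr = cfg.menarche_rr[_menarche_cat(profile.menarche_age)]
    nb = profile.breast_biopsy_count
    rr *= cfg.biopsy_rr[age_band][_biopsy_cat(nb)]
    if nb > 0:
        if profile.atypical_hyperplasia is True:
            rr *= cfg.atypical_rr["yes"]
        elif profile.atypical_hyperplasia is False:
            rr *= cfg.atypical_rr["no"]
        # unknown: multiplier 1
    afb = _afb_cat(bool(profile.nulliparous), profile.age_first_live_birth)
    rr *= cfg.afb_fdr_rr[afb][_fdr_cat(fdr_count)]
    return rr


def _hazard_at(table: dict[int, float], age: float) -> float:
    starts = sorted(table)
    h = table[starts[0]]
    for s in starts:
        if age >= s:
            h = table[s]
    return h


def absolute_risk_fraction(
    age: float,
    horizon: float,
    rr_under50: float,
    rr_over50: float,
    race: str,
    cfg: GailConfig,
) -> float:
    """Closed-form projection over annual steps with piecewise-constant hazards."""
    race = race if race in cfg.incidence else cfg.default_race
    inc = cfg.incidence[race]
    mort = cfg.mortality[race]
    omar = cfg.one_minus_ar[race]
    total = 0.0
    log_surv = 0.0
    t = age
    while t < age + horizon - 1e-9:
        step = min(1.0, age + horizon - t)
        band = "under50" if t < 50 else "over50"
        r = rr_under50 if t < 50 else rr_over50
        h1 = _hazard_at(inc, t) * omar[band] * r
        h2 = _hazard_at(mort, t)
        htot = h1 + h2
        if htot > 0:
            total += (h1 / htot) * (1 - np.exp(-htot * step)) * np.exp(log_surv)
        log_surv -= htot * step
        t += step
    return float(total)


def gail_absolute_risk(
    profile: RiskFactorProfile,
    pedigree: Pedigree,
    horizon_years: float = 5.0,
    config: GailConfig | None = None,
) -> RiskScore:
    """5-year (by default) absolute breast-cancer risk as a percent score."""
    cfg = config or load_gail_config()
    missing = required_missing(profile)
    if missing:
        return not_calculated("gail", Horizon.FIVE_YEAR, missing)
    if profile.sex != Sex.FEMALE or profile.breast_cancer_history:
        return not_calculated("gail", Horizon.FIVE_YEAR, ["eligibility"])
    fdr = fdr_breast_cancer_count(pedigree)
    rr_u = gail_relative_risk(profile, fdr, cfg, "under50")
    rr_o = gail_relative_risk(profile, fdr, cfg, "over50")
    race = (profile.race_ethnicity or cfg.default_race).lower()
    frac = absolute_risk_fraction(profile.age, horizon_years, rr_u, rr_o, race, cfg)
    return computed("gail", Horizon.FIVE_YEAR, frac)
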