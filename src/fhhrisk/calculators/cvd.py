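"""10-year cardiovascular risk equations (Framingham, Reynolds, pooled cohort).

All three share the Cox proportional-hazards survival form

    risk = 1 - S0(10) ^ exp(L - Lbar)

with a sex-stratified (and, for the pooled cohort equations, race-
stratified) linear predictor L = sum beta_j x_j, baseline 10-year survival
S0 and the stratum's mean linear predictor Lbar.  Coefficient sets are
config data (one YAML per calculator, with source notes); this module owns
the functional form, eligibility windows and the missing-input contract.

Feature vocabulary available to configs: age, ln_age, ln_tc, ln_hdl,
ln_sbp_treated / ln_sbp_untreated (ln SBP routed by antihypertensive
treatment), smoker, diabetes, ln_crp, hba1c_if_diabetic, fam_mi60
(parental myocardial infarction before age 60, derivable from the
pedigree).  A term may multiply several features (interaction / powers).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import yaml

from ..pedigree import Pedigree, Sex
from ..profiles import Horizon, RiskFactorProfile, RiskScore, computed, not_calculated

_FIELD_FOR_FEATURE = {
    "age": ["age"],
    "ln_age": ["age"],
    "ln_tc": ["total_cholesterol"],
    "ln_hdl": ["hdl"],
    "ln_sbp_treated": ["systolic_bp", "treated_hypertension"],
    "ln_sbp_untreated": ["systolic_bp", "treated_hypertension"],
    "smoker": ["smoker"],
    "diabetes": ["diabetes"],
    "ln_crp": ["hscrp"],
    "hba1c_if_diabetic": ["diabetes"],
    "fam_mi60": ["parental_mi_before_60"],
}


@dataclass
class Term:
    features: list[str]
    coef: float


@dataclass
class Stratum:
    terms: list[Term]
    baseline_survival: float
    mean_linear_predictor: float


@dataclass
class CVDConfig:
    calculator: str
    strata: dict[str, Stratum]  # key: "female", "male", "white_female", ...
    age_window: tuple[float, float]
    version: str = "unversioned"

    def stratum_key(self, profile: RiskFactorProfile) -> str:
        sex = profile.sex.value
        if sex == "unknown":
            raise ValueError("sex required for CVD risk")
        race = (profile.race_ethnicity or "white").lower()
        for key in (f"{race}_{sex}", sex):
            if key in self.strata:
                return key
        # unlisted race maps to the calculator's default (white) stratum
        if f"white_{sex}" in self.strata:
            return f"white_{sex}"
        raise ValueError(f"no stratum for sex={sex}")


def load_cvd_config(calculator: str, stream=None) -> CVDConfig:
    if stream is None:
        ref = importlib.resources.files("fhhrisk.config").joinpath(f"{calculator}.yaml")
        stream = ref.open()
    with stream:
        d = yaml.safe_load(stream)
    strata = {}
    for key, s in d["strata"].items():
        strata[key] = Stratum(
            terms=[Term(features=list(t["features"]), coef=float(t["coef"])) for t in s["terms"]],
            baseline_survival=float(s["baseline_survival"]),
            mean_linear_predictor=float(s["mean_linear_predictor"]),
        )
    return CVDConfig(
        calculator=calculator,
        strata=strata,
        age_window=(float(d["age_window"][0]), float(d["age_window"][1])),
        version=str(d.get("version", "unversioned")),
    )


def derive_fam_mi60(profile: RiskFactorProfile, pedigree: Pedigree | None) -> bool | None:
    """Parental MI before 60: profile flag, else derived from the pedigree."""
    if profile.parental_mi_before_60 is not None:
        return profile.parental_mi_before_60
    if pedigree is None:
        return None
    for code in ("mother", "father"):
        for rec in pedigree.find(code):
            onset = rec.onset_of("coronary_artery_disease")
            if onset is not None and onset < 60:
                return True
            if rec.has_condition("coronary_artery_disease") and onset is None:
                continue  # affected, onset unknown: cannot assert before-60
    # parents with known history and no early CAD count as negative
    parents = [r for c in ("mother", "father") for r in pedigree.find(c)]
    if parents and all(p.history_known for p in parents):
        return False
    return None


def feature_values(
    profile: RiskFactorProfile, needed: set[str], pedigree: Pedigree | None = None
) -> tuple[dict[str, float], list[str]]:
    """Evaluate features; returns (values, missing profile fields)."""
    missing: set[str] = set()
    vals: dict[str, float] = {}
    for feat in needed:
        for field in _FIELD_FOR_FEATURE[feat]:
            if feat == "fam_mi60":
                continue
            if getattr(profile, field) is None:
                missing.add(field)
    if missing:
        return {}, sorted(missing)
    vals["age"] = profile.age
    vals["ln_age"] = math.log(profile.age)
    if "ln_tc" in needed:
        vals["ln_tc"] = math.log(profile.total_cholesterol)
    if "ln_hdl" in needed:
        vals["ln_hdl"] = math.log(profile.hdl)
    if "ln_sbp_treated" in needed or "ln_sbp_untreated" in needed:
        lnsbp = math.log(profile.systolic_bp)
        treated = bool(profile.treated_hypertension)
        vals["ln_sbp_treated"] = lnsbp if treated else 0.0
        vals["ln_sbp_untreated"] = 0.0 if treated else lnsbp
    if "smoker" in needed:
        vals["smoker"] = 1.0 if profile.smoker else 0.0
    if "diabetes" in needed:
        vals["diabetes"] = 1.0 if profile.diabetes else 0.0
    if "ln_crp" in needed:
        if profile.hscrp is None or profile.hscrp <= 0:
            return {}, ["hscrp"]
        vals["ln_crp"] = math.log(profile.hscrp)
    if "hba1c_if_diabetic" in needed:
        if profile.diabetes:
            if profile.hba1c is None:
                return {}, ["hba1c"]
            vals["hba1c_if_diabetic"] = profile.hba1c
        else:
            vals["hba1c_if_diabetic"] = 0.0
    if "fam_mi60" in needed:
        fam = derive_fam_mi60(profile, pedigree)
        if fam is None:
            return {}, ["parental_mi_before_60"]
        vals["fam_mi60"] = 1.0 if fam else 0.0
    return vals, []


def linear_predictor(stratum: Stratum, vals: dict[str, float]) -> float:
    lp = 0.0
    for term in stratum.terms:
        x = term.coef
        for feat in term.features:
            x *= vals[feat]
        lp += x
    return lp


def risk_from_linear_predictor(lp: float, stratum: Stratum) -> float:
    """1 - S0^exp(L - Lbar); exactly 1 - S0 when L equals the stratum mean."""
    return 1.0 - stratum.baseline_survival ** math.exp(lp - stratum.mean_linear_predictor)


def ten_year_risk(
    calculator: str,
    profile: RiskFactorProfile,
    pedigree: Pedigree | None = None,
    config: CVDConfig | None = None,
) -> RiskScore:
    cfg = config or load_cvd_config(calculator)
    lo, hi = cfg.age_window
    if not (lo <= profile.age <= hi) or profile.sex == Sex.UNKNOWN:
        return not_calculated(calculator, Horizon.TEN_YEAR, ["eligibility"])
    stratum = cfg.strata[cfg.stratum_key(profile)]
    needed = {f for t in stratum.terms for f in t.features}
    vals, missing = feature_values(profile, needed, pedigree)
    if missing:
        return not_calculated(calculator, Horizon.TEN_YEAR, missing)
    frac = risk_from_linear_predictor(linear_predictor(stratum, vals), stratum)
    return computed(calculator, Horizon.TEN_YEAR, frac)


def framingham_cvd_risk(profile: RiskFactorProfile, pedigree: Pedigree | None = None, config: CVDConfig | None = None) -> RiskScore:
    """Framingham 2008 general-CVD 10-year risk (office + lipids form)."""
    return ten_year_risk("framingham", profile, pedigree, config)


def reynolds_risk(profile: RiskFactorProfile, pedigree: Pedigree | None = None, config: CVDConfig | None = None) -> RiskScore:
    """Reynolds risk score; requires hsCRP (and HbA1c for diabetic women)."""
    return ten_year_risk("reynolds", profile, pedigree, config)


def pce_ascvd_risk(profile: RiskFactorProfile, pedigree: Pedigree | None = None, config: CVDConfig | None = None) -> RiskScore:
    """ACC/AHA pooled cohort equations, race- and sex-stratified."""
    return ten_year_risk("pce", profile, pedigree, config)
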