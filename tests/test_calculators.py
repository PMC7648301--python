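"""Risk calculators: reference identities, oracles, missing-data contract."""

import math

import numpy as np
import pytest

from fhhrisk.calculators import brcapro_lifetime_risk, eligibility, run_all
from fhhrisk.calculators.cvd import (
    framingham_cvd_risk,
    linear_predictor,
    load_cvd_config,
    pce_ascvd_risk,
    reynolds_risk,
    risk_from_linear_predictor,
    feature_values,
)
from fhhrisk.calculators.gail import (
    absolute_risk_fraction,
    fdr_breast_cancer_count,
    gail_absolute_risk,
    gail_relative_risk,
    load_gail_config,
)
from fhhrisk.calculators.tyrer_cuzick import (
    extended_gene_model,
    load_tc_config,
    tyrer_cuzick_lifetime_risk,
)
from fhhrisk.graph import expand_to_graph
from fhhrisk.profiles import RiskFactorProfile, ScoreStatus
from fhhrisk.pedigree import Sex

from conftest import (
    enumeration_posterior,
    make_pedigree,
    required_six,
)


def reference_profile(**over) -> RiskFactorProfile:
    """All Gail factors at their reference categories."""
    base = dict(
        age=45,
        sex=Sex.FEMALE,
        race_ethnicity="white",
        menarche_age=14,
        nulliparous=False,
        age_first_live_birth=19,
        breast_biopsy_count=0,
        atypical_hyperplasia=None,
        hrt_use=False,
        height_cm=165,
        weight_kg=65,
        systolic_bp=125,
        treated_hypertension=False,
        total_cholesterol=200,
        hdl=50,
        smoker=False,
        diabetes=False,
        hscrp=1.5,
    )
    base.update(over)
    return RiskFactorProfile(**base)


class TestEligibility:
    def test_midlife_woman_eligible_for_all_six(self):
        assert eligibility(reference_profile(age=45)) == {
            "gail", "tyrer_cuzick", "brcapro", "framingham", "reynolds", "pce"
        }

    def test_male_excluded_from_breast_calculators(self):
        elig = eligibility(reference_profile(age=55, sex=Sex.MALE))
        assert elig == {"framingham", "reynolds", "pce"}

    def test_age_25_excluded_from_ten_year_cvd_calculators(self):
        elig = eligibility(reference_profile(age=25))
        assert not elig & {"framingham", "reynolds", "pce"}
        assert "tyrer_cuzick" in elig

    def test_prior_breast_cancer_excludes_breast_models(self):
        elig = eligibility(reference_profile(breast_cancer_history=True))
        assert not elig & {"gail", "tyrer_cuzick", "brcapro"}


class TestGailRelativeRisk:
    def test_reference_categories_give_exactly_one(self):
        assert gail_relative_risk(reference_profile(), fdr_count=0) == pytest.approx(1.0)

    def test_single_factor_equals_its_published_coefficient(self):
        cfg = load_gail_config()
        rr = gail_relative_risk(reference_profile(menarche_age=11), fdr_count=0)
        assert rr == pytest.approx(cfg.menarche_rr["lt12"])
        rr = gail_relative_risk(reference_profile(breast_biopsy_count=1), fdr_count=0)
        assert rr == pytest.approx(cfg.biopsy_rr["under50"]["1"])

    def test_multi_factor_hand_product(self):
        cfg = load_gail_config()
        prof = reference_profile(
            menarche_age=11, breast_biopsy_count=2, atypical_hyperplasia=True,
            age_first_live_birth=31,
        )
        hand = (
            cfg.menarche_rr["lt12"]
            * cfg.biopsy_rr["over50"]["2plus"]
            * cfg.atypical_rr["yes"]
            * cfg.afb_fdr_rr["ge30"]["1"]
        )
        assert gail_relative_risk(prof, fdr_count=1, age_band="over50") == pytest.approx(hand)

    def test_fdr_count_from_pedigree(self):
        ped = make_pedigree(
            required_six(mother={"conditions": [{"condition_code": "breast_cancer",
                                                 "age_of_onset": 50}]})
            + [{"relation_code": "sister", "alive": True, "current_age": 48,
                "conditions": [{"condition_code": "breast_cancer", "age_of_onset": 45}]},
               {"relation_code": "maternal aunt", "alive": True, "current_age": 70,
                "conditions": [{"condition_code": "breast_cancer", "age_of_onset": 60}]}]
        )
        assert fdr_breast_cancer_count(ped) == 2  # aunt is SDR, excluded


class TestGailAbsoluteRisk:
    def test_zero_horizon_is_zero(self, required_pedigree):
        score = gail_absolute_risk(reference_profile(), required_pedigree, horizon_years=0)
        assert score.value == 0.0

    def test_reference_profile_equals_baseline_integral(self, required_pedigree):
        cfg = load_gail_config()
        score = gail_absolute_risk(reference_profile(age=45), required_pedigree)
        base = absolute_risk_fraction(45, 5, 1.0, 1.0, "white", cfg)
        assert score.value == pytest.approx(round(base * 100, 2))

    def test_matches_fine_grid_integration_oracle(self, required_pedigree):
        # independent trapezoidal integration of the same hazard model on a
        # daily grid
        cfg = load_gail_config()
        prof = reference_profile(age=48, menarche_age=11, breast_biopsy_count=1)
        rr_u = gail_relative_risk(prof, 0, cfg, "under50")
        rr_o = gail_relative_risk(prof, 0, cfg, "over50")
        got = absolute_risk_fraction(48, 5, rr_u, rr_o, "white", cfg)

        from fhhrisk.calculators.gail import _hazard_at

        ts = np.linspace(48, 53, 5 * 365 + 1)
        h1 = np.array([
            _hazard_at(cfg.incidence["white"], t)
            * cfg.one_minus_ar["white"]["under50" if t < 50 else "over50"]
            * (rr_u if t < 50 else rr_o)
            for t in ts
        ])
        h2 = np.array([_hazard_at(cfg.mortality["white"], t) for t in ts])
        dt = ts[1] - ts[0]
        cum = np.concatenate([[0], np.cumsum((h1 + h2)[:-1] + (h1 + h2)[1:]) / 2 * dt])
        integrand = h1 * np.exp(-cum)
        oracle = np.trapezoid(integrand, ts)
        assert got == pytest.approx(oracle, rel=1e-3)

    def test_male_profile_not_calculated(self, required_pedigree):
        score = gail_absolute_risk(reference_profile(sex=Sex.MALE, menarche_age=None,
                                                     nulliparous=None,
                                                     breast_biopsy_count=None),
                                   required_pedigree)
        assert score.status == ScoreStatus.NOT_CALCULATED


class TestCVDEquations:
    @pytest.mark.parametrize("calculator", ["framingham", "reynolds", "pce"])
    def test_exponent_zero_identity(self, calculator):
        cfg = load_cvd_config(calculator)
        for key, stratum in cfg.strata.items():
            risk = risk_from_linear_predictor(stratum.mean_linear_predictor, stratum)
            assert risk == pytest.approx(1 - stratum.baseline_survival, abs=1e-15), key

    def test_framingham_hand_evaluation_oracle(self):
        # published-form hand evaluation for a woman: L = sum(beta * x)
        prof = reference_profile(age=61, total_cholesterol=180, hdl=47,
                                 systolic_bp=124, smoker=True, diabetes=False)
        cfg = load_cvd_config("framingham")
        s = cfg.strata["female"]
        L = (2.32888 * math.log(61) + 1.20904 * math.log(180)
             - 0.70833 * math.log(47) + 2.76157 * math.log(124) + 0.52873)
        hand = 1 - 0.95012 ** math.exp(L - 26.1931)
        got = framingham_cvd_risk(prof)
        assert got.value == pytest.approx(round(hand * 100, 2), abs=0.01)

    def test_pce_hand_evaluation_white_female(self):
        prof = reference_profile(age=55, total_cholesterol=213, hdl=50,
                                 systolic_bp=120, smoker=False, diabetes=False)
        la, lt, lh, ls = (math.log(55), math.log(213), math.log(50), math.log(120))
        L = (-29.799 * la + 4.884 * la * la + 13.540 * lt - 3.114 * la * lt
             - 13.578 * lh + 3.149 * la * lh + 1.957 * ls)
        hand = 1 - 0.9665 ** math.exp(L - (-29.18))
        got = pce_ascvd_risk(prof)
        assert got.value == pytest.approx(round(hand * 100, 2), abs=0.01)

    def test_reynolds_uses_family_history_from_pedigree(self):
        ped = make_pedigree(
            required_six(father={"conditions": [{"condition_code": "coronary_artery_disease",
                                                 "age_of_onset": 50}]})
        )
        prof = reference_profile(age=60)
        with_fh = reynolds_risk(prof, ped)
        without = reynolds_risk(prof, make_pedigree(required_six()))
        assert with_fh.value > without.value

    @pytest.mark.parametrize(
        "field,adverse",
        [("systolic_bp", [110, 130, 150, 170]),
         ("total_cholesterol", [160, 200, 240, 280]),
         ("age", [45, 55, 65, 74])],
    )
    def test_monotone_in_adverse_factors(self, field, adverse):
        values = []
        for v in adverse:
            kwargs = {"age": 60, field: v}
            prof = reference_profile(**kwargs)
            values.append(framingham_cvd_risk(prof).value)
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_smoking_and_diabetes_increase_risk(self):
        base = framingham_cvd_risk(reference_profile(age=60)).value
        assert framingham_cvd_risk(reference_profile(age=60, smoker=True)).value > base
        assert framingham_cvd_risk(reference_profile(age=60, diabetes=True)).value > base

    def test_all_computed_risks_within_percent_range(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            prof = reference_profile(
                age=float(rng.integers(45, 75)),
                systolic_bp=float(rng.integers(95, 200)),
                total_cholesterol=float(rng.integers(130, 320)),
                hdl=float(rng.integers(25, 95)),
                smoker=bool(rng.random() < 0.5),
                diabetes=bool(rng.random() < 0.3),
                hba1c=7.0,
                hscrp=float(rng.uniform(0.2, 10)),
                parental_mi_before_60=bool(rng.random() < 0.2),
            )
            for fn in (framingham_cvd_risk, reynolds_risk, pce_ascvd_risk):
                score = fn(prof)
                assert score.status == ScoreStatus.COMPUTED
                assert 0 <= score.value <= 100


class TestMissingDataContract:
    """Deleting any single required input flips the calculator to
    not_calculated naming exactly that input — never an imputed value."""

    CASES = [
        ("gail", "menarche_age", "menarche_age"),
        ("gail", "breast_biopsy_count", "breast_biopsy_count"),
        ("framingham", "total_cholesterol", "total_cholesterol"),
        ("framingham", "hdl", "hdl"),
        ("framingham", "systolic_bp", "systolic_bp"),
        ("reynolds", "hscrp", "hscrp"),
        ("reynolds", "total_cholesterol", "total_cholesterol"),
        ("pce", "systolic_bp", "systolic_bp"),
        ("pce", "hdl", "hdl"),
        ("tyrer_cuzick", "menarche_age", "menarche_age"),
        ("tyrer_cuzick", "height_cm", "height_cm"),
        ("tyrer_cuzick", "hrt_use", "hrt_use"),
    ]

    @pytest.mark.parametrize("calc,field,named", CASES)
    def test_each_missing_input_is_named(self, calc, field, named, required_pedigree):
        prof = reference_profile(age=52, **{field: None})
        scores = run_all(prof, required_pedigree)
        assert scores[calc].status == ScoreStatus.NOT_CALCULATED
        assert named in scores[calc].missing_inputs

    def test_parity_unknown_blocks_breast_models(self, required_pedigree):
        prof = reference_profile(age=52, nulliparous=None, age_first_live_birth=None)
        scores = run_all(prof, required_pedigree)
        assert scores["gail"].status == ScoreStatus.NOT_CALCULATED
        assert "age_first_live_birth" in scores["gail"].missing_inputs

    def test_diabetic_without_hba1c_blocks_reynolds_only(self, required_pedigree):
        prof = reference_profile(age=60, diabetes=True, hba1c=None)
        scores = run_all(prof, required_pedigree)
        assert scores["reynolds"].status == ScoreStatus.NOT_CALCULATED
        assert scores["reynolds"].missing_inputs == ["hba1c"]
        assert scores["framingham"].status == ScoreStatus.COMPUTED

    def test_determinism_identical_profile_identical_scores(self, required_pedigree):
        prof = reference_profile(age=52)
        a = run_all(prof, required_pedigree)
        b = run_all(prof, required_pedigree)
        assert {k: v.model_dump() for k, v in a.items()} == {k: v.model_dump() for k, v in b.items()}


class TestTyrerCuzick:
    def test_no_family_history_reference_factors_near_baseline(self, required_pedigree):
        prof = reference_profile(age=40, menarche_age=14, age_first_live_birth=19,
                                 hrt_use=False, height_cm=165, weight_kg=60)
        g = expand_to_graph(required_pedigree)
        score = tyrer_cuzick_lifetime_risk(prof, g)
        model = extended_gene_model()
        F0 = model.class_cdf(0, "breast_cancer", "female")
        baseline = (F0[85] - F0[40]) / (1 - F0[40])
        # posterior retains some carrier mass, so the score sits slightly
        # above the pure noncarrier baseline but within a tight band
        assert score.value >= round(baseline * 100, 2) - 0.01
        assert score.value < baseline * 100 + 3.0

    def test_affected_fdr_strictly_increases_risk(self):
        prof = reference_profile(age=40)
        base = make_pedigree(required_six())
        plus = make_pedigree(
            required_six(mother={"conditions": [{"condition_code": "breast_cancer",
                                                 "age_of_onset": 40}]})
        )
        s0 = tyrer_cuzick_lifetime_risk(prof, expand_to_graph(base))
        s1 = tyrer_cuzick_lifetime_risk(prof, expand_to_graph(plus))
        assert s1.value > s0.value

    def test_hormonal_rr_increases_noncarrier_component(self):
        prof_ref = reference_profile(age=40)
        prof_adverse = reference_profile(age=40, menarche_age=11, nulliparous=True,
                                         age_first_live_birth=None, hrt_use=True,
                                         weight_kg=95)
        g = expand_to_graph(make_pedigree(required_six()))
        assert (tyrer_cuzick_lifetime_risk(prof_adverse, g).value
                > tyrer_cuzick_lifetime_risk(prof_ref, g).value)

    def test_three_locus_posterior_matches_enumeration_oracle(self):
        # toy two-locus check: the extended model's posterior on a small
        # pedigree equals exhaustive enumeration including the hypothetical
        # locus
        from fhhrisk.mendelian import carrier_posterior

        model = extended_gene_model()
        ped = make_pedigree(
            [{"relation_code": "mother", "alive": True, "current_age": 70,
              "conditions": [{"condition_code": "breast_cancer", "age_of_onset": 42}]},
             {"relation_code": "father", "alive": True, "current_age": 71}]
        )
        g = expand_to_graph(ped)
        post = carrier_posterior(g, model)
        oracle = enumeration_posterior(g, model, "self")
        assert np.abs(post.probabilities - oracle).max() < 1e-9


class TestBrcaproScore:
    def test_posterior_mass_moves_risk_toward_carrier_curve(self, required_pedigree):
        prof = reference_profile(age=40)
        g = expand_to_graph(required_pedigree)
        base = brcapro_lifetime_risk(prof, g)
        loaded = make_pedigree(
            required_six(mother={"conditions": [{"condition_code": "breast_cancer",
                                                 "age_of_onset": 32}]})
            + [{"relation_code": "sister", "alive": True, "current_age": 44,
                "conditions": [{"condition_code": "ovarian_cancer", "age_of_onset": 40}]}]
        )
        high = brcapro_lifetime_risk(prof, expand_to_graph(loaded))
        assert high.value > base.value
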