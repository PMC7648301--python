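"""Rule engine: catalog loading, predicate semantics, evidence, reports."""

import io

import pytest

from fhhrisk.cds import (
    CatalogError,
    Evidence,
    count_affected,
    evaluate_rules,
    load_rule_catalog,
    recommendations,
    render_report,
    tier_summary,
)
from fhhrisk.profiles import Horizon, computed, not_calculated

from conftest import make_pedigree, required_six
from test_calculators import reference_profile


@pytest.fixture(scope="module")
def catalog():
    return load_rule_catalog()


def neutral_scores(**over):
    scores = {
        "gail": computed("gail", Horizon.FIVE_YEAR, 0.008),
        "tyrer_cuzick": computed("tyrer_cuzick", Horizon.LIFETIME, 0.09),
        "brcapro": computed("brcapro", Horizon.LIFETIME, 0.09),
        "framingham": computed("framingham", Horizon.TEN_YEAR, 0.05),
        "reynolds": computed("reynolds", Horizon.TEN_YEAR, 0.03),
        "pce": computed("pce", Horizon.TEN_YEAR, 0.05),
    }
    for calc, frac in over.items():
        scores[calc] = computed(calc, scores[calc].horizon, frac)
    return scores


class TestCatalogLoading:
    REQUIRED_RULES = {
        "hereditary_cardiac", "hboc", "lynch", "fap", "pten", "thrombophilia",
        "familial_hypercholesterolemia", "hemochromatosis", "wilsons",
        "alpha1_antitrypsin", "ovarian_screening_discussion", "breast_mri",
        "breast_chemoprevention", "early_colonoscopy", "aspirin_stroke_prevention",
        "diabetes_screening", "aaa_screening", "calcium_scoring_ct",
        "lung_cancer_screening",
    }

    def test_default_catalog_contains_every_line_item(self, catalog):
        assert set(catalog.ids()) == self.REQUIRED_RULES

    def test_tier_partition(self, catalog):
        assert {r.tier for r in catalog.rules} == {"monogenic", "familial", "common"}
        assert len(catalog.by_tier("monogenic")) == 10
        assert len(catalog.by_tier("familial")) == 4
        assert len(catalog.by_tier("common")) == 5

    def test_undeclared_variable_rejected_at_load_time(self):
        bad = io.StringIO(
            "version: 'x'\ncommon:\n"
            "  - id: bad\n    recommendation: r\n"
            "    when: {var: profile.shoe_size, op: '>', value: 9}\n"
        )
        with pytest.raises(CatalogError, match="bad.*shoe_size"):
            load_rule_catalog(bad)

    def test_unknown_condition_rejected_at_load_time(self):
        bad = io.StringIO(
            "version: 'x'\nmonogenic:\n"
            "  - id: bad2\n    recommendation: r\n"
            "    when: {agg: {condition: dropsy}, op: '>=', value: 1}\n"
        )
        with pytest.raises(CatalogError, match="bad2.*dropsy"):
            load_rule_catalog(bad)

    def test_malformed_comparator_names_rule(self):
        bad = io.StringIO(
            "version: 'x'\ncommon:\n"
            "  - id: bad3\n    recommendation: r\n"
            "    when: {var: profile.age, op: '~', value: 1}\n"
        )
        with pytest.raises(CatalogError, match="bad3"):
            load_rule_catalog(bad)

    def test_empty_catalog_is_valid_and_fires_nothing(self):
        cat = load_rule_catalog(io.StringIO("version: 'empty'\n"))
        results = evaluate_rules(cat, reference_profile(), make_pedigree([]), neutral_scores())
        assert results == []


class TestEvaluation:
    def test_healthy_proband_fires_no_monogenic_or_familial_rules(self, catalog):
        results = evaluate_rules(
            catalog, reference_profile(age=45), make_pedigree(required_six()), neutral_scores()
        )
        fired = [r for r in results if r.status == "fired"]
        assert all(r.tier == "common" for r in fired)

    def test_breast_mri_fires_above_lifetime_cutoff_with_evidence(self, catalog):
        results = evaluate_rules(
            catalog, reference_profile(), make_pedigree(required_six()),
            neutral_scores(tyrer_cuzick=0.23),
        )
        rec = {r.rule_id: r for r in results}["breast_mri"].recommendation
        assert rec is not None
        assert rec.evidence[0].variable == "score.tyrer_cuzick"
        assert rec.evidence[0].observed == 23.0

    def test_hboc_pattern_pedigree_fires_referral(self, catalog):
        # multiple early-onset breast + ovarian cancer in the same lineage
        ped = make_pedigree(
            required_six(mother={"conditions": [{"condition_code": "breast_cancer",
                                                 "age_of_onset": 38}]})
            + [{"relation_code": "maternal aunt", "alive": False, "age_at_death": 60,
                "cause_of_death": "ovarian cancer",
                "conditions": [{"condition_code": "ovarian_cancer", "age_of_onset": 55}]}]
        )
        results = evaluate_rules(catalog, reference_profile(), ped, neutral_scores())
        fired = {r.rule_id for r in results if r.status == "fired"}
        assert "hboc" in fired

    def test_missing_score_makes_rule_not_evaluable_not_unmet(self, catalog):
        scores = neutral_scores()
        scores["tyrer_cuzick"] = not_calculated("tyrer_cuzick", Horizon.LIFETIME, ["hrt_use"])
        results = evaluate_rules(catalog, reference_profile(), make_pedigree(required_six()), scores)
        status = {r.rule_id: r.status for r in results}
        assert status["breast_mri"] == "not_evaluable"

    def test_missing_pack_years_blocks_lung_rule(self, catalog):
        prof = reference_profile(age=60, smoker=True, pack_years=None)
        results = evaluate_rules(catalog, prof, make_pedigree(required_six()), neutral_scores())
        status = {r.rule_id: r.status for r in results}
        assert status["lung_cancer_screening"] == "not_evaluable"

    def test_strengthening_fhh_never_unfires_a_fired_rule(self, catalog):
        rels = required_six(mother={"conditions": [{"condition_code": "colon_cancer",
                                                    "age_of_onset": 45}]})
        before = evaluate_rules(catalog, reference_profile(), make_pedigree(rels), neutral_scores())
        rels_more = rels + [
            {"relation_code": "brother", "alive": True, "current_age": 50,
             "conditions": [{"condition_code": "colon_cancer", "age_of_onset": 48}]}
        ]
        after = evaluate_rules(catalog, reference_profile(), make_pedigree(rels_more), neutral_scores())
        fired_before = {r.rule_id for r in before if r.status == "fired"}
        fired_after = {r.rule_id for r in after if r.status == "fired"}
        assert fired_before <= fired_after

    def test_evidence_replay_on_all_fired_rules(self, catalog):
        ped = make_pedigree(
            required_six(mother={"conditions": [{"condition_code": "breast_cancer",
                                                 "age_of_onset": 38}]},
                         father={"conditions": [{"condition_code": "type_2_diabetes",
                                                 "age_of_onset": 55}]})
        )
        prof = reference_profile(age=62, smoker=True, pack_years=30)
        results = evaluate_rules(catalog, prof, ped, neutral_scores(pce=0.12, gail=0.021))
        recs = recommendations(results)
        assert recs  # several rules fire on this loaded fixture
        for rec in recs:
            assert rec.evidence
            assert all(e.replay() for e in rec.evidence)


class TestBoundarySemantics:
    @pytest.mark.parametrize(
        "calc,cutoff,op",
        [("tyrer_cuzick", 20.0, ">"), ("gail", 1.67, ">="), ("pce", 7.5, ">=")],
    )
    def test_threshold_rules_respect_configured_strictness(self, catalog, calc, cutoff, op):
        rule_for = {"tyrer_cuzick": "breast_mri", "gail": "breast_chemoprevention",
                    "pce": "calcium_scoring_ct"}
        eps = 0.01  # scores are reported at 2-decimal percent precision
        for value, expected in [
            (cutoff - eps, False),
            (cutoff, op == ">="),
            (cutoff + eps, True),
        ]:
            results = evaluate_rules(
                catalog, reference_profile(age=45), make_pedigree(required_six()),
                neutral_scores(**{calc: value / 100.0}),
            )
            status = {r.rule_id: r.status for r in results}[rule_for[calc]]
            assert (status == "fired") == expected, (value, expected)

    def test_evidence_replay_consistency_is_structural(self):
        ev = Evidence(variable="score.pce", observed=7.5, comparator=">=", threshold=7.5)
        assert ev.replay()
        assert not Evidence("score.pce", 7.4999, ">=", 7.5).replay()


class TestAggregates:
    def test_count_affected_filters(self):
        ped = make_pedigree(
            required_six(mother={"conditions": [{"condition_code": "breast_cancer",
                                                 "age_of_onset": 38}]})
            + [{"relation_code": "maternal aunt", "alive": True, "current_age": 70,
                "conditions": [{"condition_code": "breast_cancer", "age_of_onset": 65}]},
               {"relation_code": "brother", "alive": True, "current_age": 50,
                "conditions": [{"condition_code": "breast_cancer"}]}]
        )
        assert count_affected(ped, "breast_cancer") == 3
        assert count_affected(ped, "breast_cancer", degrees=["FDR"]) == 2
        assert count_affected(ped, "breast_cancer", side="maternal") == 2
        assert count_affected(ped, "breast_cancer", sex="male") == 1
        # onset-unknown entries excluded from onset-bounded counts
        assert count_affected(ped, "breast_cancer", max_onset=45) == 1


class TestSummaryAndReport:
    def test_empty_summary_is_all_zero(self):
        s = tier_summary([])
        assert s["participants_with_any"] == 0 and s["total_recommendations"] == 0

    def test_one_rule_per_tier_counts(self, catalog):
        ped = make_pedigree(
            required_six(mother={"conditions": [
                {"condition_code": "wilsons_disease", "age_of_onset": 30},
                {"condition_code": "colon_cancer", "age_of_onset": 45},
            ]})
        )
        prof = reference_profile(age=45, weight_kg=80)
        results = evaluate_rules(catalog, prof, ped, neutral_scores())
        s = tier_summary([results])
        assert s["participants_with_any"] == 1
        assert all(s["participants_by_tier"][t] == 1 for t in ("monogenic", "familial", "common"))

    def test_cohort_counts_match_hand_tally(self, catalog):
        fixtures = [
            (reference_profile(age=45, weight_kg=80), make_pedigree(required_six())),  # common only
            (reference_profile(age=45),
             make_pedigree(required_six(mother={"conditions": [
                 {"condition_code": "ovarian_cancer", "age_of_onset": 50}]}))),  # monogenic+familial
            (reference_profile(age=30, menarche_age=14, diabetes=None),
             make_pedigree(required_six())),  # nothing fires
        ]
        results = [evaluate_rules(catalog, p, ped, neutral_scores()) for p, ped in fixtures]
        s = tier_summary(results)
        assert s["n_participants"] == 3
        assert s["participants_by_tier"]["monogenic"] == 1
        assert s["participants_by_tier"]["familial"] == 1
        assert s["participants_with_any"] == 2

    def test_report_lists_every_score_and_is_deterministic(self, catalog):
        prof = reference_profile(age=45)
        ped = make_pedigree(required_six())
        scores = neutral_scores()
        scores["reynolds"] = not_calculated("reynolds", Horizon.TEN_YEAR, ["hscrp"])
        results = evaluate_rules(catalog, prof, ped, scores)
        j1, t1 = render_report(prof, scores, results, catalog.version)
        j2, t2 = render_report(prof, scores, results, catalog.version)
        assert (j1, t1) == (j2, t2)
        for calc in scores:
            assert calc in j1
        assert "not calculated (missing: hscrp)" in t1

    def test_zero_recommendations_states_no_criteria_met(self, catalog):
        prof = reference_profile(age=30, menarche_age=14, diabetes=None)
        ped = make_pedigree(required_six())
        results = evaluate_rules(catalog, prof, ped, neutral_scores())
        _, text = render_report(prof, neutral_scores(), results, catalog.version)
        if not recommendations(results):
            assert "No elevated-risk criteria were met." in text
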