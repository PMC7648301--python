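"""Guideline rule engine: three-tier risk-management recommendations.

Rules live in a YAML catalog grouped into three tiers of risk:

- ``monogenic`` — single-gene, high-penetrance hereditary syndromes
  (genetic counseling / testing referrals);
- ``familial`` — aggregation above population risk without a known single
  gene (intensified screening, chemoprevention);
- ``common`` — multifactorial chronic-disease risk (population screening
  triggered by risk scores and exposures).

Each rule's predicate is written in a small declarative condition language
(no scripting, for auditability): conjunction/disjunction/negation over
leaf comparisons.  A leaf compares either a named variable —
``profile.<field>`` or ``score.<calculator>`` (percent) — or a pedigree
aggregate (count of affected relatives filtered by condition, degree,
side, sex and an onset upper bound) against a threshold with an explicit
strict or inclusive operator.

Evaluation is three-valued: a rule whose referenced inputs are missing is
reported *not evaluable*, which is distinct from *not met* — missingness
is surfaced, never silently skipped.  Fired rules carry the evidence
(variable, observed value, comparator, threshold) that satisfied them, and
re-applying the comparators to the stored values reproduces the firing.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from typing import Any, Optional

import yaml

from .catalog import ConditionCatalog, default_catalog
from .pedigree import Degree, Pedigree, Sex
from .profiles import CALCULATOR_IDS, RiskScore, ScoreStatus

TIERS = ("monogenic", "familial", "common")

_OPS = {
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}

_PROFILE_VARS = {
    "age", "sex", "race_ethnicity", "menarche_age", "nulliparous",
    "age_first_live_birth", "breast_biopsy_count", "atypical_hyperplasia",
    "hrt_use", "breast_cancer_history", "height_cm", "weight_kg", "bmi",
    "systolic_bp", "treated_hypertension", "total_cholesterol", "hdl",
    "smoker", "pack_years", "years_since_quit_smoking", "diabetes",
    "hba1c", "hscrp", "parental_mi_before_60",
}


class CatalogError(ValueError):
    """Rule catalog failed load-time validation."""


@dataclass(frozen=True)
class Evidence:
    variable: str
    observed: Any
    comparator: str
    threshold: Any

    def replay(self) -> bool:
        return bool(_OPS[self.comparator](self.observed, self.threshold))


@dataclass
class Recommendation:
    rule_id: str
    tier: str
    text: str
    citation: str
    evidence: list[Evidence]


@dataclass
class RuleResult:
    rule_id: str
    tier: str
    status: str  # fired | not_met | not_evaluable
    recommendation: Optional[Recommendation] = None


@dataclass
class Rule:
    id: str
    tier: str
    predicate: dict
    text: str
    citation: str


@dataclass
class RuleCatalog:
    version: str
    rules: list[Rule]

    def by_tier(self, tier: str) -> list[Rule]:
        return [r for r in self.rules if r.tier == tier]

    def ids(self) -> list[str]:
        return [r.id for r in self.rules]


def _agg_description(a: dict) -> str:
    parts = [f"count_affected({a['condition']}"]
    for key in ("degrees", "side", "sex", "max_onset"):
        if a.get(key) is not None:
            parts.append(f"{key}={a[key]}")
    return ", ".join(parts) + ")"


def _validate_predicate(pred: Any, rule_id: str, catalog: ConditionCatalog) -> None:
    if not isinstance(pred, dict):
        raise CatalogError(f"rule {rule_id}: predicate must be a mapping, got {pred!r}")
    if "all" in pred or "any" in pred:
        key = "all" if "all" in pred else "any"
        kids = pred[key]
        if not isinstance(kids, list) or not kids:
            raise CatalogError(f"rule {rule_id}: '{key}' needs a non-empty list")
        for k in kids:
            _validate_predicate(k, rule_id, catalog)
        return
    if "not" in pred:
        _validate_predicate(pred["not"], rule_id, catalog)
        return
    op = pred.get("op")
    if op not in _OPS:
        raise CatalogError(f"rule {rule_id}: unknown comparator {op!r}")
    if "var" in pred:
        var = pred["var"]
        scope, _, name = str(var).partition(".")
        if scope == "profile":
            if name not in _PROFILE_VARS:
                raise CatalogError(f"rule {rule_id}: undeclared variable {var!r}")
        elif scope == "score":
            if name not in CALCULATOR_IDS:
                raise CatalogError(f"rule {rule_id}: unknown calculator in {var!r}")
        else:
            raise CatalogError(f"rule {rule_id}: undeclared variable {var!r}")
    elif "agg" in pred:
        a = pred["agg"]
        if a.get("fn", "count_affected") != "count_affected":
            raise CatalogError(f"rule {rule_id}: unknown aggregate {a.get('fn')!r}")
        if not catalog.resolvable(a.get("condition", "")):
            raise CatalogError(f"rule {rule_id}: unknown condition {a.get('condition')!r}")
        for d in a.get("degrees") or []:
            if d not in Degree.__members__:
                raise CatalogError(f"rule {rule_id}: unknown degree {d!r}")
    else:
        raise CatalogError(f"rule {rule_id}: leaf needs 'var' or 'agg'")


def load_rule_catalog(path_or_stream=None, catalog: ConditionCatalog | None = None) -> RuleCatalog:
    """Load and validate a rule catalog; unknown variables are rejected here."""
    catalog = catalog or default_catalog()
    if path_or_stream is None:
        path_or_stream = importlib.resources.files("fhhrisk.config").joinpath("rules.yaml").open()
    if hasattr(path_or_stream, "read"):
        with path_or_stream:
            data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            data = yaml.safe_load(fh)
    rules: list[Rule] = []
    seen: set[str] = set()
    for tier in TIERS:
        for entry in data.get(tier, []) or []:
            rid = entry["id"]
            if rid in seen:
                raise CatalogError(f"duplicate rule id {rid!r}")
            seen.add(rid)
            rule = Rule(
                id=rid,
                tier=tier,
                predicate=entry["when"],
                text=entry["recommendation"],
                citation=entry.get("citation", ""),
            )
            _validate_predicate(rule.predicate, rid, catalog)
            rules.append(rule)
    return RuleCatalog(version=str(data.get("version", "unversioned")), rules=rules)


def count_affected(
    pedigree: Pedigree,
    condition: str,
    degrees: Optional[list[str]] = None,
    side: Optional[str] = None,
    sex: Optional[str] = None,
    max_onset: Optional[float] = None,
) -> int:
    """Number of individuals (proband included when SELF is allowed)
    affected by *condition* under the given filters.

    ``max_onset`` counts only entries whose onset is recorded and at or
    below the bound; onset-unknown entries are excluded from
    onset-dependent predicates.
    """
    allowed = {Degree[d] for d in degrees} if degrees else set(Degree)
    n = 0
    for person in pedigree.individuals:
        if person.degree not in allowed:
            continue
        if side is not None and person.side.value != side:
            continue
        if sex is not None and person.sex.value != sex:
            continue
        if not person.has_condition(condition):
            continue
        if max_onset is not None:
            onset = person.onset_of(condition)
            if onset is None or onset > max_onset:
                continue
        n += 1
    return n


class _Evaluator:
    def __init__(self, profile, pedigree: Pedigree, scores: dict[str, RiskScore]):
        self.profile = profile
        self.pedigree = pedigree
        self.scores = scores

    def lookup(self, var: str):
        scope, _, name = var.partition(".")
        if scope == "profile":
            val = getattr(self.profile, name)
            if isinstance(val, Sex):
                val = val.value
            return val
        score = self.scores.get(name)
        if score is None or score.status != ScoreStatus.COMPUTED:
            return None
        return score.value

    def eval(self, pred: dict) -> tuple[Optional[bool], list[Evidence]]:
        if "all" in pred:
            evidence: list[Evidence] = []
            saw_none = False
            for kid in pred["all"]:
                res, ev = self.eval(kid)
                if res is False:
                    return False, []
                if res is None:
                    saw_none = True
                else:
                    evidence.extend(ev)
            return (None, []) if saw_none else (True, evidence)
        if "any" in pred:
            saw_none = False
            for kid in pred["any"]:
                res, ev = self.eval(kid)
                if res is True:
                    return True, ev
                if res is None:
                    saw_none = True
            return (None, []) if saw_none else (False, [])
        if "not" in pred:
            res, _ = self.eval(pred["not"])
            if res is None:
                return None, []
            return (not res), []
        # leaf comparison
        if "var" in pred:
            name = pred["var"]
            observed = self.lookup(name)
        else:
            a = pred["agg"]
            name = _agg_description(a)
            observed = count_affected(
                self.pedigree,
                a["condition"],
                degrees=a.get("degrees"),
                side=a.get("side"),
                sex=a.get("sex"),
                max_onset=a.get("max_onset"),
            )
        if observed is None:
            return None, []
        ok = bool(_OPS[pred["op"]](observed, pred["value"]))
        ev = [Evidence(variable=name, observed=observed, comparator=pred["op"], threshold=pred["value"])]
        return ok, ev if ok else []


def evaluate_rules(
    catalog: RuleCatalog,
    profile,
    pedigree: Pedigree,
    scores: dict[str, RiskScore],
) -> list[RuleResult]:
    """Evaluate every rule; deterministic order follows the catalog."""
    ev = _Evaluator(profile, pedigree, scores)
    results: list[RuleResult] = []
    for rule in catalog.rules:
        fired, evidence = ev.eval(rule.predicate)
        if fired is None:
            results.append(RuleResult(rule.id, rule.tier, "not_evaluable"))
        elif fired:
            rec = Recommendation(rule.id, rule.tier, rule.text, rule.citation, evidence)
            results.append(RuleResult(rule.id, rule.tier, "fired", rec))
        else:
            results.append(RuleResult(rule.id, rule.tier, "not_met"))
    return results


def recommendations(results: list[RuleResult]) -> list[Recommendation]:
    return [r.recommendation for r in results if r.recommendation is not None]


def tier_summary(cohort_results: list[list[RuleResult]]) -> dict[str, Any]:
    """Per-tier participant counts over a cohort of evaluations.

    A participant is counted in a tier if at least one rule of that tier
    fired; participants can appear in several tiers, so tier counts need
    not sum to the any-tier count.
    """
    out: dict[str, Any] = {
        "n_participants": len(cohort_results),
        "participants_with_any": 0,
        "total_recommendations": 0,
    }
    per_tier = {t: 0 for t in TIERS}
    per_rule: dict[str, int] = {}
    for results in cohort_results:
        fired = [r for r in results if r.status == "fired"]
        out["total_recommendations"] += len(fired)
        if fired:
            out["participants_with_any"] += 1
        for t in TIERS:
            if any(r.tier == t for r in fired):
                per_tier[t] += 1
        for r in fired:
            per_rule[r.rule_id] = per_rule.get(r.rule_id, 0) + 1
    out["participants_by_tier"] = per_tier
    out["recommendations_by_rule"] = dict(sorted(per_rule.items()))
    return out


def render_report(
    profile,
    scores: dict[str, RiskScore],
    results: list[RuleResult],
    catalog_version: str = "unversioned",
) -> tuple[str, str]:
    """(JSON report, human-readable text); stable field order, deterministic."""
    recs = recommendations(results)
    doc = {
        "catalog_version": catalog_version,
        "scores": {
            calc: {
                "status": s.status.value,
                "horizon": s.horizon.value,
                "value_percent": s.value,
                "missing_inputs": s.missing_inputs,
            }
            for calc, s in sorted(scores.items())
        },
        "recommendations": [
            {
                "rule_id": r.rule_id,
                "tier": r.tier,
                "recommendation": r.text,
                "citation": r.citation,
                "evidence": [
                    {
                        "variable": e.variable,
                        "observed": e.observed,
                        "comparator": e.comparator,
                        "threshold": e.threshold,
                    }
                    for e in r.evidence
                ],
            }
            for r in recs
        ],
        "not_evaluable": [r.rule_id for r in results if r.status == "not_evaluable"],
    }
    lines = ["Risk assessment report", "======================", "", "Calculator scores:"]
    for calc, s in sorted(scores.items()):
        if s.status == ScoreStatus.COMPUTED:
            lines.append(f"  {calc}: {s.value:.2f}% ({s.horizon.value})")
        else:
            lines.append(f"  {calc}: not calculated (missing: {', '.join(s.missing_inputs) or 'n/a'})")
    lines.append("")
    if recs:
        lines.append("Recommendations:")
        for r in recs:
            lines.append(f"  [{r.tier}] {r.text} ({r.citation})")
            for e in r.evidence:
                lines.append(f"      because {e.variable} = {e.observed} {e.comparator} {e.threshold}")
    else:
        lines.append("No elevated-risk criteria were met.")
    nonev = [r.rule_id for r in results if r.status == "not_evaluable"]
    if nonev:
        lines.append("")
        lines.append("Not evaluable (missing inputs): " + ", ".join(nonev))
    return json.dumps(doc, indent=2, sort_keys=False), "\n".join(lines) + "\n"
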