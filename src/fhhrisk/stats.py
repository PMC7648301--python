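"""Cohort-level family-health-history descriptive statistics.

Two complementary clustering summaries per condition:

- *affected families*: the proportion of pedigrees (proband included) with
  at least one affected member — high for common diseases;
- *within families*: among affected families, the mean (and SD) of the
  family-wise proportion of affected members — high for strongly
  clustering (e.g. rare dominant) conditions even when few families are
  affected at all.

Family size includes the proband (configurable).  Also provided: relative
counts and data-completeness profiles by degree of relationship, and
Patient Activation Measure (PAM) level conversion from the 0-100 raw score
using the published four-level cut-points.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .pedigree import Degree, Pedigree


class UndefinedStatistic(ValueError):
    """Requested statistic has an empty denominator (e.g. no affected family)."""


def _affected_in(p: Pedigree, condition: str) -> int:
    return sum(1 for r in p.individuals if r.has_condition(condition))


def affected_families(cohort: list[Pedigree], condition: str) -> float:
    """Proportion of families with at least one member affected by *condition*."""
    if not cohort:
        raise UndefinedStatistic("empty cohort")
    hit = sum(1 for p in cohort if _affected_in(p, condition) > 0)
    return hit / len(cohort)


def within_family(
    cohort: list[Pedigree], condition: str, include_proband: bool = True
) -> tuple[float, float]:
    """Mean and SD of family-wise affected proportions among affected families.

    The denominator of each family-wise proportion is the family size
    (proband included by default).  Raises :class:`UndefinedStatistic`
    when no family is affected — never returns a number for an empty set.
    """
    props = []
    for p in cohort:
        n_aff = _affected_in(p, condition)
        if n_aff == 0:
            continue
        size = len(p.individuals) if include_proband else len(p.relatives)
        props.append(n_aff / size)
    if not props:
        raise UndefinedStatistic(f"no family affected by {condition!r}")
    arr = np.asarray(props)
    return float(arr.mean()), float(arr.std(ddof=0))


@dataclass
class RelativeProfile:
    """Cohort summary of relative counts and completeness by degree."""

    n_families: int
    mean_family_size: float
    sd_family_size: float
    size_range: tuple[int, int]
    mean_by_degree: dict[str, float]
    sd_by_degree: dict[str, float]
    pct_by_degree: dict[str, float]  # % of entered relatives
    conditions_per_relative: dict[str, float]
    history_known_fraction: dict[str, float]
    onset_recorded_fraction: float


def relative_profile(cohort: list[Pedigree]) -> RelativeProfile:
    degs = [Degree.FDR, Degree.SDR, Degree.TDR]
    per_family = {d: [] for d in degs}
    sizes = []
    cond_counts = {d: [] for d in degs}
    known = {d: [0, 0] for d in degs}
    onsets = [0, 0]
    for p in cohort:
        counts = p.degree_counts()
        sizes.append(len(p.individuals))
        for d in degs:
            per_family[d].append(counts[d])
        for r in p.relatives:
            d = r.degree
            known[d][1] += 1
            if r.history_known:
                known[d][0] += 1
                cond_counts[d].append(len(r.conditions))
        for r in p.individuals:
            for c in r.conditions:
                onsets[1] += 1
                if c.age_of_onset is not None:
                    onsets[0] += 1
    total_rel = sum(sum(per_family[d]) for d in degs)
    sizes_arr = np.asarray(sizes)
    return RelativeProfile(
        n_families=len(cohort),
        mean_family_size=float(sizes_arr.mean()) if len(cohort) else 0.0,
        sd_family_size=float(sizes_arr.std(ddof=0)) if len(cohort) else 0.0,
        size_range=(int(sizes_arr.min()), int(sizes_arr.max())) if len(cohort) else (0, 0),
        mean_by_degree={d.value: float(np.mean(per_family[d])) if per_family[d] else 0.0 for d in degs},
        sd_by_degree={d.value: float(np.std(per_family[d])) if per_family[d] else 0.0 for d in degs},
        pct_by_degree={
            d.value: (100.0 * sum(per_family[d]) / total_rel) if total_rel else 0.0 for d in degs
        },
        conditions_per_relative={
            d.value: float(np.mean(cond_counts[d])) if cond_counts[d] else 0.0 for d in degs
        },
        history_known_fraction={
            d.value: (known[d][0] / known[d][1]) if known[d][1] else float("nan") for d in degs
        },
        onset_recorded_fraction=(onsets[0] / onsets[1]) if onsets[1] else float("nan"),
    )


# ---------------------------------------------------------------------------
# Patient Activation Measure

@dataclass
class PamCutpoints:
    """Upper bounds of PAM levels 1-3 (level 4 is everything above)."""

    level1_max: float
    level2_max: float
    level3_max: float
    version: str = "unversioned"


def load_pam_cutpoints(stream=None) -> PamCutpoints:
    if stream is None:
        stream = importlib.resources.files("fhhrisk.config").joinpath("pam.yaml").open()
    with stream:
        d = yaml.safe_load(stream)
    return PamCutpoints(
        level1_max=float(d["level1_max"]),
        level2_max=float(d["level2_max"]),
        level3_max=float(d["level3_max"]),
        version=str(d.get("version", "unversioned")),
    )


def pam_level(raw_score: float, cutpoints: Optional[PamCutpoints] = None) -> int:
    """Ordinal activation level (1 least, 4 most) from the 0-100 raw score.

    Boundaries are inclusive on the lower level: a score exactly at a
    cut-point maps to the lower level.
    """
    if not (0 <= raw_score <= 100):
        raise ValueError(f"PAM raw score {raw_score} outside [0, 100]")
    cp = cutpoints or load_pam_cutpoints()
    if raw_score <= cp.level1_max:
        return 1
    if raw_score <= cp.level2_max:
        return 2
    if raw_score <= cp.level3_max:
        return 3
    return 4


@dataclass
class CohortSummary:
    """Full cohort summary: clustering per condition + structure + PAM."""

    per_condition: dict[str, dict[str, float]] = field(default_factory=dict)
    relatives: Optional[RelativeProfile] = None
    pam_levels: dict[int, int] = field(default_factory=dict)


def summarize_cohort(
    cohort: list[Pedigree],
    conditions: list[str],
    pam_scores: Optional[list[float]] = None,
    cutpoints: Optional[PamCutpoints] = None,
) -> CohortSummary:
    summary = CohortSummary(relatives=relative_profile(cohort))
    for cond in conditions:
        entry: dict[str, float] = {"affected_families": affected_families(cohort, cond)}
        try:
            mean, sd = within_family(cohort, cond)
            entry["within_family_mean"] = mean
            entry["within_family_sd"] = sd
        except UndefinedStatistic:
            pass
        summary.per_condition[cond] = entry
    if pam_scores is not None:
        cp = cutpoints or load_pam_cutpoints()
        levels = {1: 0, 2: 0, 3: 0, 4: 0}
        for s in pam_scores:
            levels[pam_level(s, cp)] += 1
        summary.pam_levels = levels
    return summary
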