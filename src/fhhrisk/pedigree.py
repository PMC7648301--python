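"""Structured family-health-history capture.

A pedigree is entered as relationship-coded records relative to a single
proband (``self``): every relative carries a controlled relation code
(mother, paternal uncle, maternal cousin, ...), sex, vital status with the
matching age field, twin status, whether their medical history is known,
and a list of conditions with ages of onset.  This module defines the
interchange types (pydantic models), parsing/serialisation of the JSON
interchange format, degree-of-relationship classification, the
required-relative completeness check (parents and all four grandparents),
and the five-element pedigree quality score.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .catalog import ConditionCatalog, default_catalog

SCHEMA_VERSION = "fhh-pedigree/1"

MAX_AGE = 120.0


class PedigreeError(ValueError):
    """Base class for pedigree capture errors."""


class VocabularyError(PedigreeError):
    """Unknown relation or condition code."""


class ParseError(PedigreeError):
    """Interchange document does not conform to the schema."""


class Degree(str, Enum):
    SELF = "SELF"
    FDR = "FDR"  # first-degree: parents, siblings, children
    SDR = "SDR"  # second-degree: grandparents, aunts/uncles, nieces/nephews, grandchildren, half-siblings
    TDR = "TDR"  # third-degree: cousins


class Side(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    NA = "na"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class TwinStatus(str, Enum):
    NONE = "none"
    IDENTICAL = "identical"
    FRATERNAL = "fraternal"


# relation_code -> (degree, side, sex implied by the code or None, singleton slot?)
_VOCAB: dict[str, tuple[Degree, Side, Optional[Sex], bool]] = {
    "self": (Degree.SELF, Side.NA, None, True),
    "mother": (Degree.FDR, Side.MATERNAL, Sex.FEMALE, True),
    "father": (Degree.FDR, Side.PATERNAL, Sex.MALE, True),
    "sister": (Degree.FDR, Side.NA, Sex.FEMALE, False),
    "brother": (Degree.FDR, Side.NA, Sex.MALE, False),
    "daughter": (Degree.FDR, Side.NA, Sex.FEMALE, False),
    "son": (Degree.FDR, Side.NA, Sex.MALE, False),
    "maternal grandmother": (Degree.SDR, Side.MATERNAL, Sex.FEMALE, True),
    "maternal grandfather": (Degree.SDR, Side.MATERNAL, Sex.MALE, True),
    "paternal grandmother": (Degree.SDR, Side.PATERNAL, Sex.FEMALE, True),
    "paternal grandfather": (Degree.SDR, Side.PATERNAL, Sex.MALE, True),
    "maternal aunt": (Degree.SDR, Side.MATERNAL, Sex.FEMALE, False),
    "maternal uncle": (Degree.SDR, Side.MATERNAL, Sex.MALE, False),
    "paternal aunt": (Degree.SDR, Side.PATERNAL, Sex.FEMALE, False),
    "paternal uncle": (Degree.SDR, Side.PATERNAL, Sex.MALE, False),
    "niece": (Degree.SDR, Side.NA, Sex.FEMALE, False),
    "nephew": (Degree.SDR, Side.NA, Sex.MALE, False),
    "granddaughter": (Degree.SDR, Side.NA, Sex.FEMALE, False),
    "grandson": (Degree.SDR, Side.NA, Sex.MALE, False),
    "maternal half-sister": (Degree.SDR, Side.MATERNAL, Sex.FEMALE, False),
    "maternal half-brother": (Degree.SDR, Side.MATERNAL, Sex.MALE, False),
    "paternal half-sister": (Degree.SDR, Side.PATERNAL, Sex.FEMALE, False),
    "paternal half-brother": (Degree.SDR, Side.PATERNAL, Sex.MALE, False),
    "maternal cousin": (Degree.TDR, Side.MATERNAL, None, False),
    "paternal cousin": (Degree.TDR, Side.PATERNAL, None, False),
}

RELATION_CODES: tuple[str, ...] = tuple(_VOCAB)

REQUIRED_SLOTS: tuple[str, ...] = (
    "mother",
    "father",
    "maternal grandmother",
    "maternal grandfather",
    "paternal grandmother",
    "paternal grandfather",
)

# generation index: proband generation = 1, parents = 2, grandparents = 3,
# children = 0, grandchildren = -1 (distinct values count toward the
# three-generation quality element)
_GENERATION: dict[str, int] = {
    "self": 1,
    "sister": 1,
    "brother": 1,
    "maternal half-sister": 1,
    "maternal half-brother": 1,
    "paternal half-sister": 1,
    "paternal half-brother": 1,
    "maternal cousin": 1,
    "paternal cousin": 1,
    "mother": 2,
    "father": 2,
    "maternal aunt": 2,
    "maternal uncle": 2,
    "paternal aunt": 2,
    "paternal uncle": 2,
    "maternal grandmother": 3,
    "maternal grandfather": 3,
    "paternal grandmother": 3,
    "paternal grandfather": 3,
    "daughter": 0,
    "son": 0,
    "niece": 0,
    "nephew": 0,
    "granddaughter": -1,
    "grandson": -1,
}


def _check_code(relation_code: str) -> None:
    if relation_code not in _VOCAB:
        raise VocabularyError(
            f"unknown relation code {relation_code!r}; expected one of {sorted(_VOCAB)}"
        )


def classify_degree(relation_code: str) -> Degree:
    """Degree of relationship to the proband.

    Parents, siblings and children are first-degree (FDR); aunts, uncles,
    grandparents, nieces, nephews, grandchildren and half-siblings are
    second-degree (SDR); cousins are third-degree (TDR).
    """
    _check_code(relation_code)
    return _VOCAB[relation_code][0]


def family_side(relation_code: str) -> Side:
    """Maternal/paternal side implied by the relation code itself."""
    _check_code(relation_code)
    return _VOCAB[relation_code][1]


def implied_sex(relation_code: str) -> Optional[Sex]:
    """Sex implied by the relation code (None for cousins and ``self``)."""
    _check_code(relation_code)
    return _VOCAB[relation_code][2]


def generation_index(relation_code: str) -> int:
    _check_code(relation_code)
    return _GENERATION[relation_code]


class ConditionEntry(BaseModel):
    """One reported condition with an optional age of onset (years)."""

    model_config = ConfigDict(extra="allow")

    condition_code: str
    age_of_onset: Optional[float] = Field(default=None, ge=0, le=MAX_AGE)


class RelativeRecord(BaseModel):
    """One relationship-coded individual in the family history."""

    model_config = ConfigDict(extra="allow")

    relation_code: str
    sex: Sex = Sex.UNKNOWN
    alive: Optional[bool] = None
    current_age: Optional[float] = Field(default=None, ge=0, le=MAX_AGE)
    age_at_death: Optional[float] = Field(default=None, ge=0, le=MAX_AGE)
    cause_of_death: Optional[str] = None
    twin_status: TwinStatus = TwinStatus.NONE
    history_known: bool = True
    conditions: list[ConditionEntry] = Field(default_factory=list)

    @model_validator(mode="after")
    def _invariants(self) -> "RelativeRecord":
        _check_code(self.relation_code)
        forced = implied_sex(self.relation_code)
        if forced is not None and self.sex == Sex.UNKNOWN:
            self.sex = forced
        if forced is not None and self.sex != forced:
            raise ValueError(
                f"{self.relation_code!r} implies sex {forced.value}, got {self.sex.value}"
            )
        if self.alive is True and self.age_at_death is not None:
            raise ValueError("living relative cannot have age_at_death")
        if self.alive is False and self.current_age is not None:
            raise ValueError("deceased relative cannot have current_age")
        cens = self.censoring_age
        if cens is not None:
            for c in self.conditions:
                if c.age_of_onset is not None and c.age_of_onset > cens:
                    raise ValueError(
                        f"onset {c.age_of_onset} of {c.condition_code} exceeds "
                        f"age {cens} for {self.relation_code}"
                    )
        return self

    @property
    def censoring_age(self) -> Optional[float]:
        """Current age if alive, age at death if deceased, else None."""
        if self.current_age is not None:
            return self.current_age
        return self.age_at_death

    @property
    def degree(self) -> Degree:
        return classify_degree(self.relation_code)

    @property
    def side(self) -> Side:
        return family_side(self.relation_code)

    def has_condition(self, condition_code: str) -> bool:
        return any(c.condition_code == condition_code for c in self.conditions)

    def onset_of(self, condition_code: str) -> Optional[float]:
        for c in self.conditions:
            if c.condition_code == condition_code:
                return c.age_of_onset
        return None


class ProbandRecord(RelativeRecord):
    """The ``self`` record with intake extras used by the calculators."""

    race_ethnicity: Optional[str] = None
    ashkenazi: bool = False
    consanguinity: bool = False

    @model_validator(mode="after")
    def _is_self(self) -> "ProbandRecord":
        if self.relation_code != "self":
            raise ValueError("proband record must have relation_code 'self'")
        return self


class Pedigree(BaseModel):
    """A proband plus relationship-coded relatives."""

    model_config = ConfigDict(extra="allow")

    schema_version: str = SCHEMA_VERSION
    proband: ProbandRecord
    relatives: list[RelativeRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _invariants(self) -> "Pedigree":
        seen: set[str] = set()
        for r in self.relatives:
            if r.relation_code == "self":
                raise ValueError("relatives list may not contain a 'self' record")
            if _VOCAB[r.relation_code][3]:  # singleton slot
                if r.relation_code in seen:
                    raise ValueError(f"duplicate singleton slot {r.relation_code!r}")
                seen.add(r.relation_code)
        return self

    @property
    def individuals(self) -> list[RelativeRecord]:
        return [self.proband, *self.relatives]

    def find(self, relation_code: str) -> list[RelativeRecord]:
        if relation_code == "self":
            return [self.proband]
        return [r for r in self.relatives if r.relation_code == relation_code]

    def degree_counts(self) -> dict[Degree, int]:
        counts = {d: 0 for d in Degree}
        for r in self.relatives:
            counts[r.degree] += 1
        return counts


class ValidationReport(BaseModel):
    """Outcome of the required-relative completeness check."""

    passed: bool
    missing_required_slots: list[str]
    field_errors: list[str]


class QualityReport(BaseModel):
    """The five elements of a high-quality family health history."""

    element_1_relationship_and_gender: bool
    element_2_side_of_family: bool
    element_3_vital_status_and_ages: bool
    element_4_conditions_with_onset: bool
    element_5_three_generations: bool
    generations_present: int

    @property
    def all_met(self) -> bool:
        return (
            self.element_1_relationship_and_gender
            and self.element_2_side_of_family
            and self.element_3_vital_status_and_ages
            and self.element_4_conditions_with_onset
            and self.element_5_three_generations
        )


def parse_pedigree(document: str, catalog: Optional[ConditionCatalog] = None) -> Pedigree:
    """Parse a JSON interchange document into a :class:`Pedigree`.

    Raises :class:`ParseError` naming the offending path on schema
    violations and :class:`VocabularyError` for unknown relation or
    condition codes.  Unknown extra fields are preserved (round trip is
    lossless).
    """
    catalog = catalog or default_catalog()
    try:
        data = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ParseError(f"not valid JSON: {exc}") from exc
    try:
        ped = Pedigree.model_validate(data)
    except Exception as exc:  # pydantic ValidationError carries the path
        msg = str(exc)
        if "unknown relation code" in msg:
            raise VocabularyError(msg) from exc
        raise ParseError(msg) from exc
    for person in ped.individuals:
        for cond in person.conditions:
            if not catalog.resolvable(cond.condition_code):
                raise VocabularyError(
                    f"condition code {cond.condition_code!r} not in catalog "
                    f"{catalog.version!r} ({person.relation_code})"
                )
    return ped


def serialize_pedigree(p: Pedigree) -> str:
    """Serialise to the JSON interchange format (stable key order)."""
    return json.dumps(p.model_dump(mode="json", exclude_none=True), indent=2, sort_keys=True)


def validate_required(p: Pedigree) -> ValidationReport:
    """Check the required-relative contract: mother, father and all four
    grandparents must be present, and per-record field invariants hold."""
    present = {r.relation_code for r in p.relatives}
    missing = [slot for slot in REQUIRED_SLOTS if slot not in present]
    errors: list[str] = []
    for r in p.individuals:
        if r.alive is None and r.censoring_age is None and r.history_known:
            errors.append(f"{r.relation_code}: vital status and ages unknown")
    return ValidationReport(
        passed=not missing and not errors,
        missing_required_slots=missing,
        field_errors=errors,
    )


def score_quality(p: Pedigree) -> QualityReport:
    """Evaluate the five elements of a high-quality family health history.

    1. every relative has a relationship code and a known sex;
    2. side of family is determined for all blood relatives where it applies
       (built into the relation vocabulary, so it holds whenever element 1 does);
    3. vital status with current age (if alive) or age and cause of death;
    4. all conditions carry an age of onset;
    5. at least three generations present (minimum: parents + grandparents).
    """
    rels = p.individuals
    e1 = all(r.sex != Sex.UNKNOWN for r in rels)
    # side is a pure function of the relation code; met when codes are well
    # formed, which parsing guarantees
    e2 = True
    e3 = all(
        (r.alive is True and r.current_age is not None)
        or (r.alive is False and r.age_at_death is not None and r.cause_of_death is not None)
        for r in rels
    )
    entries = [c for r in rels for c in r.conditions]
    e4 = all(c.age_of_onset is not None for c in entries) and len(entries) > 0
    gens = {generation_index(r.relation_code) for r in rels}
    e5 = len(gens) >= 3
    return QualityReport(
        element_1_relationship_and_gender=e1,
        element_2_side_of_family=e2,
        element_3_vital_status_and_ages=e3,
        element_4_conditions_with_onset=e4,
        element_5_three_generations=e5,
        generations_present=len(gens),
    )
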