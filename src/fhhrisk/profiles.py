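"""Personal risk-factor profile and the uniform calculator output type.

Every calculator consumes a :class:`RiskFactorProfile` (plus, for the
breast models, the pedigree) and returns a :class:`RiskScore`.  Missing
required inputs never produce an imputed number: the score comes back with
``status="not_calculated"`` and the missing input names listed, mirroring
how a deployed assessment platform reports per-calculator missingness.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .pedigree import Sex


class Horizon(str, Enum):
    FIVE_YEAR = "5y"
    TEN_YEAR = "10y"
    LIFETIME = "lifetime"


class ScoreStatus(str, Enum):
    COMPUTED = "computed"
    NOT_CALCULATED = "not_calculated"


CALCULATOR_IDS = ("gail", "tyrer_cuzick", "brcapro", "framingham", "reynolds", "pce")


class RiskFactorProfile(BaseModel):
    """Proband personal variables feeding the six calculators.

    Any field may be None (unknown); calculators report which required
    fields were missing rather than imputing.  Units: ages in years, height
    cm, weight kg, blood pressure mmHg, lipids mg/dL, hsCRP mg/L.
    """

    model_config = ConfigDict(extra="forbid")

    age: float = Field(ge=18, le=120)
    sex: Sex
    race_ethnicity: Optional[str] = None  # white | black | hispanic | asian | other
    # reproductive / breast
    menarche_age: Optional[float] = Field(default=None, ge=5, le=25)
    nulliparous: Optional[bool] = None
    age_first_live_birth: Optional[float] = Field(default=None, ge=10, le=60)
    breast_biopsy_count: Optional[int] = Field(default=None, ge=0)
    atypical_hyperplasia: Optional[bool] = None
    hrt_use: Optional[bool] = None
    breast_cancer_history: bool = False
    # anthropometrics
    height_cm: Optional[float] = Field(default=None, ge=100, le=250)
    weight_kg: Optional[float] = Field(default=None, ge=25, le=350)
    # cardiovascular
    systolic_bp: Optional[float] = Field(default=None, ge=60, le=250)
    treated_hypertension: Optional[bool] = None
    total_cholesterol: Optional[float] = Field(default=None, ge=50, le=500)
    hdl: Optional[float] = Field(default=None, ge=10, le=150)
    smoker: Optional[bool] = None
    pack_years: Optional[float] = Field(default=None, ge=0)
    years_since_quit_smoking: Optional[float] = Field(default=None, ge=0)
    diabetes: Optional[bool] = None
    hba1c: Optional[float] = Field(default=None, ge=3, le=20)
    hscrp: Optional[float] = Field(default=None, ge=0)
    parental_mi_before_60: Optional[bool] = None

    @property
    def bmi(self) -> Optional[float]:
        if self.height_cm is None or self.weight_kg is None:
            return None
        h = self.height_cm / 100.0
        return self.weight_kg / (h * h)


class RiskScore(BaseModel):
    """One calculator's absolute-risk output."""

    calculator: str
    horizon: Horizon
    status: ScoreStatus
    value: Optional[float] = None  # percent, 0-100, rounded to 2 dp
    missing_inputs: list[str] = Field(default_factory=list)

    def model_post_init(self, __context) -> None:
        if self.calculator not in CALCULATOR_IDS:
            raise ValueError(f"unknown calculator id {self.calculator!r}")
        if (self.value is not None) != (self.status == ScoreStatus.COMPUTED):
            raise ValueError("value present iff status is computed")
        if self.value is not None and not (0 <= self.value <= 100):
            raise ValueError("risk percent outside [0, 100]")


def computed(calculator: str, horizon: Horizon, fraction: float) -> RiskScore:
    """Wrap a probability (0-1) as a computed percent score (2 dp)."""
    pct = round(float(min(max(fraction, 0.0), 1.0)) * 100.0, 2)
    return RiskScore(calculator=calculator, horizon=horizon, status=ScoreStatus.COMPUTED, value=pct)


def not_calculated(calculator: str, horizon: Horizon, missing: list[str]) -> RiskScore:
    return RiskScore(
        calculator=calculator,
        horizon=horizon,
        status=ScoreStatus.NOT_CALCULATED,
        missing_inputs=sorted(missing),
    )
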