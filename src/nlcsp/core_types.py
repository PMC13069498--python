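"""Shared domain model for the NLCSP nodule-management engine.

The Australian National Lung Cancer Screening Program (NLCSP) assigns every
screen-detected pulmonary nodule one of seven management categories.
Categories 1-6 encode increasing risk of lung cancer; category 0 is
orthogonal and marks an incomplete examination or suspected
infection/inflammation requiring a short-interval repeat scan.  Each
category carries a fixed management recommendation: a repeat low-dose CT at
a set interval for categories 0-4, and clinical referral for categories 5
and 6.

This module defines the enumerations, the validated record types shared by
the baseline and follow-up classifiers, the category -> management mapping,
and the mean-diameter measurement convention (calliper long/short axis,
reported at 0.1 mm resolution, rounded half-up).
"""

from __future__ import annotations

import datetime
import enum
from decimal import ROUND_HALF_UP, Decimal

from pydantic import BaseModel, ConfigDict, Field, model_validator


class NLCSPError(Exception):
    """Base class for engine errors."""


class ValidationError(NLCSPError, ValueError):
    """Input violates a documented contract."""


class ConfigurationError(NLCSPError):
    """A configuration file is missing, incomplete, or inconsistent."""


class ContractError(NLCSPError):
    """An operation was invoked outside its stated precondition."""


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class Composition(str, enum.Enum):
    solid = "solid"
    part_solid = "part_solid"
    ground_glass = "ground_glass"


class Lobe(str, enum.Enum):
    RUL = "RUL"
    RML = "RML"
    RLL = "RLL"
    LUL = "LUL"
    lingula = "lingula"
    LLL = "LLL"


#: Lobes counted as "middle or lower" for the intrapulmonary-lymph-node
#: pleural-proximity clause.
MIDDLE_OR_LOWER_LOBES = frozenset({Lobe.RML, Lobe.RLL, Lobe.LLL, Lobe.lingula})


class Calcification(str, enum.Enum):
    none = "none"
    complete = "complete"
    central = "central"
    popcorn = "popcorn"
    concentric_ring = "concentric_ring"
    other = "other"


#: Calcification patterns regarded as clearly benign (granuloma/hamartoma
#: patterns).  "other" (e.g. eccentric) is deliberately excluded.
BENIGN_CALCIFICATIONS = frozenset(
    {
        Calcification.complete,
        Calcification.central,
        Calcification.popcorn,
        Calcification.concentric_ring,
    }
)


class Margin(str, enum.Enum):
    smooth = "smooth"
    lobulated = "lobulated"
    spiculated = "spiculated"
    irregular = "irregular"


class Shape(str, enum.Enum):
    oval = "oval"
    lentiform = "lentiform"
    triangular = "triangular"
    round = "round"
    irregular = "irregular"


class AirwayLevel(str, enum.Enum):
    none = "none"
    subsegmental = "subsegmental"
    segmental_or_proximal = "segmental_or_proximal"


class CystFeatures(str, enum.Enum):
    none = "none"
    thick_walled = "thick_walled"
    multilocular = "multilocular"


class NLCSPCategory(enum.IntEnum):
    """The seven NLCSP categories.  1 < 2 < ... < 6 orders risk; 0 is the
    orthogonal "incomplete" category."""

    incomplete = 0
    very_low_risk = 1
    low_risk = 2
    low_to_moderate_risk = 3
    moderate_risk = 4
    high_risk = 5
    very_high_risk = 6


class ManagementAction(str, enum.Enum):
    repeat_LDCT = "repeat_LDCT"
    clinical_referral = "clinical_referral"


CATEGORY_DESCRIPTORS: dict[NLCSPCategory, str] = {
    NLCSPCategory.incomplete: "Incomplete",
    NLCSPCategory.very_low_risk: "Very low risk",
    NLCSPCategory.low_risk: "Low risk",
    NLCSPCategory.low_to_moderate_risk: "Low to moderate risk",
    NLCSPCategory.moderate_risk: "Moderate risk",
    NLCSPCategory.high_risk: "High risk",
    NLCSPCategory.very_high_risk: "Very high risk",
}

#: Repeat-LDCT intervals in months for categories 1-4.  Categories 5 and 6
#: map to clinical referral with no interval; category 0 takes a
#: caller-chosen 1-, 2- or 3-month interval.
CATEGORY_INTERVALS_MONTHS: dict[NLCSPCategory, int] = {
    NLCSPCategory.very_low_risk: 24,
    NLCSPCategory.low_risk: 12,
    NLCSPCategory.low_to_moderate_risk: 6,
    NLCSPCategory.moderate_risk: 3,
}

REFERRAL_CATEGORIES = frozenset(
    {NLCSPCategory.high_risk, NLCSPCategory.very_high_risk}
)


class ParticipantCovariates(BaseModel):
    """Participant-level risk-model inputs.

    All four fields are required; the engine does not police age against a
    screening-eligibility window — it classifies whatever it is given.
    """

    model_config = ConfigDict(frozen=True)

    age: int = Field(ge=0)
    sex: Sex
    family_history_lung_cancer: bool
    emphysema: bool


class ManagementRecommendation(BaseModel):
    """What the participant should do next: repeat scan at an interval, or
    clinical referral (no interval)."""

    model_config = ConfigDict(frozen=True)

    action: ManagementAction
    interval_months: int | None = None
    descriptor: str

    @model_validator(mode="after")
    def _check_interval(self) -> "ManagementRecommendation":
        if self.action is ManagementAction.clinical_referral:
            if self.interval_months is not None:
                raise ValueError("clinical referral carries no interval")
        elif self.interval_months is None:
            raise ValueError("repeat LDCT requires an interval")
        return self


def round_to_tenth_mm(value: float) -> float:
    """Round a length to 0.1 mm, half-up.

    Measurements are carried at 0.1 mm resolution — the finest precision
    clinically reported — so that the 1.5 mm growth threshold has a
    well-defined comparison grid.  ``Decimal(repr(...))`` avoids binary
    artefacts such as 1.5000000000000002 crossing a strict threshold.
    """
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def mean_diameter(long_axis_mm: float, short_axis_mm: float) -> float:
    """Mean nodule diameter from calliper long/short axes, at 0.1 mm.

    Raises :class:`ValidationError` for non-positive or reversed axes.
    """
    if short_axis_mm <= 0:
        raise ValidationError("short axis must be positive")
    if long_axis_mm < short_axis_mm:
        raise ValidationError("long axis must be >= short axis")
    return round_to_tenth_mm((long_axis_mm + short_axis_mm) / 2.0)


class NoduleObservation(BaseModel):
    """One nodule's features as seen on one scan — the atomic input record.

    ``nodule_id`` is a stable identifier linking observations of the same
    nodule across scans; matching is never computed by the engine.
    ``volume_mm3`` absent means volumetry was not possible and diameter
    rules apply for growth assessment.
    """

    model_config = ConfigDict(frozen=True)

    nodule_id: str
    scan_date: datetime.date
    composition: Composition
    long_axis_mm: float = Field(gt=0)
    short_axis_mm: float = Field(gt=0)
    solid_component_mean_diameter_mm: float | None = Field(default=None, gt=0)
    volume_mm3: float | None = Field(default=None, gt=0)
    lobe: Lobe
    upper_lobe: bool | None = None
    spiculation: bool = False
    nodule_count_total: int = Field(default=1, ge=1)
    calcification: Calcification = Calcification.none
    macroscopic_fat: bool = False
    margin: Margin = Margin.smooth
    shape: Shape = Shape.round
    contacts_pleura: bool = False
    distance_to_pleura_mm: float | None = Field(default=None, ge=0)
    airway_level: AirwayLevel = AirwayLevel.none
    cyst_features: CystFeatures = CystFeatures.none
    radiologist_suspicious_flag: bool = False
    suspected_infection: bool = False

    @model_validator(mode="after")
    def _invariants(self) -> "NoduleObservation":
        if self.long_axis_mm < self.short_axis_mm:
            raise ValueError("long_axis_mm must be >= short_axis_mm")
        if (
            self.solid_component_mean_diameter_mm is not None
            and self.solid_component_mean_diameter_mm > self.mean_diameter_mm
        ):
            raise ValueError("solid component cannot exceed mean diameter")
        if (
            self.airway_level is not AirwayLevel.none
            and self.cyst_features is not CystFeatures.none
        ):
            raise ValueError(
                "airway_level and cyst_features are mutually exclusive subtype flags"
            )
        if self.upper_lobe is None:
            # lingula is treated as non-upper-lobe unless overridden
            object.__setattr__(
                self, "upper_lobe", self.lobe in (Lobe.RUL, Lobe.LUL)
            )
        return self

    @property
    def mean_diameter_mm(self) -> float:
        """Mean calliper diameter, rounded to 0.1 mm."""
        return mean_diameter(self.long_axis_mm, self.short_axis_mm)


def management_for_category(
    category: NLCSPCategory | int,
    category0_interval_months: int | None = None,
) -> ManagementRecommendation:
    """Map an NLCSP category to its management recommendation.

    Category 0 requires a caller-chosen short interval of 1, 2, or 3
    months (the protocol offers all three without a selection rule).
    """
    category = NLCSPCategory(category)
    descriptor = CATEGORY_DESCRIPTORS[category]
    if category in REFERRAL_CATEGORIES:
        return ManagementRecommendation(
            action=ManagementAction.clinical_referral, descriptor=descriptor
        )
    if category is NLCSPCategory.incomplete:
        if category0_interval_months not in (1, 2, 3):
            raise ValidationError(
                "category 0 requires an interval of 1, 2, or 3 months"
            )
        return ManagementRecommendation(
            action=ManagementAction.repeat_LDCT,
            interval_months=category0_interval_months,
            descriptor=descriptor,
        )
    return ManagementRecommendation(
        action=ManagementAction.repeat_LDCT,
        interval_months=CATEGORY_INTERVALS_MONTHS[category],
        descriptor=descriptor,
    )
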