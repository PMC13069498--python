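"""Baseline (first-ever LDCT) nodule categorization.

A baseline nodule is routed down exactly one of five branches, in a fixed,
safety-ordered precedence:

(a) radiologist judges features suspicious for lung cancer -> category 6;
(b) clearly benign features (benign calcification pattern or macroscopic
    fat) or a probable intrapulmonary lymph node -> category 1;
(c) airway nodule: subsegmental -> 2, segmental or more proximal -> 4;
(d) atypical pulmonary cyst (thick-walled or multilocular) -> 4;
(e) otherwise, PanCan 2-year probability bands:
        < 1.5%          -> 1 (24-month LDCT)
        1.5% to < 6%    -> 2 (12-month LDCT)
        6% to < 10%     -> 3 (6-month LDCT)
        10% to < 30%    -> 4 (3-month LDCT)
        >= 30%          -> 5 (clinical referral)

Band edges are half-open exactly as written: a risk of exactly 1.5% is
category 2, exactly 6% is 3, exactly 10% is 4, exactly 30% is 5.  The
ordering of (a)-(e) is a protocol-engine design choice (the branches are
given, their precedence is not): radiologist suspicion outranks everything,
and benign/lymph-node recognition precedes the airway and cyst paths so a
calcified granuloma never enters them.  Every decision records the branch
it took in ``rule_trace``.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .core_types import (
    AirwayLevel,
    BENIGN_CALCIFICATIONS,
    Composition,
    CystFeatures,
    Margin,
    MIDDLE_OR_LOWER_LOBES,
    ManagementRecommendation,
    NLCSPCategory,
    NoduleObservation,
    ParticipantCovariates,
    Shape,
    ValidationError,
    management_for_category,
)
from .pancan import PanCanCoefficients, PanCanRisk, compute_pancan_risk

#: Volume below which a juxtapleural nodule can qualify as a probable
#: intrapulmonary lymph node (the volumetric twin of the < 10 mm diameter
#: clause; 524 mm^3 is the volume of a 10 mm sphere).
LYMPH_NODE_VOLUME_MM3 = 524.0
LYMPH_NODE_DIAMETER_MM = 10.0
LYMPH_NODE_PLEURA_DISTANCE_MM = 15.0

LYMPH_NODE_SHAPES = frozenset({Shape.oval, Shape.lentiform, Shape.triangular})

#: Half-open PanCan risk bands: (lower, upper, category).  Upper bound of
#: the top band is +inf.
PANCAN_BANDS: tuple[tuple[float, float, NLCSPCategory], ...] = (
    (0.0, 0.015, NLCSPCategory.very_low_risk),
    (0.015, 0.06, NLCSPCategory.low_risk),
    (0.06, 0.10, NLCSPCategory.low_to_moderate_risk),
    (0.10, 0.30, NLCSPCategory.moderate_risk),
    (0.30, float("inf"), NLCSPCategory.high_risk),
)


class CategorizedNodule(BaseModel):
    """A nodule with its assigned category, management, and audit trace."""

    model_config = ConfigDict(frozen=True)

    nodule_id: str
    category: NLCSPCategory
    management: ManagementRecommendation
    rule_trace: list[str] = Field(min_length=1)
    pancan_risk: PanCanRisk | None = None


def detect_benign_features(obs: NoduleObservation) -> bool:
    """Clearly benign nodule: benign calcification pattern or macroscopic fat.

    Complete, central, popcorn, or concentric-ring calcification suggests
    granuloma; popcorn calcification or clear macroscopic fat suggests
    hamartoma.  "other" calcification (e.g. eccentric) does not qualify.
    """
    return obs.calcification in BENIGN_CALCIFICATIONS or obs.macroscopic_fat


def is_probable_intrapulmonary_lymph_node(obs: NoduleObservation) -> bool:
    """Juxtapleural nodule very likely to be a benign intrapulmonary lymph node.

    Requires ALL of: small size (mean diameter < 10 mm OR volume < 524 mm3);
    solid composition; smooth margins; oval, lentiform, or triangular shape;
    and pleural association (contacting the pleura anywhere, or in a middle
    or lower lobe within 15 mm of the pleura).  An absent
    ``distance_to_pleura_mm`` simply fails the proximity clause.
    """
    small = obs.mean_diameter_mm < LYMPH_NODE_DIAMETER_MM or (
        obs.volume_mm3 is not None and obs.volume_mm3 < LYMPH_NODE_VOLUME_MM3
    )
    if not small:
        return False
    if obs.composition is not Composition.solid:
        return False
    if obs.margin is not Margin.smooth:
        return False
    if obs.shape not in LYMPH_NODE_SHAPES:
        return False
    if obs.contacts_pleura:
        return True
    return (
        obs.lobe in MIDDLE_OR_LOWER_LOBES
        and obs.distance_to_pleura_mm is not None
        and obs.distance_to_pleura_mm <= LYMPH_NODE_PLEURA_DISTANCE_MM
    )


def pancan_band_category(probability: float) -> NLCSPCategory:
    """Map a PanCan probability to its baseline category band."""
    for lower, upper, category in PANCAN_BANDS:
        if lower <= probability < upper:
            return category
    raise ValidationError(f"probability {probability!r} outside [0, 1]")


def classify_baseline_nodule(
    cov: ParticipantCovariates,
    obs: NoduleObservation,
    risk: PanCanRisk | None = None,
    coeffs: PanCanCoefficients | None = None,
) -> CategorizedNodule:
    """Assign the NLCSP category and management for one baseline nodule.

    ``risk`` may be supplied precomputed; when absent and the PanCan path
    is reached, it is computed from ``coeffs`` (``coeffs=None`` loads the
    packaged published set).  Special-subtype branches never consult the
    risk model.
    """
    trace: list[str] = []

    if obs.radiologist_suspicious_flag:
        trace.append("baseline.suspicious_features")
        category = NLCSPCategory.very_high_risk
    elif detect_benign_features(obs):
        trace.append("baseline.benign_features")
        category = NLCSPCategory.very_low_risk
    elif is_probable_intrapulmonary_lymph_node(obs):
        trace.append("baseline.intrapulmonary_lymph_node")
        category = NLCSPCategory.very_low_risk
    elif obs.airway_level is AirwayLevel.subsegmental:
        trace.append("baseline.airway_subsegmental")
        category = NLCSPCategory.low_risk
    elif obs.airway_level is AirwayLevel.segmental_or_proximal:
        trace.append("baseline.airway_segmental_or_proximal")
        category = NLCSPCategory.moderate_risk
    elif obs.cyst_features in (CystFeatures.thick_walled, CystFeatures.multilocular):
        trace.append(f"baseline.atypical_cyst:{obs.cyst_features.value}")
        category = NLCSPCategory.moderate_risk
    else:
        if risk is None:
            risk = compute_pancan_risk(cov, obs, coeffs)
        category = pancan_band_category(risk.probability)
        trace.append(f"baseline.pancan_band:{category.value}")

    return CategorizedNodule(
        nodule_id=obs.nodule_id,
        category=category,
        management=management_for_category(category),
        rule_trace=trace,
        pancan_risk=risk,
    )
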