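"""Follow-up LDCT categorization: escalation on growth, stepped
de-escalation on stability.

At follow-up the risk model is off the table (it is baseline-only), and
management is driven by behaviour over time:

* growth — fast or slow — prompts clinical referral (category 5);
* persistent segmental-or-more-proximal airway nodules are referred even
  when stable;
* stable or decreased nodules step down one category per stable scan
  (4 -> 3 -> 2), and a category-2 nodule returns to category 1 (biennial
  screening) only after at least 24 months of documented stability;
* nodules first seen at follow-up get an interim size-band category,
  since the baseline risk model cannot legitimately be applied to them;
* a scan with suspected infection/inflammation yields category 0 with a
  short-interval repeat, freezing (not resetting) the stability clock.

Every decision carries the full growth numerics and a rule trace so that
any category can be audited back to the measurement that produced it.
"""

from __future__ import annotations

import datetime

from pydantic import BaseModel, ConfigDict, Field

from .baseline import detect_benign_features, is_probable_intrapulmonary_lymph_node
from .core_types import (
    AirwayLevel,
    Composition,
    ContractError,
    CystFeatures,
    ManagementRecommendation,
    NLCSPCategory,
    NoduleObservation,
    ParticipantCovariates,
    ValidationError,
    management_for_category,
)
from .growth import (
    GrowthStatus,
    GrowthStatusLabel,
    NoduleHistory,
    assess_growth,
)

#: Documented stability (days) required for a category-2 nodule to return
#: to category 1 and biennial screening.
STABILITY_FOR_CATEGORY1_DAYS = 730

STEPPABLE_CATEGORIES = frozenset(
    {NLCSPCategory.low_risk, NLCSPCategory.low_to_moderate_risk, NLCSPCategory.moderate_risk}
)


class FollowupDecision(BaseModel):
    """Category, management, growth numerics, and updated stability clock
    for one tracked nodule at a follow-up scan.  A resolved nodule carries
    no category or management — it no longer contributes to the
    participant's result, but the resolution is recorded."""

    model_config = ConfigDict(frozen=True)

    nodule_id: str
    growth: GrowthStatus
    category: NLCSPCategory | None
    management: ManagementRecommendation | None
    stability_clock_days: int = Field(ge=0)
    rule_trace: list[str] = Field(min_length=1)


def step_down_category(
    prev: NLCSPCategory, stability_clock_days: int
) -> NLCSPCategory:
    """De-escalate a stable (or decreased) nodule one step.

    4 -> 3; 3 -> 2; 2 -> 1 once stability has been documented for at
    least 24 months, else 2 stays 2.  Categories 0, 1, 5, 6 do not step
    and are a contract violation here.
    """
    prev = NLCSPCategory(prev)
    if prev not in STEPPABLE_CATEGORIES:
        raise ContractError(f"category {prev.value} does not step down")
    if prev is NLCSPCategory.moderate_risk:
        return NLCSPCategory.low_to_moderate_risk
    if prev is NLCSPCategory.low_to_moderate_risk:
        return NLCSPCategory.low_risk
    if stability_clock_days >= STABILITY_FOR_CATEGORY1_DAYS:
        return NLCSPCategory.very_low_risk
    return NLCSPCategory.low_risk


def _interim_size_band(obs: NoduleObservation, trace: list[str]) -> NLCSPCategory:
    """Interim size-band category for a nodule first seen at follow-up.

    The baseline risk model cannot be used once a prior CT exists, so new
    nodules take the solid / part-solid size bands (total mean diameter
    and solid-component diameter).  This is an extrapolation beyond the
    letter of the protocol tables and is flagged as such in the trace;
    nodules at or above the top band are surfaced as category 5 for
    radiologist review rather than silently binned.
    """
    trace.append("followup.new_nodule.size_band_extrapolation")
    d = obs.mean_diameter_mm
    if obs.composition is Composition.solid:
        if d < 6.0:
            return NLCSPCategory.low_risk
        if d < 8.0:
            return NLCSPCategory.low_to_moderate_risk
        if d < 15.0:
            return NLCSPCategory.moderate_risk
        trace.append("followup.new_nodule.large_solid_flagged_for_review")
        return NLCSPCategory.high_risk
    if obs.composition is Composition.part_solid:
        if d < 6.0:
            return NLCSPCategory.low_risk
        sc = obs.solid_component_mean_diameter_mm
        if sc is None or sc < 6.0:
            return NLCSPCategory.low_to_moderate_risk
        if sc < 8.0:
            return NLCSPCategory.moderate_risk
        trace.append("followup.new_nodule.large_solid_component_flagged_for_review")
        return NLCSPCategory.high_risk
    # pure ground glass: the reprinted size bands do not cover it; treated
    # as low risk with annual follow-up, trace-flagged
    trace.append("followup.new_nodule.ground_glass_low_risk")
    return NLCSPCategory.low_risk


def _classify_new_nodule(obs: NoduleObservation, trace: list[str]) -> NLCSPCategory:
    """Special-subtype branches still outrank size bands for new nodules."""
    if detect_benign_features(obs):
        trace.append("followup.new_nodule.benign_features")
        return NLCSPCategory.very_low_risk
    if is_probable_intrapulmonary_lymph_node(obs):
        trace.append("followup.new_nodule.intrapulmonary_lymph_node")
        return NLCSPCategory.very_low_risk
    if obs.airway_level is AirwayLevel.subsegmental:
        trace.append("followup.new_nodule.airway_subsegmental")
        return NLCSPCategory.low_risk
    if obs.airway_level is AirwayLevel.segmental_or_proximal:
        trace.append("followup.new_nodule.airway_segmental_or_proximal")
        return NLCSPCategory.moderate_risk
    if obs.cyst_features is not CystFeatures.none:
        trace.append("followup.new_nodule.atypical_cyst")
        return NLCSPCategory.moderate_risk
    return _interim_size_band(obs, trace)


def classify_followup_nodule(
    hist: NoduleHistory,
    cov: ParticipantCovariates | None = None,
    current_scan_date: datetime.date | None = None,
    category0_interval_months: int = 3,
) -> FollowupDecision:
    """Assign the NLCSP category and management for one nodule at follow-up.

    ``current_scan_date`` later than the last observation signals that the
    nodule was looked for and not found on the current scan (resolution).
    A history whose ``prior_category`` is absent and which holds a single
    observation is a nodule first seen on this (non-baseline) scan.

    Decision order: radiologist suspicion -> 6; suspected infection -> 0
    (clock frozen); resolved -> recorded, no management; persistent
    segmental/proximal airway -> 5; growing or slowly growing -> 5; new
    nodule -> interim size band; stable or decreased -> stepped
    de-escalation with the clock advanced by the elapsed interval.
    """
    trace: list[str] = []
    cur = hist.current

    if current_scan_date is not None and current_scan_date > cur.scan_date:
        trace.append("followup.resolved")
        growth = GrowthStatus(
            status=GrowthStatusLabel.resolved,
            interval_days=(current_scan_date - cur.scan_date).days,
        )
        return FollowupDecision(
            nodule_id=hist.nodule_id,
            growth=growth,
            category=None,
            management=None,
            stability_clock_days=hist.stability_clock_days,
            rule_trace=trace,
        )

    is_new = hist.prior_category is None and len(hist.observations) == 1
    if hist.prior_category is None and len(hist.observations) > 1:
        raise ValidationError(
            f"nodule {hist.nodule_id!r}: tracked nodule is missing its prior category"
        )

    if is_new:
        growth = GrowthStatus(status=GrowthStatusLabel.new, interval_days=0)
        interval_days = 0
    else:
        growth = assess_growth(hist)
        interval_days = (cur.scan_date - hist.observations[-2].scan_date).days

    if cur.radiologist_suspicious_flag:
        trace.append("followup.suspicious_features")
        category = NLCSPCategory.very_high_risk
        clock = 0
    elif cur.suspected_infection:
        trace.append("followup.suspected_infection")
        category = NLCSPCategory.incomplete
        clock = hist.stability_clock_days  # frozen, not reset
    elif (
        not is_new
        and cur.airway_level is AirwayLevel.segmental_or_proximal
    ):
        # high risk even when stable; stepped management never applies
        trace.append("followup.persistent_airway_segmental_or_proximal")
        category = NLCSPCategory.high_risk
        clock = 0
    elif growth.status in (GrowthStatusLabel.growing, GrowthStatusLabel.slowly_growing):
        trace.append(f"followup.{growth.status.value}")
        category = NLCSPCategory.high_risk
        clock = 0
    elif is_new:
        category = _classify_new_nodule(cur, trace)
        clock = 0
    else:
        clock = hist.stability_clock_days + interval_days
        prev = hist.prior_category
        if prev is NLCSPCategory.very_low_risk:
            trace.append("followup.stable_category1")
            category = NLCSPCategory.very_low_risk
        elif prev in STEPPABLE_CATEGORIES:
            category = step_down_category(prev, clock)
            trace.append(f"followup.stepped:{prev.value}->{category.value}")
        elif prev is NLCSPCategory.incomplete:
            # infection resolved but the nodule persists: no stepped row
            # exists, so re-enter via the interim size bands
            trace.append("followup.post_incomplete_reentry")
            category = _classify_new_nodule(cur, trace)
            clock = 0
        else:
            raise ValidationError(
                f"nodule {hist.nodule_id!r}: prior category {prev.value} should "
                "already have been referred out of screening"
            )

    management = management_for_category(
        category,
        category0_interval_months if category is NLCSPCategory.incomplete else None,
    )
    return FollowupDecision(
        nodule_id=hist.nodule_id,
        growth=growth,
        category=category,
        management=management,
        stability_clock_days=clock,
        rule_trace=trace,
    )
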