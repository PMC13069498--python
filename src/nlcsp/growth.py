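"""Interval-change assessment for tracked nodules.

The follow-up algorithm needs each tracked nodule classified as growing,
slowly growing, stable, or decreased.  Volumetry is the preferred
measurement; calliper mean diameter is the fallback when segmentation is
not possible on either compared scan.

Volumetric rules (relative change ΔV is measured reference -> current,
where the reference is the nodule's first appearance, and VDT is the
volume doubling time over that same span):

    growing         ΔV > +25%  and  VDT < 600 days
    slowly growing  ΔV > +25%  and  VDT >= 600 days, on more than one
                    scan interval (the same condition already held at an
                    earlier assessment against the same reference)
    decreased       ΔV <= -25%
    stable          everything else, including a >25% increase with
                    VDT >= 600 days seen for the first time

The 25% corridor absorbs inter-scan measurement variability (scanner,
reconstruction, segmentation software, observer); the 600-day VDT
threshold splits growth into a fast track (immediate referral) and an
indolent track that still refers once slow growth persists.  A VDT of
exactly 600 days falls on the non-growing side: "greater than 25% and
VDT < 600" is strict, and the slow-growth surveillance track still
escalates on persistence, so the boundary resolves conservatively without
losing the nodule.

Diameter rules (Δd̄ is the change in mean diameter, quantized to the
0.1 mm measurement resolution):

    growing         Δd̄ > +1.5 mm over 24 months (730 days) or less
    slowly growing  Δd̄ > +1.5 mm over more than 24 months
    decreased       Δd̄ <= -1.5 mm
    stable          -1.5 mm <= Δd̄ <= +1.5 mm
"""

from __future__ import annotations

import enum
import math

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core_types import (
    NLCSPCategory,
    NoduleObservation,
    ValidationError,
    round_to_tenth_mm,
)

#: Relative-volume-change corridor (percent) inside which a nodule is
#: considered unchanged.
VOLUME_CHANGE_THRESHOLD_PCT = 25.0
#: VDT below which a >25% volume increase is 'growing' rather than slow growth.
VDT_GROWTH_THRESHOLD_DAYS = 600.0
#: Mean-diameter change corridor (mm) for the calliper fallback.
DIAMETER_CHANGE_THRESHOLD_MM = 1.5
#: "24 months" in the diameter rules.
TWENTY_FOUR_MONTHS_DAYS = 730


class GrowthStatusLabel(str, enum.Enum):
    growing = "growing"
    slowly_growing = "slowly_growing"
    stable = "stable"
    decreased = "decreased"
    resolved = "resolved"
    new = "new"


class MeasurementMethod(str, enum.Enum):
    volumetry = "volumetry"
    diameter = "diameter"


class GrowthStatus(BaseModel):
    """A growth call plus the measured quantities behind it, for audit."""

    model_config = ConfigDict(frozen=True)

    status: GrowthStatusLabel
    method: MeasurementMethod | None = None
    relative_volume_change_pct: float | None = None
    vdt_days: float | None = None
    diameter_change_mm: float | None = None
    interval_days: int = Field(ge=0)


class NoduleHistory(BaseModel):
    """Time-ordered observations of one nodule across scans.

    ``reference_index`` names the comparison baseline (by default the
    earliest observation — the nodule's first appearance — so that slowly
    accumulating change is judged against where the nodule started, not
    against the most recent scan).  ``prior_category`` is the category the
    nodule held after the previous scan (absent for a nodule first seen on
    the current scan).  ``stability_clock_days`` is the documented
    stability accumulated *before* the current inter-scan interval.
    """

    model_config = ConfigDict(frozen=True)

    nodule_id: str
    observations: list[NoduleObservation] = Field(min_length=1)
    reference_index: int = 0
    prior_category: NLCSPCategory | None = None
    stability_clock_days: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _invariants(self) -> "NoduleHistory":
        dates = [o.scan_date for o in self.observations]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("observation dates must be strictly increasing")
        if not 0 <= self.reference_index < len(self.observations):
            raise ValueError("reference_index out of range")
        if len(self.observations) > 1 and self.reference_index == len(self.observations) - 1:
            raise ValueError("reference must precede the current observation")
        return self

    @property
    def reference(self) -> NoduleObservation:
        return self.observations[self.reference_index]

    @property
    def current(self) -> NoduleObservation:
        return self.observations[-1]


def relative_volume_change(v_ref: float, v_cur: float) -> float:
    """Percent volume change, 100 × (v_cur − v_ref) / v_ref."""
    if v_ref <= 0 or v_cur <= 0:
        raise ValidationError("volumes must be positive")
    return 100.0 * (v_cur - v_ref) / v_ref


def volume_doubling_time(v_ref: float, v_cur: float, days: float) -> float | None:
    """Volume doubling time in days under exponential growth.

    VDT = days × ln 2 / ln(v_cur / v_ref), the standard definition used
    throughout the volumetric screening literature.  Returns ``None`` for
    an unchanged or shrinking nodule (a doubling time is undefined there;
    shrinkage is handled by the decrease rule, not by a negative VDT).
    """
    if v_ref <= 0 or v_cur <= 0:
        raise ValidationError("volumes must be positive")
    if days <= 0:
        raise ValidationError("interval must be positive")
    if v_cur <= v_ref:
        return None
    return days * math.log(2.0) / math.log(v_cur / v_ref)


def _volumetric_call(
    v_ref: float, v_cur: float, days: float
) -> tuple[float, float | None, bool]:
    """(ΔV %, VDT, qualifies-for-slow-growth) for one reference->scan pair."""
    dv = relative_volume_change(v_ref, v_cur)
    vdt = volume_doubling_time(v_ref, v_cur, days)
    slow = (
        dv > VOLUME_CHANGE_THRESHOLD_PCT
        and vdt is not None
        and vdt >= VDT_GROWTH_THRESHOLD_DAYS
    )
    return dv, vdt, slow


def classify_volume_pair(
    v_ref: float,
    v_cur: float,
    days: float,
    prior_slow_growth: bool = False,
) -> GrowthStatus:
    """Apply the volumetric change rules to a single reference/current pair.

    ``days`` may be fractional (histories derived from calendar dates pass
    whole days).  ``prior_slow_growth`` states whether the slow-growth
    condition (ΔV > 25%, VDT >= 600 d against the same reference) already
    held at an earlier assessment — without it, a first-time slow increase
    is 'stable'.
    """
    dv, vdt, slow_now = _volumetric_call(v_ref, v_cur, days)

    if dv <= -VOLUME_CHANGE_THRESHOLD_PCT:
        status = GrowthStatusLabel.decreased
    elif dv > VOLUME_CHANGE_THRESHOLD_PCT and vdt is not None and vdt < VDT_GROWTH_THRESHOLD_DAYS:
        status = GrowthStatusLabel.growing
    elif slow_now and prior_slow_growth:
        status = GrowthStatusLabel.slowly_growing
    else:
        status = GrowthStatusLabel.stable

    return GrowthStatus(
        status=status,
        method=MeasurementMethod.volumetry,
        relative_volume_change_pct=dv,
        vdt_days=vdt,
        interval_days=round(days),
    )


def classify_volumetric_change(hist: NoduleHistory) -> GrowthStatus:
    """Classify interval change using segmented volumes.

    Requires volumes on the reference and current observations.  The
    slow-growth persistence requirement is evaluated against the same
    reference: the (ΔV > 25%, VDT >= 600 d) condition must hold now *and*
    at at least one earlier assessment.
    """
    ref, cur = hist.reference, hist.current
    if ref.volume_mm3 is None or cur.volume_mm3 is None:
        raise ValidationError(
            "volumetric classification requires volumes on both compared scans"
        )
    if ref is cur:
        raise ValidationError("growth assessment needs two distinct observations")
    days = (cur.scan_date - ref.scan_date).days
    return classify_volume_pair(
        ref.volume_mm3,
        cur.volume_mm3,
        days,
        prior_slow_growth=_slow_growth_seen_earlier(hist),
    )


def _slow_growth_seen_earlier(hist: NoduleHistory) -> bool:
    ref = hist.reference
    for obs in hist.observations[hist.reference_index + 1 : -1]:
        if obs.volume_mm3 is None:
            continue
        days = (obs.scan_date - ref.scan_date).days
        _, _, slow = _volumetric_call(ref.volume_mm3, obs.volume_mm3, days)
        if slow:
            return True
    return False


def classify_diameter_change(hist: NoduleHistory) -> GrowthStatus:
    """Classify interval change using calliper mean diameters.

    Used when volumetry is unavailable on at least one compared scan.  The
    diameter difference is quantized to the 0.1 mm measurement resolution
    before threshold comparison, so binary floating-point artefacts cannot
    push a true 1.5 mm change across the strict > 1.5 mm boundary.
    """
    ref, cur = hist.reference, hist.current
    if ref is cur:
        raise ValidationError("growth assessment needs two distinct observations")
    days = (cur.scan_date - ref.scan_date).days
    dd = round_to_tenth_mm(cur.mean_diameter_mm - ref.mean_diameter_mm)

    if dd > DIAMETER_CHANGE_THRESHOLD_MM:
        if days <= TWENTY_FOUR_MONTHS_DAYS:
            status = GrowthStatusLabel.growing
        else:
            status = GrowthStatusLabel.slowly_growing
    elif dd <= -DIAMETER_CHANGE_THRESHOLD_MM:
        status = GrowthStatusLabel.decreased
    else:
        status = GrowthStatusLabel.stable

    return GrowthStatus(
        status=status,
        method=MeasurementMethod.diameter,
        diameter_change_mm=dd,
        interval_days=days,
    )


def assess_growth(hist: NoduleHistory) -> GrowthStatus:
    """Classify interval change, preferring volumetry over diameter.

    Falls back to the diameter rules for mixed-method histories where
    either compared observation lacks a segmented volume.
    """
    if hist.reference.volume_mm3 is not None and hist.current.volume_mm3 is not None:
        return classify_volumetric_change(hist)
    return classify_diameter_change(hist)
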