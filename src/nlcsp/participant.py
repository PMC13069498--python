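"""Participant-level aggregation: one screening-episode result per scan.

A participant's management is driven by their highest-risk nodule: the
overall category is the maximum of the per-nodule categories 1-6.
Category 0 (incomplete exam, or suspected infection/inflammation) is not
on that risk ordering and is arbitrated safety-first: it outranks
categories 1-4 (the exam must be repeated or completed before lengthy
surveillance intervals are trusted) but never delays a referral (5-6).
A participant with no nodules at all is very low risk and returns to
routine biennial screening (category 1, 24-month LDCT).
"""

from __future__ import annotations

import datetime

from pydantic import BaseModel, ConfigDict

from .baseline import CategorizedNodule
from .core_types import (
    CATEGORY_DESCRIPTORS,
    ManagementRecommendation,
    NLCSPCategory,
    ValidationError,
    management_for_category,
)
from .followup import FollowupDecision

NoduleResult = CategorizedNodule | FollowupDecision


class ScreeningEpisodeReport(BaseModel):
    """One participant's result for one screening episode."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    scan_date: datetime.date
    exam_complete: bool
    nodule_results: list[NoduleResult]
    overall_category: NLCSPCategory
    overall_management: ManagementRecommendation
    summary_text: str


def overall_category_for(
    categories: list[NLCSPCategory],
    exam_complete: bool = True,
    suspected_infection: bool = False,
) -> NLCSPCategory:
    """Arbitrate the participant-level category.

    ``categories`` lists the per-nodule categories (resolved nodules,
    which carry none, are simply not listed).  Category 0 applies when
    the exam is incomplete, infection is suspected, or any nodule was
    itself assigned 0; it wins over 1-4 but loses to 5-6.
    """
    cat0 = (
        not exam_complete
        or suspected_infection
        or any(c is NLCSPCategory.incomplete for c in categories)
    )
    risk_cats = [c for c in categories if c is not NLCSPCategory.incomplete]
    top = max(risk_cats, default=NLCSPCategory.very_low_risk)
    if cat0 and top < NLCSPCategory.high_risk:
        return NLCSPCategory.incomplete
    return top


def aggregate_episode(
    results: list[NoduleResult],
    participant_id: str,
    scan_date: datetime.date,
    exam_complete: bool = True,
    suspected_infection: bool = False,
    no_nodules: bool = False,
    category0_interval_months: int = 3,
) -> ScreeningEpisodeReport:
    """Fold per-nodule results into one screening-episode report.

    An empty ``results`` list must be accompanied by the explicit
    ``no_nodules`` flag — silence and "no nodules seen" are different
    clinical statements.
    """
    if not results and not no_nodules:
        raise ValidationError(
            "empty result list requires the explicit no_nodules flag"
        )
    categories = [r.category for r in results if r.category is not None]
    overall = overall_category_for(
        categories, exam_complete=exam_complete, suspected_infection=suspected_infection
    )
    management = management_for_category(
        overall,
        category0_interval_months
        if overall is NLCSPCategory.incomplete
        else None,
    )
    n_active = len(categories)
    n_resolved = len(results) - n_active
    parts = [
        f"participant {participant_id}",
        f"scan {scan_date.isoformat()}",
        f"{n_active} nodule(s) under management"
        + (f", {n_resolved} resolved" if n_resolved else ""),
        f"overall category {overall.value} ({CATEGORY_DESCRIPTORS[overall]})",
        (
            f"repeat LDCT in {management.interval_months} months"
            if management.interval_months is not None
            else "clinical referral"
        ),
    ]
    return ScreeningEpisodeReport(
        participant_id=participant_id,
        scan_date=scan_date,
        exam_complete=exam_complete,
        nodule_results=list(results),
        overall_category=overall,
        overall_management=management,
        summary_text="; ".join(parts),
    )
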