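"""PanCan (Brock) malignancy-probability model for baseline nodules.

The PanCan model is a published logistic regression giving the probability
that a nodule detected on a *first* screening LDCT is diagnosed as lung
cancer within a horizon (2 years by default).  Its nine variables are:
participant age, sex, family history of lung cancer, emphysema; and nodule
mean diameter, morphology (solid / part-solid / ground-glass), upper-lobe
location, spiculation, and total nodule count on the scan.

Two usage restrictions are enforced here rather than left to convention:

* The model contains no growth term, so it must not be used when a prior
  CT is available for comparison — it is a baseline-only instrument.
* Specific nodule subtypes (clearly benign nodules, probable
  intrapulmonary lymph nodes, airway nodules, atypical pulmonary cysts)
  are managed by dedicated rules and must not be pushed through the model.

Coefficients are configuration, not code: they ship as a versioned YAML
file with a provenance block, and every downstream classifier also accepts
a precomputed probability so that classification logic is testable
independently of any particular coefficient set.
"""

from __future__ import annotations

import enum
import math
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core_types import (
    AirwayLevel,
    Composition,
    ConfigurationError,
    CystFeatures,
    NoduleObservation,
    ParticipantCovariates,
    Sex,
)


class RiskHorizon(str, enum.Enum):
    two_year = "2y"
    four_year = "4y"


class _CenteredTerm(BaseModel):
    model_config = ConfigDict(frozen=True)
    coefficient: float
    center: float


class PanCanCoefficients(BaseModel):
    """A complete, versioned PanCan coefficient set.

    ``size.center`` is on the transformed scale: the size term contributes
    ``coefficient * ((d_mm / 10) ** -0.5 - center)``, so a *negative*
    coefficient makes risk increase with diameter.
    """

    model_config = ConfigDict(frozen=True)

    provenance: str
    version: str
    horizon: RiskHorizon
    intercept: float
    age: _CenteredTerm
    sex_female: float
    family_history_lung_cancer: float
    emphysema: float
    size: _CenteredTerm
    morphology: dict[Composition, float]
    upper_lobe: float
    spiculation: float
    nodule_count: _CenteredTerm

    @classmethod
    def from_file(cls, path: str | Path) -> "PanCanCoefficients":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        except OSError as exc:
            raise ConfigurationError(f"cannot read coefficient file: {exc}") from exc
        return cls.from_mapping(raw, source=str(path))

    @classmethod
    def from_mapping(cls, raw: object, source: str = "<mapping>") -> "PanCanCoefficients":
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{source}: coefficient config must be a mapping")
        try:
            coeffs = cls.model_validate(raw)
        except Exception as exc:
            raise ConfigurationError(f"{source}: incomplete or invalid coefficient set: {exc}") from exc
        missing = set(Composition) - set(coeffs.morphology)
        if missing:
            raise ConfigurationError(
                f"{source}: morphology contrasts missing for {sorted(m.value for m in missing)}"
            )
        return coeffs


class PanCanRisk(BaseModel):
    """A computed probability of lung cancer within the stated horizon."""

    model_config = ConfigDict(frozen=True)

    probability: float = Field(ge=0.0, le=1.0)
    horizon: RiskHorizon = RiskHorizon.two_year


def load_default_coefficients() -> PanCanCoefficients:
    """Load the packaged published full-model-with-spiculation coefficients."""
    ref = resources.files("nlcsp").joinpath("data/pancan_brock_full.yaml")
    raw = yaml.safe_load(ref.read_text())
    return PanCanCoefficients.from_mapping(raw, source="nlcsp/data/pancan_brock_full.yaml")


def linear_predictor(
    cov: ParticipantCovariates,
    obs: NoduleObservation,
    coeffs: PanCanCoefficients,
) -> float:
    """Evaluate the logistic linear predictor for one baseline nodule."""
    lp = coeffs.intercept
    lp += coeffs.age.coefficient * (cov.age - coeffs.age.center)
    lp += coeffs.sex_female * (cov.sex is Sex.female)
    lp += coeffs.family_history_lung_cancer * cov.family_history_lung_cancer
    lp += coeffs.emphysema * cov.emphysema
    d = obs.mean_diameter_mm
    lp += coeffs.size.coefficient * ((d / 10.0) ** -0.5 - coeffs.size.center)
    lp += coeffs.morphology[obs.composition]
    lp += coeffs.upper_lobe * bool(obs.upper_lobe)
    lp += coeffs.spiculation * obs.spiculation
    lp += coeffs.nodule_count.coefficient * (
        obs.nodule_count_total - coeffs.nodule_count.center
    )
    return lp


def compute_pancan_risk(
    cov: ParticipantCovariates,
    obs: NoduleObservation,
    coeffs: PanCanCoefficients | None = None,
    horizon: RiskHorizon = RiskHorizon.two_year,
) -> PanCanRisk:
    """Inverse-logit of the linear predictor under the loaded coefficients.

    Deterministic.  Raises :class:`ConfigurationError` if the coefficient
    set was fitted for a different horizon than requested.
    """
    if coeffs is None:
        coeffs = load_default_coefficients()
    horizon = RiskHorizon(horizon)
    if horizon is not coeffs.horizon:
        raise ConfigurationError(
            f"coefficient set {coeffs.version!r} is for horizon "
            f"{coeffs.horizon.value}, not {horizon.value}"
        )
    lp = linear_predictor(cov, obs, coeffs)
    probability = 1.0 / (1.0 + math.exp(-lp))
    return PanCanRisk(probability=probability, horizon=horizon)


def pancan_applicable(
    obs: NoduleObservation, has_prior_ct: bool
) -> tuple[bool, str | None]:
    """Whether the PanCan model may be used for this nodule.

    Returns ``(False, reason)`` when a prior CT is available (the model has
    no growth term) or when the nodule belongs to a subtype managed by a
    dedicated rule path; ``(True, None)`` otherwise.
    """
    from .baseline import detect_benign_features, is_probable_intrapulmonary_lymph_node

    if has_prior_ct:
        return False, "prior CT available"
    if detect_benign_features(obs):
        return False, "benign features"
    if is_probable_intrapulmonary_lymph_node(obs):
        return False, "probable intrapulmonary lymph node"
    if obs.airway_level is not AirwayLevel.none:
        return False, "airway nodule"
    if obs.cyst_features is not CystFeatures.none:
        return False, "atypical pulmonary cyst"
    return True, None
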