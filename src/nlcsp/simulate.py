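"""Synthetic longitudinal screening cohorts.

Every rule path of the engine must be testable without real imaging data,
so this module generates multi-round screening histories from a simple
natural-history model:

* each participant carries at most one nodule, drawn from one of five
  classes — ``no_nodule``, ``benign_stable`` (static volume),
  ``benign_resolving`` (exponential shrinkage until it drops below the
  detection limit), ``indolent`` (exponential growth with a volume
  doubling time well above the 600-day threshold), and ``aggressive``
  (exponential growth with a VDT well below it);
* true volume follows the exact exponential law
  ``v(t2)/v(t1) = 2^((t2-t1)/VDT)``;
* measured volume is the true volume times multiplicative log-normal
  noise with a configurable coefficient of variation (mean-one noise, so
  CV 0 reproduces truth exactly); calliper diameters are derived from
  measured volume assuming sphericity, with a fixed 1.1/0.9 long/short
  axis asymmetry so the mean diameter equals the spherical diameter.

Scans happen either on a fixed grid (open loop) or at whatever interval
the engine itself recommends (closed loop), so the simulator can exercise
the stepped de-escalation and referral logic end to end.  All randomness
flows from a single integer seed; identical configs produce identical
tables.
"""

from __future__ import annotations

import datetime
import enum
import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .baseline import classify_baseline_nodule
from .core_types import (
    Composition,
    Lobe,
    NLCSPCategory,
    NoduleObservation,
    ParticipantCovariates,
    Sex,
    ValidationError,
)
from .followup import FollowupDecision, classify_followup_nodule
from .growth import NoduleHistory
from .pancan import PanCanCoefficients, load_default_coefficients
from .participant import ScreeningEpisodeReport, aggregate_episode

AVERAGE_DAYS_PER_MONTH = 30.4375


def months_to_days(months: int) -> int:
    """Nominal month count -> whole days, for scheduling simulated scans."""
    return round(months * AVERAGE_DAYS_PER_MONTH)


class NoduleClass(str, enum.Enum):
    no_nodule = "no_nodule"
    benign_stable = "benign_stable"
    benign_resolving = "benign_resolving"
    indolent = "indolent"
    aggressive = "aggressive"


class LogNormal(BaseModel):
    """Log-normal with a clinically interpretable median and log-sd."""

    model_config = ConfigDict(frozen=True)

    median: float = Field(gt=0)
    sigma: float = Field(ge=0)

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.median * np.exp(self.sigma * rng.standard_normal()))


class CovariateDistributions(BaseModel):
    """Sampling model for participant covariates.

    Defaults emulate the NLCSP-eligible population: ages 50-70, balanced
    sex, and family-history / emphysema prevalences plausible for a
    heavy-smoking screening cohort.
    """

    model_config = ConfigDict(frozen=True)

    age_min: int = 50
    age_max: int = 70
    p_female: float = Field(default=0.5, ge=0, le=1)
    p_family_history: float = Field(default=0.15, ge=0, le=1)
    p_emphysema: float = Field(default=0.30, ge=0, le=1)


class SchedulingMode(str, enum.Enum):
    closed_loop = "closed_loop"
    open_loop = "open_loop"


class SimulationConfig(BaseModel):
    """Full specification of a synthetic cohort.

    VDT medians put the growing classes firmly on either side of the
    600-day growth threshold: aggressive nodules double in ~180 days
    (the fast, referral-on-first-growth track), indolent ones in ~900
    days (reachable only through the slow-growth rule).  The resolving
    class shrinks with a ~120-day halving time.  Baseline diameters are
    log-normal with a 6 mm median, the small-nodule regime screening
    mostly sees, and volumetric measurement noise defaults to a 10%
    coefficient of variation — the regime the ±25% change corridor is
    designed to absorb.
    """

    model_config = ConfigDict(frozen=True)

    n_participants: int = Field(ge=0)
    seed: int = Field(ge=0)
    class_mix: dict[NoduleClass, float] = Field(
        default={
            NoduleClass.no_nodule: 0.55,
            NoduleClass.benign_stable: 0.25,
            NoduleClass.benign_resolving: 0.08,
            NoduleClass.indolent: 0.06,
            NoduleClass.aggressive: 0.06,
        }
    )
    vdt_days: dict[NoduleClass, LogNormal] = Field(
        default={
            NoduleClass.indolent: LogNormal(median=900.0, sigma=0.15),
            NoduleClass.aggressive: LogNormal(median=180.0, sigma=0.25),
        }
    )
    halving_time_days: LogNormal = LogNormal(median=120.0, sigma=0.2)
    baseline_diameter_mm: LogNormal = LogNormal(median=6.0, sigma=0.35)
    volumetric_noise_cv: float = Field(default=0.10, ge=0)
    covariates: CovariateDistributions = CovariateDistributions()
    max_rounds: int = Field(default=6, ge=1)
    scheduling: SchedulingMode = SchedulingMode.closed_loop
    open_interval_months: int = Field(default=24, ge=1)
    detection_volume_mm3: float = Field(default=15.0, gt=0)
    start_date: datetime.date = datetime.date(2025, 7, 1)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions sum to {total}, not 1")
        if any(p < 0 for p in self.class_mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        for cls in (NoduleClass.indolent, NoduleClass.aggressive):
            if self.class_mix.get(cls, 0) > 0 and cls not in self.vdt_days:
                raise ValueError(f"vdt_days missing for class {cls.value}")
        return self


def sphere_volume_mm3(diameter_mm: float) -> float:
    return math.pi / 6.0 * diameter_mm**3


def sphere_diameter_mm(volume_mm3: float) -> float:
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


class TrueTrajectory(BaseModel):
    """Ground-truth natural history of one nodule.

    ``vdt_days`` is positive for growth, ``None`` for a static nodule;
    resolving nodules carry a positive ``halving_time_days`` instead.
    Volume follows the exponential law exactly; emergence is at day 0
    (baseline) for every simulated nodule.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    nodule_id: str
    nodule_class: NoduleClass
    baseline_volume_mm3: float = Field(gt=0)
    vdt_days: float | None = None
    halving_time_days: float | None = None
    lobe: Lobe
    spiculation: bool

    def volume_at(self, day: float) -> float:
        if self.vdt_days is not None:
            return self.baseline_volume_mm3 * 2.0 ** (day / self.vdt_days)
        if self.halving_time_days is not None:
            return self.baseline_volume_mm3 * 2.0 ** (-day / self.halving_time_days)
        return self.baseline_volume_mm3


class ParticipantTruth(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant_id: str
    covariates: ParticipantCovariates
    nodule_class: NoduleClass
    trajectory: TrueTrajectory | None = None


_LOBES = list(Lobe)


def generate_truth(config: SimulationConfig) -> list[ParticipantTruth]:
    """Sample covariates and natural histories for the whole cohort."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    cov_cfg = config.covariates
    out: list[ParticipantTruth] = []
    for i in range(config.n_participants):
        pid = f"P{i:05d}"
        cov = ParticipantCovariates(
            age=int(rng.integers(cov_cfg.age_min, cov_cfg.age_max + 1)),
            sex=Sex.female if rng.random() < cov_cfg.p_female else Sex.male,
            family_history_lung_cancer=bool(rng.random() < cov_cfg.p_family_history),
            emphysema=bool(rng.random() < cov_cfg.p_emphysema),
        )
        cls = classes[int(rng.choice(len(classes), p=probs))]
        trajectory = None
        if cls is not NoduleClass.no_nodule:
            d0 = config.baseline_diameter_mm.sample(rng)
            vdt = halving = None
            if cls in (NoduleClass.indolent, NoduleClass.aggressive):
                vdt = config.vdt_days[cls].sample(rng)
            elif cls is NoduleClass.benign_resolving:
                halving = config.halving_time_days.sample(rng)
            trajectory = TrueTrajectory(
                participant_id=pid,
                nodule_id=f"{pid}-N1",
                nodule_class=cls,
                baseline_volume_mm3=sphere_volume_mm3(d0),
                vdt_days=vdt,
                halving_time_days=halving,
                lobe=_LOBES[int(rng.integers(0, len(_LOBES)))],
                spiculation=bool(
                    rng.random() < (0.4 if cls is NoduleClass.aggressive else 0.05)
                ),
            )
        out.append(
            ParticipantTruth(
                participant_id=pid,
                covariates=cov,
                nodule_class=cls,
                trajectory=trajectory,
            )
        )
    return out


class _Measurer:
    """Mean-one multiplicative log-normal measurement noise."""

    def __init__(self, cv: float, rng: np.random.Generator):
        self.rng = rng
        if cv > 0:
            self.sigma = math.sqrt(math.log(1.0 + cv * cv))
        else:
            self.sigma = 0.0

    def observe(
        self, traj: TrueTrajectory, day: int, scan_date: datetime.date
    ) -> NoduleObservation:
        true_v = traj.volume_at(day)
        if self.sigma > 0:
            factor = math.exp(
                self.rng.normal(-0.5 * self.sigma**2, self.sigma)
            )
        else:
            factor = 1.0
        v = true_v * factor
        d = sphere_diameter_mm(v)
        return NoduleObservation(
            nodule_id=traj.nodule_id,
            scan_date=scan_date,
            composition=Composition.solid,
            long_axis_mm=1.1 * d,
            short_axis_mm=0.9 * d,
            volume_mm3=v,
            lobe=traj.lobe,
            spiculation=traj.spiculation,
        )


_OBS_COLUMNS = [
    "participant_id",
    "scan_date",
    "nodule_id",
    "age",
    "sex",
    "family_history_lung_cancer",
    "emphysema",
    "composition",
    "long_axis_mm",
    "short_axis_mm",
    "solid_component_mean_diameter_mm",
    "volume_mm3",
    "lobe",
    "upper_lobe",
    "spiculation",
    "nodule_count_total",
    "calcification",
    "macroscopic_fat",
    "margin",
    "shape",
    "contacts_pleura",
    "distance_to_pleura_mm",
    "airway_level",
    "cyst_features",
    "radiologist_suspicious_flag",
    "suspected_infection",
]

_TRUTH_COLUMNS = [
    "participant_id",
    "nodule_id",
    "nodule_class",
    "age",
    "sex",
    "family_history_lung_cancer",
    "emphysema",
    "baseline_volume_mm3",
    "vdt_days",
    "halving_time_days",
    "lobe",
    "spiculation",
]


def _obs_row(pt: ParticipantTruth, obs: NoduleObservation) -> dict:
    row = {"participant_id": pt.participant_id}
    row.update(
        {
            "age": pt.covariates.age,
            "sex": pt.covariates.sex.value,
            "family_history_lung_cancer": pt.covariates.family_history_lung_cancer,
            "emphysema": pt.covariates.emphysema,
        }
    )
    dumped = obs.model_dump(mode="json")
    row.update(dumped)
    return row


def _truth_rows(truth: list[ParticipantTruth]) -> pd.DataFrame:
    rows = []
    for pt in truth:
        if pt.trajectory is None:
            continue
        t = pt.trajectory
        rows.append(
            {
                "participant_id": pt.participant_id,
                "nodule_id": t.nodule_id,
                "nodule_class": t.nodule_class.value,
                "age": pt.covariates.age,
                "sex": pt.covariates.sex.value,
                "family_history_lung_cancer": pt.covariates.family_history_lung_cancer,
                "emphysema": pt.covariates.emphysema,
                "baseline_volume_mm3": t.baseline_volume_mm3,
                "vdt_days": t.vdt_days,
                "halving_time_days": t.halving_time_days,
                "lobe": t.lobe.value,
                "spiculation": t.spiculation,
            }
        )
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Open-loop simulation on a fixed scan grid.

    Returns ``(observations, truth)`` as DataFrames in the engine's
    tabular dialect.  Scans occur every ``open_interval_months`` for
    ``max_rounds`` rounds regardless of what the engine would recommend;
    use :func:`run_program` for the closed loop.  Nodules are recorded
    only while their true volume is at or above the detection limit.
    """
    truth = generate_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    measurer = _Measurer(config.volumetric_noise_cv, rng)
    interval = months_to_days(config.open_interval_months)
    rows: list[dict] = []
    for pt in truth:
        if pt.trajectory is None:
            continue
        for r in range(config.max_rounds):
            day = r * interval
            if pt.trajectory.volume_at(day) < config.detection_volume_mm3:
                continue
            scan_date = config.start_date + datetime.timedelta(days=day)
            rows.append(_obs_row(pt, measurer.observe(pt.trajectory, day, scan_date)))
    obs_df = pd.DataFrame(rows, columns=_OBS_COLUMNS)
    return obs_df, _truth_rows(truth)


class ParticipantRun(BaseModel):
    """Closed-loop history for one participant: one report per round."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    nodule_class: NoduleClass
    reports: list[ScreeningEpisodeReport]
    scan_days: list[int]
    referred: bool
    days_to_referral: int | None = None


def run_program(
    config: SimulationConfig,
    coeffs: PanCanCoefficients | None = None,
) -> list[ParticipantRun]:
    """Closed-loop simulation: scans happen when the engine says so.

    Each participant is screened at baseline, then re-scanned at the
    interval the engine recommends, with the engine's own follow-up
    decisions feeding the next round, until referral (screening ends
    there) or ``max_rounds`` scans.
    """
    if config.scheduling is not SchedulingMode.closed_loop:
        raise ValidationError("run_program requires closed_loop scheduling")
    if coeffs is None:
        coeffs = load_default_coefficients()
    truth = generate_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    measurer = _Measurer(config.volumetric_noise_cv, rng)

    runs: list[ParticipantRun] = []
    for pt in truth:
        reports: list[ScreeningEpisodeReport] = []
        scan_days: list[int] = []
        observations: list[NoduleObservation] = []
        prior_category: NLCSPCategory | None = None
        stability_clock = 0
        nodule_gone = False
        day = 0
        referred = False
        days_to_referral: int | None = None

        for round_no in range(config.max_rounds):
            scan_date = config.start_date + datetime.timedelta(days=day)
            scan_days.append(day)
            traj = pt.trajectory
            visible = (
                traj is not None
                and not nodule_gone
                and traj.volume_at(day) >= config.detection_volume_mm3
            )
            if visible:
                observations.append(measurer.observe(traj, day, scan_date))

            if round_no == 0:
                if visible:
                    decision = classify_baseline_nodule(
                        pt.covariates, observations[-1], coeffs=coeffs
                    )
                    prior_category = decision.category
                    report = aggregate_episode(
                        [decision], pt.participant_id, scan_date
                    )
                else:
                    report = aggregate_episode(
                        [], pt.participant_id, scan_date, no_nodules=True
                    )
            else:
                if observations and (visible or not nodule_gone):
                    hist = NoduleHistory(
                        nodule_id=traj.nodule_id,
                        observations=observations,
                        prior_category=prior_category,
                        stability_clock_days=stability_clock,
                    )
                    fu = classify_followup_nodule(
                        hist,
                        pt.covariates,
                        current_scan_date=None if visible else scan_date,
                    )
                    if fu.category is None:
                        nodule_gone = True
                    else:
                        prior_category = fu.category
                        stability_clock = fu.stability_clock_days
                    report = aggregate_episode([fu], pt.participant_id, scan_date)
                else:
                    report = aggregate_episode(
                        [], pt.participant_id, scan_date, no_nodules=True
                    )

            reports.append(report)
            if report.overall_management.interval_months is None:
                referred = True
                days_to_referral = day
                break
            day += months_to_days(report.overall_management.interval_months)

        runs.append(
            ParticipantRun(
                participant_id=pt.participant_id,
                nodule_class=pt.nodule_class,
                reports=reports,
                scan_days=scan_days,
                referred=referred,
                days_to_referral=days_to_referral,
            )
        )
    return runs


def summarize_run(runs: list[ParticipantRun]) -> pd.DataFrame:
    """Per-participant outcome table for a completed closed-loop run."""
    rows = []
    for run in runs:
        final = run.reports[-1]
        rows.append(
            {
                "participant_id": run.participant_id,
                "nodule_class": run.nodule_class.value,
                "n_scans": len(run.reports),
                "final_category": int(final.overall_category),
                "referred": run.referred,
                "days_to_referral": run.days_to_referral,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "nodule_class",
            "n_scans",
            "final_category",
            "referred",
            "days_to_referral",
        ],
    )


def fit_vdt(days: np.ndarray, volumes_mm3: np.ndarray) -> float:
    """Recover a VDT by least squares on log2(volume) vs. time.

    The slope of log2 v against days is 1/VDT under exponential growth;
    negative slopes (shrinkage) yield a negative 'VDT' (a halving time
    with sign flipped), which callers can interpret as decay.
    """
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes_mm3, dtype=float)
    if days.size < 2:
        raise ValidationError("VDT recovery needs at least two scans")
    slope = np.polyfit(days, np.log2(volumes), 1)[0]
    if slope == 0:
        return math.inf
    return 1.0 / slope
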