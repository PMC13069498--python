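"""Readers and writers for the observation and report dialects.

The normative encoding is JSON; CSV is a flat projection of the same
records (UTF-8, mandatory header row, ISO-8601 dates, empty cells for
absent values).  Column names are exactly the field names of the domain
models, plus the participant columns (``participant_id``, ``age``,
``sex``, ``family_history_lung_cancer``, ``emphysema``) repeated on every
row.  Loading is all-or-nothing: every record must pass the domain-model
invariants or the load fails with row-addressed errors.  Static
JSON-schema files generated from the pydantic models ship under
``nlcsp/schemas/``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import pydantic

from .core_types import (
    NoduleObservation,
    ParticipantCovariates,
    ValidationError,
)
from .participant import ScreeningEpisodeReport

logger = logging.getLogger("nlcsp")

_COVARIATE_FIELDS = ("age", "sex", "family_history_lung_cancer", "emphysema")
_BOOL_STRINGS = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "yes": True,
    "no": False,
}


class ObservationRecord(NamedTuple):
    """One validated row: who was scanned, and what was seen."""

    participant_id: str
    covariates: ParticipantCovariates
    observation: NoduleObservation


class ObservationLoadError(ValidationError):
    """Raised when any row of an observation table fails validation.

    ``errors`` holds one ``(row, message)`` pair per offending record.
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = [f"row {row}: {msg}" for row, msg in errors]
        super().__init__(
            f"{len(errors)} invalid observation record(s):\n" + "\n".join(lines)
        )


def _coerce(value: object) -> object:
    """CSV cells arrive as strings or NaN; normalize to model-ready values."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        s = value.strip()
        if s == "":
            return None
        if s.lower() in _BOOL_STRINGS:
            return _BOOL_STRINGS[s.lower()]
        return s
    return value


def _record_from_mapping(raw: dict) -> ObservationRecord:
    clean = {k: _coerce(v) for k, v in raw.items()}
    participant_id = clean.pop("participant_id", None)
    if participant_id is None:
        raise ValueError("participant_id: missing")
    cov = ParticipantCovariates.model_validate(
        {k: clean[k] for k in _COVARIATE_FIELDS if clean.get(k) is not None}
    )
    obs_fields = {
        k: v
        for k, v in clean.items()
        if k not in _COVARIATE_FIELDS and v is not None
    }
    obs = NoduleObservation.model_validate(obs_fields)
    return ObservationRecord(str(participant_id), cov, obs)


def _format_pydantic_error(exc: pydantic.ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<record>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def read_observations(
    path: str | Path, dialect: str | None = None
) -> list[ObservationRecord]:
    """Load and validate an observation table (CSV or JSON).

    ``dialect`` defaults to the file extension.  Raises
    :class:`ObservationLoadError` naming every offending row if any
    record violates the domain invariants.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect == "csv":
        frame = pd.read_csv(path, dtype=str)
        raw_records = frame.to_dict(orient="records")
    elif dialect == "json":
        with open(path) as fh:
            payload = json.load(fh)
        raw_records = payload["observations"] if isinstance(payload, dict) else payload
    else:
        raise ValidationError(f"unknown dialect {dialect!r} (expected csv or json)")

    records: list[ObservationRecord] = []
    errors: list[tuple[int, str]] = []
    for i, raw in enumerate(raw_records):
        try:
            records.append(_record_from_mapping(dict(raw)))
        except pydantic.ValidationError as exc:
            errors.append((i, _format_pydantic_error(exc)))
        except (ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
    if errors:
        raise ObservationLoadError(errors)
    logger.info("loaded %d observation record(s) from %s", len(records), path)
    return records


def observations_to_frame(records: list[ObservationRecord]) -> pd.DataFrame:
    """Flatten validated records back to the CSV column layout."""
    rows = []
    for rec in records:
        row = {"participant_id": rec.participant_id}
        row.update(rec.covariates.model_dump(mode="json"))
        row.update(rec.observation.model_dump(mode="json"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(
    report: ScreeningEpisodeReport, path: str | Path, dialect: str = "json"
) -> None:
    """Write a screening-episode report (JSON normative, CSV summary).

    JSON output uses sorted keys and a fixed indent so that reruns on the
    same inputs are byte-identical and diffs stay readable.
    """
    path = Path(path)
    if dialect == "json":
        payload = report.model_dump(mode="json", exclude_none=True)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif dialect == "csv":
        row = {
            "participant_id": report.participant_id,
            "scan_date": report.scan_date.isoformat(),
            "exam_complete": report.exam_complete,
            "overall_category": int(report.overall_category),
            "action": report.overall_management.action.value,
            "interval_months": report.overall_management.interval_months,
            "n_nodules": len(report.nodule_results),
            "summary_text": report.summary_text,
        }
        pd.DataFrame([row]).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown dialect {dialect!r} (expected csv or json)")
    logger.info(
        "wrote report for %s (%s): overall category %d",
        report.participant_id,
        report.scan_date,
        report.overall_category,
    )


def read_report(path: str | Path) -> ScreeningEpisodeReport:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return ScreeningEpisodeReport.model_validate(json.load(fh))


def group_records_by_participant(
    records: list[ObservationRecord],
) -> dict[str, list[ObservationRecord]]:
    """Group validated records by participant, preserving input order."""
    grouped: dict[str, list[ObservationRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.participant_id, []).append(rec)
    return grouped
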