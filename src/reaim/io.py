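"""Reading and writing cohort files.

Participant and site tables travel as plain CSV with a fixed column
dictionary; the eligibility / evaluation configuration travels as YAML or
JSON.  Missing measurement cells load as missing (``None``), never as
zero — every downstream statistic selects its own maximal complete subset.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .model import (
    CohortDataset,
    EligibilityModel,
    MeasurementSet,
    ParticipantRecord,
    SiteRecord,
    Timepoint,
    ValidationError,
    N_COMPONENTS,
)

__all__ = ["read_cohort", "write_cohort", "load_config", "eligibility_from_config"]

#: CSV suffix used for each measurement timepoint
_TP_SUFFIX = {
    Timepoint.BASELINE: "baseline",
    Timepoint.END_PHASE1: "p1",
    Timepoint.END_PHASE2: "p2",
}

#: measurement field -> CSV column stem
_MEASURE_STEMS = {
    "weight_lb": "weight_lb",
    "bmi_kg_m2": "bmi",
    "systolic_mmHg": "sbp",
    "diastolic_mmHg": "dbp",
    "body_fat_pct": "bodyfat",
    "waist_in": "waist",
}

PARTICIPANT_BASE_COLUMNS = [
    "participant_id", "site_id", "sex", "age_years", "enrollment_date",
    "height_in", "completed_phase1", "completed_phase2",
]

SITE_COLUMNS = (
    ["site_id", "site_type", "approval_date"]
    + [f"comp_{i:02d}" for i in range(1, N_COMPONENTS + 1)]
    + ["still_accepting"]
)


def _measure_columns() -> list[str]:
    return [f"{stem}_{suf}" for stem in _MEASURE_STEMS.values()
            for suf in ("baseline", "p1", "p2")]


def _opt(value: Any) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _parse_bool(value: Any, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise ValidationError(f"row {row}: cannot parse {column}={value!r} as boolean")


def _parse_date(value: Any, column: str, row: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValidationError(
            f"row {row}: cannot parse {column}={value!r} as ISO date"
        ) from exc


def read_cohort(
    participants_path: str | Path,
    sites_path: str | Path,
    config: Mapping[str, Any],
) -> CohortDataset:
    """Load and validate a cohort from participant and site CSVs.

    ``config`` supplies the eligibility model, the data collection date
    and the number of potential sites (see :func:`load_config`).  Rows
    that fail validation are reported with their 1-based data row number.
    """
    participants_path = Path(participants_path)
    sites_path = Path(sites_path)
    for path in (participants_path, sites_path):
        if not path.exists():
            raise FileNotFoundError(path)

    pdf = pd.read_csv(participants_path, dtype={"participant_id": str, "site_id": str})
    sdf = pd.read_csv(sites_path, dtype={"site_id": str})

    missing = [c for c in PARTICIPANT_BASE_COLUMNS if c not in pdf.columns]
    if missing:
        raise ValidationError(f"participant file missing columns: {missing}")
    missing = [c for c in SITE_COLUMNS if c not in sdf.columns]
    if missing:
        raise ValidationError(f"site file missing columns: {missing}")

    errors: list[str] = []
    participants: list[ParticipantRecord] = []
    for i, row in enumerate(pdf.to_dict("records"), start=1):
        try:
            participants.append(_participant_from_row(row, i))
        except ValidationError as exc:
            errors.append(str(exc))
    sites: list[SiteRecord] = []
    for i, row in enumerate(sdf.to_dict("records"), start=1):
        try:
            sites.append(_site_from_row(row, i))
        except ValidationError as exc:
            errors.append(f"sites: {exc}")
    if errors:
        raise ValidationError("invalid input rows:\n" + "\n".join(errors))

    return CohortDataset(
        participants=participants,
        sites=sites,
        data_collection_date=_as_date(config["data_collection_date"]),
        eligibility=eligibility_from_config(config),
        n_potential_sites=int(config["n_potential_sites"]),
    )


def _participant_from_row(row: Mapping[str, Any], rownum: int) -> ParticipantRecord:
    sex = str(row["sex"]).strip().lower()
    if sex not in ("female", "male"):
        raise ValidationError(f"row {rownum}: unknown sex code {row['sex']!r}")
    measurements: dict[Timepoint, MeasurementSet] = {}
    for tp, suf in _TP_SUFFIX.items():
        kwargs = {
            fld: _opt(row.get(f"{stem}_{suf}"))
            for fld, stem in _MEASURE_STEMS.items()
        }
        # height is measured once, at intake
        kwargs["height_in"] = _opt(row.get("height_in")) if tp is Timepoint.BASELINE else None
        measurements[tp] = MeasurementSet(**kwargs)
    try:
        return ParticipantRecord(
            participant_id=str(row["participant_id"]),
            site_id=str(row["site_id"]),
            sex=sex,
            age_years=float(row["age_years"]),
            enrollment_date=_parse_date(row["enrollment_date"], "enrollment_date", rownum),
            measurements=measurements,
            completed_phase1=_parse_bool(row["completed_phase1"], "completed_phase1", rownum),
            completed_phase2=_parse_bool(row["completed_phase2"], "completed_phase2", rownum),
        )
    except ValidationError as exc:
        raise ValidationError(f"row {rownum}: {exc}") from exc


def _site_from_row(row: Mapping[str, Any], rownum: int) -> SiteRecord:
    try:
        return SiteRecord(
            site_id=str(row["site_id"]),
            site_type=str(row["site_type"]).strip().lower(),
            approval_date=_parse_date(row["approval_date"], "approval_date", rownum),
            components_implemented=tuple(
                _parse_bool(row[f"comp_{i:02d}"], f"comp_{i:02d}", rownum)
                for i in range(1, N_COMPONENTS + 1)
            ),
            still_accepting=_parse_bool(row["still_accepting"], "still_accepting", rownum),
        )
    except ValueError as exc:  # unknown site_type enum code
        raise ValidationError(f"row {rownum}: {exc}") from exc


def write_cohort(
    dataset: CohortDataset,
    participants_path: str | Path,
    sites_path: str | Path,
) -> None:
    """Write a cohort back to the CSV dialect consumed by :func:`read_cohort`."""
    prow = []
    for p in dataset.participants:
        row: dict[str, Any] = {
            "participant_id": p.participant_id,
            "site_id": p.site_id,
            "sex": p.sex.value,
            "age_years": p.age_years,
            "enrollment_date": p.enrollment_date.isoformat(),
            "height_in": p.measurement(Timepoint.BASELINE).height_in,
            "completed_phase1": int(p.completed_phase1),
            "completed_phase2": int(p.completed_phase2),
        }
        for tp, suf in _TP_SUFFIX.items():
            ms = p.measurement(tp)
            for fld, stem in _MEASURE_STEMS.items():
                row[f"{stem}_{suf}"] = getattr(ms, fld)
        prow.append(row)
    cols = PARTICIPANT_BASE_COLUMNS[:5] + _measure_columns() + [
        "height_in", "completed_phase1", "completed_phase2"]
    pd.DataFrame(prow).reindex(columns=cols).to_csv(participants_path, index=False)

    srow = []
    for s in dataset.sites:
        row = {
            "site_id": s.site_id,
            "site_type": s.site_type.value,
            "approval_date": s.approval_date.isoformat(),
            "still_accepting": int(s.still_accepting),
        }
        for i, flag in enumerate(s.components_implemented, start=1):
            row[f"comp_{i:02d}"] = int(flag)
        srow.append(row)
    pd.DataFrame(srow).reindex(columns=SITE_COLUMNS).to_csv(sites_path, index=False)


def _as_date(value: Any) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def load_config(path: str | Path) -> dict[str, Any]:
    """Load an evaluation config from YAML or JSON (by file suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def eligibility_from_config(config: Mapping[str, Any]) -> EligibilityModel:
    return EligibilityModel(
        n_adult_members=int(config["n_adult_members"]),
        p_obese=float(config["p_obese"]),
        p_overweight=float(config["p_overweight"]),
        p_comorbid_overweight=float(config["p_comorbid_overweight"]),
        eligible_sex_split=float(config.get("eligible_sex_split", 0.5)),
        eligible_age_distribution=tuple(config["eligible_age_distribution"]),
    )
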