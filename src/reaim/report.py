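"""Human-readable evaluation reports.

Assembles the component/index table (the headline summary of the
evaluation), per-sex descriptive tables for each measurement at each
timepoint with change-from-baseline columns (negative change = improvement),
and a per-sex, per-age-group completion table.  The same report renders to
JSON and to aligned plain text with identical numbers: indices at one
decimal, components at three decimals, measurements at one decimal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__
from .engine import ComponentValues, ReaimIndices
from .model import (
    AGE_GROUP_LABELS,
    CohortDataset,
    ParticipantRecord,
    Timepoint,
)
from .stats import DescriptiveSummary, summarize

__all__ = ["EvaluationReport", "build_report", "render_text"]

_MEASURES = [
    ("weight_lb", "Weight, lb"),
    ("bmi_kg_m2", "BMI, kg/m2"),
    ("systolic_mmHg", "Systolic blood pressure, mm Hg"),
    ("diastolic_mmHg", "Diastolic blood pressure, mm Hg"),
    ("body_fat_pct", "Body fat, %"),
    ("waist_in", "Waist, in"),
]

_COMPONENT_ROWS = [
    ("ipr", "Individual participation rate (IPR)"),
    ("dr", "Demographic representativeness (DR)"),
    ("icr_phase1", "Phase I individual completion rate (ICR-I)"),
    ("outcome_phase1", "Phase I outcome (O-I)"),
    ("di_phase1", "Phase I differential impact (DI-I)"),
    ("spr", "Setting participation rate (SPR)"),
    ("cir", "Component implementation rate (CIR)"),
    ("icr_phase2", "Phase II individual completion rate (ICR-II)"),
    ("outcome_phase2", "Phase II outcome (O-II)"),
    ("di_phase2", "Phase II differential impact (DI-II)"),
    ("scr", "Setting continuation rate (SCR)"),
]

_INDEX_ROWS = [
    ("reach", "Reach (R)"),
    ("effectiveness", "Effectiveness (E)"),
    ("adoption", "Adoption (A)"),
    ("implementation", "Implementation (I)"),
    ("maintenance_individual", "Individual maintenance (M-I)"),
    ("maintenance_setting", "Setting maintenance (M-S)"),
    ("impact_individual", "Individual-level impact (R*E/100)"),
    ("impact_setting", "Setting-level impact (A*I/100)"),
    ("impact_maintenance", "Long-term maintenance (M-I*M-S/100)"),
]


@dataclass
class EvaluationReport:
    component_table: list[dict[str, Any]]
    index_table: list[dict[str, Any]]
    descriptive_tables: dict[str, Any]
    completion_table: list[dict[str, Any]]
    provenance: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _formula(name: str, c: ComponentValues) -> str:
    r3 = lambda v: f"{v:.3f}".lstrip("0") or "0"
    f = {
        "ipr": f"n_participants / {c.n_eligible:,.0f}",
        "dr": "mean(sex, age representativeness effect sizes)",
        "icr_phase1": "phase-I completers / phase-I eligible",
        "outcome_phase1": "eta2(time), weight baseline->12 wk",
        "di_phase1": "mean(sex, age interaction eta2)",
        "spr": "active sites / potential sites",
        "cir": "mean components implemented / 14",
        "icr_phase2": "phase-II completers / phase-II eligible",
        "outcome_phase2": "eta2(time), weight baseline->1 yr",
        "di_phase2": "mean(sex, age interaction eta2)",
        "scr": "continuing mature sites / mature sites",
    }[name]
    return f"{f} = {r3(getattr(c, name))}"


def build_report(
    dataset: CohortDataset | None,
    components: ComponentValues,
    indices: ReaimIndices,
    provenance: Mapping[str, str] | None = None,
    extra_provenance: Mapping[str, Any] | None = None,
) -> EvaluationReport:
    """Assemble the full evaluation report.

    ``dataset`` may be ``None`` when only externally supplied components
    are evaluated (no descriptive or completion tables in that case).
    """
    component_table = [
        {"component": label, "formula": _formula(name, components),
         "value": round(getattr(components, name), 3),
         "source": (provenance or {}).get(name, "supplied")}
        for name, label in _COMPONENT_ROWS
    ]
    index_table = [
        {"index": label, "value": round(getattr(indices, name), 1)}
        for name, label in _INDEX_ROWS
    ]
    prov: dict[str, Any] = {"software_version": __version__}
    if extra_provenance:
        prov.update(extra_provenance)
    if dataset is not None:
        prov["config_hash"] = _dataset_hash(dataset)
    return EvaluationReport(
        component_table=component_table,
        index_table=index_table,
        descriptive_tables=_descriptives(dataset) if dataset else {},
        completion_table=_completion(dataset) if dataset else [],
        provenance=prov,
    )


def _summary_cell(values: Sequence[float]) -> dict[str, Any] | None:
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        return None  # rendered as a not-available marker
    s = summarize(vals)
    cell = {"n": s.n, "style": s.style, "central": round(s.central, 1)}
    if s.style == "median_iqr":
        cell["q25"] = round(s.spread_low, 1)
        cell["q75"] = round(s.spread_high, 1)
    else:
        cell["sd"] = round(s.sd, 1)
    return cell


def _descriptives(dataset: CohortDataset) -> dict[str, Any]:
    """Baseline and end-of-phase summaries per sex, with change columns."""
    out: dict[str, Any] = {}
    by_sex: dict[str, list[ParticipantRecord]] = {"female": [], "male": []}
    for p in dataset.participants:
        by_sex[p.sex.value].append(p)
    for sex, people in by_sex.items():
        tables: dict[str, Any] = {}
        for tp_name, tp, flag in (
                ("baseline", Timepoint.BASELINE, None),
                ("end_phase1", Timepoint.END_PHASE1, "completed_phase1"),
                ("end_phase2", Timepoint.END_PHASE2, "completed_phase2")):
            rows = {}
            subset = [p for p in people if flag is None or getattr(p, flag)]
            for fld, label in _MEASURES:
                vals = [getattr(p.measurement(tp), fld) for p in subset]
                row: dict[str, Any] = {"value": _summary_cell(vals)}
                if tp is not Timepoint.BASELINE:
                    changes, pct = [], []
                    for p in subset:
                        b = getattr(p.measurement(Timepoint.BASELINE), fld)
                        f = getattr(p.measurement(tp), fld)
                        if b is None or f is None:
                            continue
                        changes.append(f - b)
                        if fld == "weight_lb":
                            pct.append((f - b) / b * 100.0)
                    row["change"] = _summary_cell(changes)
                    if fld == "weight_lb":
                        # percent change is per participant, then summarized
                        row["change_pct"] = _summary_cell(pct)
                rows[label] = row
            tables[tp_name] = rows
        out[sex] = tables
    return out


def _completion(dataset: CohortDataset) -> list[dict[str, Any]]:
    rows = []
    for phase, flag in ((1, "completed_phase1"), (2, "completed_phase2")):
        eligible = dataset.phase_eligible_participants(phase)
        cells: dict[tuple[str, str], list[ParticipantRecord]] = {}
        for p in eligible:
            cells.setdefault((p.sex.value, p.age_group), []).append(p)
        for sex in ("female", "male"):
            for ag in AGE_GROUP_LABELS:
                people = cells.get((sex, ag), [])
                if not people:
                    continue
                done = sum(getattr(p, flag) for p in people)
                rows.append({
                    "phase": phase, "sex": sex, "age_group": ag,
                    "n_eligible": len(people), "n_completed": done,
                    "rate_pct": round(100.0 * done / len(people), 1),
                })
        done_all = sum(getattr(p, flag) for p in eligible)
        if eligible:
            rows.append({
                "phase": phase, "sex": "all", "age_group": "all",
                "n_eligible": len(eligible), "n_completed": done_all,
                "rate_pct": round(100.0 * done_all / len(eligible), 1),
            })
    return rows


def _dataset_hash(dataset: CohortDataset) -> str:
    h = hashlib.sha256()
    h.update(str(len(dataset.participants)).encode())
    h.update(str(len(dataset.sites)).encode())
    h.update(dataset.data_collection_date.isoformat().encode())
    for p in dataset.participants[:100]:
        h.update(p.participant_id.encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# plain-text rendering


def _fmt_cell(cell: dict[str, Any] | None) -> str:
    if cell is None:
        return "NA"
    if cell["style"] == "median_iqr":
        return f"{cell['central']:.1f} ({cell['q25']:.1f} to {cell['q75']:.1f})"
    return f"{cell['central']:.1f} ({cell['sd']:.1f})"


def _rule(widths: Sequence[int]) -> str:
    return "-+-".join("-" * w for w in widths)


def _table(headers: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    widths = [max(len(str(h)), *(len(str(r[i])) for r in rows)) if rows else len(h)
              for i, h in enumerate(headers)]
    lines = [" | ".join(str(h).ljust(w) for h, w in zip(headers, widths)),
             _rule(widths)]
    for r in rows:
        lines.append(" | ".join(str(c).ljust(w) for c, w in zip(r, widths)))
    return "\n".join(lines)


def render_text(report: EvaluationReport) -> str:
    """Render the report as aligned plain-text tables."""
    parts = ["RE-AIM component and index values", ""]
    parts.append(_table(
        ["Component", "Definition", "Value", "Source"],
        [[r["component"], r["formula"], f"{r['value']:.3f}", r["source"]]
         for r in report.component_table]))
    parts += ["", _table(
        ["Index", "Value"],
        [[r["index"], f"{r['value']:.1f}"] for r in report.index_table])]
    if report.completion_table:
        parts += ["", "Completion by phase, sex and age group", "", _table(
            ["Phase", "Sex", "Age group", "Eligible", "Completed", "Rate %"],
            [[r["phase"], r["sex"], r["age_group"], r["n_eligible"],
              r["n_completed"], f"{r['rate_pct']:.1f}"]
             for r in report.completion_table])]
    for sex, tables in report.descriptive_tables.items():
        for tp_name, rows in tables.items():
            header = f"{sex.capitalize()} - {tp_name.replace('_', ' ')}"
            body = []
            for label, row in rows.items():
                line = [label, _fmt_cell(row["value"])]
                if "change" in row:
                    line.append(_fmt_cell(row["change"]))
                else:
                    line.append("")
                body.append(line)
            parts += ["", header, "", _table(
                ["Measurement", "Value", "Change from baseline"], body)]
    parts += ["", f"Provenance: {json.dumps(report.provenance, sort_keys=True)}"]
    return "\n".join(parts)
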