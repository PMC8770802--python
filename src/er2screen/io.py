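"""Cohort CSV I/O, pipeline configuration, and report rendering.

The cohort file is a plain CSV, one row per ED visitor::

    id,age,sex,lives_at_home,home_support,polypharmacy,walking_aid,
    temporal_disorientation,visit_reason,triage_level,mnd_diagnosis,admitted

Booleans are encoded ``yes``/``no`` (mirroring the instrument's closed
questions); a missing answer is an empty field. Lines starting with ``#``
are comments (the writer records the generator seed in one).

:func:`run_pipeline` ties the stages together: score -> 2x2 tables ->
performance panel -> odds ratios -> baseline comparisons, and renders a
JSON report (exact fractions alongside rounded display values) plus a
markdown summary. Reports are byte-reproducible for a fixed input and
configuration.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from ._format import fraction_payload, round_half_up
from .association import logistic_fit_binary, odds_ratio_2x2, table1_summary
from .cohort import (
    CohortModel,
    PatientRecord,
    cohort_to_frame,
    fixture_table1,
    generate_cohort,
)
from .diagnostics import ConfusionTable, build_confusion, diagnostic_performance
from .instrument import ER2Items

__all__ = [
    "COHORT_COLUMNS",
    "SchemaError",
    "PipelineConfig",
    "AnalysisReport",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = (
    "id",
    "age",
    "sex",
    "lives_at_home",
    "home_support",
    "polypharmacy",
    "walking_aid",
    "temporal_disorientation",
    "visit_reason",
    "triage_level",
    "mnd_diagnosis",
    "admitted",
)

_BOOL = {"yes": True, "no": False}


class SchemaError(ValueError):
    """The cohort file header does not match the expected schema."""


def _parse_bool(value: str, column: str, *, allow_missing: bool = False):
    v = value.strip().lower()
    if v == "" and allow_missing:
        return None
    if v not in _BOOL:
        raise ValueError(f"column {column!r}: {value!r} is not yes/no")
    return _BOOL[v]


def _record_from_row(row: dict[str, str]) -> PatientRecord:
    age = float(row["age"])
    sex = row["sex"].strip().lower()
    if sex not in ("male", "female"):
        raise ValueError(f"column 'sex': {row['sex']!r} is not male/female")
    items = ER2Items(
        age_85_plus=age >= 85,
        male=sex == "male",
        polypharmacy=_parse_bool(row["polypharmacy"], "polypharmacy", allow_missing=True),
        home_support=_parse_bool(row["home_support"], "home_support", allow_missing=True),
        walking_aid=_parse_bool(row["walking_aid"], "walking_aid", allow_missing=True),
        temporal_disorientation=_parse_bool(
            row["temporal_disorientation"], "temporal_disorientation", allow_missing=True
        ),
    )
    return PatientRecord(
        id=int(row["id"]),
        age=age,
        sex=sex,
        lives_at_home=_parse_bool(row["lives_at_home"], "lives_at_home"),
        visit_reason=row["visit_reason"].strip(),
        triage_level=int(row["triage_level"]),
        er2_items=items,
        mnd_diagnosis=_parse_bool(row["mnd_diagnosis"], "mnd_diagnosis"),
        admitted=_parse_bool(row["admitted"], "admitted"),
    )


def read_cohort(
    path: str | Path, *, return_diagnostics: bool = False
):
    """Read a cohort CSV into typed records.

    Malformed rows are rejected with a message citing the row number and
    logged; with ``return_diagnostics=True`` the list of
    ``(row_number, message)`` pairs is returned alongside the records.
    A missing required column raises :class:`SchemaError` naming it.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    header = [h.strip().lower() for h in (reader.fieldnames or [])]
    missing = [c for c in COHORT_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    reader.fieldnames = header

    records: list[PatientRecord] = []
    rejected: list[tuple[int, str]] = []
    for line_no, row in enumerate(reader, start=2):
        try:
            records.append(_record_from_row(row))
        except (ValueError, KeyError) as exc:
            msg = f"row {line_no}: {exc}"
            rejected.append((line_no, msg))
            logger.warning("rejected %s", msg)
    logger.info(
        "read %d rows: %d records, %d rejected",
        len(records) + len(rejected),
        len(records),
        len(rejected),
    )
    if return_diagnostics:
        return records, rejected
    return records


def _bool_str(value) -> str:
    if value is None:
        return ""
    return "yes" if value else "no"


def write_cohort(
    cohort: Sequence[PatientRecord], path: str | Path, *, seed: int | None = None
) -> None:
    """Write records as cohort CSV; the seed is recorded in a comment line."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in cohort:
            writer.writerow(
                [
                    r.id,
                    r.age,
                    r.sex,
                    _bool_str(r.lives_at_home),
                    _bool_str(r.er2_items.home_support),
                    _bool_str(r.er2_items.polypharmacy),
                    _bool_str(r.er2_items.walking_aid),
                    _bool_str(r.er2_items.temporal_disorientation),
                    r.visit_reason,
                    r.triage_level,
                    _bool_str(r.mnd_diagnosis),
                    _bool_str(r.admitted),
                ]
            )


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one analysis run.

    Exactly one input source must be set: an ``input_csv`` path, a
    synthetic ``model`` (with a seed), or ``use_fixture_counts`` for the
    frozen published cross-tabulations.
    """

    input_csv: str | Path | None = None
    model: CohortModel | None = None
    use_fixture_counts: bool = False
    seed: int | None = None
    ci_method: str = "wilson"
    or_method: str = "woolf"  # "woolf" | "logistic" — which leads table3
    yates: bool = False
    welch: bool = False
    out_json: str | Path | None = None
    out_md: str | Path | None = None


@dataclass(frozen=True)
class AnalysisReport:
    """Structured report plus its rendered JSON bytes and markdown."""

    sections: dict
    json_bytes: bytes
    markdown: str


HIGH_RISK_PPV_NOTE = (
    "known inconsistency in the source cohort table: the published PPV for "
    "the high-risk level (0.59) is not derivable from the published counts "
    "(340/684 = 0.50); the count-based value is reported"
)


def _performance_section(table: ConfusionTable, ci_method: str) -> dict:
    perf = diagnostic_performance(table, ci_method=ci_method)
    section: dict = {
        "counts": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "prevalence": fraction_payload(perf.prevalence, 3),
        "ci_method": perf.ci_method,
        "undefined": list(perf.undefined),
        "metrics": {},
        "notes": [
            "inv_lr_neg is specificity/(1-sensitivity), the reciprocal of the "
            "conventional negative likelihood ratio; reports quoting values "
            ">1 for the 'negative likelihood ratio' use this convention"
        ],
    }
    for name in (
        "sensitivity",
        "specificity",
        "ppv",
        "npv",
        "lr_pos",
        "lr_neg",
        "inv_lr_neg",
        "auroc",
    ):
        value = getattr(perf, name)
        payload = fraction_payload(value, 2)
        if payload is not None and name in perf.ci:
            lo, hi = perf.ci[name]
            payload["ci95"] = [round(lo, 4), round(hi, 4)]
        section["metrics"][name] = payload
    return section


def _association_section(table: ConfusionTable, or_method: str) -> dict:
    woolf = odds_ratio_2x2(table)
    logistic = logistic_fit_binary(table)
    lead = woolf if or_method == "woolf" else logistic
    section = {"lead_method": lead.method}
    for est in (woolf, logistic):
        key = "woolf" if est.method == "woolf_closed_form" else "logistic"
        section[key] = {
            "odds_ratio": {"value": est.odds_ratio, "display": round_half_up(est.odds_ratio, 1)},
            "ci95": {
                "low": {"value": est.ci_low, "display": round_half_up(est.ci_low, 1)},
                "high": {"value": est.ci_high, "display": round_half_up(est.ci_high, 1)},
            },
            "log_or": est.log_or,
            "se_log_or": est.se_log_or,
            "p_value": est.p_value,
        }
    return section


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run the full analysis and render the report.

    With patient-level input (CSV or synthetic model) the report carries a
    baseline-comparison section, the two accuracy panels (ER² high-risk
    level and temporal-disorientation item), and both odds-ratio routes.
    With the frozen fixture counts only the 2x2-derived sections appear.
    """
    sources = [
        config.input_csv is not None,
        config.model is not None,
        config.use_fixture_counts,
    ]
    if sum(sources) != 1:
        raise ValueError(
            "configuration error: exactly one of input_csv, model, "
            "use_fixture_counts must be set"
        )

    sections: dict = {
        "provenance": {
            "package": "er2screen",
            "version": __version__,
            "seed": config.seed,
            "ci_method": config.ci_method,
            "or_method": config.or_method,
        }
    }

    if config.use_fixture_counts:
        fx = fixture_table1()
        high, temporal = fx.high_risk, fx.temporal
        sections["provenance"]["source"] = "fixture_table1"
        sections["table1"] = {
            "group_sizes": {"mnd_present": fx.n_mnd, "mnd_absent": fx.n_no_mnd},
            "high_risk_counts": {
                "present": high.tp,
                "absent": high.fp,
                "present_pct": round_half_up(100 * high.tp / fx.n_mnd, 1),
                "absent_pct": round_half_up(100 * high.fp / fx.n_no_mnd, 1),
            },
            "temporal_counts": {
                "present": temporal.tp,
                "absent": temporal.fp,
                "present_pct": round_half_up(100 * temporal.tp / fx.n_mnd, 1),
                "absent_pct": round_half_up(100 * temporal.fp / fx.n_no_mnd, 1),
            },
        }
    else:
        if config.input_csv is not None:
            path = Path(config.input_csv)
            cohort = read_cohort(path)
            sections["provenance"]["source"] = f"csv:{path.name}"
            sections["provenance"]["input_sha256"] = _file_sha256(path)
        else:
            if config.seed is None and config.model.seed is None:
                raise ValueError("synthetic input needs a seed")
            cohort = generate_cohort(config.model, seed=config.seed)
            sections["provenance"]["source"] = "synthetic"
        frame = cohort_to_frame(cohort)
        comparisons, md_table1 = table1_summary(
            frame, yates=config.yates, welch=config.welch
        )
        sections["table1"] = {
            "group_sizes": {
                "mnd_present": int(frame["mnd_diagnosis"].sum()),
                "mnd_absent": int((~frame["mnd_diagnosis"]).sum()),
            },
            "comparisons": [
                {
                    "variable": c.variable,
                    "kind": c.kind,
                    "test": c.test,
                    "statistic": c.statistic,
                    "df": c.df,
                    "p_value": c.p_value,
                    "summaries": c.summaries,
                    "warnings": list(c.warnings),
                }
                for c in comparisons
            ],
            "markdown": md_table1,
        }
        high = build_confusion(cohort, "er2_high_risk")
        temporal = build_confusion(cohort, "temporal_disorientation")

    sections["table2"] = {
        "high_risk_level": _performance_section(high, config.ci_method),
        "temporal_disorientation": _performance_section(temporal, config.ci_method),
    }
    sections["table2"]["high_risk_level"]["notes"].append(HIGH_RISK_PPV_NOTE)
    sections["table3"] = {
        "high_risk_level": _association_section(high, config.or_method),
        "temporal_disorientation": _association_section(temporal, config.or_method),
    }

    json_bytes = json.dumps(sections, indent=2, sort_keys=False).encode()
    markdown = _render_markdown(sections)
    if config.out_json is not None:
        Path(config.out_json).write_bytes(json_bytes)
    if config.out_md is not None:
        Path(config.out_md).write_text(markdown)
    return AnalysisReport(sections=sections, json_bytes=json_bytes, markdown=markdown)


_METRIC_LABELS = {
    "sensitivity": "Sensitivity",
    "specificity": "Specificity",
    "ppv": "Positive predictive value",
    "npv": "Negative predictive value",
    "lr_pos": "LR+ (sens/(1-spec))",
    "lr_neg": "LR- ((1-sens)/spec)",
    "inv_lr_neg": "1/LR- (spec/(1-sens))",
    "auroc": "AUROC",
}


def _render_markdown(sections: dict) -> str:
    lines = ["# ER² screening accuracy report", ""]
    prov = sections["provenance"]
    lines.append(
        f"source: {prov['source']} | seed: {prov['seed']} | "
        f"CI method: {prov['ci_method']} | version: {prov['version']}"
    )
    lines.append("")
    if "markdown" in sections.get("table1", {}):
        lines += ["## Baseline characteristics", "", sections["table1"]["markdown"], ""]
    lines += [
        "## Diagnostic performance",
        "",
        "| Metric | High-risk level | Temporal disorientation |",
        "|---|---|---|",
    ]
    t2 = sections["table2"]
    for key, label in _METRIC_LABELS.items():
        row = []
        for screen in ("high_risk_level", "temporal_disorientation"):
            m = t2[screen]["metrics"][key]
            row.append("undefined" if m is None else f"{m['display']:.2f}")
        lines.append(f"| {label} | {row[0]} | {row[1]} |")
    lines.append("")
    for note in t2["high_risk_level"]["notes"]:
        lines.append(f"> {note}")
        lines.append("")
    lines += [
        "## Unadjusted odds ratios (MND ~ screen)",
        "",
        "| Screen | OR | 95% CI | method |",
        "|---|---|---|---|",
    ]
    for screen, label in (
        ("high_risk_level", "ER² high-risk level"),
        ("temporal_disorientation", "Temporal disorientation item"),
    ):
        sec = sections["table3"][screen]
        key = "woolf" if sec["lead_method"] == "woolf_closed_form" else "logistic"
        est = sec[key]
        lines.append(
            f"| {label} | {est['odds_ratio']['display']:.1f} "
            f"| [{est['ci95']['low']['display']:.1f}; "
            f"{est['ci95']['high']['display']:.1f}] | {key} |"
        )
    lines.append("")
    return "\n".join(lines)
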