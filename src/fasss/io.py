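"""CSV/JSON/YAML interchange for annotations, score sheets and reports.

Annotation CSV (long format, one row per observed lesion or DVU exclusion):
    record_type{lesion|dvu_exclusion|exam}, patient_id, exam_time_years,
    reader_id, dvu, endplate, region, slice_domain, size_grade,
    cortex_large{0|1|NA}, midpoint_large{0|1|NA}
Fields not applicable to a record type are left empty. Input is sparse:
absent sites are simply absent rows. An ``exam`` row marks an exam with no
findings at all (a lesion-free read), which would otherwise be invisible
in the sparse long format; writers emit it only for such exams.

Score sheet CSV: patient_id, exam_time_years, reader_id, total, cervical,
thoracic, lumbar, then the 23 per-DVU columns named by DVU code, then
excluded_dvus (semicolon-joined codes).

Statistics are serialized at 4 decimal places, scores as integers, for
reproducible diffs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .anatomy import (
    DVU,
    Endplate,
    LesionSite,
    Region,
    SliceDomain,
    enumerate_dvus,
    parse_dvu,
)
from .reliability import ReliabilityResults, StratumSpec, default_strata
from .scoring import (
    AnnotationError,
    ChangeRecord,
    ExamAnnotationSet,
    ExamScoreSheet,
    LesionAnnotation,
    SizeGrade,
    validate_annotations,
)
from .simulate import CohortParams, ReaderErrorParams

__all__ = [
    "ANNOTATION_COLUMNS",
    "read_annotations",
    "write_annotations",
    "read_score_sheets",
    "write_score_sheets",
    "write_change_records",
    "read_change_records",
    "write_reliability_report",
    "RunConfig",
    "load_simulation_config",
]

ANNOTATION_COLUMNS = [
    "record_type",
    "patient_id",
    "exam_time_years",
    "reader_id",
    "dvu",
    "endplate",
    "region",
    "slice_domain",
    "size_grade",
    "cortex_large",
    "midpoint_large",
]

SCORE_SHEET_COLUMNS = [
    "patient_id",
    "exam_time_years",
    "reader_id",
    "total",
    "cervical",
    "thoracic",
    "lumbar",
    *[d.code for d in enumerate_dvus()],
    "excluded_dvus",
]

CHANGE_COLUMNS = [
    "patient_id",
    "reader_id",
    "interval_years",
    "delta_total",
    "delta_cervical",
    "delta_thoracic",
    "delta_lumbar",
]


class AnnotationFileError(ValueError):
    """A malformed annotation file; message carries 1-based line numbers."""


def _parse_flag(raw: str, line_no: int, name: str) -> bool:
    if raw in ("", "NA", "na", None):
        return False
    if raw in ("0", "1"):
        return raw == "1"
    raise AnnotationFileError(f"line {line_no}: {name} must be 0, 1 or NA, got {raw!r}")


def _parse_lesion_row(row: dict, line_no: int) -> LesionAnnotation:
    try:
        dvu = parse_dvu(row["dvu"])
    except ValueError as e:
        raise AnnotationFileError(f"line {line_no}: {e}") from None
    try:
        site = LesionSite(
            dvu,
            Endplate(row["endplate"]),
            Region(row["region"]),
            SliceDomain(row["slice_domain"]),
        )
        grade = SizeGrade(row["size_grade"])
    except ValueError as e:
        raise AnnotationFileError(f"line {line_no}: {e}") from None
    return LesionAnnotation(
        site,
        grade,
        cortex_large=_parse_flag(row.get("cortex_large", ""), line_no, "cortex_large"),
        midpoint_large=_parse_flag(
            row.get("midpoint_large", ""), line_no, "midpoint_large"
        ),
    )


def read_annotations(path, validate: bool = True) -> list[ExamAnnotationSet]:
    """Read an annotation CSV into exam sets grouped by (patient, time, reader).

    Raises :class:`AnnotationFileError` (with 1-based line numbers) on
    malformed rows and :class:`~fasss.scoring.AnnotationError` if
    ``validate`` and any exam has schema violations.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFileError(f"missing annotation columns: {missing}")
    exams: dict[tuple, ExamAnnotationSet] = {}
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # 1-based, after the header line
        try:
            t = float(row["exam_time_years"])
        except ValueError:
            raise AnnotationFileError(
                f"line {line_no}: bad exam_time_years {row['exam_time_years']!r}"
            ) from None
        key = (row["patient_id"], t, row["reader_id"])
        exam = exams.setdefault(
            key,
            ExamAnnotationSet(
                patient_id=row["patient_id"], exam_time=t, reader_id=row["reader_id"]
            ),
        )
        kind = row["record_type"]
        if kind == "exam":
            continue  # marker row; the exam itself was registered above
        if kind == "lesion":
            exam.lesions.append(_parse_lesion_row(dict(row), line_no))
        elif kind == "dvu_exclusion":
            try:
                dvu = parse_dvu(row["dvu"])
            except ValueError as e:
                raise AnnotationFileError(f"line {line_no}: {e}") from None
            exam.excluded_dvus = exam.excluded_dvus | {dvu}
        else:
            raise AnnotationFileError(
                f"line {line_no}: unknown record_type {kind!r}"
            )
    result = list(exams.values())
    if validate:
        all_violations = []
        for exam in result:
            for v in validate_annotations(exam):
                all_violations.append(
                    type(v)(
                        f"{exam.patient_id} t={exam.exam_time} "
                        f"{exam.reader_id}: {v.message}",
                        site=v.site,
                        dvu=v.dvu,
                    )
                )
        if all_violations:
            raise AnnotationError(all_violations)
    return result


def write_annotations(exams: list[ExamAnnotationSet], path) -> None:
    rows = []
    for exam in exams:
        head = {
            "patient_id": exam.patient_id,
            "exam_time_years": exam.exam_time,
            "reader_id": exam.reader_id,
        }
        if not exam.lesions and not exam.excluded_dvus:
            rows.append(
                {
                    "record_type": "exam",
                    **head,
                    **{c: "" for c in ANNOTATION_COLUMNS[4:]},
                }
            )
            continue
        for dvu in sorted(exam.excluded_dvus, key=lambda d: d.upper_level.index):
            rows.append(
                {
                    "record_type": "dvu_exclusion",
                    **head,
                    "dvu": dvu.code,
                    "endplate": "",
                    "region": "",
                    "slice_domain": "",
                    "size_grade": "",
                    "cortex_large": "",
                    "midpoint_large": "",
                }
            )
        for ann in exam.lesions:
            combined = ann.size_grade is SizeGrade.PRESENT_COMBINED
            rows.append(
                {
                    "record_type": "lesion",
                    **head,
                    "dvu": ann.site.dvu.code,
                    "endplate": ann.site.endplate.value,
                    "region": ann.site.region.value,
                    "slice_domain": ann.site.slice_domain.value,
                    "size_grade": ann.size_grade.value,
                    "cortex_large": int(ann.cortex_large) if combined else "NA",
                    "midpoint_large": int(ann.midpoint_large) if combined else "NA",
                }
            )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def write_score_sheets(sheets: list[ExamScoreSheet], path) -> None:
    rows = []
    for s in sheets:
        row = {
            "patient_id": s.patient_id,
            "exam_time_years": s.exam_time,
            "reader_id": s.reader_id,
            "total": s.total,
            "cervical": s.cervical,
            "thoracic": s.thoracic,
            "lumbar": s.lumbar,
            **s.per_dvu,
            "excluded_dvus": ";".join(
                sorted((d.code for d in s.excluded_dvus))
            ),
        }
        rows.append(row)
    pd.DataFrame(rows, columns=SCORE_SHEET_COLUMNS).to_csv(path, index=False)


def read_score_sheets(path) -> list[ExamScoreSheet]:
    df = pd.read_csv(path, dtype={"patient_id": str, "reader_id": str}, keep_default_na=False)
    sheets = []
    for _, row in df.iterrows():
        excluded = frozenset(
            parse_dvu(c) for c in str(row["excluded_dvus"]).split(";") if c
        )
        sheets.append(
            ExamScoreSheet(
                patient_id=row["patient_id"],
                exam_time=float(row["exam_time_years"]),
                reader_id=row["reader_id"],
                per_dvu={d.code: int(row[d.code]) for d in enumerate_dvus()},
                cervical=int(row["cervical"]),
                thoracic=int(row["thoracic"]),
                lumbar=int(row["lumbar"]),
                total=int(row["total"]),
                excluded_dvus=excluded,
            )
        )
    return sheets


def write_change_records(records: list[ChangeRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "reader_id": r.reader_id,
            "interval_years": round(r.interval_years, 4),
            "delta_total": r.delta_total,
            "delta_cervical": r.delta_cervical,
            "delta_thoracic": r.delta_thoracic,
            "delta_lumbar": r.delta_lumbar,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CHANGE_COLUMNS).to_csv(path, index=False)


def read_change_records(path) -> list[ChangeRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str, "reader_id": str})
    return [
        ChangeRecord(
            patient_id=row["patient_id"],
            reader_id=row["reader_id"],
            interval_years=float(row["interval_years"]),
            delta_total=int(row["delta_total"]),
            delta_cervical=int(row["delta_cervical"]),
            delta_thoracic=int(row["delta_thoracic"]),
            delta_lumbar=int(row["delta_lumbar"]),
        )
        for _, row in df.iterrows()
    ]


def write_reliability_report(
    results: ReliabilityResults, json_path=None, csv_path=None,
    points_path=None,
) -> dict:
    """Write the fitted reliability report as JSON and/or tidy CSVs.

    The CSV has one row per (population, statistic); ``points_path`` gets
    the Bland–Altman and cumulative-probability point sets for external
    plotting. Returns the JSON-shaped report dict.
    """
    report = results.to_report()
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2)
    if csv_path is not None:
        rows = []
        for pop in ("status", "change"):
            blk = report.get(f"icc_{pop}")
            if blk:
                rows.append(
                    {
                        "population": pop,
                        "n": blk["n"],
                        "statistic": "icc_a1",
                        "estimate": blk["estimate"],
                        "ci_low": blk["ci_low"],
                        "ci_high": blk["ci_high"],
                        "band": blk["band"],
                    }
                )
            ba = report.get(f"bland_altman_{pop}")
            if ba:
                rows.append(
                    {
                        "population": pop,
                        "n": ba["n"],
                        "statistic": f"loa_{int(ba['coverage']*100)}",
                        "estimate": ba["mean_diff"],
                        "ci_low": ba["loa_low"],
                        "ci_high": ba["loa_high"],
                        "band": "",
                    }
                )
        if report.get("sdc"):
            rows.append(
                {
                    "population": "change",
                    "n": report["sdc"]["n"],
                    "statistic": "sdc",
                    "estimate": report["sdc"]["value"],
                    "ci_low": "",
                    "ci_high": "",
                    "band": "",
                }
            )
        for s in report.get("strata", []) or []:
            if s["icc_status"]:
                rows.append(
                    {
                        "population": f"stratum {s['label']}",
                        "n": s["n"],
                        "statistic": "icc_a1_status",
                        "estimate": s["icc_status"]["estimate"],
                        "ci_low": s["icc_status"]["ci_low"],
                        "ci_high": s["icc_status"]["ci_high"],
                        "band": s["icc_status"]["band"],
                    }
                )
        pd.DataFrame(rows).to_csv(csv_path, index=False)
    if points_path is not None:
        pts = []
        for pop, ba in (
            ("status", results.baseline_agreement),
            ("change", results.change_agreement),
        ):
            if ba is None:
                continue
            for m, d in zip(ba.means, ba.diffs):
                pts.append(
                    {
                        "plot": "bland_altman",
                        "population": pop,
                        "reader": "",
                        "x": round(float(m), 4),
                        "y": round(float(d), 4),
                    }
                )
        for pop in ("baseline", "change"):
            try:
                cp = results.cumulative_probability(pop)
            except ValueError:
                continue
            for rid, pairs in cp.items():
                for prob, val in pairs:
                    pts.append(
                        {
                            "plot": "cumulative_probability",
                            "population": "status" if pop == "baseline" else pop,
                            "reader": rid,
                            "x": round(prob, 4),
                            "y": round(val, 4),
                        }
                    )
        pd.DataFrame(pts).to_csv(points_path, index=False)
    return report


@dataclass
class RunConfig:
    """Effective settings of a command run; defaults match the standard
    analysis (80% limits of agreement, the four interval strata, seed 0)."""

    coverage: float = 0.80
    strata: list[StratumSpec] = field(default_factory=default_strata)
    seed: int = 0
    verbosity: int = 0


def load_simulation_config(path) -> tuple[CohortParams, ReaderErrorParams, ReaderErrorParams]:
    """Load a YAML/JSON simulation config mirroring the parameter dataclasses.

    Structure: top-level ``cohort:`` mapping of CohortParams fields (segment
    and site-type weights keyed by name) and ``readers:`` list of two
    ReaderErrorParams mappings. All fields optional; defaults apply.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cohort_doc = dict(doc.get("cohort", {}))
    from .anatomy import Segment

    if "segment_weights" in cohort_doc:
        cohort_doc["segment_weights"] = {
            Segment(k): float(v) for k, v in cohort_doc["segment_weights"].items()
        }
    cohort = CohortParams(**cohort_doc)
    readers_doc = doc.get("readers", [{}, {}])
    if len(readers_doc) != 2:
        raise ValueError("config must define exactly two readers")
    readers = []
    for i, rdoc in enumerate(readers_doc):
        rdoc = dict(rdoc)
        rdoc.setdefault("seed_offset", i + 1)
        readers.append(ReaderErrorParams(**rdoc))
    return cohort, readers[0], readers[1]
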