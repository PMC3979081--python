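"""FASSS scoring engine: annotations for one exam -> per-DVU, segmental and
total scores, and paired change scores.

Scoring rules
-------------
Corner fat lesions on central or lateral slices are scored dichotomously
(present = 1). In thoracic and lumbar (not cervical) DVUs a central corner
lesion gains +1 if large (involves >=25% of the anterior-posterior endplate
diameter and/or vertebral body height). Noncorner lesions are scored only
on central slices (present = 2), with +2 if large (>=25% of body height) in
thoracic/lumbar DVUs. A central corner lesion spanning >50% of the
anterior-posterior diameter is a *combined* corner-and-noncorner lesion: it
scores a corner component of 1 (+1 if the lesion reaches >=25% of body
height at the anterior or posterior cortex) and credits the endplate's
noncorner site with 2 (+2 if >=25% of height at the endplate midpoint).
Cervical lesions carry presence only (no size grading, no lateral slices).
Per endplate the noncorner component is counted once — the maximum credit
among a direct noncorner annotation and any combined corners wins — so the
per-DVU maxima (24 thoracolumbar = 16 central + 8 lateral; 8 cervical) are
never exceeded. DVUs whose disc height is unequivocally reduced by >=50%
are excluded: they score 0 and stay flagged in the output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .anatomy import (
    DVU,
    Endplate,
    LesionSite,
    Region,
    Segment,
    SliceDomain,
    enumerate_dvus,
    enumerate_sites,
    max_dvu_score,
)

__all__ = [
    "SizeGrade",
    "LesionAnnotation",
    "ExamAnnotationSet",
    "ExamScoreSheet",
    "ChangeRecord",
    "Violation",
    "AnnotationError",
    "score_site",
    "noncorner_credit",
    "score_dvu",
    "score_exam",
    "change_score",
    "validate_annotations",
    "saturated_exam",
]


class SizeGrade(str, enum.Enum):
    PRESENT = "present"                    # lateral corners; all cervical sites
    PRESENT_SMALL = "present_small"        # thoracolumbar central sites
    PRESENT_LARGE = "present_large"
    PRESENT_COMBINED = "present_combined"  # thoracolumbar central corners only


@dataclass(frozen=True)
class LesionAnnotation:
    """One reader's finding at one anatomical site.

    ``cortex_large`` / ``midpoint_large`` are meaningful only for
    ``PRESENT_COMBINED`` (lesion involves >=25% of vertebral body height at
    the anterior/posterior cortex, resp. at the endplate midpoint).
    """

    site: LesionSite
    size_grade: SizeGrade
    cortex_large: bool = False
    midpoint_large: bool = False


@dataclass(frozen=True)
class Violation:
    """A schema violation found during validation; data, not an exception."""

    message: str
    site: LesionSite | None = None
    dvu: DVU | None = None

    def __str__(self) -> str:
        loc = self.site or self.dvu
        return f"{loc}: {self.message}" if loc is not None else self.message


class AnnotationError(ValueError):
    """Raised when scoring is attempted on an invalid annotation set."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "invalid annotation set:\n" + "\n".join(f"  - {v}" for v in violations)
        )


@dataclass
class ExamAnnotationSet:
    """All of one reader's lesion annotations for one (patient, timepoint).

    Input is sparse: only observed lesions are recorded; absent sites score 0.
    """

    patient_id: str
    exam_time: float  # years from baseline
    reader_id: str
    lesions: list[LesionAnnotation] = field(default_factory=list)
    excluded_dvus: frozenset[DVU] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ExamScoreSheet:
    patient_id: str
    exam_time: float
    reader_id: str
    per_dvu: dict[str, int]  # DVU code -> score, all 23 DVUs
    cervical: int
    thoracic: int
    lumbar: int
    total: int
    excluded_dvus: frozenset[DVU] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ChangeRecord:
    patient_id: str
    reader_id: str
    interval_years: float
    delta_total: int
    delta_cervical: int
    delta_thoracic: int
    delta_lumbar: int


def _allowed_grades(site: LesionSite) -> frozenset[SizeGrade]:
    if site.dvu.segment is Segment.CERVICAL:
        return frozenset({SizeGrade.PRESENT})
    if site.slice_domain is not SliceDomain.CENTRAL:
        return frozenset({SizeGrade.PRESENT})
    if site.region is Region.NONCORNER:
        return frozenset({SizeGrade.PRESENT_SMALL, SizeGrade.PRESENT_LARGE})
    return frozenset(
        {SizeGrade.PRESENT_SMALL, SizeGrade.PRESENT_LARGE, SizeGrade.PRESENT_COMBINED}
    )


def score_site(annotation: LesionAnnotation) -> int:
    """Direct score of one annotated site.

    For a combined corner lesion this is the *corner* component only
    (1 + 1 if cortex_large); the noncorner credit it generates is applied at
    DVU level (see :func:`noncorner_credit` and :func:`score_dvu`) so that
    each endplate's noncorner component is counted at most once.
    """
    site, grade = annotation.site, annotation.size_grade
    if grade not in _allowed_grades(site):
        raise AnnotationError(
            [Violation(f"size grade {grade.value!r} not allowed here", site=site)]
        )
    if site.dvu.segment is Segment.CERVICAL:
        return 2 if site.region is Region.NONCORNER else 1
    if site.slice_domain is not SliceDomain.CENTRAL:
        return 1  # lateral corners: presence only
    if site.region is Region.NONCORNER:
        return 2 if grade is SizeGrade.PRESENT_SMALL else 4
    if grade is SizeGrade.PRESENT_SMALL:
        return 1
    if grade is SizeGrade.PRESENT_LARGE:
        return 2
    return 1 + (1 if annotation.cortex_large else 0)  # combined, corner part


def noncorner_credit(annotation: LesionAnnotation) -> int:
    """Noncorner-component credit an annotation contributes to its endplate.

    Direct noncorner annotations credit their own score; combined corner
    lesions credit 2 (+2 if midpoint_large); everything else credits 0.
    """
    site, grade = annotation.site, annotation.size_grade
    if site.region is Region.NONCORNER and site.dvu.segment is not Segment.CERVICAL:
        return score_site(annotation)
    if grade is SizeGrade.PRESENT_COMBINED:
        return 2 + (2 if annotation.midpoint_large else 0)
    return 0


def validate_annotations(exam: ExamAnnotationSet) -> list[Violation]:
    """All schema violations in an exam; empty list iff scoreable."""
    violations: list[Violation] = []
    seen: set[tuple[str, str, str, str]] = set()
    valid_sites = {
        s.key for d in enumerate_dvus() for s in enumerate_sites(d)
    }
    for ann in exam.lesions:
        site = ann.site
        if site.key not in valid_sites:
            violations.append(Violation("unknown lesion site", site=site))
            continue
        if site.key in seen:
            violations.append(Violation("duplicate annotation for site", site=site))
        seen.add(site.key)
        if ann.size_grade not in _allowed_grades(site):
            violations.append(
                Violation(
                    f"size grade {ann.size_grade.value!r} not allowed for this "
                    "site type",
                    site=site,
                )
            )
        if site.dvu in exam.excluded_dvus:
            violations.append(
                Violation("annotation on excluded DVU", site=site)
            )
    return violations


def score_dvu(exam: ExamAnnotationSet, dvu: DVU) -> int:
    """Score one DVU: corner components + once-per-endplate noncorner credit.

    Excluded DVUs score 0.
    """
    if dvu in exam.excluded_dvus:
        return 0
    corner_total = 0
    best_noncorner: dict[Endplate, int] = {Endplate.CRANIAL: 0, Endplate.CAUDAL: 0}
    for ann in exam.lesions:
        if ann.site.dvu != dvu:
            continue
        if ann.site.region is Region.NONCORNER and dvu.segment is not Segment.CERVICAL:
            credit = noncorner_credit(ann)
            if credit > best_noncorner[ann.site.endplate]:
                best_noncorner[ann.site.endplate] = credit
        else:
            corner_total += score_site(ann)
            credit = noncorner_credit(ann)
            if credit > best_noncorner[ann.site.endplate]:
                best_noncorner[ann.site.endplate] = credit
    return corner_total + sum(best_noncorner.values())


def score_exam(exam: ExamAnnotationSet) -> ExamScoreSheet:
    """Full score sheet for one exam: 23 per-DVU scores, segments, total."""
    violations = validate_annotations(exam)
    if violations:
        raise AnnotationError(violations)
    per_dvu: dict[str, int] = {}
    seg_totals = {s: 0 for s in Segment}
    for dvu in enumerate_dvus():
        s = score_dvu(exam, dvu)
        assert 0 <= s <= max_dvu_score(dvu)
        per_dvu[dvu.code] = s
        seg_totals[dvu.segment] += s
    return ExamScoreSheet(
        patient_id=exam.patient_id,
        exam_time=exam.exam_time,
        reader_id=exam.reader_id,
        per_dvu=per_dvu,
        cervical=seg_totals[Segment.CERVICAL],
        thoracic=seg_totals[Segment.THORACIC],
        lumbar=seg_totals[Segment.LUMBAR],
        total=sum(seg_totals.values()),
        excluded_dvus=frozenset(exam.excluded_dvus),
    )


def change_score(
    baseline: ExamScoreSheet,
    followup: ExamScoreSheet,
    interval_years: float | None = None,
) -> ChangeRecord:
    """Follow-up minus baseline deltas for the total and each segment."""
    if baseline.patient_id != followup.patient_id:
        raise ValueError(
            f"patient mismatch: {baseline.patient_id!r} vs {followup.patient_id!r}"
        )
    if baseline.reader_id != followup.reader_id:
        raise ValueError(
            f"reader mismatch: {baseline.reader_id!r} vs {followup.reader_id!r}"
        )
    if interval_years is None:
        interval_years = followup.exam_time - baseline.exam_time
    if interval_years <= 0:
        raise ValueError(f"interval_years must be > 0, got {interval_years}")
    return ChangeRecord(
        patient_id=baseline.patient_id,
        reader_id=baseline.reader_id,
        interval_years=interval_years,
        delta_total=followup.total - baseline.total,
        delta_cervical=followup.cervical - baseline.cervical,
        delta_thoracic=followup.thoracic - baseline.thoracic,
        delta_lumbar=followup.lumbar - baseline.lumbar,
    )


def saturated_annotation(site: LesionSite) -> LesionAnnotation:
    """The maximal-grade annotation for a site."""
    grades = _allowed_grades(site)
    if SizeGrade.PRESENT_LARGE in grades:
        return LesionAnnotation(site, SizeGrade.PRESENT_LARGE)
    return LesionAnnotation(site, SizeGrade.PRESENT)


def saturated_exam(
    patient_id: str = "saturated", exam_time: float = 0.0, reader_id: str = "R1"
) -> ExamAnnotationSet:
    """Every site of every DVU annotated at maximal grade; total scores 456."""
    lesions = [
        saturated_annotation(site)
        for dvu in enumerate_dvus()
        for site in enumerate_sites(dvu)
    ]
    return ExamAnnotationSet(patient_id, exam_time, reader_id, lesions)
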