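import random

import pytest

from fasss.anatomy import (
    Endplate,
    LesionSite,
    Region,
    Segment,
    SliceDomain,
    enumerate_dvus,
    enumerate_sites,
    max_dvu_score,
    parse_dvu,
)
from fasss.scoring import (
    AnnotationError,
    ExamAnnotationSet,
    LesionAnnotation,
    SizeGrade,
    change_score,
    saturated_exam,
    score_dvu,
    score_exam,
    score_site,
    validate_annotations,
)

from conftest import central_corner, random_annotation_set


def oracle_dvu_score(exam: ExamAnnotationSet, dvu) -> int:
    """Independent per-DVU scoring by direct enumeration of the rules:
    corners 1 (+1 large in thoracolumbar central), lateral corners 1,
    noncorner 2 (+2 large), combined corners credit the endplate's
    noncorner component, which counts once at its maximum."""
    if dvu in exam.excluded_dvus:
        return 0
    total = 0
    for ep in Endplate:
        anns = [
            a for a in exam.lesions if a.site.dvu == dvu and a.site.endplate is ep
        ]
        noncorner_credits = [0]
        for a in anns:
            if dvu.segment is Segment.CERVICAL:
                total += 2 if a.site.region is Region.NONCORNER else 1
            elif a.site.slice_domain is not SliceDomain.CENTRAL:
                total += 1
            elif a.site.region is Region.NONCORNER:
                noncorner_credits.append(
                    2 + (2 if a.size_grade is SizeGrade.PRESENT_LARGE else 0)
                )
            elif a.size_grade is SizeGrade.PRESENT_COMBINED:
                total += 1 + (1 if a.cortex_large else 0)
                noncorner_credits.append(2 + (2 if a.midpoint_large else 0))
            else:
                total += 1 if a.size_grade is SizeGrade.PRESENT_SMALL else 2
        total += max(noncorner_credits)
    return total


def make_exam(lesions, excluded=frozenset()):
    return ExamAnnotationSet("p1", 0.0, "R1", list(lesions), frozenset(excluded))


def site(code, endplate=Endplate.CRANIAL, region=Region.ANTERIOR_CORNER,
         domain=SliceDomain.CENTRAL):
    return LesionSite(parse_dvu(code), endplate, region, domain)


class TestScoreSite:
    @pytest.mark.parametrize(
        "lesion_site,grade,expected",
        [
            (site("L2/L3"), SizeGrade.PRESENT_SMALL, 1),
            (site("L2/L3"), SizeGrade.PRESENT_LARGE, 2),
            (site("T5/T6", domain=SliceDomain.LATERAL_LEFT), SizeGrade.PRESENT, 1),
            (site("C3/C4"), SizeGrade.PRESENT, 1),
            (site("C3/C4", region=Region.NONCORNER), SizeGrade.PRESENT, 2),
            (site("T5/T6", region=Region.NONCORNER), SizeGrade.PRESENT_SMALL, 2),
            (site("T5/T6", region=Region.NONCORNER), SizeGrade.PRESENT_LARGE, 4),
        ],
    )
    def test_site_weights(self, lesion_site, grade, expected):
        assert score_site(LesionAnnotation(lesion_site, grade)) == expected

    @pytest.mark.parametrize(
        "cortex,corner_part", [(False, 1), (True, 2)]
    )
    def test_combined_corner_component(self, cortex, corner_part):
        ann = LesionAnnotation(
            site("L1/L2"), SizeGrade.PRESENT_COMBINED, cortex_large=cortex
        )
        assert score_site(ann) == corner_part

    @pytest.mark.parametrize(
        "bad",
        [
            LesionAnnotation(site("C3/C4"), SizeGrade.PRESENT_SMALL),
            LesionAnnotation(site("C3/C4"), SizeGrade.PRESENT_COMBINED),
            LesionAnnotation(
                site("T5/T6", domain=SliceDomain.LATERAL_RIGHT),
                SizeGrade.PRESENT_LARGE,
            ),
            LesionAnnotation(
                site("T5/T6", region=Region.NONCORNER), SizeGrade.PRESENT_COMBINED
            ),
            LesionAnnotation(site("T5/T6"), SizeGrade.PRESENT),
        ],
    )
    def test_disallowed_grades_raise(self, bad):
        with pytest.raises(AnnotationError):
            score_site(bad)


class TestScoreDvu:
    def test_worked_example_dvu(self):
        exam = make_exam(
            [
                central_corner("L2/L3", Endplate.CAUDAL, SizeGrade.PRESENT_SMALL),
                central_corner("L2/L3", Endplate.CRANIAL, SizeGrade.PRESENT_LARGE),
            ]
        )
        assert score_dvu(exam, parse_dvu("L2/L3")) == 3

    def test_saturated_maxima_decompose(self):
        dvu = parse_dvu("L2/L3")
        sites = enumerate_sites(dvu)
        central = [s for s in sites if s.slice_domain is SliceDomain.CENTRAL]
        lateral = [s for s in sites if s.slice_domain is not SliceDomain.CENTRAL]

        def saturate(s):
            grade = (
                SizeGrade.PRESENT
                if s.slice_domain is not SliceDomain.CENTRAL
                else SizeGrade.PRESENT_LARGE
            )
            return LesionAnnotation(s, grade)

        assert score_dvu(make_exam(map(saturate, sites)), dvu) == 24
        assert score_dvu(make_exam(map(saturate, central)), dvu) == 16
        assert score_dvu(make_exam(map(saturate, lateral)), dvu) == 8

    def test_saturated_cervical_max(self):
        dvu = parse_dvu("C4/C5")
        anns = [
            LesionAnnotation(s, SizeGrade.PRESENT) for s in enumerate_sites(dvu)
        ]
        assert score_dvu(make_exam(anns), dvu) == 8

    def test_combined_and_direct_noncorner_do_not_double_count(self):
        # combined corner (midpoint large -> credit 4) + direct small
        # noncorner (credit 2) on the same endplate: max wins, not the sum
        combined = LesionAnnotation(
            site("L1/L2"), SizeGrade.PRESENT_COMBINED,
            cortex_large=False, midpoint_large=True,
        )
        direct = LesionAnnotation(
            site("L1/L2", region=Region.NONCORNER), SizeGrade.PRESENT_SMALL
        )
        assert score_dvu(make_exam([combined]), parse_dvu("L1/L2")) == 1 + 4
        assert score_dvu(make_exam([combined, direct]), parse_dvu("L1/L2")) == 1 + 4
        # two combined corners on one endplate still credit noncorner once
        combined2 = LesionAnnotation(
            site("L1/L2", region=Region.POSTERIOR_CORNER),
            SizeGrade.PRESENT_COMBINED, midpoint_large=True,
        )
        assert (
            score_dvu(make_exam([combined, combined2]), parse_dvu("L1/L2")) == 1 + 1 + 4
        )

    def test_excluded_dvu_scores_zero(self):
        dvu = parse_dvu("L2/L3")
        exam = make_exam([], excluded={dvu})
        assert score_dvu(exam, dvu) == 0


class TestScoreExam:
    def test_empty_exam_scores_zero(self):
        sheet = score_exam(make_exam([]))
        assert sheet.total == 0
        assert sheet.cervical == sheet.thoracic == sheet.lumbar == 0
        assert set(sheet.per_dvu) == {d.code for d in enumerate_dvus()}

    def test_saturated_exam_reaches_global_max(self):
        sheet = score_exam(saturated_exam())
        assert sheet.total == 456
        assert sheet.cervical == 6 * 8 == 48
        assert sheet.thoracic == 12 * 24 == 288
        assert sheet.lumbar == 5 * 24 == 120

    def test_worked_example_scores(self, figure_worked_example):
        sheet = score_exam(figure_worked_example)
        window = ["T11/T12", "T12/L1", "L1/L2", "L2/L3"]
        assert [sheet.per_dvu[c] for c in window] == [1, 1, 1, 3]
        assert sum(sheet.per_dvu[c] for c in window) == 6 == sheet.total

    def test_duplicate_annotation_rejected(self):
        ann = central_corner("L2/L3", Endplate.CRANIAL, SizeGrade.PRESENT_SMALL)
        with pytest.raises(AnnotationError) as exc:
            score_exam(make_exam([ann, ann]))
        assert "duplicate" in str(exc.value)

    def test_annotation_on_excluded_dvu_rejected(self):
        ann = central_corner("L2/L3", Endplate.CRANIAL, SizeGrade.PRESENT_SMALL)
        exam = make_exam([ann], excluded={parse_dvu("L2/L3")})
        assert len(validate_annotations(exam)) == 1
        with pytest.raises(AnnotationError):
            score_exam(exam)


class TestValidation:
    def test_lateral_cervical_is_a_violation(self):
        # the site type itself forbids lateral cervical construction
        with pytest.raises(ValueError):
            LesionSite(
                parse_dvu("C3/C4"),
                Endplate.CRANIAL,
                Region.ANTERIOR_CORNER,
                SliceDomain.LATERAL_LEFT,
            )

    def test_clean_worked_example_has_no_violations(self, figure_worked_example):
        assert validate_annotations(figure_worked_example) == []

    def test_violations_are_data_not_exceptions(self):
        bad = LesionAnnotation(site("C3/C4"), SizeGrade.PRESENT_LARGE)
        violations = validate_annotations(make_exam([bad]))
        assert len(violations) == 1 and "size grade" in violations[0].message


class TestChangeScore:
    def test_deltas_and_antisymmetry(self, figure_worked_example):
        a = score_exam(figure_worked_example)
        b = score_exam(saturated_exam("fig-example", 1.5, "R1"))
        fwd = change_score(a, b)
        rev = change_score(b, a, interval_years=1.5)
        assert fwd.delta_total == 456 - 6 == -rev.delta_total
        assert fwd.interval_years == pytest.approx(1.5)
        assert fwd.delta_cervical == -rev.delta_cervical
        same = change_score(a, a, interval_years=1.0)
        assert same.delta_total == same.delta_thoracic == 0

    def test_pairing_contract_enforced(self, figure_worked_example):
        a = score_exam(figure_worked_example)
        other = score_exam(saturated_exam("someone-else", 1.0, "R1"))
        with pytest.raises(ValueError):
            change_score(a, other)
        with pytest.raises(ValueError):
            change_score(a, a)  # zero interval


@pytest.mark.parametrize("seed", range(8))
def test_random_exams_match_bruteforce_oracle(seed):
    """Engine per-DVU scores equal direct rule enumeration; caps and
    additivity hold for arbitrary schema-valid sparse annotation sets."""
    rng = random.Random(seed)
    exam = random_annotation_set(rng, n_lesions=rng.randint(5, 60))
    sheet = score_exam(exam)
    for dvu in enumerate_dvus():
        s = sheet.per_dvu[dvu.code]
        assert s == oracle_dvu_score(exam, dvu)
        assert 0 <= s <= max_dvu_score(dvu)
    assert sheet.total == sum(sheet.per_dvu.values())
    assert sheet.total == sheet.cervical + sheet.thoracic + sheet.lumbar


@pytest.mark.parametrize("seed", range(5))
def test_adding_an_annotation_never_decreases_scores(seed):
    rng = random.Random(1000 + seed)
    exam = random_annotation_set(rng, n_lesions=20)
    base = score_exam(make_exam(exam.lesions[:-1]))
    grown = score_exam(make_exam(exam.lesions))
    assert grown.total >= base.total
    for code in base.per_dvu:
        assert grown.per_dvu[code] >= base.per_dvu[code]
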