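import random

import pytest
from hypothesis import settings

from fasss.anatomy import Endplate, Region, SliceDomain, enumerate_dvus, enumerate_sites, parse_dvu
from fasss.scoring import (
    ExamAnnotationSet,
    LesionAnnotation,
    SizeGrade,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def central_corner(dvu_code: str, endplate: Endplate, grade: SizeGrade,
                   region: Region = Region.ANTERIOR_CORNER) -> LesionAnnotation:
    from fasss.anatomy import LesionSite

    site = LesionSite(parse_dvu(dvu_code), endplate, region, SliceDomain.CENTRAL)
    return LesionAnnotation(site, grade)


@pytest.fixture
def figure_worked_example() -> ExamAnnotationSet:
    """The published single-slice worked example: small anterior corner
    lesions at the upper endplates of T12, L1, L2 and L3 (the caudal
    endplates of T11/T12..L2/L3) plus a large anterior corner lesion at the
    lower endplate of L2 (the cranial endplate of L2/L3)."""
    lesions = [
        central_corner("T11/T12", Endplate.CAUDAL, SizeGrade.PRESENT_SMALL),
        central_corner("T12/L1", Endplate.CAUDAL, SizeGrade.PRESENT_SMALL),
        central_corner("L1/L2", Endplate.CAUDAL, SizeGrade.PRESENT_SMALL),
        central_corner("L2/L3", Endplate.CAUDAL, SizeGrade.PRESENT_SMALL),
        central_corner("L2/L3", Endplate.CRANIAL, SizeGrade.PRESENT_LARGE),
    ]
    return ExamAnnotationSet("fig-example", 0.0, "R1", lesions)


def random_annotation_set(rng: random.Random, n_lesions: int = 30) -> ExamAnnotationSet:
    """A schema-valid random sparse annotation set (test helper)."""
    from fasss.scoring import _allowed_grades

    all_sites = [s for d in enumerate_dvus() for s in enumerate_sites(d)]
    chosen = rng.sample(all_sites, min(n_lesions, len(all_sites)))
    lesions = []
    for site in chosen:
        grade = rng.choice(sorted(_allowed_grades(site), key=lambda g: g.value))
        lesions.append(
            LesionAnnotation(
                site,
                grade,
                cortex_large=(
                    grade is SizeGrade.PRESENT_COMBINED and rng.random() < 0.5
                ),
                midpoint_large=(
                    grade is SizeGrade.PRESENT_COMBINED and rng.random() < 0.5
                ),
            )
        )
    return ExamAnnotationSet("rand", 0.0, "R1", lesions)
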