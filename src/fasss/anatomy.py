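"""Scoreable spinal anatomy for the FAt Spondyloarthritis Spine Score (FASSS).

The scoring unit is the disco-vertebral unit (DVU): the region between
horizontal lines through the midpoints of two adjacent vertebrae on sagittal
MRI. Twenty-three DVUs are assessed, C2/C3 (most cranial) through L5/S1
(most caudal). Each DVU exposes a fixed set of lesion sites:

* two endplates (cranial = lower endplate of the DVU's upper vertebra,
  caudal = upper endplate of the DVU's lower vertebra),
* per endplate on the central sagittal slices: an anterior corner, a
  posterior corner and a noncorner site,
* for thoracic and lumbar DVUs only, per endplate: anterior and posterior
  corner sites on the left and right lateral slices (cervical vertebrae have
  no sagittal slice showing both pedicle and vertebral body, so lateral
  sites do not exist there).

Segment membership partitions the 23 DVUs as 6 cervical (C2/C3..C7/T1),
12 thoracic (T1/T2..T12/L1) and 5 lumbar (L1/L2..L5/S1). The transitional
units C7/T1 and T12/L1 are scored under cervical and thoracic rules
respectively; this is the only partition consistent with the published
global maximum of 456 (6*8 + 17*24).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import total_ordering
from typing import Iterator

__all__ = [
    "Segment",
    "Endplate",
    "Region",
    "SliceDomain",
    "VertebralLevel",
    "DVU",
    "LesionSite",
    "VERTEBRAL_LEVELS",
    "enumerate_dvus",
    "enumerate_sites",
    "max_dvu_score",
    "parse_dvu",
    "TOTAL_MAX_SCORE",
]


class Segment(str, enum.Enum):
    CERVICAL = "cervical"
    THORACIC = "thoracic"
    LUMBAR = "lumbar"


class Endplate(str, enum.Enum):
    """Endplate within a DVU.

    CRANIAL is the lower endplate of the DVU's upper vertebra; CAUDAL is
    the upper endplate of the DVU's lower vertebra. (The bijection to
    vertebra-relative labels: cranial endplate of X/Y == lower endplate of
    vertebra X; caudal endplate of X/Y == upper endplate of vertebra Y.)
    """

    CRANIAL = "cranial"
    CAUDAL = "caudal"


class Region(str, enum.Enum):
    ANTERIOR_CORNER = "anterior_corner"
    POSTERIOR_CORNER = "posterior_corner"
    NONCORNER = "noncorner"


class SliceDomain(str, enum.Enum):
    CENTRAL = "central"
    LATERAL_LEFT = "lateral_left"
    LATERAL_RIGHT = "lateral_right"


# C2..C7, T1..T12, L1..L5, S1 — 24 levels, cranio-caudal.
_LEVEL_CODES: tuple[str, ...] = (
    *[f"C{i}" for i in range(2, 8)],
    *[f"T{i}" for i in range(1, 13)],
    *[f"L{i}" for i in range(1, 6)],
    "S1",
)


@total_ordering
@dataclass(frozen=True)
class VertebralLevel:
    """One of the 24 vertebral levels C2..S1, ordered cranio-caudally."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in _LEVEL_CODES:
            raise ValueError(f"unknown vertebral level {self.code!r}")

    @property
    def index(self) -> int:
        return _LEVEL_CODES.index(self.code)

    def __lt__(self, other: "VertebralLevel") -> bool:
        return self.index < other.index

    def __str__(self) -> str:
        return self.code


VERTEBRAL_LEVELS: tuple[VertebralLevel, ...] = tuple(
    VertebralLevel(c) for c in _LEVEL_CODES
)


@dataclass(frozen=True)
class DVU:
    """A disco-vertebral unit: two adjacent vertebral levels plus segment."""

    upper_level: VertebralLevel
    lower_level: VertebralLevel

    def __post_init__(self) -> None:
        if self.lower_level.index != self.upper_level.index + 1:
            raise ValueError(
                f"{self.lower_level} is not the immediate successor of "
                f"{self.upper_level}"
            )

    @property
    def code(self) -> str:
        return f"{self.upper_level}/{self.lower_level}"

    @property
    def segment(self) -> Segment:
        # cervical = C2/C3..C7/T1, thoracic = T1/T2..T12/L1, lumbar rest
        if self.upper_level.code.startswith("C"):
            return Segment.CERVICAL
        if self.upper_level.code.startswith("T"):
            return Segment.THORACIC
        return Segment.LUMBAR

    def __str__(self) -> str:
        return self.code


@dataclass(frozen=True)
class LesionSite:
    """A single scoreable anatomical site within a DVU."""

    dvu: DVU
    endplate: Endplate
    region: Region
    slice_domain: SliceDomain

    def __post_init__(self) -> None:
        if (
            self.region is Region.NONCORNER
            and self.slice_domain is not SliceDomain.CENTRAL
        ):
            raise ValueError("noncorner sites exist only on central slices")
        if (
            self.slice_domain is not SliceDomain.CENTRAL
            and self.dvu.segment is Segment.CERVICAL
        ):
            raise ValueError("cervical DVUs have no lateral slices")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (
            self.dvu.code,
            self.endplate.value,
            self.region.value,
            self.slice_domain.value,
        )

    def __str__(self) -> str:
        return ":".join(self.key)


def enumerate_dvus() -> list[DVU]:
    """All 23 DVUs, C2/C3 through L5/S1, in cranio-caudal order."""
    return [
        DVU(VERTEBRAL_LEVELS[i], VERTEBRAL_LEVELS[i + 1])
        for i in range(len(VERTEBRAL_LEVELS) - 1)
    ]


def parse_dvu(code: str) -> DVU:
    """Parse a DVU code like ``"T12/L1"`` (upper vertebra / lower vertebra)."""
    try:
        upper, lower = code.strip().split("/")
    except ValueError:
        raise ValueError(f"malformed DVU code {code!r}; expected e.g. 'T12/L1'")
    return DVU(VertebralLevel(upper), VertebralLevel(lower))


def _iter_sites(dvu: DVU) -> Iterator[LesionSite]:
    corner_regions = (Region.ANTERIOR_CORNER, Region.POSTERIOR_CORNER)
    for endplate in Endplate:
        for region in corner_regions:
            yield LesionSite(dvu, endplate, region, SliceDomain.CENTRAL)
        yield LesionSite(dvu, endplate, Region.NONCORNER, SliceDomain.CENTRAL)
        if dvu.segment is not Segment.CERVICAL:
            for domain in (SliceDomain.LATERAL_LEFT, SliceDomain.LATERAL_RIGHT):
                for region in corner_regions:
                    yield LesionSite(dvu, endplate, region, domain)


def enumerate_sites(dvu: DVU) -> list[LesionSite]:
    """All scoreable sites of a DVU.

    Thoracic/lumbar: 14 (4 central corners, 2 central noncorners, 8 lateral
    corners). Cervical: 6 (no lateral slices).
    """
    if not isinstance(dvu, DVU):
        raise TypeError(f"expected DVU, got {type(dvu).__name__}")
    return list(_iter_sites(dvu))


def max_dvu_score(dvu: DVU) -> int:
    """Maximum attainable score of a DVU: 8 cervical, 24 thoracic/lumbar."""
    return 8 if dvu.segment is Segment.CERVICAL else 24


TOTAL_MAX_SCORE: int = sum(max_dvu_score(d) for d in enumerate_dvus())
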