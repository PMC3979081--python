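"""Inter-reader reliability statistics for FASSS scores.

Implements the analysis used to validate semi-quantitative MRI scores:

* intraclass correlation from a two-way model with patients random and
  readers fixed, reported as single measures for absolute agreement —
  ICC(A,1) in the McGraw–Wong taxonomy — with F-based 95% confidence
  bounds and a qualitative band (fair < 0.4 <= moderate < 0.6 <= good
  < 0.8 <= very good < 0.9 <= excellent);
* Bland–Altman limits of agreement at configurable coverage (default 80%);
* the smallest detectable change, SDC = z * SD(d) / sqrt(k) with d the
  inter-reader difference in change scores, z the standard-normal quantile
  at (1 + coverage)/2 (1.2816 at 80%) and k = 2 readings;
* descriptive statistics, cumulative-probability plotting positions,
  stratification of change-score reliability by inter-scan interval, and
  the three pre-specified discrepancy-adjudication rules.

The high-level entry point is :class:`ReliabilityStudy`, built from paired
per-patient scores, whose :meth:`~ReliabilityStudy.fit` returns a
:class:`ReliabilityResults` carrying all estimates with a ``summary()``
table and plotting helpers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCBand",
    "ReliabilityMatrix",
    "ICCResult",
    "AgreementResult",
    "SDCResult",
    "StratumSpec",
    "StratumResult",
    "DiscrepancyFlag",
    "icc_a1",
    "band_of",
    "bland_altman",
    "sdc",
    "descriptives",
    "cumulative_probability_points",
    "default_strata",
    "stratified_reliability",
    "flag_discrepant",
    "ReliabilityStudy",
    "ReliabilityResults",
]


class ICCBand(str, enum.Enum):
    FAIR = "fair"
    MODERATE = "moderate"
    GOOD = "good"
    VERY_GOOD = "very_good"
    EXCELLENT = "excellent"


@dataclass(frozen=True)
class ReliabilityMatrix:
    """An n_subjects x k_readers score matrix with no missing cells."""

    values: np.ndarray
    subject_ids: tuple = ()
    reader_ids: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x readers) array")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 readers")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite (drop incomplete subjects first)")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_readers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    band: ICCBand | None
    n_subjects: int
    k_readers: int
    degenerate: bool = False  # zero total variance: estimate undefined

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.degenerate:
            return f"ICCResult(degenerate, n={self.n_subjects}, k={self.k_readers})"
        return (
            f"ICCResult({self.estimate:.4f}, 95% CI [{self.ci_low:.4f}, "
            f"{self.ci_high:.4f}], {self.band.value}, n={self.n_subjects})"
        )


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement between two paired score vectors."""

    mean_diff: float
    sd_diff: float
    coverage: float
    loa_low: float
    loa_high: float
    n: int
    # (mean of pair, difference) points for plotting
    means: np.ndarray = field(default=None, repr=False)
    diffs: np.ndarray = field(default=None, repr=False)


@dataclass(frozen=True)
class SDCResult:
    """Smallest detectable change with its formula components exposed."""

    value: float
    z: float
    sd_diff: float
    mean_diff: float
    coverage: float
    k: int
    n: int

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class StratumSpec:
    """Half-open interval (lower, upper] of inter-scan intervals, in years."""

    label: str
    lower_bound_years: float  # exclusive
    upper_bound_years: float  # inclusive; math.inf for the open top stratum

    def contains(self, interval_years: float) -> bool:
        return self.lower_bound_years < interval_years <= self.upper_bound_years


@dataclass(frozen=True)
class StratumResult:
    spec: StratumSpec
    n: int
    baseline_icc: ICCResult | None
    change_icc: ICCResult | None
    sdc: SDCResult | None
    descriptives: dict  # per reader: {'baseline': {...}, 'change': {...}}


@dataclass(frozen=True)
class DiscrepancyFlag:
    patient_id: object
    rules_fired: frozenset[str]
    delta_reader1: int
    delta_reader2: int


# ---------------------------------------------------------------------------
# ICC


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, cols=readers, no replication)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    # residual SS computed directly (not by subtraction) so that perfectly
    # agreeing readers yield an exact zero error mean square
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(matrix: ReliabilityMatrix | np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-measure absolute-agreement ICC from a two-way model.

    estimate = (MSR - MSE) / (MSR + (k-1)*MSE + (k/n)*(MSC - MSE)) with
    MSR/MSC/MSE the subject, reader and error mean squares. Confidence
    bounds use the F-distribution method with Satterthwaite degrees of
    freedom. A matrix with zero total variance yields a flagged degenerate
    result rather than an exception.
    """
    if not isinstance(matrix, ReliabilityMatrix):
        matrix = ReliabilityMatrix(np.asarray(matrix, dtype=float))
    x = matrix.values
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or not np.isfinite(denom) or np.allclose(x, x.flat[0]):
        return ICCResult(
            estimate=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            band=None, n_subjects=n, k_readers=k, degenerate=True,
        )
    est = (msr - mse) / denom

    a = (k * est) / (n * (1.0 - est)) if est < 1.0 else float("inf")
    b = 1.0 + (k * est * (n - 1)) / (n * (1.0 - est)) if est < 1.0 else float("inf")
    if not (np.isfinite(a) and np.isfinite(b)):
        return ICCResult(est, est, est, band_of(est), n, k)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else float((n - 1) * (k - 1))
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    lo = min(lo, est)
    hi = max(hi, est)
    return ICCResult(float(est), float(lo), float(hi), band_of(est), n, k)


def band_of(icc_estimate: float) -> ICCBand:
    """Qualitative ICC band per the published thresholds."""
    if not np.isfinite(icc_estimate):
        raise ValueError("ICC estimate must be finite")
    if icc_estimate < 0.4:
        return ICCBand.FAIR
    if icc_estimate < 0.6:
        return ICCBand.MODERATE
    if icc_estimate < 0.8:
        return ICCBand.GOOD
    if icc_estimate < 0.9:
        return ICCBand.VERY_GOOD
    return ICCBand.EXCELLENT


# ---------------------------------------------------------------------------
# Agreement


def _z(coverage: float) -> float:
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    return float(stats.norm.ppf((1.0 + coverage) / 2.0))


def bland_altman(
    x: Sequence[float], y: Sequence[float], coverage: float = 0.80
) -> AgreementResult:
    """Bland–Altman limits of agreement for paired scores x and y.

    Differences d = x - y; limits at mean(d) +/- z * SD(d) (sample SD,
    n-1 denominator) with z the standard-normal quantile at
    (1 + coverage)/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    z = _z(coverage)
    return AgreementResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        coverage=coverage,
        loa_low=mean_diff - z * sd_diff,
        loa_high=mean_diff + z * sd_diff,
        n=int(x.size),
        means=(x + y) / 2.0,
        diffs=d,
    )


def sdc(
    change_r1: Sequence[float],
    change_r2: Sequence[float],
    coverage: float = 0.80,
    k: int = 2,
) -> SDCResult:
    """Smallest detectable change from paired change scores.

    SDC = z(coverage) * SD(d) / sqrt(k), d = change_r1 - change_r2. The
    default 80% coverage gives z = 1.2816; k = 2 readings gives the sqrt(2)
    divisor. All components are exposed so alternative conventions can be
    audited.
    """
    ba = bland_altman(change_r1, change_r2, coverage=coverage)
    z = _z(coverage)
    return SDCResult(
        value=z * ba.sd_diff / math.sqrt(k),
        z=z,
        sd_diff=ba.sd_diff,
        mean_diff=ba.mean_diff,
        coverage=coverage,
        k=k,
        n=ba.n,
    )


def descriptives(values: Sequence[float]) -> dict:
    """Mean, sample SD, median, quartiles (linear interpolation) and range."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        "median": float(med),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def cumulative_probability_points(
    values: Sequence[float],
) -> list[tuple[float, float]]:
    """(cumulative probability, value) pairs at positions (i - 0.5)/n.

    Values sorted ascending; ties keep their own points.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty vector")
    n = v.size
    return [((i + 0.5) / n, float(v[i])) for i in range(n)]


# ---------------------------------------------------------------------------
# Stratification


def default_strata() -> list[StratumSpec]:
    """Inter-scan interval strata: <=1.0, (1.0,1.5], (1.5,2.0], >2.0 years."""
    return [
        StratumSpec("<=1.0y", 0.0, 1.0),
        StratumSpec(">1.0-1.5y", 1.0, 1.5),
        StratumSpec(">1.5-2.0y", 1.5, 2.0),
        StratumSpec(">2.0y", 2.0, math.inf),
    ]


_PAIRED_COLUMNS = (
    "patient_id",
    "interval_years",
    "baseline_r1",
    "baseline_r2",
    "change_r1",
    "change_r2",
)


def stratified_reliability(
    changes: pd.DataFrame, strata: list[StratumSpec] | None = None,
    coverage: float = 0.80,
) -> list[StratumResult]:
    """Per-stratum reliability of baseline and change scores.

    ``changes`` must have columns patient_id, interval_years, baseline_r1,
    baseline_r2, change_r1, change_r2 (one row per patient). Every patient
    must fall in exactly one stratum; strata with n < 2 are reported with
    statistics flagged as unavailable (None).
    """
    missing = [c for c in _PAIRED_COLUMNS if c not in changes.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (changes["interval_years"] <= 0).any():
        bad = changes.loc[changes["interval_years"] <= 0, "patient_id"].tolist()
        raise ValueError(f"non-positive inter-scan interval for patients {bad}")
    strata = strata if strata is not None else default_strata()

    assigned = np.zeros(len(changes), dtype=int)
    membership = []
    for spec in strata:
        in_s = changes["interval_years"].apply(spec.contains).to_numpy()
        membership.append(in_s)
        assigned += in_s
    if (assigned != 1).any():
        bad = changes.loc[assigned != 1, "patient_id"].tolist()
        raise ValueError(f"patients not in exactly one stratum: {bad}")

    results = []
    for spec, in_s in zip(strata, membership):
        sub = changes.loc[in_s]
        n = len(sub)
        if n < 2:
            results.append(StratumResult(spec, n, None, None, None, {}))
            continue
        base = sub[["baseline_r1", "baseline_r2"]].to_numpy(dtype=float)
        chg = sub[["change_r1", "change_r2"]].to_numpy(dtype=float)
        results.append(
            StratumResult(
                spec=spec,
                n=n,
                baseline_icc=icc_a1(base),
                change_icc=icc_a1(chg),
                sdc=sdc(chg[:, 0], chg[:, 1], coverage=coverage),
                descriptives={
                    "reader1": {
                        "baseline": descriptives(base[:, 0]),
                        "change": descriptives(chg[:, 0]),
                    },
                    "reader2": {
                        "baseline": descriptives(base[:, 1]),
                        "change": descriptives(chg[:, 1]),
                    },
                },
            )
        )
    return results


# ---------------------------------------------------------------------------
# Discrepancy adjudication


def _rules_for_pair(d1: float, d2: float) -> frozenset[str]:
    fired = set()
    diff = abs(d1 - d2)
    # A: absolute difference >= 10 AND relative difference > 100% of the
    # pair-mean change (division-free: |d1-d2| > |(d1+d2)/2|)
    if diff >= 10 and diff > abs((d1 + d2) / 2.0):
        fired.add("A")
    # B: change scores in opposite directions at magnitude >= 2
    if (d1 <= -2 and d2 >= 2) or (d2 <= -2 and d1 >= 2):
        fired.add("B")
    # C: one reader scored no change, the other differs by >= 3
    if (d1 == 0) != (d2 == 0) and max(abs(d1), abs(d2)) >= 3:
        fired.add("C")
    return frozenset(fired)


def flag_discrepant(
    delta_r1: Sequence[float],
    delta_r2: Sequence[float],
    ids: Sequence | None = None,
) -> list[DiscrepancyFlag]:
    """Patients whose paired change scores meet any adjudication rule."""
    d1 = np.asarray(delta_r1, dtype=float)
    d2 = np.asarray(delta_r2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("paired change-score vectors must have equal length")
    if ids is None:
        ids = list(range(len(d1)))
    flags = []
    for pid, a, b in zip(ids, d1, d2):
        fired = _rules_for_pair(a, b)
        if fired:
            flags.append(DiscrepancyFlag(pid, fired, int(a), int(b)))
    return flags


# ---------------------------------------------------------------------------
# Study / Results (high-level interface)


class ReliabilityStudy:
    """A two-reader (or k-reader) reliability study over one patient set.

    Built from paired per-patient scores; ``fit()`` computes ICCs with
    confidence bounds and bands, Bland–Altman agreement, the smallest
    detectable change, descriptives, cumulative-probability points and, when
    inter-scan intervals are given, the interval-stratified analysis.

    Parameters
    ----------
    baseline : (n, k) array or DataFrame
        Status scores, one column per reader.
    change : (n, k) array or DataFrame, optional
        Paired change scores for the same patients.
    intervals : length-n sequence, optional
        Inter-scan interval in years (enables stratification).
    coverage : float
        Coverage of the limits of agreement (default 0.80).
    strata : list of StratumSpec, optional
        Interval strata; defaults to <=1.0 / 1.0-1.5 / 1.5-2.0 / >2.0 years.
    """

    def __init__(
        self,
        baseline,
        change=None,
        intervals=None,
        coverage: float = 0.80,
        strata: list[StratumSpec] | None = None,
        subject_ids=None,
        reader_ids=None,
    ):
        self.baseline = np.asarray(baseline, dtype=float)
        self.change = None if change is None else np.asarray(change, dtype=float)
        self.intervals = (
            None if intervals is None else np.asarray(intervals, dtype=float)
        )
        self.coverage = coverage
        self.strata = strata
        self.subject_ids = (
            tuple(subject_ids)
            if subject_ids is not None
            else tuple(range(self.baseline.shape[0]))
        )
        self.reader_ids = (
            tuple(reader_ids)
            if reader_ids is not None
            else tuple(f"R{i+1}" for i in range(self.baseline.shape[1]))
        )
        if self.change is not None and self.change.shape != self.baseline.shape:
            raise ValueError("baseline and change must have identical shape")
        if self.intervals is not None and len(self.intervals) != len(self.baseline):
            raise ValueError("intervals must have one entry per patient")

    @classmethod
    def from_dataframe(
        cls,
        paired: pd.DataFrame,
        coverage: float = 0.80,
        strata: list[StratumSpec] | None = None,
    ) -> "ReliabilityStudy":
        """Build from the paired long-to-wide table used for stratification.

        Expects columns patient_id, interval_years, baseline_r1, baseline_r2,
        change_r1, change_r2.
        """
        missing = [c for c in _PAIRED_COLUMNS if c not in paired.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return cls(
            baseline=paired[["baseline_r1", "baseline_r2"]].to_numpy(dtype=float),
            change=paired[["change_r1", "change_r2"]].to_numpy(dtype=float),
            intervals=paired["interval_years"].to_numpy(dtype=float),
            coverage=coverage,
            strata=strata,
            subject_ids=paired["patient_id"].tolist(),
        )

    def fit(self) -> "ReliabilityResults":
        baseline_icc = icc_a1(self.baseline)
        baseline_ba = bland_altman(
            self.baseline[:, 0], self.baseline[:, 1], coverage=self.coverage
        )
        change_icc = change_ba = change_sdc = None
        strata_results = None
        if self.change is not None:
            change_icc = icc_a1(self.change)
            change_ba = bland_altman(
                self.change[:, 0], self.change[:, 1], coverage=self.coverage
            )
            change_sdc = sdc(
                self.change[:, 0], self.change[:, 1], coverage=self.coverage
            )
            if self.intervals is not None:
                paired = pd.DataFrame(
                    {
                        "patient_id": list(self.subject_ids),
                        "interval_years": self.intervals,
                        "baseline_r1": self.baseline[:, 0],
                        "baseline_r2": self.baseline[:, 1],
                        "change_r1": self.change[:, 0],
                        "change_r2": self.change[:, 1],
                    }
                )
                strata_results = stratified_reliability(
                    paired, strata=self.strata, coverage=self.coverage
                )
        return ReliabilityResults(
            study=self,
            baseline_icc=baseline_icc,
            change_icc=change_icc,
            baseline_agreement=baseline_ba,
            change_agreement=change_ba,
            sdc=change_sdc,
            strata=strata_results,
        )


@dataclass
class ReliabilityResults:
    """Fitted reliability estimates with summary and plotting helpers."""

    study: ReliabilityStudy
    baseline_icc: ICCResult
    change_icc: ICCResult | None
    baseline_agreement: AgreementResult
    change_agreement: AgreementResult | None
    sdc: SDCResult | None
    strata: list[StratumResult] | None

    def descriptives(self, which: str = "baseline") -> dict:
        data = self.study.baseline if which == "baseline" else self.study.change
        if data is None:
            raise ValueError(f"no {which} scores in this study")
        return {
            rid: descriptives(data[:, j])
            for j, rid in enumerate(self.study.reader_ids)
        }

    def cumulative_probability(self, which: str = "baseline") -> dict:
        data = self.study.baseline if which == "baseline" else self.study.change
        if data is None:
            raise ValueError(f"no {which} scores in this study")
        return {
            rid: cumulative_probability_points(data[:, j])
            for j, rid in enumerate(self.study.reader_ids)
        }

    def summary(self) -> str:
        """Human-readable study summary table."""

        def icc_line(name: str, r: ICCResult | None) -> str:
            if r is None:
                return f"{name:<22s} (not available)"
            if r.degenerate:
                return f"{name:<22s} undefined (zero variance), n={r.n_subjects}"
            return (
                f"{name:<22s} {r.estimate:6.3f}  "
                f"[{r.ci_low:6.3f}, {r.ci_high:6.3f}]  {r.band.value:<10s} "
                f"n={r.n_subjects}"
            )

        cov = int(round(self.study.coverage * 100))
        lines = [
            "FASSS inter-reader reliability",
            "=" * 62,
            f"{'statistic':<22s} {'est.':>6s}  {'95% CI':>18s}  band",
            "-" * 62,
            icc_line("ICC status (A,1)", self.baseline_icc),
            icc_line("ICC change (A,1)", self.change_icc),
        ]
        ba = self.baseline_agreement
        lines.append(
            f"{'LoA status (' + str(cov) + '%)':<22s} "
            f"{ba.mean_diff:6.3f}  [{ba.loa_low:6.3f}, {ba.loa_high:6.3f}]"
        )
        if self.change_agreement is not None:
            ba = self.change_agreement
            lines.append(
                f"{'LoA change (' + str(cov) + '%)':<22s} "
                f"{ba.mean_diff:6.3f}  [{ba.loa_low:6.3f}, {ba.loa_high:6.3f}]"
            )
        if self.sdc is not None:
            lines.append(
                f"{'SDC':<22s} {self.sdc.value:6.3f}  "
                f"(z={self.sdc.z:.4f}, SD(d)={self.sdc.sd_diff:.3f}, "
                f"k={self.sdc.k})"
            )
        if self.strata:
            lines.append("-" * 62)
            lines.append("stratified by inter-scan interval:")
            for s in self.strata:
                if s.baseline_icc is None:
                    lines.append(f"  {s.spec.label:<12s} n={s.n} (too few patients)")
                else:
                    lines.append(
                        f"  {s.spec.label:<12s} n={s.n:<4d} "
                        f"ICC status {s.baseline_icc.estimate:6.3f}  "
                        f"ICC change {s.change_icc.estimate:6.3f}  "
                        f"SDC {s.sdc.value:6.3f}"
                    )
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable report of all estimates (4-decimal statistics)."""

        def r4(x):
            return None if x is None or not np.isfinite(x) else round(float(x), 4)

        def icc_block(r: ICCResult | None):
            if r is None:
                return None
            return {
                "estimate": r4(r.estimate),
                "ci_low": r4(r.ci_low),
                "ci_high": r4(r.ci_high),
                "band": r.band.value if r.band else None,
                "n": r.n_subjects,
                "k": r.k_readers,
                "degenerate": r.degenerate,
            }

        def ba_block(b: AgreementResult | None):
            if b is None:
                return None
            return {
                "mean_diff": r4(b.mean_diff),
                "sd_diff": r4(b.sd_diff),
                "coverage": b.coverage,
                "loa_low": r4(b.loa_low),
                "loa_high": r4(b.loa_high),
                "n": b.n,
            }

        report = {
            "icc_status": icc_block(self.baseline_icc),
            "icc_change": icc_block(self.change_icc),
            "bland_altman_status": ba_block(self.baseline_agreement),
            "bland_altman_change": ba_block(self.change_agreement),
            "sdc": None
            if self.sdc is None
            else {
                "value": r4(self.sdc.value),
                "z": r4(self.sdc.z),
                "sd_diff": r4(self.sdc.sd_diff),
                "coverage": self.sdc.coverage,
                "k": self.sdc.k,
                "n": self.sdc.n,
            },
            "descriptives_status": self.descriptives("baseline"),
        }
        if self.study.change is not None:
            report["descriptives_change"] = self.descriptives("change")
        if self.strata is not None:
            report["strata"] = [
                {
                    "label": s.spec.label,
                    "n": s.n,
                    "icc_status": icc_block(s.baseline_icc),
                    "icc_change": icc_block(s.change_icc),
                    "sdc": r4(s.sdc.value) if s.sdc else None,
                }
                for s in self.strata
            ]
        return report

    def plot_bland_altman(self, which: str = "baseline", ax=None):
        """Bland–Altman scatter with mean difference and limits of agreement."""
        import matplotlib.pyplot as plt

        ba = (
            self.baseline_agreement if which == "baseline" else self.change_agreement
        )
        if ba is None:
            raise ValueError(f"no {which} agreement in this study")
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(ba.means, ba.diffs, s=18, alpha=0.7)
        ax.axhline(ba.mean_diff, color="k", lw=1)
        for y in (ba.loa_low, ba.loa_high):
            ax.axhline(y, color="k", lw=1, ls="--")
        ax.set_xlabel("mean of the two readers' scores")
        ax.set_ylabel("reader 1 - reader 2")
        ax.set_title(f"Bland–Altman ({which}, {int(ba.coverage*100)}% LoA)")
        return ax

    def plot_cumulative_probability(self, which: str = "baseline", ax=None):
        """Cumulative probability plot of each reader's scores."""
        import matplotlib.pyplot as plt

        points = self.cumulative_probability(which)
        if ax is None:
            _, ax = plt.subplots()
        for rid, pts in points.items():
            probs, vals = zip(*pts)
            ax.plot(probs, vals, marker=".", ls="", label=rid)
        ax.set_xlabel("cumulative probability")
        ax.set_ylabel(f"{which} score")
        ax.legend()
        return ax
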