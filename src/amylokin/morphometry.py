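"""Statistics for per-fibril AFM/TEM dimension measurements.

Fibril lengths (traced along the median axis, um), cross-sectional heights
(AFM, nm) and widths (TEM, nm) are summarized with an error convention that
keeps the instrument floor visible: the reported *total error* of a mean is
the standard error of the mean plus the instrument *sensitivity error* (for
AFM heights: electrical noise, <0.05 nm, plus sample roughness, <0.1 nm; for
TEM: the 0.7 nm pixel size of the quantification magnification).  Because the
sensitivity error is a systematic floor rather than a random term, it is
added, not combined in quadrature.

Between-condition comparisons use a Welch two-sample t-test whose null
hypothesis is shifted by the sensitivity error: a difference of means is only
called significant if it exceeds what the instrument could fabricate.  With a
zero sensitivity error the test reduces exactly to the ordinary two-sided
Welch test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Default instrument sensitivity floors, keyed by (modality, dimension).
#: AFM height: 0.05 nm electrical noise + 0.1 nm sample roughness.
#: TEM width: one 0.7 nm pixel at the quantification magnification.
#: AFM length: one pixel of a 10 um, 1024-pixel scan (um).
DEFAULT_SENSITIVITY = {
    ("AFM", "height"): 0.15,
    ("TEM", "width"): 0.7,
    ("AFM", "length"): 0.01,
}

DIMENSIONS = ("length", "height", "width")
MODALITIES = ("AFM", "TEM")

#: Star-level significance thresholds.
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class FibrilMeasurementSet:
    """Per-fibril measurements of one dimension under one condition.

    ``values`` are in um for lengths and nm for heights/widths;
    ``sensitivity_error`` is the instrument floor in the same units.
    """

    values: np.ndarray
    dimension: str
    modality: str
    sensitivity_error: float | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"dimension must be one of {DIMENSIONS}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values <= 0):
            raise ValueError("fibril dimensions must be positive")
        if self.sensitivity_error is None:
            default = DEFAULT_SENSITIVITY.get((self.modality, self.dimension), 0.0)
            object.__setattr__(self, "sensitivity_error", default)
        if self.sensitivity_error < 0:
            raise ValueError("sensitivity_error must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DimensionSummary:
    """Summary statistics of one measurement set; total_error = sem + floor."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    sd: float
    sem: float
    total_error: float


@dataclass(frozen=True)
class ComparisonResult:
    """Shifted Welch test between two conditions."""

    t_statistic: float
    p_value: float
    significant: bool
    stars: str
    df: float
    mean_difference: float
    sensitivity_error: float


@dataclass(frozen=True)
class ConsistencyVerdict:
    """Agreement between an observed length ratio and the kinetic prediction."""

    consistent: bool
    observed: float
    predicted: float
    deviation: float
    tolerance: float


def summarize_dimensions(mset: FibrilMeasurementSet) -> DimensionSummary:
    """Summary statistics plus the total-error convention.

    Requires at least two measurements (the SEM is undefined otherwise).
    """
    if mset.n < 2:
        raise ValueError("at least 2 measurements are required for summary statistics")
    v = mset.values
    sd = float(np.std(v, ddof=1))
    sem = sd / math.sqrt(mset.n)
    q1, med, q3 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    return DimensionSummary(
        n=mset.n,
        mean=float(np.mean(v)),
        median=med,
        q1=q1,
        q3=q3,
        sd=sd,
        sem=sem,
        total_error=sem + mset.sensitivity_error,
    )


def _stars(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return "ns"


def compare_conditions(a: FibrilMeasurementSet, b: FibrilMeasurementSet) -> ComparisonResult:
    """Welch two-sample t-test of means shifted by the sensitivity error.

    Tests H0: |mean_a - mean_b| <= sensitivity_error, i.e. the observed
    difference of means is reduced by the instrument floor before being
    compared with its standard error.  The p-value is two-sided-calibrated,
    ``min(1, 2*sf(t))``, so that a zero sensitivity error recovers the
    standard Welch test exactly.
    """
    if a.dimension != b.dimension or a.modality != b.modality:
        raise ValueError(
            f"cannot compare {a.modality}/{a.dimension} with {b.modality}/{b.dimension}"
        )
    if a.n < 2 or b.n < 2:
        raise ValueError("both samples need n >= 2")
    sens = max(a.sensitivity_error, b.sensitivity_error)
    va, vb = np.var(a.values, ddof=1), np.var(b.values, ddof=1)
    se2 = va / a.n + vb / b.n
    se = math.sqrt(se2)
    diff = abs(float(np.mean(a.values) - np.mean(b.values)))
    # Welch-Satterthwaite degrees of freedom
    df = se2**2 / (
        (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
    )
    t = (diff - sens) / se
    p = min(1.0, 2.0 * float(stats.t.sf(t, df)))
    return ComparisonResult(
        t_statistic=t,
        p_value=p,
        significant=p < 0.05,
        stars=_stars(p),
        df=df,
        mean_difference=diff,
        sensitivity_error=sens,
    )


def length_ratio(
    treated: FibrilMeasurementSet, control: FibrilMeasurementSet
) -> tuple[float, float]:
    """Ratio of mean fibril lengths, treated/control, with propagated error.

    First-order propagation of the total errors of both means:
    ``err = r * sqrt((e_t/m_t)^2 + (e_c/m_c)^2)``.
    """
    if treated.dimension != "length" or control.dimension != "length":
        raise ValueError("length_ratio requires length measurement sets")
    st = summarize_dimensions(treated)
    sc = summarize_dimensions(control)
    r = st.mean / sc.mean
    err = r * math.sqrt(
        (st.total_error / st.mean) ** 2 + (sc.total_error / sc.mean) ** 2
    )
    return r, err


def scaling_consistency(
    observed_ratio: float,
    factor_k2: float,
    factor_kplus: float = 1.0,
    tolerance: float = 0.15,
) -> ConsistencyVerdict:
    """Check an observed length ratio against the sqrt(k_plus/k_2) prediction."""
    from .kinetics import predicted_length_scale

    if observed_ratio <= 0:
        raise ValueError("observed_ratio must be positive")
    predicted = predicted_length_scale(factor_k2, factor_kplus)
    dev = abs(observed_ratio - predicted)
    return ConsistencyVerdict(
        consistent=dev <= tolerance,
        observed=observed_ratio,
        predicted=predicted,
        deviation=dev,
        tolerance=tolerance,
    )
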