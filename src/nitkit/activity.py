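"""Reduction of timed colorimetric ammonia assays to specific activities.

Absorbance readings (Nessler or indophenol chemistry) taken at increasing
incubation times are converted to specific nitrilase activity in
nKat·mg⁻¹ (nmol ammonia released per second per mg enzyme): the absorbance
slope inside the longest well-fitting linear window (at least four points)
is divided by the calibration slope (absorbance per nmol ammonia) and the
enzyme mass. An inactivated-enzyme control series, when supplied, has its
fitted slope subtracted first. Negative estimates are clipped to zero and
flagged below detection. Replicates are summarised as inclusive
linear-interpolation quartiles, median, and sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "InsufficientDataError",
    "CalibrationCurve",
    "ActivitySeries",
    "ActivityResult",
    "fit_calibration",
    "find_linear_range",
    "specific_activity",
    "summarize_replicates",
]

_FLAT_EPS = 1e-12


class InsufficientDataError(ValueError):
    """Raised when a series has no usable linear range."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Ammonia standard curve: absorbance = slope·nmol + intercept."""

    slope: float  # absorbance per nmol ammonia
    intercept: float
    r2: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("R² must lie in [0, 1]")


@dataclass
class ActivitySeries:
    """Timed absorbance readings for one reaction."""

    times_s: np.ndarray
    absorbances: np.ndarray
    enzyme_mg: float
    replicate: str = "1"
    substrate: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.times_s.shape != self.absorbances.shape or self.times_s.ndim != 1:
            raise ValueError("times and absorbances must be 1-d arrays of equal length")
        if len(self.times_s) < 2:
            raise ValueError("need at least 2 timed readings")
        if not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")
        if self.enzyme_mg <= 0:
            raise ValueError("enzyme mass must be positive")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass(frozen=True)
class ActivityResult:
    """Specific activity (nKat·mg⁻¹) with its linear window and flags."""

    activity_nkat_per_mg: float
    window: tuple[int, int]  # inclusive (first, last) point indices
    below_detection: bool
    replicate: str = "1"
    substrate: str = ""


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """R² of a least-squares line; a flat (zero-variance) response fits
    perfectly, so it scores 1."""
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < _FLAT_EPS:
        return 1.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least-squares fit of absorbance against nmol ammonia."""
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need at least 2 (nmol, absorbance) standards")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all standard concentrations identical; cannot fit a line")
    fit = stats.linregress(x, y)
    r2 = _r_squared(x, y)
    return CalibrationCurve(slope=float(fit.slope), intercept=float(fit.intercept), r2=r2)


def find_linear_range(
    series: ActivitySeries, min_points: int = 4, r2_threshold: float = 0.99
) -> Optional[tuple[int, int]]:
    """Longest contiguous window (inclusive indices) of at least ``min_points``
    whose internal line fit reaches the R² threshold.

    Among windows of equal length the earliest wins. Returns None when no
    window qualifies; raises :class:`InsufficientDataError` when the series
    itself is shorter than ``min_points``.
    """
    n = len(series)
    if n < min_points:
        raise InsufficientDataError(
            f"series has {n} points; at least {min_points} required in the linear range"
        )
    t, a = series.times_s, series.absorbances
    for length in range(n, min_points - 1, -1):
        for start in range(0, n - length + 1):
            stop = start + length - 1
            if _r_squared(t[start : stop + 1], a[start : stop + 1]) >= r2_threshold:
                return (start, stop)
    return None


def specific_activity(
    series: ActivitySeries,
    cal: CalibrationCurve,
    control: Optional[ActivitySeries] = None,
    min_points: int = 4,
    r2_threshold: float = 0.99,
) -> ActivityResult:
    """Specific activity from the linear-range absorbance slope.

    slope [abs/s] / cal.slope [abs/nmol] gives nmol·s⁻¹ = nKat; dividing by
    the enzyme mass gives nKat·mg⁻¹. The fitted slope of an
    inactivated-enzyme control is subtracted when supplied.
    """
    window = find_linear_range(series, min_points=min_points, r2_threshold=r2_threshold)
    if window is None:
        raise InsufficientDataError(
            "no contiguous window reaches the linearity threshold"
        )
    lo, hi = window
    slope = float(
        np.polyfit(series.times_s[lo : hi + 1], series.absorbances[lo : hi + 1], 1)[0]
    )
    if control is not None:
        cw = find_linear_range(control, min_points=min_points, r2_threshold=r2_threshold)
        if cw is None:
            raise InsufficientDataError("control series has no linear range")
        slope -= float(
            np.polyfit(
                control.times_s[cw[0] : cw[1] + 1],
                control.absorbances[cw[0] : cw[1] + 1],
                1,
            )[0]
        )
    raw = slope / cal.slope / series.enzyme_mg
    below = raw <= 0.0
    return ActivityResult(
        activity_nkat_per_mg=max(0.0, raw),
        window=window,
        below_detection=below,
        replicate=series.replicate,
        substrate=series.substrate,
    )


def summarize_replicates(
    values: Sequence[float],
) -> tuple[float, float, float, Optional[float]]:
    """(Q1, median, Q3, sample sd) of replicate activities.

    Quartiles use inclusive linear interpolation (the common spreadsheet
    convention); sd uses the n−1 denominator and is None for n = 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return float(q1), float(med), float(q3), sd
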