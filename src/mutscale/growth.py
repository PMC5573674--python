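"""Exponential growth-rate estimation from OD600 time series.

The growth rate is defined as mu = ln(Cj/Ci)/(tj - ti) for optical densities
C at two times within the exponential phase; for robustness the estimate is
the slope of a log-linear regression over a detected exponential window (the
two-point formula is the window's 2-point special case). Window detection
looks for contiguous runs of readings inside an OD band (default 0.01-0.1,
early exponential, above typical plate-reader noise) whose log-linear fit is
close to perfect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthCurve",
    "GrowthEstimate",
    "ExponentialWindow",
    "NoExponentialWindowError",
    "detect_exponential_window",
    "growth_rate",
    "subtract_blank",
]


class NoExponentialWindowError(ValueError):
    """Raised when too few readings fall inside the exponential OD band."""


@dataclass(frozen=True)
class GrowthCurve:
    """Blank-subtracted OD600 readings for one strain/medium/replicate.

    Non-positive readings must be dropped before construction (log fits need
    positive OD).
    """

    strain_id: str
    medium: str
    times: np.ndarray  # hours
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if times.ndim != 1 or times.shape != od.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValueError("a growth curve needs at least 2 readings")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("od must be positive after blank subtraction")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)


@dataclass(frozen=True)
class ExponentialWindow:
    start: int  # inclusive index
    end: int  # exclusive index
    slope: float
    r2: float
    flagged: bool  # True when no window reached the r2 threshold


@dataclass(frozen=True)
class GrowthEstimate:
    mu: float  # h^-1
    window_start: int
    window_end: int
    r2: float
    flagged: bool = False


def subtract_blank(od: np.ndarray, blank: float) -> np.ndarray:
    """Blank-subtract readings and drop non-positive values (returns mask too)."""
    od = np.asarray(od, dtype=float) - blank
    return od


def _window_stats(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and r2 of y on t; zero-variance y reports r2 = 0."""
    t = t - t.mean()
    y_c = y - y.mean()
    stt = float(np.dot(t, t))
    sty = float(np.dot(t, y_c))
    syy = float(np.dot(y_c, y_c))
    slope = sty / stt
    if syy < 1e-24:
        return slope, 0.0
    ss_res = syy - sty * sty / stt
    return slope, max(0.0, 1.0 - ss_res / syy)


def detect_exponential_window(
    curve: GrowthCurve,
    min_points: int = 5,
    od_range: tuple[float, float] = (0.02, 0.1),
    r2_threshold: float = 0.99,
) -> ExponentialWindow:
    """Find the exponential-phase window of a growth curve.

    The window is the longest contiguous run of >= min_points readings with
    OD inside ``od_range`` (ties broken by higher log-linear r2). Using the
    longest run rather than the steepest or best-fitting sub-window keeps
    the slope estimate free of the selection bias that reader noise induces
    on short windows; when the run's r2 falls below ``r2_threshold`` the
    window is flagged rather than replaced. The default band starts at
    OD 0.02 so relative reader noise stays modest while remaining in early
    exponential phase.
    """
    lo, hi = od_range
    in_range = (curve.od >= lo) & (curve.od <= hi)
    log_od = np.log(curve.od)

    idx = np.flatnonzero(in_range)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        runs = [r for r in np.split(idx, breaks + 1) if len(r) >= min_points]
    else:
        runs = []
    if not runs:
        raise NoExponentialWindowError(
            f"no exponential window: fewer than {min_points} readings with OD in "
            f"[{lo}, {hi}]"
        )
    best: ExponentialWindow | None = None
    for run in runs:
        a, b = int(run[0]), int(run[-1]) + 1
        slope, r2 = _window_stats(curve.times[a:b], log_od[a:b])
        cand = ExponentialWindow(a, b, slope, r2, flagged=r2 < r2_threshold)
        if best is None or (cand.end - cand.start, cand.r2) > (
            best.end - best.start,
            best.r2,
        ):
            best = cand
    return best


def _plateau_level(
    curve: GrowthCurve, od_hi: float, n_tail: int = 5
) -> float | None:
    """Stationary-phase OD if the curve visibly plateaus, else None.

    The last ``n_tail`` readings must be flat (relative SD < 5%) and sit
    well above the fitting band (> 3x its upper bound) to count as a
    plateau; otherwise no carrying capacity is inferred.
    """
    if len(curve.od) < n_tail + 2:
        return None
    tail = curve.od[-n_tail:]
    level = float(tail.mean())
    if level <= 3.0 * od_hi:
        return None
    if float(tail.std()) / level >= 0.05:
        return None
    return level


def growth_rate(
    curve: GrowthCurve,
    min_points: int = 5,
    od_range: tuple[float, float] = (0.02, 0.1),
    r2_threshold: float = 0.99,
    saturation_correction: bool = True,
) -> GrowthEstimate:
    """Growth rate mu (h^-1) as the log-linear slope over the detected window.

    When the curve itself reaches a clear stationary plateau K, the response
    is linearized as ln(od) - ln(1 - od/K) before fitting (the exact
    logistic linearization), which removes the few-percent downward slope
    bias that band-limited log-linear fitting otherwise inherits from
    saturation. Curves without an observed plateau are fit on ln(od)
    unchanged, so pure exponentials are recovered exactly.
    """
    win = detect_exponential_window(
        curve, min_points=min_points, od_range=od_range, r2_threshold=r2_threshold
    )
    mu, r2 = win.slope, win.r2
    if saturation_correction:
        k = _plateau_level(curve, od_range[1])
        if k is not None:
            seg = slice(win.start, win.end)
            y = np.log(curve.od[seg]) - np.log1p(-curve.od[seg] / k)
            mu, r2 = _window_stats(curve.times[seg], y)
    return GrowthEstimate(
        mu=mu,
        window_start=win.start,
        window_end=win.end,
        r2=r2,
        flagged=win.flagged,
    )
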