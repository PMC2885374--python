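"""Data-side estimators for S-phase time-course copy-number matrices.

Measured DNA content at a locus rises from one copy at the start of
S phase to two copies at the end; after per-locus normalisation the curve
is the empirical replication CDF of that locus across the synchronised
population.  From these curves we extract the classic timing statistics —
T0 (initiation), T50 (half replication), T100 (completion) and the span
DT = T100 - T0 — and estimate the replication-fork velocity from the
slopes of the T50 profile between origins and the convergence points of
their forks.

Note on orientation: timing is stored in minutes, so origins are local
*minima* of the T50 track (they replicate earliest).  Replication-timing
figures are conventionally drawn with early replication upward, in which
orientation the same origins appear as peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TimeCourse",
    "TimingProfile",
    "InvalidTimeCourseError",
    "VelocityEstimationError",
    "normalize_timecourse",
    "estimate_timing_profile",
    "estimate_fork_velocity",
]


class InvalidTimeCourseError(ValueError):
    """Raised when a time course has no usable loci for an operation."""


class VelocityEstimationError(RuntimeError):
    """Raised when fork velocity cannot be inferred from the T50 track."""


@dataclass(frozen=True)
class TimeCourse:
    """Loci x time-points matrix of DNA content.

    ``valid`` marks loci usable downstream; normalisation flags loci with
    no dynamic range (failed or non-replicating probes) as invalid.
    """

    chrom: str
    positions: np.ndarray
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (positions.size, times.size):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{positions.size} positions x {times.size} times"
            )
        if positions.size > 1 and np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if times.size > 1 and np.any(np.diff(times) < 0):
            raise ValueError("times must be ascending")
        valid = self.valid
        valid = np.ones(positions.size, bool) if valid is None else np.asarray(valid, bool)
        if valid.shape != (positions.size,):
            raise ValueError("valid mask must have one entry per locus")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)

    @property
    def n_loci(self) -> int:
        return self.positions.size

    @property
    def n_times(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TimingProfile:
    """Per-locus replication timing statistics (minutes).

    Invalid loci (no threshold crossing) carry NaN and valid=False.
    """

    positions: np.ndarray
    t0: np.ndarray
    t50: np.ndarray
    t100: np.ndarray
    dt: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.positions).size
        for name in ("t0", "t50", "t100", "dt", "valid"):
            if np.asarray(getattr(self, name)).shape != (n,):
                raise ValueError(f"{name} must have one entry per position")


def _smooth3(values: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average along time, ends untouched."""
    out = values.copy()
    if values.shape[1] >= 3:
        out[:, 1:-1] = (values[:, :-2] + values[:, 1:-1] + values[:, 2:]) / 3.0
    return out


def normalize_timecourse(
    tc: TimeCourse, epsilon: float = 0.2, smooth: bool = False
) -> TimeCourse:
    """Rescale each locus to run from 0 at the first to 1 at the last time point.

    The affine map uses the (optionally 3-point-smoothed) values at the
    first and last time points as anchors; intermediate values are not
    clamped and monotonicity is not enforced, so noise excursions outside
    [0, 1] survive — exactly as microarray ratios would.  Loci whose
    dynamic range ``|y_end - y_start|`` falls below ``epsilon`` cannot be
    meaningfully rescaled (failed or non-replicating probes) and are
    flagged invalid.
    """
    if tc.n_times < 2:
        raise ValueError("normalisation needs at least 2 time points")
    anchors = _smooth3(tc.values) if smooth else tc.values
    y0 = anchors[:, 0]
    y1 = anchors[:, -1]
    span = y1 - y0
    valid = tc.valid & (np.abs(span) >= epsilon)
    safe = np.where(valid, span, 1.0)
    values = (tc.values - y0[:, None]) / safe[:, None]
    values[~valid] = tc.values[~valid]
    return replace(tc, values=values, normalized=True, valid=valid)


def _first_upward_crossing(y: np.ndarray, t: np.ndarray, level: float) -> float:
    """Time of the first upward crossing of ``level``; NaN if never crossed."""
    if y[0] >= level:
        return float(t[0])
    above = np.nonzero(y >= level)[0]
    if above.size == 0:
        return float("nan")
    j = above[0]
    y0, y1 = y[j - 1], y[j]
    if y1 == y0:
        return float(t[j])
    return float(t[j - 1] + (level - y0) / (y1 - y0) * (t[j] - t[j - 1]))


def estimate_timing_profile(
    tc: TimeCourse, lo: float = 0.05, hi: float = 0.95
) -> TimingProfile:
    """Extract T0/T50/T100/DT per locus from a normalised time course.

    T50 is the first upward crossing of 0.5 (linear interpolation between
    adjacent time points).  T0 and T100 come from the crossings of the
    ``lo`` and ``hi`` thresholds, linearly extrapolated out to levels 0
    and 1 — thresholds strictly inside (0, 1) are robust to tail noise,
    and the extrapolation undoes the bias they would otherwise introduce.
    Loci whose curve never crosses a threshold, or whose crossings come
    out of order, are flagged invalid.
    """
    if not tc.normalized:
        raise ValueError("timing profiles require a normalised time course")
    if not (0 < lo < 0.5 < hi < 1):
        raise ValueError(f"need 0 < lo < 0.5 < hi < 1, got lo={lo}, hi={hi}")

    n = tc.n_loci
    t0 = np.full(n, np.nan)
    t50 = np.full(n, np.nan)
    t100 = np.full(n, np.nan)
    valid = tc.valid.copy()
    for i in range(n):
        if not valid[i]:
            continue
        y = tc.values[i]
        c_lo = _first_upward_crossing(y, tc.times, lo)
        c_mid = _first_upward_crossing(y, tc.times, 0.5)
        c_hi = _first_upward_crossing(y, tc.times, hi)
        if np.isnan(c_lo) or np.isnan(c_mid) or np.isnan(c_hi) or c_hi < c_lo:
            valid[i] = False
            continue
        slope = (c_hi - c_lo) / (hi - lo)
        t0[i] = c_lo - lo * slope
        t100[i] = c_hi + (1.0 - hi) * slope
        t50[i] = min(max(c_mid, t0[i]), t100[i])
    return TimingProfile(
        positions=tc.positions.copy(),
        t0=t0,
        t50=t50,
        t100=t100,
        dt=t100 - t0,
        valid=valid,
    )


def _moving_median3(y: np.ndarray) -> np.ndarray:
    out = y.copy()
    if y.size >= 3:
        out[1:-1] = np.median(np.stack([y[:-2], y[1:-1], y[2:]]), axis=0)
    return out


def _track_extrema(y: np.ndarray, min_prominence: float) -> tuple[np.ndarray, np.ndarray]:
    """Plateau-tolerant local minima and maxima above a prominence floor."""
    from scipy.signal import find_peaks

    maxima, _ = find_peaks(y, prominence=min_prominence, plateau_size=(1, None))
    minima, _ = find_peaks(-y, prominence=min_prominence, plateau_size=(1, None))
    return minima, maxima


def estimate_fork_velocity(profile: TimingProfile) -> float:
    """Fork velocity (bp/min) from the slopes of the T50 track.

    Origins are local minima of T50; the forks they send out meet the
    neighbouring origins' forks at local maxima (convergence valleys).
    For each origin flanked by a valley on both sides the velocity is the
    total distance to the two valleys divided by the total T50 rise, and
    the estimate returned is the median over qualifying origins — a
    first-order reading of the track that ignores fork directionality.
    Extrema are taken on the 3-probe moving-median-smoothed track and must
    clear a prominence floor of 10% of the track's range, which suppresses
    the shallow wiggles measurement noise would otherwise turn into fake
    origin/valley pairs.
    """
    pos = profile.positions[profile.valid]
    t50 = profile.t50[profile.valid]
    if pos.size < 5:
        raise VelocityEstimationError(
            "too few valid loci to read fork velocity from the T50 track; "
            "supply the velocity manually"
        )
    smoothed = _moving_median3(t50)
    prominence = 0.1 * float(smoothed.max() - smoothed.min())
    minima, maxima = _track_extrema(smoothed, prominence)
    # Extrema hugging the chromosome ends are unreliable (forks run off).
    minima = minima[(minima > 1) & (minima < pos.size - 2)]
    estimates = []
    for p in minima:
        left = maxima[maxima < p]
        right = maxima[maxima > p]
        if left.size == 0 or right.size == 0:
            continue
        l, r = left[-1], right[0]
        # Indices come from the smoothed track; rises from the raw one
        # (the median filter clips extremum values by one probe's slope).
        rise = (t50[l] - t50[p]) + (t50[r] - t50[p])
        if rise <= 0:
            continue
        dist = abs(pos[p] - pos[l]) + abs(pos[r] - pos[p])
        estimates.append(dist / rise)
    if not estimates:
        raise VelocityEstimationError(
            "no origin peak with valleys on both sides in the T50 track; "
            "supply the velocity manually"
        )
    return float(np.median(estimates))
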