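"""Inverse problem: fit the firing-time model to a normalised time course.

The generative parameters are ``m`` origin triplets (location, firing
start, firing end) plus the fork velocity.  Velocity comes from the T50
track (or the user); the triplets are found by minimising the sum of
squared errors (SSE) between the measured normalised copy-number matrix
and the model replication CDF, over all loci and time points, with
simulated annealing restarted from many random initial states and swept
over a range of candidate origin counts.

Because any single search can split or merge origins, calls are not read
off one best fit.  Instead each search contributes its fitted origins to
a regional firing-efficiency curve (window-aggregated efficiency along
the chromosome), the curves are averaged over all searches, and origins
are called at peaks of the averaged curve above a height threshold; the
peak height is the reported efficiency and the firing window of a call is
the median over the contributing fitted origins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .model import Origin, ReplicationModel, firing_efficiency
from .profiles import (
    InvalidTimeCourseError,
    TimeCourse,
    estimate_fork_velocity,
    estimate_timing_profile,
    normalize_timecourse,
)

__all__ = [
    "SAConfig",
    "FitConfig",
    "SearchResult",
    "OriginCall",
    "EfficiencyCurve",
    "sse_objective",
    "anneal_search",
    "regional_efficiency_curve",
    "call_origins",
    "fit_sftm",
]

# Fitted origins with efficiency below this are treated as exactly zero
# (dormant) and discarded; pure floating-point guard.
ZERO_EFFICIENCY = 1e-6


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule.

    The initial temperature, when not given, is calibrated so that about
    80% of uphill moves from the initial state are accepted.  Cooling is
    geometric; each level runs ``iters_per_origin * m`` proposals; the
    search stops after ``max_levels`` levels or ``stale_levels`` levels
    without improving the best SSE.  A zero-temperature quench with step
    sizes shrunk by ``quench_step_scale`` then polishes the best state —
    without it the Gaussian proposal scale leaves fits visibly short of
    their local optimum.
    """

    initial_temp: float | None = None
    cooling: float = 0.97
    iters_per_origin: int = 100
    max_levels: int = 150
    stale_levels: int = 15
    quench_iters_per_origin: int = 300
    quench_step_scale: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the full fitting pipeline.

    ``m_range=None`` defaults to 5%-15% of the valid loci;
    the sweep uses at most 10 evenly spaced origin counts.
    ``region_window`` defaults to 3 kbp (yeast probe scale); use ~50 kbp
    for human-scale data.  ``combine`` selects the within-window
    aggregation of fitted efficiencies: ``"sum"`` (capped at 1; active
    firings of tightly clustered origins are near mutually exclusive) or
    ``"product"`` for the complement-product 1 - prod(1 - e_i).
    """

    m_range: tuple[int, int] | None = None
    n_restarts: int = 10
    velocity: float | None = None
    sa: SAConfig = field(default_factory=SAConfig)
    region_window: float = 3000.0
    peak_threshold: float = 0.05
    combine: str = "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.peak_threshold < 1:
            raise ValueError("peak_threshold must be in (0, 1)")
        if self.combine not in ("sum", "product"):
            raise ValueError("combine must be 'sum' or 'product'")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class SearchResult:
    """One annealing search: fitted origins (dormant ones removed) + SSE."""

    locations: np.ndarray
    t_starts: np.ndarray
    t_ends: np.ndarray
    efficiencies: np.ndarray
    sse: float
    m_requested: int
    seed: int

    @property
    def n_origins(self) -> int:
        return self.locations.size


@dataclass(frozen=True)
class OriginCall:
    """A called origin: curve-peak location/height + consolidated window."""

    location: float
    efficiency: float
    t_fire_start: float
    t_fire_end: float
    n_support: int


@dataclass(frozen=True)
class EfficiencyCurve:
    """Search-averaged regional firing-efficiency track."""

    positions: np.ndarray
    values: np.ndarray


def _model_cdf_matrix(
    state: np.ndarray, positions: np.ndarray, times: np.ndarray, velocity: float
) -> np.ndarray:
    """Replication CDF matrix (loci x times) for a (m, 3) triplet state."""
    factors = np.empty((state.shape[0], positions.size, times.size))
    for i in range(state.shape[0]):
        factors[i] = _origin_factor(state[i], positions, times, velocity)
    return 1.0 - factors.prod(axis=0)


def _origin_factor(
    triplet: np.ndarray, positions: np.ndarray, times: np.ndarray, velocity: float
) -> np.ndarray:
    """1 - U_ik(t): per-locus survival factor of one origin triplet."""
    loc, ts, te = triplet
    travel = np.abs(positions - loc) / velocity
    a = ts + travel
    b = te + travel
    span = b - a
    if span[0] <= 0:  # degenerate window: step CDF
        u = (times[None, :] >= a[:, None]).astype(float)
    else:
        u = np.clip((times[None, :] - a[:, None]) / span[:, None], 0.0, 1.0)
    return 1.0 - u


def sse_objective(candidate: ReplicationModel, tc: TimeCourse) -> float:
    """Sum of squared errors between data and model CDF over valid loci/times.

    The measured matrix must be normalised so both sides live on the
    replication-probability scale.
    """
    if not tc.normalized:
        raise ValueError("sse_objective requires a normalised time course")
    pos = tc.positions[tc.valid]
    state = np.column_stack(
        [candidate.locations(), candidate.windows()[:, 0], candidate.windows()[:, 1]]
    )
    pred = _model_cdf_matrix(state, pos, tc.times, candidate.fork_velocity)
    return float(np.sum((tc.values[tc.valid] - pred) ** 2))


def _state_efficiencies(state: np.ndarray, velocity: float, chrom_length: float) -> np.ndarray:
    """Firing efficiencies of a triplet state (coincident locations jittered)."""
    order = np.argsort(state[:, 0])
    state = state[order]
    locs = state[:, 0].copy()
    for i in range(1, locs.size):  # break exact ties so the model validates
        if locs[i] <= locs[i - 1]:
            locs[i] = np.nextafter(locs[i - 1], np.inf)
    model = ReplicationModel(
        origins=[Origin(l, t[1], t[2]) for l, t in zip(locs, state)],
        fork_velocity=velocity,
        chrom_length=max(chrom_length, locs[-1]),
    )
    eff = np.array([firing_efficiency(model, i) for i in range(locs.size)])
    out = np.empty_like(eff)
    out[order] = eff
    return out


def anneal_search(
    tc: TimeCourse, m: int, config: FitConfig, seed: int
) -> SearchResult:
    """One simulated-annealing minimisation of the SSE with ``m`` origins.

    State is the flat vector of ``m`` (location, T_s, T_e) triplets.  A
    proposal perturbs one uniformly chosen coordinate with Gaussian noise
    (sd: two probe spacings for locations, 5% of the sampled S-phase span
    for times), reflecting at the box bounds and swapping the window
    bounds if they cross.  Fitted origins with zero firing efficiency
    (dormant in every cell) are removed from the result.
    """
    if not tc.normalized:
        raise ValueError("anneal_search requires a normalised time course")
    pos = tc.positions[tc.valid]
    data = tc.values[tc.valid]
    if pos.size == 0:
        raise InvalidTimeCourseError("no valid loci to fit")
    if m < 1 or m > pos.size:
        raise ValueError(f"origin count m={m} outside [1, {pos.size}]")
    velocity = config.velocity
    if velocity is None or velocity <= 0:
        raise ValueError("anneal_search needs a positive fork velocity in config")

    times = tc.times
    t_max = float(times[-1])
    chrom_length = float(pos[-1])
    spacing = float(np.median(np.diff(pos))) if pos.size > 1 else chrom_length
    sd_loc = 2.0 * spacing
    sd_time = 0.05 * (t_max - float(times[0]))
    rng = np.random.default_rng(seed)

    # Random initial state: uniform locations, ordered uniform window pair.
    state = np.empty((m, 3))
    state[:, 0] = rng.uniform(0.0, chrom_length, m)
    tw = np.sort(rng.uniform(0.0, t_max, (m, 2)), axis=1)
    state[:, 1:] = tw

    factors = np.empty((m, pos.size, times.size))
    for i in range(m):
        factors[i] = _origin_factor(state[i], pos, times, velocity)

    def current_sse() -> float:
        pred = 1.0 - factors.prod(axis=0)
        return float(np.sum((data - pred) ** 2))

    sse = current_sse()
    best_state, best_sse = state.copy(), sse

    def propose(scale: float = 1.0) -> tuple[int, np.ndarray, np.ndarray, float]:
        i = rng.integers(m)
        c = rng.integers(3)
        trip = state[i].copy()
        if c == 0:
            trip[0] = _reflect(trip[0] + rng.normal(0.0, scale * sd_loc), 0.0, chrom_length)
        else:
            trip[c] = _reflect(trip[c] + rng.normal(0.0, scale * sd_time), 0.0, t_max)
            if trip[1] > trip[2]:
                trip[1], trip[2] = trip[2], trip[1]
        new_factor = _origin_factor(trip, pos, times, velocity)
        old_factor = factors[i].copy()
        factors[i] = new_factor
        new_sse = current_sse()
        return i, trip, old_factor, new_sse

    temp = config.sa.initial_temp
    if temp is None:
        # Calibrate so ~80% of initial uphill moves would be accepted.
        deltas = []
        for _ in range(50):
            i, trip, old_factor, new_sse = propose()
            if new_sse > sse:
                deltas.append(new_sse - sse)
            factors[i] = old_factor  # roll back: calibration only
        temp = (float(np.mean(deltas)) / -math.log(0.8)) if deltas else 1.0

    iters = config.sa.iters_per_origin * m
    stale = 0
    for _level in range(config.sa.max_levels):
        improved = False
        for _ in range(iters):
            i, trip, old_factor, new_sse = propose()
            delta = new_sse - sse
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                state[i] = trip
                sse = new_sse
                if sse < best_sse:
                    best_sse, best_state = sse, state.copy()
                    improved = True
            else:
                factors[i] = old_factor
        temp *= config.sa.cooling
        stale = 0 if improved else stale + 1
        if stale >= config.sa.stale_levels:
            break

    # Zero-temperature quench from the best state with reduced step sizes:
    # polishes the local optimum the cooling schedule landed near.
    state = best_state.copy()
    for i in range(m):
        factors[i] = _origin_factor(state[i], pos, times, velocity)
    sse = best_sse
    for _ in range(config.sa.quench_iters_per_origin * m):
        i, trip, old_factor, new_sse = propose(scale=config.sa.quench_step_scale)
        if new_sse < sse:
            state[i] = trip
            sse = new_sse
        else:
            factors[i] = old_factor
    best_state, best_sse = state, sse

    eff = _state_efficiencies(best_state, velocity, chrom_length)
    keep = eff >= ZERO_EFFICIENCY
    order = np.argsort(best_state[keep, 0])
    kept = best_state[keep][order]
    return SearchResult(
        locations=kept[:, 0],
        t_starts=kept[:, 1],
        t_ends=kept[:, 2],
        efficiencies=eff[keep][order],
        sse=best_sse,
        m_requested=m,
        seed=seed,
    )


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a proposal back into [lo, hi]."""
    span = hi - lo
    if span <= 0:
        return lo
    x = (x - lo) % (2 * span)
    return lo + (x if x <= span else 2 * span - x)


def regional_efficiency_curve(
    results: Sequence[SearchResult],
    positions: np.ndarray,
    window: float,
    combine: str = "sum",
) -> EfficiencyCurve:
    """Search-averaged regional firing efficiency on a position grid.

    Per search, the curve value at x aggregates the efficiencies of that
    search's fitted origins within [x - w/2, x + w/2]: a capped sum by
    default, or the complement product with ``combine="product"``.  The
    final curve is the plain mean over all searches (every origin count
    and restart weighted equally); values stay in [0, 1].
    """
    if len(results) == 0:
        raise ValueError("need at least one search result")
    positions = np.asarray(positions, dtype=float)
    half = window / 2.0
    acc = np.zeros(positions.size)
    for res in results:
        if res.n_origins == 0:
            continue
        inside = np.abs(res.locations[:, None] - positions[None, :]) <= half
        if combine == "sum":
            curve = np.minimum(1.0, res.efficiencies @ inside)
        else:
            curve = 1.0 - np.prod(
                np.where(inside, 1.0 - res.efficiencies[:, None], 1.0), axis=0
            )
        acc += curve
    return EfficiencyCurve(positions=positions, values=acc / len(results))


def call_origins(
    curve: EfficiencyCurve,
    results: Sequence[SearchResult],
    threshold: float = 0.05,
    window: float = 3000.0,
) -> list[OriginCall]:
    """Call origins at peaks of the averaged regional-efficiency curve.

    Peaks are local maxima (plateaus resolved to their midpoint — an
    isolated origin produces a window-wide rectangular plateau centred on
    it) separated by at least ``window/2``; only peaks with height
    strictly above ``threshold`` become calls.  The firing window of a
    call is the median of the windows of all fitted origins (across every
    search) within ``window/2`` of the peak; ``n_support`` counts the
    searches contributing at least one such origin.
    """
    positions = curve.positions
    values = curve.values
    if positions.size < 3:
        return []
    step = float(np.median(np.diff(positions)))
    distance = max(1, int(round((window / 2.0) / step)))
    peaks, _ = find_peaks(values, distance=distance, plateau_size=(1, None))
    calls: list[OriginCall] = []
    half = window / 2.0
    for idx in peaks:
        height = float(values[idx])
        if height <= threshold:
            continue
        x = float(positions[idx])
        ts_all, te_all, support = [], [], 0
        for res in results:
            near = np.abs(res.locations - x) <= half
            if np.any(near):
                support += 1
                ts_all.extend(res.t_starts[near])
                te_all.extend(res.t_ends[near])
        if support == 0:
            continue
        calls.append(
            OriginCall(
                location=x,
                efficiency=height,
                t_fire_start=float(np.median(ts_all)),
                t_fire_end=float(np.median(te_all)),
                n_support=support,
            )
        )
    return calls


def _m_values(n_valid: int, m_range: tuple[int, int] | None) -> list[int]:
    if m_range is None:
        lo = max(1, int(round(0.05 * n_valid)))
        hi = max(lo, int(round(0.15 * n_valid)))
    else:
        lo, hi = m_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid m_range {m_range}")
    n = min(10, hi - lo + 1)
    return sorted({int(round(v)) for v in np.linspace(lo, hi, n)})


def fit_sftm(
    tc: TimeCourse, config: FitConfig | None = None
) -> tuple[list[OriginCall], dict]:
    """Full pipeline: normalise, get velocity, sweep m x restarts, call origins.

    Returns the origin calls and a diagnostics dict with the resolved
    velocity, the averaged efficiency curve, and one record per search
    (m, seed, SSE, origins kept).  Fully deterministic for a fixed
    ``config.seed``: per-search seeds are spawned from it.
    """
    config = config or FitConfig()
    if not tc.normalized:
        tc = normalize_timecourse(tc)
    n_valid = int(tc.valid.sum())
    if n_valid == 0:
        raise InvalidTimeCourseError("no valid loci in input time course")

    velocity = config.velocity
    if velocity is None:
        profile = estimate_timing_profile(tc)
        velocity = estimate_fork_velocity(profile)
    run_config = FitConfig(
        m_range=config.m_range,
        n_restarts=config.n_restarts,
        velocity=velocity,
        sa=config.sa,
        region_window=config.region_window,
        peak_threshold=config.peak_threshold,
        combine=config.combine,
        seed=config.seed,
    )

    m_values = _m_values(n_valid, config.m_range)
    children = np.random.SeedSequence(config.seed).spawn(len(m_values) * config.n_restarts)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in children]

    results: list[SearchResult] = []
    records = []
    si = 0
    for m in m_values:
        for _ in range(config.n_restarts):
            res = anneal_search(tc, m, run_config, seeds[si])
            results.append(res)
            records.append(
                {"m": m, "seed": res.seed, "sse": res.sse, "n_origins_kept": res.n_origins}
            )
            si += 1

    # Curve grid padded by one window beyond the probed range: calls near
    # the chromosome ends would otherwise sit on edge-truncated plateaus
    # that peak finding cannot see.
    step = (
        float(np.median(np.diff(tc.positions)))
        if tc.positions.size > 1
        else config.region_window / 2.0
    )
    grid = np.arange(
        tc.positions[0] - config.region_window,
        tc.positions[-1] + config.region_window + step,
        step,
    )
    curve = regional_efficiency_curve(
        results, grid, config.region_window, config.combine
    )
    calls = call_origins(curve, results, config.peak_threshold, config.region_window)
    diagnostics = {
        "velocity": velocity,
        "m_values": m_values,
        "searches": records,
        "curve": curve,
    }
    return calls, diagnostics
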