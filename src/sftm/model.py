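"""Analytic forward model of stochastic replication-origin firing.

A chromosome is modelled as a line carrying ``m`` replication origins.
Origin *i* sits at position ``L_i`` and, in any given cell, fires at a
latent time drawn uniformly from its firing window ``(T_si, T_ei)``.
Replication forks move bidirectionally at a constant velocity ``v``, so a
fork emanating from origin *i* reaches locus *k* (distance ``D_ik``)
between ``T_si + D_ik/v`` and ``T_ei + D_ik/v``.  Every origin is licensed
(potential firing probability 1), but an origin whose latent firing time
is pre-empted by an incoming fork is passively replicated and never fires
actively — which is what makes observed firing *efficiencies* less than 1.

This module provides the analytic quantities of that model — the per-locus
replication CDF, the population initiation/completion times T0/T100, and
the exact active-firing efficiency of each origin — together with a
per-cell Monte-Carlo simulator that serves as an independent correctness
oracle for all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Origin",
    "ReplicationModel",
    "ArrivalWindow",
    "arrival_window",
    "locus_replication_cdf",
    "replication_times",
    "firing_efficiency",
    "simulate_cells",
]


@dataclass(frozen=True)
class Origin:
    """A replication origin: position (bp) and uniform firing window (min).

    ``t_fire_start == t_fire_end`` is permitted and means deterministic
    firing at that instant (a point mass), which keeps limiting cases
    well defined and lets tests build deterministic scenarios.
    """

    location: float
    t_fire_start: float
    t_fire_end: float

    def __post_init__(self) -> None:
        if self.location < 0:
            raise ValueError(f"origin location must be >= 0, got {self.location}")
        if not 0 <= self.t_fire_start <= self.t_fire_end:
            raise ValueError(
                "firing window must satisfy 0 <= t_fire_start <= t_fire_end, "
                f"got ({self.t_fire_start}, {self.t_fire_end})"
            )

    @property
    def window_span(self) -> float:
        return self.t_fire_end - self.t_fire_start


@dataclass(frozen=True)
class ArrivalWindow:
    """Time window within which a fork from one origin can reach a locus."""

    t_earliest: float
    t_latest: float

    def __post_init__(self) -> None:
        if self.t_earliest > self.t_latest:
            raise ValueError("arrival window bounds out of order")


@dataclass(frozen=True)
class ReplicationModel:
    """An origin set plus fork velocity on a linear chromosome.

    Parameters
    ----------
    origins
        Origins sorted by strictly increasing location (duplicates are
        unidentifiable and rejected).
    fork_velocity
        Fork speed in bp/min; constant along the chromosome, forks move
        bidirectionally and do not stall.
    chrom_length
        Chromosome length in bp; all origins must lie within it.
    potential_firing_prob
        Licensing probability of every origin.  Fixed at 1: every origin
        can fire; sub-unit observed efficiencies arise solely from passive
        replication by neighbouring forks.
    """

    origins: tuple[Origin, ...]
    fork_velocity: float
    chrom_length: float
    potential_firing_prob: float = field(default=1.0)

    def __init__(
        self,
        origins: Sequence[Origin],
        fork_velocity: float,
        chrom_length: float,
    ) -> None:
        origins = tuple(sorted(origins, key=lambda o: o.location))
        if not origins:
            raise ValueError("a replication model needs at least one origin")
        if fork_velocity <= 0:
            raise ValueError(f"fork_velocity must be positive, got {fork_velocity}")
        locs = np.array([o.location for o in origins], dtype=float)
        if np.any(np.diff(locs) <= 0):
            raise ValueError("origin locations must be unique (strictly increasing)")
        if locs[0] < 0 or locs[-1] > chrom_length:
            raise ValueError("all origin locations must lie in [0, chrom_length]")
        object.__setattr__(self, "origins", origins)
        object.__setattr__(self, "fork_velocity", float(fork_velocity))
        object.__setattr__(self, "chrom_length", float(chrom_length))
        object.__setattr__(self, "potential_firing_prob", 1.0)

    @property
    def n_origins(self) -> int:
        return len(self.origins)

    def locations(self) -> np.ndarray:
        return np.array([o.location for o in self.origins], dtype=float)

    def windows(self) -> np.ndarray:
        """(m, 2) array of firing window bounds in minutes."""
        return np.array(
            [[o.t_fire_start, o.t_fire_end] for o in self.origins], dtype=float
        )


def arrival_window(origin: Origin, locus: float, velocity: float) -> ArrivalWindow:
    """Window of fork arrival at ``locus`` from ``origin``.

    The fork needs ``|L_i - locus| / v`` minutes of travel, so arrival is
    uniform on the firing window shifted by the travel time.  At the
    origin's own location the window is the firing window itself.
    """
    if velocity <= 0:
        raise ValueError(f"velocity must be positive, got {velocity}")
    travel = abs(origin.location - locus) / velocity
    return ArrivalWindow(origin.t_fire_start + travel, origin.t_fire_end + travel)


def _arrival_bounds(model: ReplicationModel, locus: float) -> tuple[np.ndarray, np.ndarray]:
    """Earliest/latest fork arrival at ``locus`` from every origin."""
    travel = np.abs(model.locations() - locus) / model.fork_velocity
    win = model.windows()
    return win[:, 0] + travel, win[:, 1] + travel


def _uniform_cdf(t: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """CDF of U(a, b) broadcast over ``t``; a == b is a unit step at a."""
    t, a, b = np.broadcast_arrays(t, a, b)
    span = b - a
    out = np.empty(t.shape, dtype=float)
    degenerate = span <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.clip((t - a) / np.where(degenerate, 1.0, span), 0.0, 1.0)
    out = np.where(degenerate, (t >= a).astype(float), out)
    return out


def locus_replication_cdf(
    model: ReplicationModel, locus: float, times: Sequence[float]
) -> np.ndarray:
    """P{locus replicated by time t} for each t in ``times``.

    Independence of the per-origin latent firing times gives
    ``P{Y_k <= t} = 1 - prod_i (1 - f_i * U_ik(t))`` with ``U_ik`` the
    uniform CDF on the fork-arrival window of origin *i* at the locus and
    ``f_i = 1``.  The curve is 0 before the earliest possible arrival and
    1 from the first of the latest arrivals onward.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    a, b = _arrival_bounds(model, locus)
    u = _uniform_cdf(t[None, :], a[:, None], b[:, None])
    survival = np.prod(1.0 - model.potential_firing_prob * u, axis=0)
    return 1.0 - survival


def replication_times(model: ReplicationModel, locus: float) -> tuple[float, float]:
    """(T0, T100): population replication initiation/completion at a locus.

    The locus starts replicating when the earliest possible fork arrives
    (min over origins of the earliest arrival bound) and is replicated in
    every cell once the first of the latest arrival bounds has passed.
    """
    a, b = _arrival_bounds(model, locus)
    return float(a.min()), float(b.min())


def _survival_factors(t: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """P(arrival_j > t) for each competitor j (rows) at times t (cols)."""
    span = b - a
    degenerate = span <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.clip((b[:, None] - t[None, :]) / np.where(degenerate, 1.0, span)[:, None], 0.0, 1.0)
    s = np.where(degenerate[:, None], (t[None, :] < a[:, None]).astype(float), s)
    return s


def firing_efficiency(model: ReplicationModel, origin_index: int) -> float:
    """Probability that an origin fires actively rather than passively.

    Origin *k* fires in the fraction of cells where its latent firing time
    ``F_k ~ U(T_sk, T_ek)`` precedes every competing fork arrival
    ``A_jk = F_j + D_jk/v``.  Writing ``S_j(t) = P(A_jk > t)``, the
    efficiency is::

        e_k = (1 / (T_ek - T_sk)) * integral_{T_sk}^{T_ek} prod_{j != k} S_j(t) dt

    Each ``S_j`` is piecewise linear, so the integrand is piecewise
    polynomial of degree at most m-1.  The integral is evaluated exactly:
    the range is split at every competitor window bound and each segment
    integrated with a Gauss-Legendre rule of sufficient order.
    """
    m = model.n_origins
    if not 0 <= origin_index < m:
        raise IndexError(f"origin_index {origin_index} out of range for {m} origins")
    if m == 1:
        return 1.0

    k = origin_index
    focal = model.origins[k]
    others = [i for i in range(m) if i != k]
    travel = np.abs(model.locations()[others] - focal.location) / model.fork_velocity
    win = model.windows()[others]
    a = win[:, 0] + travel
    b = win[:, 1] + travel

    s, e = focal.t_fire_start, focal.t_fire_end
    if e == s:
        # Deterministic firing: survive every competitor at the instant s.
        return float(np.prod(_survival_factors(np.array([s]), a, b)[:, 0]))

    knots = np.unique(np.concatenate([[s, e], np.clip(a, s, e), np.clip(b, s, e)]))
    # Gauss-Legendre exact for polynomials of degree <= 2n-1; degree here <= m-1.
    n_nodes = max(3, (m + 1) // 2 + 1)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)

    total = 0.0
    for lo, hi in zip(knots[:-1], knots[1:]):
        if hi <= lo:
            continue
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        t = mid + half * nodes
        integrand = np.prod(_survival_factors(t, a, b), axis=0)
        total += half * float(weights @ integrand)
    return float(min(1.0, max(0.0, total / (e - s))))


def simulate_cells(
    model: ReplicationModel,
    loci: Sequence[float],
    times: Sequence[float],
    n_cells: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell Monte-Carlo realisation of the firing model.

    Draws one latent firing time per origin per cell.  On a linear
    chromosome with constant bidirectional fork speed, the replication
    time of any locus equals ``min_i (F_i + D_ik/v)`` whether or not
    origin *i* actually fired actively: a fork relayed through a passively
    replicated origin is never later than the direct one (triangle
    inequality along the line).  Origin *k* fires actively in a cell iff
    ``F_k < min_{j != k} (F_j + D_jk/v)``.

    Returns
    -------
    fractions : (n_loci, n_times) ndarray
        Empirical replication fractions, converging to
        :func:`locus_replication_cdf`.
    frequencies : (m,) ndarray
        Empirical per-origin active-firing frequencies, converging to
        :func:`firing_efficiency`.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    loci = np.asarray(loci, dtype=float)
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)

    win = model.windows()
    locs = model.locations()
    m = model.n_origins
    firing = win[:, 0] + (win[:, 1] - win[:, 0]) * rng.random((n_cells, m))

    fractions = np.empty((loci.size, t.size), dtype=float)
    for idx, x in enumerate(loci):
        arrival = firing + np.abs(locs - x)[None, :] / model.fork_velocity
        t_rep = arrival.min(axis=1)
        fractions[idx] = (t_rep[:, None] <= t[None, :]).mean(axis=0)

    frequencies = np.empty(m, dtype=float)
    for k in range(m):
        if m == 1:
            frequencies[k] = 1.0
            continue
        others = np.arange(m) != k
        arrival = firing[:, others] + (
            np.abs(locs[others] - locs[k])[None, :] / model.fork_velocity
        )
        frequencies[k] = (firing[:, k] < arrival.min(axis=1)).mean()
    return fractions, frequencies
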