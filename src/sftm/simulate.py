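"""Synthetic S-phase time-course generator.

Produces loci x time copy-number matrices from a known (hidden) origin
model by evaluating the analytic replication CDF on a probe grid and
adding i.i.d. Gaussian measurement noise.  The generator emulates
normalised microarray time courses: per-locus curves rising 0 -> 1 over
S phase, corrupted with additive N(0, sd) noise that is *not* clamped to
[0, 1], so downstream normalisation sees out-of-range values just as it
would with real array ratios.

Two study models are packaged: a 5 kbp two-origin chromosome whose every
quantity is hand-checkable, and a 100 kbp nine-origin benchmark used for
end-to-end parameter-recovery tests, including two late-firing origins
placed close to early efficient neighbours — the configuration in which
T50-peak finding fails but the regional-efficiency curve does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Origin, ReplicationModel, locus_replication_cdf
from .profiles import TimeCourse

__all__ = [
    "SimulationConfig",
    "simulate_timecourse",
    "noiseless_timecourse",
    "example_two_origin",
    "benchmark_nine_origin",
    "NINE_ORIGIN_TRUTH",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a synthetic time-course experiment.

    Parameters
    ----------
    model
        The generative origin model.
    loci_spacing
        Probe spacing in bp; probes sit at spacing, 2*spacing, ...
    time_points
        Sampling times in minutes, ascending.
    noise_sd
        Standard deviation of the additive Gaussian noise on the
        normalised signal (0.1 matches a realistic array noise floor).
    n_replicates
        Independent noisy replicates averaged into the returned matrix.
    seed
        Seed for the noise generator.
    """

    model: ReplicationModel
    loci_spacing: float
    time_points: tuple[float, ...]
    noise_sd: float = 0.1
    n_replicates: int = 1
    seed: int = 0
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.loci_spacing <= 0:
            raise ValueError("loci_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        t = np.asarray(self.time_points, dtype=float)
        if t.size == 0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
            raise ValueError("time_points must be non-empty and strictly ascending")


def _probe_positions(config: SimulationConfig) -> np.ndarray:
    step = config.loci_spacing
    n = int(np.floor(config.model.chrom_length / step + 1e-9))
    return step * np.arange(1, n + 1, dtype=float)


def _cdf_matrix(model: ReplicationModel, positions: np.ndarray, times: np.ndarray) -> np.ndarray:
    return np.stack([locus_replication_cdf(model, x, times) for x in positions])


def noiseless_timecourse(config: SimulationConfig) -> TimeCourse:
    """The analytic replication CDF sampled on the probe/time grid."""
    positions = _probe_positions(config)
    times = np.asarray(config.time_points, dtype=float)
    values = _cdf_matrix(config.model, positions, times)
    return TimeCourse(
        chrom=config.chrom, positions=positions, times=times,
        values=values, normalized=True,
    )


def simulate_timecourse(config: SimulationConfig) -> TimeCourse:
    """Noisy synthetic time course: analytic CDF plus N(0, noise_sd) noise.

    With ``n_replicates > 1`` the returned matrix is the mean of that many
    independent noisy realisations (residual sd shrinks by sqrt(n)).
    Deterministic for a fixed seed.
    """
    clean = noiseless_timecourse(config)
    if config.noise_sd == 0:
        return clean
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(
        0.0, config.noise_sd, size=(config.n_replicates, *clean.values.shape)
    ).mean(axis=0)
    return TimeCourse(
        chrom=clean.chrom, positions=clean.positions, times=clean.times,
        values=clean.values + noise, normalized=False,
    )


def example_two_origin() -> tuple[ReplicationModel, TimeCourse]:
    """5 kbp chromosome, two origins, fork velocity 1 kbp/min, no noise.

    Origins at 1 kbp (window 0-10 min) and 4 kbp (window 2-6 min); probes
    every 1 kbp, sampled each minute over 0-12 min.  The locus at 2 kbp
    sees forks within (1, 11) and (4, 8) min, hence starts replicating at
    t = 1 and finishes by t = 8.
    """
    model = ReplicationModel(
        origins=[Origin(1000, 0.0, 10.0), Origin(4000, 2.0, 6.0)],
        fork_velocity=1000.0,
        chrom_length=5000.0,
    )
    config = SimulationConfig(
        model=model, loci_spacing=1000.0,
        time_points=tuple(float(t) for t in range(13)),
        noise_sd=0.0, chrom="chrDemo",
    )
    return model, noiseless_timecourse(config)


# True parameters of the nine-origin benchmark: (location bp, T_s, T_e) min.
# Invented constants of this package, chosen to give a realistic spread of
# efficiencies.  The origins at 12 kbp (near the early origin at 18 kbp)
# and at 70 kbp (near 76 kbp) fire late and are mostly passively
# replicated: their T50 signature is weak, making them the hard cases for
# timing-profile peak calling.
NINE_ORIGIN_TRUTH: tuple[tuple[float, float, float], ...] = (
    (5_000.0, 0.0, 6.0),
    (12_000.0, 4.0, 12.0),
    (18_000.0, 0.0, 5.0),
    (33_000.0, 2.0, 10.0),
    (47_000.0, 0.0, 8.0),
    (60_000.0, 3.0, 11.0),
    (70_000.0, 6.0, 12.0),
    (76_000.0, 1.0, 7.0),
    (90_000.0, 0.0, 9.0),
)

NINE_ORIGIN_VELOCITY = 1500.0  # bp/min
NINE_ORIGIN_TIMES = tuple(float(t) for t in range(0, 20, 2))


def benchmark_nine_origin(
    seed: int = 0, noise_sd: float = 0.1
) -> tuple[ReplicationModel, TimeCourse]:
    """100 kbp nine-origin chromosome with one noisy realisation.

    Probes every 1 kbp (100 loci), ten time points over 0-18 min, fork
    velocity 1.5 kbp/min, additive N(0, noise_sd) noise.  Byte-identical
    output for a fixed seed.
    """
    model = ReplicationModel(
        origins=[Origin(*triplet) for triplet in NINE_ORIGIN_TRUTH],
        fork_velocity=NINE_ORIGIN_VELOCITY,
        chrom_length=100_000.0,
    )
    config = SimulationConfig(
        model=model, loci_spacing=1000.0, time_points=NINE_ORIGIN_TIMES,
        noise_sd=noise_sd, seed=seed, chrom="chrBench",
    )
    return model, simulate_timecourse(config)
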