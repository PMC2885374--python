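import numpy as np
import pytest
from scipy.integrate import quad

from sftm import Origin, ReplicationModel


@pytest.fixture
def two_origin_model() -> ReplicationModel:
    """5 kbp chromosome: origins at 1 kbp (0-10 min) and 4 kbp (2-6 min)."""
    return ReplicationModel(
        origins=[Origin(1000, 0, 10), Origin(4000, 2, 6)],
        fork_velocity=1000.0,
        chrom_length=5000.0,
    )


def late_first_origin_model(velocity: float) -> ReplicationModel:
    """Origins at 1 kbp (window 9.5-11 min) and 4 kbp (window 2-6 min).

    The late-firing first origin is passively replicated more or less
    often depending on how fast the second origin's fork travels.
    """
    return ReplicationModel(
        origins=[Origin(1000, 9.5, 11), Origin(4000, 2, 6)],
        fork_velocity=velocity,
        chrom_length=5000.0,
    )


def efficiency_quad(model: ReplicationModel, k: int) -> float:
    """Independent adaptive-quadrature oracle for the firing efficiency.

    Integrates the survival product of competing fork arrivals over the
    focal origin's firing window with scipy's adaptive quadrature,
    splitting at the arrival-window bounds.  Shares no code with the
    exact piecewise-polynomial implementation.
    """
    focal = model.origins[k]
    others = [o for i, o in enumerate(model.origins) if i != k]
    bounds = []
    for o in others:
        travel = abs(o.location - focal.location) / model.fork_velocity
        bounds.append((o.t_fire_start + travel, o.t_fire_end + travel))

    def survival(t: float) -> float:
        s = 1.0
        for a, b in bounds:
            if t >= b:
                return 0.0
            if t > a:
                s *= (b - t) / (b - a)
        return s

    s0, e0 = focal.t_fire_start, focal.t_fire_end
    if e0 == s0:
        return survival(s0)
    points = sorted({x for a, b in bounds for x in (a, b) if s0 < x < e0})
    total, _ = quad(survival, s0, e0, points=points or None, limit=200, epsabs=1e-9)
    return total / (e0 - s0)


def random_small_model(rng: np.random.Generator, max_origins: int = 6) -> ReplicationModel:
    """Random model on <= 20 kbp with 1..max_origins origins."""
    m = int(rng.integers(1, max_origins + 1))
    length = 20_000.0
    locs = np.sort(rng.choice(np.arange(1, 200), size=m, replace=False)) * 100.0
    t_max = 15.0
    windows = np.sort(np.round(rng.uniform(0, t_max, (m, 2)), 1), axis=1)
    origins = [Origin(l, w[0], w[1]) for l, w in zip(locs, windows)]
    velocity = float(rng.uniform(300, 2000))
    return ReplicationModel(origins, velocity, length)
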