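import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rollscr as rs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_traps() -> rs.TrapArray:
    """4x5 camera grid at 2 km spacing (20 stations)."""
    return rs.grid_traps(4, 5, 2000.0)


@pytest.fixture(scope="session")
def year_records(paper_traps):
    """One 365-day simulated record under the default (unmodulated) scenario."""
    scn, traps = rs.scenario_paper_like(seed=7)
    pop = rs.simulate_population(scn)
    return rs.simulate_detections(pop, traps, scn)


@pytest.fixture(scope="session")
def coarse_mask(paper_traps):
    """Coarse mask for fast fitting in tests (guarded by invariance tests)."""
    return rs.build_mask(paper_traps, buffer=15_000.0, spacing=3_000.0)


@pytest.fixture(scope="session")
def modulated_series(paper_traps, coarse_mask):
    """90- and 180-day rolling fits of one sigma-modulated year (seed 11)."""
    scn, traps = rs.scenario_paper_like(modulation_amplitude=0.3, seed=11)
    pop = rs.simulate_population(scn)
    recs = rs.simulate_detections(pop, traps, scn)
    s90 = rs.batch_fit(recs, traps, 90, mask=coarse_mask, compute_ci=False)
    s180 = rs.batch_fit(recs, traps, 180, mask=coarse_mask, compute_ci=False)
    return s90, s180


def random_small_instance(rng: np.random.Generator):
    """A tiny random SCR instance for likelihood oracle checks.

    Scales are O(1) units so nothing underflows: traps and mask points in a
    ~4-unit box, sigma ~ 1, T in [2, 6], n in [1, 4], K in [1, 3], M <= 25.
    """
    K = int(rng.integers(1, 4))
    n = int(rng.integers(1, 5))
    M = int(rng.integers(2, 26))
    T = int(rng.integers(2, 7))
    trap_xy = rng.uniform(-2.0, 2.0, size=(K, 2))
    mask_pts = rng.uniform(-3.0, 3.0, size=(M, 2))
    spacing = float(rng.uniform(0.3, 1.5))
    counts = rng.binomial(T, 0.35, size=(n, K)).astype(float)
    for i in range(n):  # every detected individual needs >= 1 detection
        if counts[i].sum() == 0:
            counts[i, int(rng.integers(0, K))] = 1.0
    theta = np.array(
        [
            rng.uniform(-2.0, 1.0),  # log D
            rng.uniform(-2.5, 0.5),  # logit g0
            rng.uniform(-0.7, 0.7),  # log sigma
        ]
    )
    traps = rs.TrapArray(
        [rs.Detector(f"T{k}", float(x), float(y)) for k, (x, y) in enumerate(trap_xy)]
    )
    mask = rs.HabitatMask(points=mask_pts, spacing=spacing, buffer=1.0)
    hist = rs.SessionHistories(
        [f"i{j}" for j in range(n)], counts, T=T, K=K
    )
    return theta, hist, traps, mask
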