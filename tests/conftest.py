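"""Shared fixtures: small synthetic cohorts and hand-built tracks."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from cnvland.array_io import ProbeMap
from cnvland.synthetic import (
    PlantedRegion,
    SimulationConfig,
    default_config,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_probe_map() -> ProbeMap:
    """Two chromosomes x 200 evenly spaced probes."""
    n = 200
    ids = [f"c{c}_p{i:03d}" for c in (1, 2) for i in range(n)]
    chroms = ["1"] * n + ["2"] * n
    pos = list(range(100_000, 100_000 * (n + 1), 100_000)) * 2
    return ProbeMap(np.array(ids, object), np.array(chroms, object), np.array(pos))


def small_config(seed: int, **overrides) -> SimulationConfig:
    """A scaled-down variant of the reference cohort for fast tests."""
    base = default_config(seed)
    small = dataclasses.replace(
        base,
        n_samples=overrides.pop("n_samples", 12),
        n_chromosomes=overrides.pop("n_chromosomes", 6),
        probes_per_chromosome=overrides.pop("probes_per_chromosome", 400),
        **overrides,
    )
    return small


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free scaled cohort: every planted segment is exactly recoverable."""
    cfg = small_config(123, lrr_noise_sd=0.0, baf_noise_sd=0.0)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-noise scaled cohort."""
    cfg = small_config(321)
    return cfg, simulate_cohort(cfg)
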