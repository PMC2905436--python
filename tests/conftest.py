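"""Shared fixtures: small planted-structure matrices and fixture builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from follinet.simulate import SimulationConfig, Treatment, generate_expression


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_fixture():
    """50 genes, 2 small modules, one treatment with 10 DE genes."""
    cfg = SimulationConfig(
        n_genes=50,
        module_sizes=[15, 10],
        background_genes=25,
        treatments=[Treatment("TRT", 3, 10, 2.0)],
        n_controls=4,
        module_cohesion=0.9,
        seed=7,
    )
    expr, design, truth = generate_expression(cfg)
    return cfg, expr, design, truth


def planted_modules_config(seed: int, cohesion: float = 0.8) -> SimulationConfig:
    """The 5-equal-module recovery fixture: 2,000 genes, 38 samples."""
    return SimulationConfig(
        n_genes=2000,
        module_sizes=[400] * 5,
        background_genes=0,
        treatments=[Treatment(n, 3, 0, 1.0) for n in "ABCDEFG"]
        + [Treatment("H", 2, 0, 1.0)],
        n_controls=15,
        module_cohesion=cohesion,
        seed=seed,
    )


def sixteen_module_config(seed: int) -> SimulationConfig:
    """16 planted modules, one perturbation arm each (2 reps) + 6 controls."""
    rng = np.random.default_rng(seed)
    sizes = [int(s) for s in rng.integers(40, 160, size=16)]
    n = 2000
    return SimulationConfig(
        n_genes=n,
        module_sizes=sizes,
        background_genes=n - sum(sizes),
        treatments=[Treatment(f"T{i:02d}", 2, sizes[i], 1.5) for i in range(16)],
        n_controls=6,
        module_cohesion=0.8,
        de_mode="module",
        de_direction="both",
        seed=seed,
    )


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric adjacency with off-diagonal entries in [0, 1)."""
    a = rng.uniform(0.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a
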