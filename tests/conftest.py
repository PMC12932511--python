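"""Shared fixtures.

The 20-patient SEEG cohort at the default study conditions is expensive
(113 +/- 20 contacts at 2 kHz, 10 s epochs, both states), so it is
simulated once per session and shared by the statistical and density
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from eztopo.pipeline import cohort_density_table, cohort_feature_table
from eztopo.simulate import SimulationConfig, simulate_seeg

COHORT_SEED = 1


@pytest.fixture(scope="session")
def seeg_cohort():
    """Recordings, feature tables and density tables for both states."""
    out = {}
    frames = []
    for state in ("interictal", "ictal"):
        cfg = SimulationConfig(n_patients=20, state=state, seed=COHORT_SEED)
        recs = simulate_seeg(cfg)
        out[state] = {
            "recordings": recs,
            "features": cohort_feature_table(recs),
        }
        frames.append(cohort_density_table(recs))
    import pandas as pd

    out["densities"] = pd.concat(frames, ignore_index=True)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.35) -> np.ndarray:
    """Random Erdos-Renyi adjacency matrix (symmetric, no self-loops)."""
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a + a.T
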