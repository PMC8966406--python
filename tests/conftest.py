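import numpy as np
import pandas as pd
import pytest

from caprigen import SimConfig, io as cio


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    return pd.DataFrame({"id": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]})


def random_pedigree(n_founders: int, n_offspring: int, seed: int) -> pd.DataFrame:
    """Random two-sex pedigree with parents preceding offspring."""
    rng = np.random.default_rng(seed)
    n = n_founders + n_offspring
    sex = np.empty(n, dtype="U1")
    sex[:n_founders] = np.where(np.arange(n_founders) % 2 == 0, "M", "F")
    ids = np.arange(1, n + 1)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(n_founders, n):
        males = np.flatnonzero(sex[:i] == "M")
        females = np.flatnonzero(sex[:i] == "F")
        sire[i] = ids[rng.choice(males)]
        dam[i] = ids[rng.choice(females)]
        sex[i] = "M" if rng.random() < 0.5 else "F"
    return pd.DataFrame({"id": ids, "sire": sire, "dam": dam, "sex": sex})


def micro_sim_config(**overrides) -> SimConfig:
    """A seconds-scale simulation configuration for integration tests."""
    base = dict(
        hist_gens_phase1=80, hist_size_phase1=120, hist_gens_phase2=0,
        hist_final_males=60, hist_final_females=60,
        exp_founder_males=20, exp_founder_females=60,
        exp_gens=2, exp_offspring_per_dam=3, exp_pop_cap=500,
        rec_founder_males=10, rec_founder_females=60,
        n_markers=600, n_qtl=30, candidate_factor=2.5,
        h2=0.34, direction=-1,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def micro_recent():
    """One cached micro-scale simulated population (FD configuration)."""
    return cio.simulate_population(micro_sim_config(), seed=1234)
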