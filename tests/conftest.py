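import numpy as np
import pandas as pd
import pytest

import rfieval as rv


@pytest.fixture(scope="session")
def small_config():
    return rv.SimulationConfig(
        n_founders=80, n_generations=3, n_offspring_per_generation=80, n_snps=300
    )


@pytest.fixture(scope="session")
def small_pedigree(small_config):
    return rv.simulate_pedigree(small_config, seed=11)


@pytest.fixture(scope="session")
def small_A(small_pedigree):
    return rv.build_A(small_pedigree)


def make_clean_cow_daily(
    n_cows=6, seed=0, noise=0.0, n_days=141, trial_levels=2, slope_bw=0.5
):
    """Deterministic (or bounded-noise) daily cow records for QC fixtures."""
    rng = np.random.default_rng(seed)
    dims = np.arange(100, 100 + n_days)
    rows = []
    for i in range(n_cows):
        bw = 650.0 + slope_bw * (dims - 100)
        my = 32.0 - 0.03 * (dims - 100)
        fat = np.full(n_days, 4.2)
        prot = np.full(n_days, 3.3)
        dmi = 20.0 + 0.01 * (dims - 100)
        if noise > 0:
            half = np.sqrt(3) * noise
            bw = bw + rng.uniform(-half, half, n_days)
            dmi = dmi + rng.uniform(-half / 10, half / 10, n_days)
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": i + 1,
                    "trial": f"T{i % trial_levels + 1}",
                    "lactation": 1 + i % 2,
                    "age": 900.0 + i * 10 + dims,
                    "dim": dims,
                    "bw": bw,
                    "my": my,
                    "fat_pct": fat,
                    "prot_pct": prot,
                    "dmi": dmi,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
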