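import numpy as np
import pandas as pd
import pytest

from feedquant import simulate as sm


@pytest.fixture(scope="session")
def small_population():
    """A small but complete simulated trial shared by read-only tests."""
    cfg = sm.default_config(seed=42)
    cfg.n_sires = 40
    cfg.n_dams = 80
    cfg.offspring_per_dam = 6
    cfg.n_birds_target = 480
    cfg.n_genotyped = 400
    return sm.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_phenotypes(small_population):
    from feedquant.phenotypes import derive_phenotypes

    pheno, models = derive_phenotypes(small_population.records)
    return pheno, models


@pytest.fixture()
def founder_only_pedigree():
    def make(n):
        return pd.DataFrame(
            {
                "id": np.arange(1, n + 1),
                "sire": 0,
                "dam": 0,
                "sex": ["M", "F"] * (n // 2) + ["M"] * (n % 2),
                "pen": "",
                "is_founder": True,
            }
        )

    return make
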