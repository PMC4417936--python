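import numpy as np
import pandas as pd
import pytest

import foodcode as fc


def make_expression_table(means: dict[str, list[float]], sd: float, n: int,
                          seed: int = 0, genotype: str = "wildtype") -> pd.DataFrame:
    """Gaussian expression table with one row block per food level.

    `means` maps food label -> [NSM, ADF, ASI] means; foods get ascending
    fake concentrations in insertion order.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fi, (label, mu) in enumerate(means.items()):
        for i in range(n):
            vals = np.abs(rng.normal(mu, sd))
            rows.append({
                "animal_id": f"{genotype}-{label}-{i:04d}", "genotype": genotype,
                "food_label": label, "food_cells_per_ml": float(fi),
                "NSM": vals[0], "ADF": vals[1], "ASI": vals[2],
            })
    return pd.DataFrame(rows)


def make_lifespan_table(params: dict[str, tuple[float, float]], n: int,
                        seed: int = 0, genotype: str = "wildtype") -> pd.DataFrame:
    """Weibull lifespan table; `params` maps food label -> (shape, scale)."""
    rng = np.random.default_rng(seed)
    rows = []
    for fi, (label, (shape, scale)) in enumerate(params.items()):
        ages = scale * rng.weibull(shape, size=n)
        for i, age in enumerate(ages):
            rows.append({
                "animal_id": f"{genotype}-{label}-{i:04d}", "genotype": genotype,
                "food_label": label, "food_cells_per_ml": float(fi),
                "age_days": age, "event": 1,
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_config():
    return fc.default_config(n_per_condition=120, seed=7)


@pytest.fixture(scope="session")
def wildtype_expression(default_config):
    return fc.generate_expression(default_config, "wildtype")


@pytest.fixture(scope="session")
def wildtype_lifespans(default_config):
    return fc.generate_lifespans(default_config, "wildtype")
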