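import numpy as np
import pandas as pd
import pytest

from pcsel.simulate import SimConfig, default_trial_config, simulate_trial
from pcsel.traits import default_registry
from pcsel.trial_data import PhenotypeTable


def make_table(records: list[dict]) -> PhenotypeTable:
    """Build a PhenotypeTable from dict records, defaulting is_check=False."""
    df = pd.DataFrame(records)
    if "is_check" not in df.columns:
        df["is_check"] = False
    return PhenotypeTable(data=df, traits=default_registry())


def grid_table(
    n_genotypes: int,
    n_env: int,
    n_rep: int,
    values: np.ndarray | None = None,
    trait: str = "GY",
    n_blocks: int = 1,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Fully balanced single-trait table over a genotype x env x rep grid.

    ``values`` has shape (n_env, n_rep, n_genotypes); defaults to standard
    normal draws.  Genotypes are split into ``n_blocks`` consecutive blocks
    per replicate (randomly permuted when an rng is given).
    """
    if values is None:
        values = (rng or np.random.default_rng(0)).standard_normal(
            (n_env, n_rep, n_genotypes)
        )
    block_size = n_genotypes // n_blocks
    rows = []
    for j in range(n_env):
        for k in range(n_rep):
            order = (
                (rng.permutation(n_genotypes)) if rng is not None else np.arange(n_genotypes)
            )
            block_of = np.empty(n_genotypes, dtype=int)
            block_of[order] = np.arange(n_genotypes) // block_size
            for i in range(n_genotypes):
                rows.append(
                    {
                        "genotype": f"g{i + 1:03d}",
                        "environment": f"E{j + 1}",
                        "replicate": f"R{k + 1}",
                        "block": f"B{block_of[i] + 1}",
                        "is_check": False,
                        trait: float(values[j, k, i]),
                    }
                )
    return PhenotypeTable(data=pd.DataFrame(rows), traits=default_registry())


def gy_only_config(seed: int, block_var: float = 0.04) -> SimConfig:
    """Single-trait paper-scale config with the published GY components."""
    return SimConfig(
        trait_names=["GY"],
        grand_means={"GY": 5.11},
        genetic_cov=pd.DataFrame([[0.88]], index=["GY"], columns=["GY"]),
        ge_var={"GY": 0.72},
        resid_var={"GY": 1.70},
        env_var={"GY": 1.0},
        rep_var={"GY": 0.09},
        block_var={"GY": block_var},
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_trial():
    """One paper-scale six-trait synthetic trial, shared across tests."""
    return simulate_trial(default_trial_config(seed=11))


@pytest.fixture(scope="session")
def fitted_met(default_trial):
    from pcsel.met import MetAnalyzer

    table, _ = default_trial
    return MetAnalyzer().fit(table)
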