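import pandas as pd
import pytest

from gbmdyn.simulate import SimulationConfig, simulate_all


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A reduced-size configuration for fast unit tests."""
    defaults = dict(
        seed=seed,
        n_genes={"stable": 12, "dynamic": 12, "unmethylated": 12},
        n_expression_genes={"dynamic": 60, "stable": 60, "background": 80},
        n_control_cytosines=500,
        n_flank_dmr_genes=4,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default synthetic dataset (study-scale conditions)."""
    return simulate_all(SimulationConfig())


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_all(small_config())


def make_sites(rows) -> pd.DataFrame:
    """Helper: build a pooled CG-site frame from (chrom, start, n_meth, n_total)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "n_meth", "n_total"])
    df["h"] = df["n_meth"] / df["n_total"]
    return df
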