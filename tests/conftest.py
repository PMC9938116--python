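import numpy as np
import pandas as pd
import pytest

from mefkit.data_io import AbundanceTable, PlotMetadata, TraitTable


@pytest.fixture
def tiny_abundance() -> AbundanceTable:
    return AbundanceTable(pd.DataFrame(
        [[5, 0, 5], [2, 8, 0]],
        index=["p1", "p2"], columns=["ga", "gb", "gc"]))


@pytest.fixture
def tiny_traits() -> TraitTable:
    values = pd.DataFrame(
        {"wd": [0.63, 0.45, 0.80], "latex": [1.0, 2.0, 1.0]},
        index=["ga", "gb", "gc"])
    return TraitTable(values, kinds={"wd": "continuous", "latex": "binary"})


@pytest.fixture
def tiny_metadata() -> PlotMetadata:
    return PlotMetadata(pd.DataFrame({
        "latitude": [-3.0, -3.2],
        "longitude": [-60.0, -60.4],
        "forest_type": ["TF", "SW"],
        "area_ha": [1.0, 1.0],
    }, index=pd.Index(["p1", "p2"], name="plot_id")))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def correlated_trait_table(n_genera=200, r=0.8, missing_frac=0.3,
                           mean=10.0, sd=2.0, seed=0) -> tuple[TraitTable, pd.DataFrame]:
    """Two correlated continuous traits with MCAR gaps on the second one."""
    g = np.random.default_rng(seed)
    cov = sd ** 2 * np.array([[1.0, r], [r, 1.0]])
    X = g.multivariate_normal([mean, mean], cov, size=n_genera)
    ids = [f"G{i:04d}" for i in range(n_genera)]
    truth = pd.DataFrame(X, index=ids, columns=["t1", "t2"])
    values = truth.copy()
    mask = g.random(n_genera) < missing_frac
    values.loc[mask, "t2"] = np.nan
    table = TraitTable(values, kinds={"t1": "continuous", "t2": "continuous"})
    return table, truth
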