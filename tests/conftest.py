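import numpy as np
import pandas as pd
import pytest

from phfkit.io import AbundanceTable
from phfkit.taxonomy import HostLineage


def make_lineage(
    dom="Bacteria", phy="P1", cls="C1", order="O1", fam="F1", gen="G1", sp="S1"
) -> HostLineage:
    """A fully named lineage with per-rank overrides."""
    return HostLineage((dom, phy, cls, order, fam, gen, sp))


def random_abundance_table(
    rng: np.random.Generator,
    n_features: int = 20,
    n_samples: int = 8,
    n_individuals: int = 4,
) -> AbundanceTable:
    values = pd.DataFrame(
        rng.integers(0, 50, size=(n_features, n_samples)).astype(float),
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    # avoid all-zero samples so distance metrics are defined
    for j in range(n_samples):
        if values.iloc[:, j].sum() == 0:
            values.iloc[rng.integers(n_features), j] = 1.0
    meta = pd.DataFrame(
        {
            "individual_id": [f"i{j % n_individuals}" for j in range(n_samples)],
            "time_index": [j // n_individuals for j in range(n_samples)],
        },
        index=values.columns,
    )
    return AbundanceTable(values, None, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
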