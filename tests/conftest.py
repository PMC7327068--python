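import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cernaflow.io import ExpressionMatrix
from cernaflow.synthetic import SimulationConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated experiment at the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture
def small_matrix():
    """Tiny two-group expression matrix with a planted strong feature."""
    # "anchor" keeps library sizes comparable so the planted 4-fold shift in
    # gUP does not compositionally distort the other features' CPM
    values = pd.DataFrame(
        {
            "A_1": [100, 200, 50, 10, 10000],
            "A_2": [110, 190, 55, 12, 10100],
            "A_3": [90, 210, 45, 9, 9900],
            "B_1": [400, 200, 50, 11, 10050],
            "B_2": [380, 195, 52, 10, 9950],
            "B_3": [420, 205, 48, 12, 10000],
        },
        index=["gUP", "g2", "g3", "g4", "anchor"],
    )
    values.index.name = "feature_id"
    design = pd.Series(
        {s: s.split("_")[0] for s in values.columns}, name="group"
    )
    return ExpressionMatrix(layer="mRNA", values=values, design=design)


def null_config(seed: int, **overrides) -> SimulationConfig:
    """A configuration with no planted structure (pure NB noise)."""
    kwargs = dict(
        seed=seed,
        n_mrna=500,
        n_mirna=50,
        n_lncrna=10,
        n_de_mrna=0,
        n_true_mirna_pairs=0,
        n_sponge_triads=0,
        n_pathways=2,
        pathway_size=5,
        n_planted_enriched=0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
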