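import pytest
from hypothesis import settings

from tfoverlap.core import InteractionTable, threshold_significant
from tfoverlap.simulate import WorldParams, generate_world

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


SMALL_PARAMS = dict(
    n_tfs=16,
    n_genes=120,
    mean_targets_per_tf=10.0,
    n_terms=60,
    mean_terms_per_tf=6.0,
)


@pytest.fixture(scope="session")
def small_params():
    return dict(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_world():
    """A fast, reduced-scale world with the default effect structure."""
    return generate_world(WorldParams(seed=7, **SMALL_PARAMS))


@pytest.fixture(scope="session")
def default_world():
    """One full-scale world (173 TFs x 4065 genes) shared across tests."""
    return generate_world(WorldParams(seed=11))


@pytest.fixture
def toy_maps():
    """Hand-sized binding/knockout maps with known overlap structure."""
    binding = threshold_significant(
        InteractionTable(
            records=(
                ("t1", "g1", 0.001), ("t1", "g2", 0.002),
                ("t2", "g2", 0.001), ("t2", "g3", 0.001), ("t2", "g4", 0.004),
            ),
            dataset_kind="binding",
        ),
        0.005,
    )
    knockout = threshold_significant(
        InteractionTable(
            records=(
                ("t1", "g2", 0.003), ("t1", "g5", 0.001),
                ("t2", "g3", 0.002), ("t2", "g4", 0.001),
            ),
            dataset_kind="knockout",
        ),
        0.005,
    )
    return binding, knockout
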