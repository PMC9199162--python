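import pytest

from damlink import SimParams, make_toy_fixtures, simulate_dataset


@pytest.fixture(scope="session")
def toy():
    return make_toy_fixtures()


@pytest.fixture(scope="session")
def small_sim():
    """A compact three-type dataset with well-separated types for
    cluster/annotation tests."""
    params = SimParams(
        n_cells=600, n_genes=260, markers_per_type=20, n_null_markers=20, seed=11
    )
    dataset, truth = simulate_dataset(params)
    return dataset, truth, params
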