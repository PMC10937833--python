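import pytest

from sigplier import build_prior_matrix, filter_genes, fit_plier, simulate_dataset


@pytest.fixture(scope="session")
def sim_small():
    """A compact planted dataset shared across tests (3 active signatures)."""
    return simulate_dataset(
        n_genes=400, n_samples=60, n_signatures=10, signature_size=25,
        n_active=3, seed=7,
    )


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    em, atlas, labels, truth = sim_small
    emf = filter_genes(em, atlas)
    C = build_prior_matrix(atlas, emf.genes)
    model = fit_plier(emf, C, n_components=6, random_state=7)
    return emf, C, model
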