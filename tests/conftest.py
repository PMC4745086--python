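"""Shared fixtures: a synthetic bundle and reusable DE simulations."""

import pytest

import snailnet as sn


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A 100-gene synthetic input bundle with ground truth (seed 1)."""
    return sn.simulate_bundle(100, seed=1, out_dir=tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def null_de_results():
    """DE calls on a 2,000-gene null simulation (no true DE, seed 7)."""
    counts, is_de = sn.simulate_nb_counts(2000, alpha=0.05, n_de=0, seed=7)
    assert not is_de.any()
    return sn.call_de(counts[:, 0], counts[:, 1])


@pytest.fixture(scope="session")
def planted_de():
    """DE calls on a planted simulation: 50 genes at |lfc| = 3, means >= 200."""
    counts, is_de = sn.simulate_nb_counts(
        2000, mean_range=(200.0, 2000.0), alpha=0.05, n_de=50, lfc=3.0, seed=7
    )
    results = sn.call_de(counts[:, 0], counts[:, 1])
    return results, is_de
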