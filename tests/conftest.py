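import numpy as np
import pytest

from bandpop.simulate import PanelSpec, simulate_panel, simulate_traits, worked_fixture


@pytest.fixture(scope="session")
def fixture_panel():
    """The hand-checkable 8-genotype, 2-primer panel."""
    return worked_fixture()


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated panel (3 groups, strong structure) shared by
    distance/tree/ordination tests."""
    spec = PanelSpec(
        group_sizes=(8, 8, 8), group_names=("A", "B", "C"),
        group_clusters=(0, 1, 2),
        primer_classes={f"P{i}": "All" for i in range(1, 9)},
        divergence_f=0.45, alpha=0.05,
    )
    return simulate_panel(spec, seed=11)


@pytest.fixture(scope="session")
def default_panel():
    """Default study-scale panel: 70 genotypes, 26 primers, 7 groups."""
    return simulate_panel(PanelSpec(), seed=5)


@pytest.fixture(scope="session")
def default_traits(default_panel):
    bm, popmap, _ = default_panel
    tt, truth = simulate_traits(bm, popmap, seed=6)
    return tt, truth


def random_band_matrix(rng, n, n_bands=6, n_primers=2, missing=0.0):
    """Helper for property tests: a random valid BandMatrix."""
    from bandpop.io import BandMatrix

    per = n_bands // n_primers
    band_ids = [f"P{p}_{b}" for p in range(1, n_primers + 1) for b in range(1, per + 1)]
    scores = rng.integers(0, 2, size=(n, len(band_ids))).astype(float)
    if missing:
        mask = rng.uniform(size=scores.shape) < missing
        scores[mask] = np.nan
    return BandMatrix([f"g{i}" for i in range(n)], band_ids, scores)
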