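import numpy as np
import pytest
from hypothesis import settings

import ssbench as sb

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def band_ds():
    """Side-20 lattice, 4 vertical domain bands, 40 planted marker genes."""
    cfg = sb.SyntheticConfig(
        n_spots_side=20,
        n_genes=200,
        n_domains=4,
        n_marker_genes_per_domain=10,
        seed=7,
    )
    ds, info = sb.generate_dataset(cfg)
    return ds, info


@pytest.fixture(scope="session")
def band_graph(band_ds):
    ds, _ = band_ds
    return sb.build_neighbor_graph(ds.coords)


@pytest.fixture(scope="session")
def small_ds():
    """Tiny 8x8 fixture for fast structural checks."""
    cfg = sb.SyntheticConfig(
        n_spots_side=8,
        n_genes=60,
        n_domains=2,
        n_marker_genes_per_domain=5,
        seed=1,
    )
    ds, info = sb.generate_dataset(cfg)
    return ds, info


@pytest.fixture(scope="session")
def small_graph(small_ds):
    ds, _ = small_ds
    return sb.build_neighbor_graph(ds.coords)


def random_labeled_graph(rng, n_min=8, n_max=16, k_domains=2):
    """Random coordinates + kNN graph + random domain labels (for oracles)."""
    n = int(rng.integers(n_min, n_max + 1))
    coords = rng.uniform(0, 10, size=(n, 2))
    graph = sb.build_neighbor_graph(coords, k=min(3, n - 1))
    labels = rng.integers(0, k_domains, size=n)
    # ensure every domain occurs
    labels[:k_domains] = np.arange(k_domains)
    return coords, graph, labels
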