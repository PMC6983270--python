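import numpy as np
import pandas as pd
import pytest

from decondoublet.io_formats import AnnotatedExpression
from decondoublet.pipeline import RunConfig, detect_doublets
from decondoublet.simulate import SimulationParams, simulate_dataset


@pytest.fixture
def tiny_ae():
    """3 genes x 4 cells, two clusters of two cells."""
    values = pd.DataFrame(
        [[3.0, 2.5, 0.1, 0.2], [2.8, 3.2, 0.0, 0.3], [0.2, 0.1, 2.9, 3.1]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2", "c3", "c4"],
    )
    clusters = pd.Series([1, 1, 2, 2], index=values.columns)
    gene_cluster = pd.Series([1, 1, 2], index=values.index)
    return AnnotatedExpression(values, clusters, gene_cluster)


@pytest.fixture(scope="session")
def two_pop_fixture():
    """The shipped two-population study fixture: 1,000 singlets in two
    clusters with disjoint 50-gene marker blocks, 100 spiked even-weight
    heterotypic doublets, seed 7."""
    params = SimulationParams(seed=7)
    marker_ae, truth, full_ae = simulate_dataset(params)
    return params, marker_ae, truth, full_ae


@pytest.fixture(scope="session")
def two_pop_run_3070(two_pop_fixture):
    _, marker_ae, truth, full_ae = two_pop_fixture
    res = detect_doublets(marker_ae, full_ae, RunConfig(seed=7))
    return res, truth


@pytest.fixture(scope="session")
def two_pop_run_only50(two_pop_fixture):
    _, marker_ae, truth, full_ae = two_pop_fixture
    res = detect_doublets(marker_ae, full_ae, RunConfig(seed=7, only50=True))
    return res, truth


@pytest.fixture(scope="session")
def homotypic_run():
    params = SimulationParams(seed=7, homotypic_fraction=1.0)
    marker_ae, truth, full_ae = simulate_dataset(params)
    res = detect_doublets(marker_ae, full_ae, RunConfig(seed=7))
    return res, truth


@pytest.fixture(scope="session")
def transitional_run():
    params = SimulationParams(seed=7, doublet_rate=0.0, transitional_cluster=True)
    marker_ae, truth, full_ae = simulate_dataset(params)
    res = detect_doublets(marker_ae, full_ae, RunConfig(seed=7))
    return res, truth


def random_annotated(
    rng: np.random.Generator,
    n_clusters: int = 3,
    cells_per_cluster: int = 5,
    n_genes: int = 20,
) -> AnnotatedExpression:
    """Small random cluster-structured table for property tests."""
    cells, labels = [], []
    for c in range(1, n_clusters + 1):
        for i in range(cells_per_cluster):
            cells.append(f"c{c}_{i}")
            labels.append(c)
    values = pd.DataFrame(
        rng.uniform(0, 5, size=(n_genes, len(cells))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cells,
    )
    return AnnotatedExpression(values, pd.Series(labels, index=cells))
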