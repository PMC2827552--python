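import numpy as np
import pytest

from kleevec import datagen, indicator

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_dataset():
    """5 well-separated groups x 10 sequences, no ambiguity."""
    spec = datagen.SimSpec(n_groups=5, seqs_per_group=10, n_sites=120,
                           between_divergence=0.2, within_divergence=0.02,
                           rng_seed=11)
    return datagen.simulate(spec)


@pytest.fixture
def small_training_set(small_dataset):
    aln, manifest, _ = small_dataset
    return indicator.split_train_test(
        aln, manifest, indicator.TrainingConfig(n_per_group=5, rng_seed=3)
    )


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree with positive branch lengths.

    Returns (labels, distance matrix) where the matrix holds exact
    path lengths — an additive matrix with a known generating tree.
    Built edge-by-edge; distances via networkx shortest paths, fully
    independent of the package's tree code.
    """
    import networkx as nx

    g = nx.Graph()
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    center = "internal0"
    next_internal = 1
    for leaf in labels[:3]:
        g.add_edge(center, leaf, weight=float(rng.uniform(0.1, 2.0)))
    for leaf in labels[3:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"internal{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, leaf, weight=float(rng.uniform(0.1, 2.0)))
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    D = np.array([[dist[a][b] for b in labels] for a in labels])
    D = (D + D.T) / 2.0  # exact symmetry (path sums commute up to rounding)
    np.fill_diagonal(D, 0.0)
    return labels, D
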