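"""Correlation-derived distances and neighbor-joining trees.

The law-of-cosines identity ``D_H = n (1 - rho)`` converts any correlation
matrix (structure or diversity) into a distance matrix — unitless ``1 - rho``
by default, or average-Hamming units when the number of analyzed sites is
supplied. Neighbor joining (Saitou & Nei) then yields an unrooted tree that
is intrinsic to the data: on an additive distance matrix the reconstruction
is exact, and NJ topology is invariant to positive rescaling of distances,
so the unitless and Hamming-scaled matrices give the same tree shape.

The agglomeration is implemented here with fixed, lexicographic tie-breaking
so runs are reproducible across platforms; scikit-bio's ``TreeNode`` is used
as the tree container (Newick serialization, patristic distances).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .exceptions import TreeError
from .matrices import LabeledMatrix

__all__ = ["DistanceMatrix", "NJTree", "correlation_to_distance",
           "nj_tree", "leaf_order"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal and labels.

    ``scale`` records the units: ``"correlation"`` for the unitless
    ``1 - rho`` form, ``"hamming"`` for average substitutions.
    """

    values: np.ndarray
    labels: list[str]
    scale: str = "correlation"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        G = len(self.labels)
        if self.values.shape != (G, G):
            raise TreeError(f"matrix shape {self.values.shape} vs {G} labels")
        if np.isnan(self.values).any():
            raise TreeError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise TreeError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise TreeError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise TreeError("distances must be non-negative")

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    def to_phylip(self, path) -> None:
        """PHYLIP square format (labels padded to 10 characters)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(f"{lab[:10]:<10s} "
                         + " ".join(f"{x:.10g}" for x in row) + "\n")


def correlation_to_distance(
    m: LabeledMatrix, n_sites: int | None = None
) -> DistanceMatrix:
    """Convert a correlation matrix to distances via ``d = 1 - rho``.

    With ``n_sites`` the result is scaled to average Hamming units,
    ``d = n (1 - rho)``. Entries above ``1 + 1e-9`` are a domain error;
    rounding above 1 by less is clipped to distance zero.
    """
    rho = np.asarray(m.values, dtype=float)
    if np.any(rho > 1 + 1e-9):
        raise TreeError(f"correlation entries exceed 1: max {rho.max()}")
    d = np.clip(1.0 - rho, 0.0, None)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    if n_sites is not None:
        return DistanceMatrix(n_sites * d, list(m.group_order), "hamming")
    return DistanceMatrix(d, list(m.group_order), "correlation")


@dataclass
class NJTree:
    """Unrooted NJ tree (trifurcating root node) over the input labels."""

    tree: TreeNode
    labels: list[str]
    #: branch lengths before clipping, one record per negative branch:
    #: {"cluster": smallest tip label below the branch, "raw_length": x}
    clipped_branches: list[dict] = field(default_factory=list)

    @property
    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick + "\n")

    def patristic(self) -> tuple[np.ndarray, list[str]]:
        """Tip-to-tip path-length matrix (clipped branch lengths)."""
        dm = self.tree.tip_tip_distances()
        return np.asarray(dm.data), list(dm.ids)


def _attach(parent: TreeNode, child: TreeNode, length: float,
            key: str, clipped: list[dict]) -> None:
    if length < 0:
        clipped.append({"cluster": key, "raw_length": float(length)})
        length = 0.0
    child.length = float(length)
    parent.append(child)


def nj_tree(d: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion is joined; exact ties
    are resolved toward the lexicographically smallest pair of cluster
    labels (a cluster is labeled by its smallest tip). Negative branch
    lengths are clipped to zero for the tree, with raw values retained in
    ``clipped_branches`` and a warning emitted. On an additive input matrix
    the tree's patristic distances reproduce the input exactly.
    """
    if len(d.labels) < 3:
        raise TreeError(f"need >= 3 taxa for neighbor joining, got "
                        f"{len(d.labels)}")
    D = d.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in d.labels]
    keys: list[str] = list(d.labels)
    clipped: list[dict] = []

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu, ju = np.triu_indices(m, k=1)
        qvals = Q[iu, ju]
        tied = np.nonzero(qvals == qvals.min())[0]
        best = min(tied, key=lambda t: tuple(sorted((keys[iu[t]], keys[ju[t]]))))
        i, j = int(iu[best]), int(ju[best])

        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        _attach(parent, nodes[i], li, keys[i], clipped)
        _attach(parent, nodes[j], lj, keys[j], clipped)

        dnew = (D[:, i] + D[:, j] - D[i, j]) / 2.0
        old = [k for k in range(m) if k not in (i, j)]
        Dk = np.empty((m - 1, m - 1))
        Dk[:-1, :-1] = D[np.ix_(old, old)]
        Dk[-1, :-1] = dnew[old]
        Dk[:-1, -1] = dnew[old]
        Dk[-1, -1] = 0.0
        D = Dk
        nodes = [nodes[k] for k in old] + [parent]
        keys = [keys[k] for k in old] + [min(keys[i], keys[j])]

    # terminal 3-star: unrooted tree with a trifurcating root
    root = TreeNode()
    l0 = (D[0, 1] + D[0, 2] - D[1, 2]) / 2.0
    l1 = (D[0, 1] + D[1, 2] - D[0, 2]) / 2.0
    l2 = (D[0, 2] + D[1, 2] - D[0, 1]) / 2.0
    for k, lk in zip(range(3), (l0, l1, l2)):
        _attach(root, nodes[k], lk, keys[k], clipped)

    if clipped:
        warnings.warn(
            f"{len(clipped)} negative NJ branch length(s) clipped to 0",
            stacklevel=2,
        )
    return NJTree(root, list(d.labels), clipped)


def leaf_order(t: NJTree, anchor: str | None = None) -> list[str]:
    """Circular depth-first ordering of leaves for matrix rearrangement.

    The traversal starts at ``anchor`` (default: lexicographically smallest
    leaf) and walks the unrooted tree depth-first, so adjacent labels in the
    ordering are adjacent in the traversal. Deterministic for a fixed tree.
    """
    tips = [n.name for n in t.tree.tips()]
    if anchor is None:
        anchor = min(tips)
    elif anchor not in tips:
        raise TreeError(f"anchor {anchor!r} is not a leaf of the tree")

    adjacency: dict[int, list[TreeNode]] = {}
    for node in t.tree.traverse(include_self=True):
        neighbors = list(node.children)
        if node.parent is not None:
            neighbors.append(node.parent)
        adjacency[id(node)] = neighbors

    start = next(n for n in t.tree.tips() if n.name == anchor)
    order: list[str] = []
    seen: set[int] = set()
    stack = [start]
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        if node.is_tip():
            order.append(node.name)
        # reversed so the first neighbor is explored first (LIFO stack)
        stack.extend(reversed([nb for nb in adjacency[id(node)]
                               if id(nb) not in seen]))
    return order
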