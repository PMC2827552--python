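"""Klee diagrams: annotated heatmaps of correlation matrices.

A Klee diagram renders a (structure, diversity or prediction) matrix as a
color matrix; discontinuities — "fractures" — between blocks of high
within-block correlation reveal taxonomic divisions. Blocks are usually
annotated from known taxonomy; :func:`block_detect` offers a greedy
contiguous-segmentation heuristic when no taxonomy is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Rectangle  # noqa: E402
import numpy as np  # noqa: E402

from .matrices import LabeledMatrix  # noqa: E402

__all__ = ["KleePlotSpec", "render_klee", "block_detect",
           "read_block_annotations", "write_block_annotations"]


@dataclass
class KleePlotSpec:
    """Everything needed to render one Klee diagram.

    ``block_annotations`` are ``(label, start, end)`` with 0-based inclusive
    index ranges into ``ordering``; ranges must be disjoint, ordered and
    within bounds. ``value_range`` fixes the color scale (None = auto), so
    two panels can deliberately use differing scales to emphasize
    off-diagonal resemblance.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str] | None = None
    block_annotations: list[tuple[str, int, int]] = field(default_factory=list)
    colormap: str = "viridis"
    value_range: tuple[float, float] | None = None
    title: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.col_labels is None:
            self.col_labels = list(self.row_labels)
        prev_end = -1
        n = min(self.values.shape)
        for label, start, end in self.block_annotations:
            if not (0 <= start <= end < n):
                raise ValueError(f"block {label!r} range {start}..{end} "
                                 f"out of bounds for size {n}")
            if start <= prev_end:
                raise ValueError(f"block {label!r} overlaps its predecessor")
            prev_end = end

    @classmethod
    def from_matrix(cls, m: LabeledMatrix, **kwargs) -> "KleePlotSpec":
        return cls(values=m.values, row_labels=list(m.group_order), **kwargs)


def render_klee(spec: KleePlotSpec, path) -> str:
    """Render the diagram to ``path`` (format from extension: png/svg/pdf)."""
    n_rows, n_cols = spec.values.shape
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.35 * n_cols + 2), max(3.5, 0.35 * min(n_rows, 40) + 2))
    )
    vmin, vmax = spec.value_range or (None, None)
    im = ax.imshow(spec.values, cmap=spec.colormap, vmin=vmin, vmax=vmax,
                   interpolation="nearest", aspect="auto")
    ax.set_xticks(range(n_cols))
    ax.set_xticklabels(spec.col_labels, rotation=90, fontsize=7)
    if n_rows <= 60:
        ax.set_yticks(range(n_rows))
        ax.set_yticklabels(spec.row_labels, fontsize=7)
    else:
        ax.set_ylabel(f"{n_rows} rows")
    for label, start, end in spec.block_annotations:
        size = end - start + 1
        ax.add_patch(Rectangle((start - 0.5, start - 0.5), size, size,
                               fill=False, edgecolor="black", linewidth=1.5))
        ax.annotate(label, (end + 0.6, start - 0.2), fontsize=7,
                    annotation_clip=False)
    if spec.title:
        ax.set_title(spec.title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    # strip volatile metadata so vector output is byte-stable per spec
    metadata = {"Date": None} if str(path).endswith(".svg") else None
    fig.savefig(path, dpi=150, metadata=metadata)
    plt.close(fig)
    return str(path)


def block_detect(
    m: LabeledMatrix | np.ndarray,
    ordering: list[str] | None = None,
    threshold: float = 0.3,
) -> list[tuple[str, int, int]]:
    """Greedy contiguous segmentation of an ordered correlation matrix.

    Walking down the diagonal, the current block is extended to the next
    element while the mean within-block correlation minus the mean
    correlation of the block to that element stays at or below
    ``threshold``; a larger contrast closes the block. A heuristic aid —
    taxonomy-driven annotation is the primary path. Returns
    ``(label, start, end)`` with 0-based inclusive ranges; labels are
    ``block1..blockB``.
    """
    if isinstance(m, LabeledMatrix):
        values = m.values
        ordering = ordering or list(m.group_order)
    else:
        values = np.asarray(m, dtype=float)
        ordering = ordering or [str(i) for i in range(values.shape[0])]
    order_idx = list(range(len(ordering)))
    if isinstance(m, LabeledMatrix) and ordering != list(m.group_order):
        order_idx = [m.group_order.index(g) for g in ordering]
        values = values[np.ix_(order_idx, order_idx)]

    n = values.shape[0]
    blocks: list[tuple[int, int]] = []
    start = 0
    for j in range(1, n):
        block = list(range(start, j))
        within = float(values[np.ix_(block, block)].mean())
        link = float(values[block, j].mean())
        if within - link > threshold:
            blocks.append((start, j - 1))
            start = j
    blocks.append((start, n - 1))
    return [(f"block{i + 1}", s, e) for i, (s, e) in enumerate(blocks)]


def write_block_annotations(blocks: list[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tstart\tend\n")
        for label, start, end in blocks:
            fh.write(f"{label}\t{start}\t{end}\n")


def read_block_annotations(path) -> list[tuple[str, int, int]]:
    blocks = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            label, start, end = line.rstrip("\n").split("\t")
            blocks.append((label, int(start), int(end)))
    return blocks
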