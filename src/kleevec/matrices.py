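"""Structure, diversity and prediction matrices, and correlation ordering.

The *structure matrix* is the G x G matrix of inner products between group
indicator vectors (auto- and cross-correlations of the groups' discriminant
directions). The *diversity matrix* replaces indicator vectors with the
groups' sequence ensembles: entry (k, m) is the mean inner product over all
pairs of unit sequence vectors drawn from groups k and m, so its diagonal is
an objective, variance-based measure of within-group diversity. The
*prediction matrix* correlates each test sequence with every indicator
vector; the argmax of a row is the taxonomic assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .estimators import _unit_rows
from .exceptions import ShapeError
from .indicator import IndicatorVector, TrainingSet

__all__ = [
    "StructureMatrix", "DiversityMatrix", "PredictionMatrix",
    "structure_matrix", "diversity_matrix", "predict", "accuracy_report",
    "order_by_correlation",
]


@dataclass
class LabeledMatrix:
    values: np.ndarray
    group_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        G = len(self.group_order)
        if self.values.shape != (G, G):
            raise ShapeError(
                f"matrix shape {self.values.shape} does not match "
                f"{G} group labels"
            )

    def permute(self, new_order: list[str]) -> "LabeledMatrix":
        """Reorder both axes consistently to ``new_order``."""
        if sorted(new_order) != sorted(self.group_order):
            raise ValueError("new_order must be a permutation of group_order")
        idx = [self.group_order.index(g) for g in new_order]
        return type(self)(self.values[np.ix_(idx, idx)], list(new_order))

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("group\t" + "\t".join(self.group_order) + "\n")
            for g, row in zip(self.group_order, self.values):
                fh.write(g + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


@dataclass
class StructureMatrix(LabeledMatrix):
    """G x G inner products between unit indicator vectors."""


@dataclass
class DiversityMatrix(LabeledMatrix):
    """G x G mean pairwise sequence correlations within/between groups."""

    includes_self_pairs: bool = True


@dataclass
class PredictionMatrix:
    """Test-sequence x indicator-vector correlations with assignments."""

    values: np.ndarray  # (T, G)
    group_order: list[str]
    test_ids: list[str]
    true_group: list[str] | None
    assigned_group: list[str] = field(init=False)
    ambiguous: np.ndarray = field(init=False)  # exact-tie flags

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.test_ids), len(self.group_order)):
            raise ShapeError("prediction matrix shape mismatch")
        best = np.argmax(self.values, axis=1)
        self.assigned_group = [self.group_order[i] for i in best]
        self.ambiguous = (
            (self.values == self.values.max(axis=1, keepdims=True)).sum(axis=1)
            > 1
        ) if len(self.test_ids) else np.zeros(0, dtype=bool)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            cols = ["test_id", "true_group", "assigned_group", "ambiguous"]
            fh.write("\t".join(cols + list(self.group_order)) + "\n")
            for t, sid in enumerate(self.test_ids):
                true = self.true_group[t] if self.true_group else "NA"
                fh.write(
                    f"{sid}\t{true}\t{self.assigned_group[t]}\t"
                    f"{int(self.ambiguous[t])}\t"
                    + "\t".join(f"{x:.10g}" for x in self.values[t]) + "\n"
                )


def structure_matrix(indicators: list[IndicatorVector]) -> StructureMatrix:
    """Inner products between the groups' unit indicator vectors."""
    if not indicators:
        raise ValueError("no indicator vectors given")
    lengths = {iv.unit_form.size for iv in indicators}
    if len(lengths) != 1:
        raise ShapeError(f"indicator lengths differ: {sorted(lengths)}")
    Q = np.array([iv.unit_form for iv in indicators])
    return StructureMatrix(Q @ Q.T, [iv.group for iv in indicators])


def diversity_matrix(ts: TrainingSet,
                     includes_self_pairs: bool = True) -> DiversityMatrix:
    """Mean inner products over all member pairs of each group pair.

    Entry (k, m) is the mean over all N x N ordered pairs (i in S_k,
    j in S_m) of the unit-vector inner products. On the diagonal the i = j
    self-pairs (each contributing 1) are included by default; the exclusive
    variant differs by O(1/N).
    """
    means, counts = [], []
    for g in ts.group_order:
        U = ts.train_vectors[g]
        if len(U) == 0:
            raise ValueError(f"group {g!r} has no training members")
        means.append(U.mean(axis=0))
        counts.append(len(U))
    M = np.array(means)
    values = M @ M.T
    if not includes_self_pairs:
        for i, n in enumerate(counts):
            if n < 2:
                raise ValueError(
                    f"group {ts.group_order[i]!r} needs >= 2 members for the "
                    "self-pair-exclusive diagonal"
                )
            values[i, i] = (values[i, i] * n * n - n) / (n * (n - 1))
    return DiversityMatrix(values, list(ts.group_order),
                           includes_self_pairs=includes_self_pairs)


def predict(
    test_vectors: np.ndarray,
    indicators: list[IndicatorVector],
    test_ids: list[str] | None = None,
    true_group: list[str] | None = None,
) -> PredictionMatrix:
    """Correlate unit test vectors with each indicator; argmax assigns.

    Exact ties are flagged ``ambiguous`` rather than silently broken —
    identical indicator vectors (indistinguishable groups) make ties a
    real event. A row's maximum correlation is also useful for outlier
    screening: a sequence from a group absent from training is still
    assigned to its most-correlated available group.
    """
    test_vectors = np.asarray(test_vectors, dtype=float)
    Q = np.array([iv.unit_form for iv in indicators])
    if test_vectors.ndim != 2 or test_vectors.shape[1] != Q.shape[1]:
        raise ShapeError(
            f"test vectors shape {test_vectors.shape} does not match "
            f"indicator length {Q.shape[1]}"
        )
    corr = _unit_rows(test_vectors) @ Q.T
    ids = test_ids or [f"t{i}" for i in range(len(test_vectors))]
    return PredictionMatrix(corr, [iv.group for iv in indicators], ids,
                            true_group)


def accuracy_report(pm: PredictionMatrix) -> dict:
    """Overall and per-group accuracy plus a list of misassignments."""
    if pm.true_group is None:
        raise ValueError("true groups are not populated")
    errors = []
    per_group: dict[str, list[int]] = {}
    for t, sid in enumerate(pm.test_ids):
        true, assigned = pm.true_group[t], pm.assigned_group[t]
        correct = int(true == assigned)
        per_group.setdefault(true, []).append(correct)
        if not correct:
            row = pm.values[t]
            true_corr = (row[pm.group_order.index(true)]
                         if true in pm.group_order else float("nan"))
            errors.append({
                "id": sid, "true": true, "assigned": assigned,
                "correlation_gap": float(row.max() - true_corr),
                "ambiguous": bool(pm.ambiguous[t]),
            })
    overall = (sum(sum(v) for v in per_group.values())
               / max(1, len(pm.test_ids)))
    return {
        "n_test": len(pm.test_ids),
        "overall_accuracy": overall,
        "per_group_accuracy": {
            g: sum(v) / len(v) for g, v in sorted(per_group.items())
        },
        "n_ambiguous": int(pm.ambiguous.sum()),
        "errors": errors,
    }


def write_accuracy_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def order_by_correlation(
    sm: LabeledMatrix, blocks: list[list[str]] | None = None
) -> list[str]:
    """Within each block, sort groups by descending total correlation with
    their block-mates (diagonal excluded); block order is preserved. The
    default single block covers all groups, putting the group most
    correlated with the rest first."""
    if blocks is None:
        blocks = [list(sm.group_order)]
    flat = [g for b in blocks for g in b]
    if sorted(flat) != sorted(sm.group_order):
        raise ValueError("blocks must partition group_order")
    order: list[str] = []
    for block in blocks:
        scores = {}
        for g in block:
            i = sm.group_order.index(g)
            scores[g] = sum(
                sm.values[i, sm.group_order.index(m)]
                for m in block if m != g
            )
        # stable: ties keep their within-block input order
        order.extend(sorted(block, key=lambda g: -scores[g]))
    return order
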