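"""Group indicator vectors: training-set assembly and the eigenproblem.

An indicator vector for group k is the unit vector with maximal mean squared
correlation with k's training sequences and minimal mean squared correlation
with every other group's (competitors weighted equally). It is the dominant
eigenvector of the within-minus-between correlation operator; the heavy
lifting lives in :class:`kleevec.estimators.IndicatorVectorClassifier` and
the functions here are thin wrappers plus serialization.

Because every sequence quartet sums to one, the indicator vector inherits a
conservation property: all of its quartet sums are mutually equal, so it can
be rescaled into per-position quartets of (signed) base probabilities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import seqspace
from .alignio import Alignment, GroupManifest
from .estimators import IndicatorVectorClassifier, normalize_probability
from .exceptions import ConfigurationError, ShapeError
from .seqspace import DEFAULT_CONVENTION, EncodingConvention, SiteMask

__all__ = [
    "TrainingConfig", "TrainingSet", "IndicatorVector",
    "split_train_test", "criterion_J", "compute_indicator",
    "compute_indicators", "quartet_sums", "normalize_probability",
    "save_indicator", "load_indicator",
]

# re-exported: the per-position sums underlying the conservation property
quartet_sums = seqspace.quartet_sums


@dataclass(frozen=True)
class TrainingConfig:
    """How to draw equal-weight training sets.

    ``n_per_group`` sequences are sampled uniformly without replacement from
    every group holding at least that many members ("admissible" groups);
    the rest form the test set. A fixed count per group confers equal weight
    on each taxon in the eigenproblem.
    """

    n_per_group: int
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")


@dataclass
class TrainingSet:
    """Masked, unit-normalized training vectors per group, plus test data."""

    group_order: list[str]
    train_vectors: dict[str, np.ndarray]  # group -> (N, d) unit rows
    train_ids: dict[str, list[str]]
    test_ids: list[str]
    test_groups: list[str]
    test_vectors: np.ndarray  # (T, d) unit rows (T may be 0)
    mask: SiteMask
    n_per_group: int
    rng_seed: int
    excluded_groups: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All training vectors and their labels, classifier-ready."""
        X = np.vstack([self.train_vectors[g] for g in self.group_order])
        y = np.concatenate(
            [[g] * len(self.train_vectors[g]) for g in self.group_order]
        )
        return X, y


@dataclass
class IndicatorVector:
    """A group's indicator in unit-norm and probability form."""

    group: str
    unit_form: np.ndarray
    prob_form: np.ndarray | None
    eigenvalue: float
    criterion_value: float


def split_train_test(
    aln: Alignment,
    manifest: GroupManifest,
    cfg: TrainingConfig,
    mask: SiteMask | None = None,
    conv: EncodingConvention = DEFAULT_CONVENTION,
    mask_rule: str = "strict",
) -> TrainingSet:
    """Sample training members per group; encode, mask and normalize.

    Groups with fewer than ``cfg.n_per_group`` members are excluded (with a
    record in ``excluded_groups``). The conserved-site mask defaults to one
    computed from the *pooled* alignment (all groups, training and test
    together); pass ``mask`` to override.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    if mask is None:
        mask = seqspace.find_conserved_sites(aln.rows, rule=mask_rule)

    encoded = seqspace.encode_matrix(aln.rows, conv)[:, mask.column_indices()]
    norms = np.linalg.norm(encoded, axis=1, keepdims=True)
    unit = encoded / norms
    index = {sid: i for i, sid in enumerate(aln.ids)}

    admissible, excluded = [], []
    for g in manifest.groups:
        members = [sid for sid in manifest.members(g, order=aln.ids)
                   if sid in index]
        (admissible if len(members) >= cfg.n_per_group else excluded).append(g)
    if not admissible:
        raise ConfigurationError(
            f"no group has >= {cfg.n_per_group} members; nothing to train on"
        )

    train_vectors: dict[str, np.ndarray] = {}
    train_ids: dict[str, list[str]] = {}
    test_ids: list[str] = []
    test_groups: list[str] = []
    for g in admissible:
        members = [sid for sid in manifest.members(g, order=aln.ids)
                   if sid in index]
        chosen = rng.choice(len(members), size=cfg.n_per_group, replace=False)
        chosen_ids = [members[i] for i in sorted(chosen)]
        train_ids[g] = chosen_ids
        train_vectors[g] = unit[[index[sid] for sid in chosen_ids]]
        for sid in members:
            if sid not in set(chosen_ids):
                test_ids.append(sid)
                test_groups.append(g)

    test_vectors = (unit[[index[sid] for sid in test_ids]]
                    if test_ids else np.zeros((0, unit.shape[1])))
    return TrainingSet(
        group_order=admissible,
        train_vectors=train_vectors,
        train_ids=train_ids,
        test_ids=test_ids,
        test_groups=test_groups,
        test_vectors=test_vectors,
        mask=mask,
        n_per_group=cfg.n_per_group,
        rng_seed=cfg.rng_seed,
        excluded_groups=excluded,
    )


def criterion_J(q: np.ndarray, ts: TrainingSet, k: str) -> float:
    """The discriminant criterion at unit vector ``q`` for group ``k``:
    mean squared correlation with k's members minus the equal-weighted mean
    over other groups of their mean squared correlations."""
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-8:
        raise ValueError("q must be a unit vector")
    own = float(np.mean((ts.train_vectors[k] @ q) ** 2))
    others = [g for g in ts.group_order if g != k]
    if not others:
        return own
    between = np.mean(
        [np.mean((ts.train_vectors[g] @ q) ** 2) for g in others]
    )
    return own - float(between)


def fit_classifier(
    ts: TrainingSet, solver: str = "dense"
) -> IndicatorVectorClassifier:
    """Fit the eigenvector discriminant on a training set."""
    X, y = ts.stacked()
    clf = IndicatorVectorClassifier(solver=solver)
    clf.fit(X, y)
    return clf


def compute_indicators(
    ts: TrainingSet, solver: str = "dense"
) -> dict[str, IndicatorVector]:
    """Indicator vectors for every group of a training set."""
    clf = fit_classifier(ts, solver=solver)
    out = {}
    for i, g in enumerate(clf.classes_):
        prob = None if clf.prob_forms_ is None else clf.prob_forms_[i]
        out[str(g)] = IndicatorVector(
            group=str(g),
            unit_form=clf.indicator_vectors_[i],
            prob_form=prob,
            eigenvalue=float(clf.eigenvalues_[i]),
            criterion_value=float(clf.criterion_values_[i]),
        )
    return out


def compute_indicator(
    ts: TrainingSet, k: str, solver: str = "dense"
) -> IndicatorVector:
    """Indicator vector for group ``k`` (wrapper over the classifier)."""
    if k not in ts.group_order:
        raise ConfigurationError(f"unknown group {k!r}")
    return compute_indicators(ts, solver=solver)[k]


# -- serialization -----------------------------------------------------------

def mask_checksum(mask: SiteMask) -> str:
    payload = ",".join(map(str, mask.dropped_positions)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_indicator(iv: IndicatorVector, ts: TrainingSet, path,
                   conv: EncodingConvention = DEFAULT_CONVENTION) -> None:
    """Write one group's indicator as TSV plus a JSON sidecar.

    TSV columns: masked position index, original 1-based position, base,
    unit-form weight, probability-form weight.
    """
    if iv.unit_form.size % 4:
        raise ShapeError("indicator length not divisible by 4")
    n_kept = iv.unit_form.size // 4
    kept = ts.mask.kept_positions
    with open(path, "w") as fh:
        fh.write("position\toriginal_position\tbase\tweight_unit\tweight_prob\n")
        for p in range(n_kept):
            for b in range(4):
                w_unit = iv.unit_form[4 * p + b]
                w_prob = (float("nan") if iv.prob_form is None
                          else iv.prob_form[4 * p + b])
                fh.write(
                    f"{p + 1}\t{kept[p]}\t{conv.base_order[b]}\t"
                    f"{w_unit:.12g}\t{w_prob:.12g}\n"
                )
    sidecar = {
        "group": iv.group,
        "eigenvalue": iv.eigenvalue,
        "criterion_value": iv.criterion_value,
        "n_per_group": ts.n_per_group,
        "rng_seed": ts.rng_seed,
        "mask_checksum": mask_checksum(ts.mask),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_indicator(path) -> IndicatorVector:
    """Read an indicator TSV (+ sidecar) written by :func:`save_indicator`."""
    units, probs = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("position"):
            raise ShapeError(f"{path} is not an indicator TSV")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            units.append(float(parts[3]))
            probs.append(float(parts[4]))
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    prob_arr = np.array(probs)
    return IndicatorVector(
        group=meta["group"],
        unit_form=np.array(units),
        prob_form=None if np.isnan(prob_arr).all() else prob_arr,
        eigenvalue=meta["eigenvalue"],
        criterion_value=meta["criterion_value"],
    )
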