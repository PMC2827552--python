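"""Synthetic grouped alignments with controlled divergence structure.

The generator emulates the structure of a multi-taxon barcode compilation:
G well-separated groups whose within-group divergence is much smaller than
the between-group divergence, a fraction of sites frozen across all groups
(conserved), and occasional ambiguous characters.

Model: a uniform random root sequence; each group ancestor mutates every
non-conserved root site independently with probability ``between_divergence``
(choosing uniformly among the 3 alternative bases, Jukes-Cantor-like); each
member mutates its ancestor likewise at ``within_divergence``; finally each
character is replaced by ``N`` with probability ``ambiguous_rate``. Groups
are star phylogenies (ancestor plus independent tips), which gives closed
forms for expectations: two members of one group differ at a non-conserved
site with probability ``2 mu (1 - mu) + (2/3) mu^2``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .alignio import Alignment, GroupManifest
from .exceptions import ConfigurationError

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic dataset.

    Rates are per-site substitution probabilities; ``conserved_fraction``
    freezes that share of sites in every lineage; ``ambiguous_rate`` is the
    per-character probability of masking to ``N``.
    """

    n_groups: int = 12
    seqs_per_group: int = 60
    n_sites: int = 501
    between_divergence: float = 0.20
    within_divergence: float = 0.02
    conserved_fraction: float = 0.0
    ambiguous_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.seqs_per_group < 1 or self.n_sites < 1:
            raise ConfigurationError("counts must be positive")
        for name in ("between_divergence", "within_divergence",
                     "conserved_fraction", "ambiguous_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.conserved_fraction == 1.0 and self.between_divergence > 0:
            raise ConfigurationError(
                "conserved_fraction=1 leaves no sites free to diverge"
            )


def _mutate(seq: np.ndarray, rate: float, free: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Substitute each free site with prob ``rate``, uniform among the
    3 alternative bases."""
    out = seq.copy()
    hit = free & (rng.random(seq.size) < rate)
    idx = np.nonzero(hit)[0]
    if idx.size:
        # shift by 1..3 within the base alphabet: uniform over alternatives
        current = np.searchsorted(BASES, seq[idx])
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = BASES[(current + shift) % 4]
    return out


def simulate(spec: SimSpec) -> tuple[Alignment, GroupManifest, dict]:
    """Generate an alignment, its manifest, and a ground-truth record.

    The ground truth holds the root, the group ancestors, the 1-based
    conserved positions and the seed; same seed reproduces identical
    output byte-for-byte.
    """
    rng = np.random.default_rng(spec.rng_seed)
    root = BASES[rng.integers(0, 4, size=spec.n_sites)]
    n_conserved = round(spec.conserved_fraction * spec.n_sites)
    conserved_idx = rng.choice(spec.n_sites, size=n_conserved, replace=False)
    free = np.ones(spec.n_sites, dtype=bool)
    free[conserved_idx] = False

    ids, rows, assignments = [], [], {}
    ancestors = {}
    for g in range(spec.n_groups):
        label = f"grp{g + 1:02d}"
        ancestor = _mutate(root, spec.between_divergence, free, rng)
        ancestors[label] = "".join(ancestor)
        for s in range(spec.seqs_per_group):
            member = _mutate(ancestor, spec.within_divergence, free, rng)
            if spec.ambiguous_rate > 0:
                blank = rng.random(spec.n_sites) < spec.ambiguous_rate
                member = member.copy()
                member[blank] = "N"
            sid = f"{label}_s{s + 1:04d}"
            ids.append(sid)
            rows.append("".join(member))
            assignments[sid] = label

    truth = {
        "spec": asdict(spec),
        "root": "".join(root),
        "ancestors": ancestors,
        "conserved_positions": sorted(int(i) + 1 for i in conserved_idx),
        "rng_seed": spec.rng_seed,
    }
    return Alignment(ids, rows), GroupManifest(assignments), truth


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
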