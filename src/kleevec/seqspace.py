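"""The digital vector embedding of aligned nucleotide sequences.

Each character of an aligned sequence is translated into a *quartet* — four
real entries holding the probability of A, C, G and T at that position.
Canonical bases map to unit basis quartets, IUPAC ambiguity codes to uniform
distributions over their compatible bases, and a fully unknown character
(``N``, a gap, or any unresolvable symbol) to ``(1/4, 1/4, 1/4, 1/4)``.

The embedding preserves the Hamming distance exactly: for unambiguous
sequences ``a`` and ``b`` of length ``n``,

    ||encode(a) - encode(b)||^2 = 2 * hamming(a, b)

and the cosine of the angle between the (unit-normalized) vectors is
``1 - hamming(a, b) / n`` — the law of cosines links the correlation
coefficient and the substitution fraction. These identities make the
Euclidean geometry of the embedded space an exact carrier of sequence
distances, with a principled fractional extension to ambiguous characters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import EncodingError, MaskError, ShapeError

CANONICAL_BASES = ("A", "C", "G", "T")

#: IUPAC nucleotide codes -> compatible canonical bases. Gaps and unknown
#: placeholders carry no information and are treated as fully ambiguous.
IUPAC_COMPAT: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", ".": "ACGT", "?": "ACGT",
}


@dataclass(frozen=True)
class EncodingConvention:
    """Assignment of probability quartets to sequence characters.

    Parameters
    ----------
    base_order : tuple of str
        Order in which the four canonical bases occupy quartet slots.
        Any permutation yields identical distances and correlations; the
        default ``(A, C, G, T)`` is fixed so probability quartets are
        interpretable.
    """

    base_order: tuple[str, str, str, str] = CANONICAL_BASES

    def __post_init__(self) -> None:
        if sorted(self.base_order) != sorted(CANONICAL_BASES):
            raise ValueError(
                f"base_order must be a permutation of {CANONICAL_BASES}, "
                f"got {self.base_order}"
            )

    @property
    def ambiguity_map(self) -> dict[str, np.ndarray]:
        """Character -> probability quartet, in ``base_order`` slots."""
        slot = {b: i for i, b in enumerate(self.base_order)}
        out = {}
        for code, compat in IUPAC_COMPAT.items():
            q = np.zeros(4)
            for b in compat:
                q[slot[b]] = 1.0 / len(compat)
            out[code] = q
        return out

    def lookup_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(256, 4) quartet table indexed by ASCII code, plus validity mask."""
        table = np.zeros((256, 4))
        valid = np.zeros(256, dtype=bool)
        for code, quartet in self.ambiguity_map.items():
            table[ord(code)] = quartet
            valid[ord(code)] = True
        return table, valid


DEFAULT_CONVENTION = EncodingConvention()


@dataclass
class SequenceVector:
    """A sequence embedded as ``4 * n_sites`` stacked probability quartets."""

    values: np.ndarray
    n_sites: int
    id: str | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4 * self.n_sites,):
            raise ShapeError(
                f"expected {4 * self.n_sites} entries, got {self.values.shape}"
            )

    def unit(self) -> "SequenceVector":
        """Return a unit-Euclidean-norm copy (projection onto the sphere)."""
        norm = float(np.linalg.norm(self.values))
        if norm == 0.0:
            raise ShapeError(f"cannot normalize zero vector (id={self.id!r})")
        return SequenceVector(self.values / norm, self.n_sites, self.id, True)


@dataclass(frozen=True)
class SiteMask:
    """Partition of 1-based alignment positions into kept and dropped."""

    kept_positions: tuple[int, ...]
    dropped_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.kept_positions) + len(self.dropped_positions)
        if set(self.kept_positions) | set(self.dropped_positions) != set(
            range(1, n + 1)
        ) or set(self.kept_positions) & set(self.dropped_positions):
            raise MaskError("kept and dropped must partition 1..n_sites")

    @property
    def n_sites(self) -> int:
        return len(self.kept_positions) + len(self.dropped_positions)

    @classmethod
    def from_dropped(cls, dropped: Iterable[int], n_sites: int) -> "SiteMask":
        dropped = tuple(sorted(set(int(p) for p in dropped)))
        if dropped and (dropped[0] < 1 or dropped[-1] > n_sites):
            raise MaskError(
                f"dropped positions must lie in 1..{n_sites}, got {dropped}"
            )
        kept = tuple(p for p in range(1, n_sites + 1) if p not in set(dropped))
        return cls(kept, dropped)

    def column_indices(self) -> np.ndarray:
        """0-based indices into the 4n-entry vector for kept quartets."""
        kept0 = np.asarray(self.kept_positions, dtype=int) - 1
        return (kept0[:, None] * 4 + np.arange(4)[None, :]).ravel()


def encode(seq: str, conv: EncodingConvention = DEFAULT_CONVENTION,
           id: str | None = None) -> SequenceVector:
    """Embed an aligned character string as stacked probability quartets.

    Canonical bases give unit basis quartets; IUPAC ambiguity codes give
    uniform quartets over compatible bases; ``N``/gaps give (1/4,)*4.

    Raises
    ------
    EncodingError
        If the sequence is empty or contains an unresolvable character
        (reported with its 1-based position).
    """
    if not seq:
        raise EncodingError("cannot encode empty sequence")
    codes = np.frombuffer(seq.upper().encode("ascii", "replace"), dtype=np.uint8)
    table, valid = conv.lookup_table()
    bad = np.nonzero(~valid[codes])[0]
    if bad.size:
        pos = int(bad[0]) + 1
        raise EncodingError(
            f"unresolvable character {seq[pos - 1]!r} at position {pos}"
            + (f" of {id}" if id else "")
        )
    return SequenceVector(table[codes].ravel(), len(seq), id=id)


def encode_matrix(rows: Sequence[str],
                  conv: EncodingConvention = DEFAULT_CONVENTION) -> np.ndarray:
    """Encode many equal-length sequences into an ``(n_seq, 4n)`` array."""
    if not rows:
        raise EncodingError("no sequences to encode")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ShapeError(f"sequences have unequal lengths: {sorted(lengths)}")
    table, valid = conv.lookup_table()
    codes = np.frombuffer("".join(r.upper() for r in rows).encode("ascii", "replace"),
                          dtype=np.uint8).reshape(len(rows), -1)
    bad_rows, bad_cols = np.nonzero(~valid[codes])
    if bad_rows.size:
        r, c = int(bad_rows[0]), int(bad_cols[0])
        raise EncodingError(
            f"unresolvable character {rows[r][c]!r} at position {c + 1} of row {r}"
        )
    return table[codes].reshape(len(rows), -1)


def decode_probabilities(v: SequenceVector | np.ndarray) -> np.ndarray:
    """Reshape a 4n vector into n rows of per-position base probabilities.

    Applied to the mean vector of an ensemble of encoded sequences, row ``p``
    holds the empirical base frequencies at position ``p``.
    """
    values = v.values if isinstance(v, SequenceVector) else np.asarray(v, float)
    if values.ndim != 1 or values.size % 4:
        raise ShapeError(f"length {values.size} is not divisible by 4")
    return values.reshape(-1, 4)


def quartet_sums(values: np.ndarray) -> np.ndarray:
    """Per-position sums of consecutive quartets of a 4n vector."""
    return decode_probabilities(values).sum(axis=1)


def find_conserved_sites(rows: Sequence[str], rule: str = "strict") -> SiteMask:
    """Identify alignment columns that carry no differential information.

    A conserved column contributes a constant to every inner product and is
    dropped before correlation analysis.

    Parameters
    ----------
    rows : sequences spanning all groups (equal lengths, >= 2 rows)
    rule : {"strict", "unambiguous"}
        ``strict``: a column is conserved iff every sequence carries the
        identical character and it is a canonical base (any ambiguity breaks
        conservation). ``unambiguous``: ambiguous characters are ignored and
        the column is conserved iff the canonical characters present are all
        identical (and at least one exists).
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 sequences to assess conservation")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ShapeError(f"sequences have unequal lengths: {sorted(lengths)}")
    arr = np.frombuffer("".join(r.upper() for r in rows).encode(),
                        dtype="S1").reshape(len(rows), -1)
    canonical = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    same_as_first = arr == arr[0]
    if rule == "strict":
        conserved = canonical.all(axis=0) & same_as_first.all(axis=0)
    elif rule == "unambiguous":
        n_canon = canonical.sum(axis=0)
        # per column: all canonical chars equal <=> at most one distinct value
        conserved = np.zeros(arr.shape[1], dtype=bool)
        for j in np.nonzero(n_canon > 0)[0]:
            col = arr[canonical[:, j], j]
            conserved[j] = (col == col[0]).all()
    else:
        raise ValueError(f"unknown conserved-site rule {rule!r}")
    dropped = tuple(int(j) + 1 for j in np.nonzero(conserved)[0])
    return SiteMask.from_dropped(dropped, arr.shape[1])


def apply_mask(v: SequenceVector, mask: SiteMask) -> SequenceVector:
    """Remove dropped positions' quartets from an embedded sequence."""
    if v.n_sites != mask.n_sites:
        raise ShapeError(
            f"mask covers {mask.n_sites} sites but vector has {v.n_sites}"
        )
    if not mask.kept_positions:
        raise MaskError("mask drops every position; nothing left to analyze")
    return SequenceVector(v.values[mask.column_indices()],
                          len(mask.kept_positions), v.id, v.normalized)


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ShapeError(f"unequal lengths {len(a)} vs {len(b)}")
    x = np.frombuffer(a.upper().encode(), dtype="S1")
    y = np.frombuffer(b.upper().encode(), dtype="S1")
    return int((x != y).sum())


def generalized_hamming(v: SequenceVector, w: SequenceVector) -> float:
    """Half squared Euclidean distance between embedded sequences.

    Equals the integer Hamming distance exactly when both sequences are
    unambiguous; ambiguous characters contribute a fractional mismatch.
    """
    if v.values.shape != w.values.shape:
        raise ShapeError(
            f"shape mismatch {v.values.shape} vs {w.values.shape}"
        )
    d = v.values - w.values
    return 0.5 * float(d @ d)


def correlation(v: SequenceVector, w: SequenceVector) -> float:
    """Cosine of the angle between embedded sequences (zero origin).

    For unambiguous sequences this equals ``1 - hamming/n`` on the encoded
    sites — the correlation coefficient of the law-of-cosines identity.
    """
    nv = float(np.linalg.norm(v.values))
    nw = float(np.linalg.norm(w.values))
    if nv == 0.0 or nw == 0.0:
        raise ShapeError("cannot correlate a zero vector")
    return float(v.values @ w.values) / (nv * nw)


# -- site-list serialization -------------------------------------------------

def load_site_list(path, offset: int = 0) -> list[int]:
    """Read a one-column text file of 1-based positions (``#`` comments
    allowed), adding ``offset`` to each (e.g. -99 maps original-alignment
    coordinates into a window starting at position 100)."""
    positions = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                positions.append(int(line) + offset)
    return positions


def save_site_list(positions: Iterable[int], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for p in positions:
            fh.write(f"{p}\n")


def reference_conserved_sites() -> list[int]:
    """The bundled conserved-position list for the standard 501-bp COI
    barcode window (original-alignment coordinates, positions 100-600)."""
    ref = importlib.resources.files("kleevec.data") / "coi_conserved_sites.txt"
    with importlib.resources.as_file(ref) as path:
        return load_site_list(path)
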