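"""Reading, windowing and quality-filtering of aligned sequence sets.

Input is a multiple sequence alignment of equal-length nucleotide rows
(FASTA) plus a group-membership manifest (TSV ``id<TAB>group``). Coordinates
in the public API are 1-based inclusive, matching the convention of barcode
window descriptions such as "positions 100 through 600".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import AlignmentError, EmptyDatasetError, ManifestError


@dataclass
class Alignment:
    """Equal-length aligned rows with parallel unique identifiers."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows must be parallel")
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        n = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(row)}, expected {n}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)]

    def subset(self, keep_ids: list[str]) -> "Alignment":
        index = {sid: i for i, sid in enumerate(self.ids)}
        return Alignment([sid for sid in keep_ids],
                         [self.rows[index[sid]] for sid in keep_ids])


@dataclass
class GroupManifest:
    """Sequence id -> group label, with groups in first-appearance order."""

    assignments: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for g in self.assignments.values():
            if g not in seen:
                seen.append(g)
        if not self.groups:
            self.groups = seen
        elif sorted(self.groups) != sorted(set(seen)):
            raise ManifestError("groups must be the labels used in assignments")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def members(self, group: str, order: list[str] | None = None) -> list[str]:
        """Ids assigned to ``group``, optionally in the order of ``order``."""
        ids = [i for i, g in self.assignments.items() if g == group]
        if order is not None:
            rank = {sid: k for k, sid in enumerate(order)}
            ids.sort(key=lambda sid: rank.get(sid, len(rank)))
        return ids


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_fasta(path) -> Alignment:
    """Parse an aligned FASTA file; uppercases and maps ``.`` to ``-``.

    Raises :class:`AlignmentError` naming the first id whose length differs,
    and on an empty file.
    """
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalize(str(rec.seq)))
    if not rows:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(ids, rows)


def write_fasta(aln: Alignment, path) -> None:
    records = [SeqRecord(Seq(row), id=sid, description="")
               for sid, row in zip(aln.ids, aln.rows)]
    SeqIO.write(records, str(path), "fasta")


def extract_window(aln: Alignment, start: int, end: int) -> Alignment:
    """Restrict to positions ``start..end`` (1-based, inclusive)."""
    if not (1 <= start <= end <= aln.n_sites):
        raise AlignmentError(
            f"window {start}..{end} out of range for {aln.n_sites} sites"
        )
    return Alignment(list(aln.ids), [r[start - 1:end] for r in aln.rows])


def filter_quality(
    aln: Alignment, max_ambiguous_fraction: float = 0.02
) -> tuple[Alignment, list[tuple[str, float]]]:
    """Drop rows with excessive ambiguous content.

    A character is ambiguous if outside ``{A, C, G, T}`` (gaps included).
    Returns the filtered alignment and a report of ``(id, fraction)`` for
    each dropped row.
    """
    if not 0.0 <= max_ambiguous_fraction <= 1.0:
        raise ValueError("max_ambiguous_fraction must lie in [0, 1]")
    keep_ids, keep_rows, dropped = [], [], []
    for sid, row in zip(aln.ids, aln.rows):
        frac = sum(c not in "ACGT" for c in row) / len(row)
        if frac > max_ambiguous_fraction:
            dropped.append((sid, frac))
        else:
            keep_ids.append(sid)
            keep_rows.append(row)
    if not keep_rows:
        raise EmptyDatasetError(
            f"quality filter at {max_ambiguous_fraction} dropped all "
            f"{len(aln)} sequences"
        )
    return Alignment(keep_ids, keep_rows), dropped


def read_manifest(path, aln: Alignment | None = None) -> GroupManifest:
    """Read a TSV manifest with header ``id<TAB>group``.

    If an alignment is given, every alignment id must be assigned a group
    (else :class:`ManifestError`); manifest ids absent from the alignment
    are reported as warnings. Duplicate rows with conflicting labels are an
    error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"id", "group"}.issubset(df.columns):
        raise ManifestError(
            f"manifest must have columns 'id' and 'group', got {list(df.columns)}"
        )
    assignments: dict[str, str] = {}
    for sid, group in zip(df["id"], df["group"]):
        if sid in assignments and assignments[sid] != group:
            raise ManifestError(
                f"id {sid!r} assigned to both {assignments[sid]!r} and {group!r}"
            )
        assignments[sid] = group
    if aln is not None:
        missing = [sid for sid in aln.ids if sid not in assignments]
        if missing:
            raise ManifestError(
                f"{len(missing)} alignment ids missing from manifest, "
                f"first: {missing[0]!r}"
            )
        extra = [sid for sid in assignments if sid not in set(aln.ids)]
        if extra:
            warnings.warn(
                f"{len(extra)} manifest ids not in alignment (e.g. {extra[0]!r})",
                stacklevel=2,
            )
    return GroupManifest(assignments)


def write_manifest(manifest: GroupManifest, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgroup\n")
        for sid, group in manifest.assignments.items():
            fh.write(f"{sid}\t{group}\n")


def write_dropped_report(dropped: list[tuple[str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tambiguous_fraction\n")
        for sid, frac in dropped:
            fh.write(f"{sid}\t{frac:.6f}\n")
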