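"""Insertion-region detection in multiple sequence alignments.

Spiral-forming nitrilases carry two sequence insertions relative to the
non-spiral members of the superfamily; in *B. pumilus* CynD these are
residues 55-72 (region 1) and 222-235 (region 2), and both map onto the
C-surface that drives spiral elongation.  This module parses alignments,
finds such insertions as gap runs in a chosen non-spiral reference, and
projects region boundaries between homologs.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Literal, Optional

from Bio import AlignIO

__all__ = [
    "Alignment",
    "InsertionRegion",
    "MappedRegion",
    "AlignmentError",
    "read_alignment",
    "detect_insertion_regions",
    "map_region_between_sequences",
]

# amino acids plus ambiguity codes (X/B/Z), selenocysteine U and gap symbols
_VALID = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZUOJacdefghiklmnpqrstvwyxbzuoj.\-]*$")


class AlignmentError(ValueError):
    pass


@dataclasses.dataclass
class Alignment:
    """Gapped sequences of equal length with unique ids."""

    sequences: list[tuple[str, str]]  # (id, gapped sequence)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [i for i, _ in self.sequences]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids")
        for sid, seq in self.sequences:
            if not _VALID.match(seq):
                bad = sorted({c for c in seq if not _VALID.match(c)})
                raise AlignmentError(f"invalid characters {bad} in sequence {sid!r}")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.sequences]

    def sequence(self, seq_id: str) -> str:
        for sid, seq in self.sequences:
            if sid == seq_id:
                return seq
        raise KeyError(f"sequence id {seq_id!r} not in alignment")


@dataclasses.dataclass(frozen=True)
class InsertionRegion:
    """A region in one sequence's ungapped 1-based coordinates, plus the
    alignment columns (0-based, inclusive) it came from."""

    sequence_id: str
    start: int
    end: int
    column_start: int
    column_end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def column_span(self) -> int:
        return self.column_end - self.column_start + 1


@dataclasses.dataclass(frozen=True)
class MappedRegion:
    """Result of projecting a region onto another sequence."""

    region: Optional[InsertionRegion]  # None when the target is all gaps
    absent: bool
    length_difference: Optional[int]  # source length minus target length


def read_alignment(
    path: str | Path, format: Literal["clustal", "aligned_fasta"] = "aligned_fasta"
) -> Alignment:
    """Read a Clustal or aligned-FASTA file into an :class:`Alignment`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"clustal": "clustal", "aligned_fasta": "fasta"}.get(format)
    if fmt is None:
        raise AlignmentError(f"unknown alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"failed to parse {path} as {format}: {exc}") from exc
    return Alignment([(rec.id, str(rec.seq)) for rec in msa])


def _ungapped_positions(seq: str) -> list[Optional[int]]:
    """Per-column ungapped 1-based residue number, None at gap columns."""
    out: list[Optional[int]] = []
    n = 0
    for c in seq:
        if c in "-.":
            out.append(None)
        else:
            n += 1
            out.append(n)
    return out


def detect_insertion_regions(
    alignment: Alignment,
    reference_id: str,
    query_id: str,
    min_length: int = 4,
    gap_merge: int = 2,
) -> list[InsertionRegion]:
    """Find query segments inserted relative to a non-spiral reference.

    An insertion column is one where the reference is gapped and the query
    holds a residue.  Maximal runs of insertion columns separated by fewer
    than ``gap_merge`` intervening columns are merged; merged runs whose
    query-residue count reaches ``min_length`` are reported in the query's
    ungapped 1-based coordinates.
    """
    ref = alignment.sequence(reference_id)
    qry = alignment.sequence(query_id)
    is_ins = [r in "-." and q not in "-." for r, q in zip(ref, qry)]
    runs: list[list[int]] = []  # [start_col, end_col]
    for col, flag in enumerate(is_ins):
        if not flag:
            continue
        if runs and col - runs[-1][1] - 1 < gap_merge:
            runs[-1][1] = col
        else:
            runs.append([col, col])
    qpos = _ungapped_positions(qry)
    regions = []
    for cs, ce in runs:
        residues = [qpos[c] for c in range(cs, ce + 1) if qpos[c] is not None]
        if len(residues) < min_length:
            continue
        regions.append(
            InsertionRegion(
                sequence_id=query_id,
                start=residues[0],
                end=residues[-1],
                column_start=cs,
                column_end=ce,
            )
        )
    return regions


def map_region_between_sequences(
    alignment: Alignment, region: InsertionRegion, target_id: str
) -> MappedRegion:
    """Project a region's alignment columns onto another sequence.

    Returns ``absent`` when the target is entirely gapped across the span;
    otherwise the target-coordinate region plus the source-minus-target
    length difference (e.g. a region eight residues shorter in beta-alanine
    synthase than in CynD gives a difference of 8).
    """
    if region.sequence_id not in alignment.ids:
        raise KeyError(f"region's sequence {region.sequence_id!r} not in alignment")
    tgt = alignment.sequence(target_id)
    tpos = _ungapped_positions(tgt)
    residues = [
        tpos[c]
        for c in range(region.column_start, region.column_end + 1)
        if tpos[c] is not None
    ]
    if not residues:
        return MappedRegion(region=None, absent=True, length_difference=None)
    mapped = InsertionRegion(
        sequence_id=target_id,
        start=residues[0],
        end=residues[-1],
        column_start=region.column_start,
        column_end=region.column_end,
    )
    return MappedRegion(
        region=mapped,
        absent=False,
        length_difference=region.length - mapped.length,
    )
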