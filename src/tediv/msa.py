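"""Aligned-FASTA I/O, coordinate maps, and pairwise extraction.

A multi-species alignment is held as an ordered list of equal-length gapped
sequences.  Pairwise analyses work on a :class:`PairAlignment`: two rows of
the parent alignment with every mutually gapped column removed, so that each
remaining gap is informative about an insertion or deletion separating the
two species.  Regions that were never sequenced (runs of ``N``, or intervals
supplied explicitly) are recorded as *missing* column intervals; downstream
metrics treat them as if the missing sequence exactly matched its partner —
the most conservative reading, contributing neither substitutions nor indels.

Coordinates are 0-based half-open throughout this module; ``-`` is the only
accepted gap character (``.`` is rejected so silently mixed conventions
cannot slip through).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError, CoordinateError, SpeciesLookupError

GAP = "-"
_FASTA_WRAP = 60


@dataclass(frozen=True)
class MissingSpec:
    """Policy describing which stretches of a sequence are unsequenced.

    Parameters
    ----------
    n_run_min:
        Minimum length of a run of ``N`` (in ungapped sequence coordinates)
        that is flagged as missing data.  ``None`` disables run detection.
    intervals:
        Explicit per-species intervals of missing sequence, 0-based
        half-open, in ungapped coordinates of that species.
    """

    n_run_min: int | None = 10
    intervals: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)


@dataclass
class MSA:
    """An ordered multiple sequence alignment over {A,C,G,T,N,-,IUPAC}."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentFormatError("an alignment needs at least 2 records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"records have unequal lengths: {sorted(lengths)}"
            )
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError("duplicate species ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def species_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def row(self, species_id: str) -> str:
        for sid, seq in self.records:
            if sid == species_id:
                return seq
        raise SpeciesLookupError(f"species {species_id!r} not in alignment")


@dataclass
class CoordinateMap:
    """Bidirectional map between alignment columns and ungapped positions."""

    species_id: str
    column_to_position: list[int | None]  # None at gap columns
    position_to_column: list[int]

    def column_of(self, position: int) -> int:
        if not 0 <= position < len(self.position_to_column):
            raise CoordinateError(
                f"position {position} outside ungapped length "
                f"{len(self.position_to_column)} of {self.species_id}"
            )
        return self.position_to_column[position]

    def position_at(self, column: int) -> int | None:
        if not 0 <= column < len(self.column_to_position):
            raise CoordinateError(f"column {column} outside alignment")
        return self.column_to_position[column]

    @property
    def ungapped_length(self) -> int:
        return len(self.position_to_column)


@dataclass
class PairAlignment:
    """Two alignment rows after mutual-gap stripping.

    ``missing_a``/``missing_b`` are half-open column intervals (in the
    stripped coordinate system) flagged as unsequenced in the respective
    species.
    """

    species_a: str
    species_b: str
    seq_a: str
    seq_b: str
    missing_a: list[tuple[int, int]] = field(default_factory=list)
    missing_b: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise AlignmentFormatError("pair rows differ in length")
        for interval_list in (self.missing_a, self.missing_b):
            for s, e in interval_list:
                if not (0 <= s < e <= self.length):
                    raise CoordinateError(f"missing interval ({s},{e}) outside pair")

    @property
    def length(self) -> int:
        return len(self.seq_a)

    def swapped(self) -> "PairAlignment":
        return PairAlignment(
            self.species_b, self.species_a, self.seq_b, self.seq_a,
            list(self.missing_b), list(self.missing_a),
        )


def _validate_alphabet(species_id: str, seq: str) -> None:
    if "." in seq:
        raise AlignmentFormatError(
            f"record {species_id!r} uses '.' as a gap; only '-' is accepted"
        )


def read_alignment(path: str | Path) -> MSA:
    """Read an aligned FASTA file into an :class:`MSA`.

    Record order is preserved and sequences are uppercased.  Records of
    unequal length raise :class:`AlignmentFormatError` naming the offender.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _validate_alphabet(rec.id, seq)
        records.append((rec.id, seq))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    ref_len = len(records[0][1])
    for sid, seq in records:
        if len(seq) != ref_len:
            raise AlignmentFormatError(
                f"record {sid!r} has length {len(seq)}, expected {ref_len}"
            )
    return MSA(records)


def write_alignment(msa: MSA, path: str | Path) -> None:
    """Write an alignment as FASTA, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in msa.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WRAP)
        writer.write_file(seq_records)


def build_coordinate_map(msa: MSA, species_id: str) -> CoordinateMap:
    """Map alignment columns to ungapped positions of one row (and back)."""
    row = msa.row(species_id)
    return coordinate_map_for_row(species_id, row)


def coordinate_map_for_row(species_id: str, row: str) -> CoordinateMap:
    col_to_pos: list[int | None] = []
    pos_to_col: list[int] = []
    pos = 0
    for col, ch in enumerate(row):
        if ch == GAP:
            col_to_pos.append(None)
        else:
            col_to_pos.append(pos)
            pos_to_col.append(col)
            pos += 1
    return CoordinateMap(species_id, col_to_pos, pos_to_col)


def ungapped(seq: str) -> str:
    return seq.replace(GAP, "")


def _n_run_intervals(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Ungapped-coordinate intervals of N runs of length >= min_len."""
    bases = ungapped(seq)
    out: list[tuple[int, int]] = []
    i = 0
    n = len(bases)
    while i < n:
        if bases[i] == "N":
            j = i
            while j < n and bases[j] == "N":
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _missing_columns(
    stripped_row: str,
    species_id: str,
    policy: MissingSpec,
) -> list[tuple[int, int]]:
    """Missing intervals of one stripped row, as stripped-column intervals.

    An ungapped missing interval [s, e) maps to the column span from the
    column of base s through the column of base e-1 inclusive; interior
    columns where this row is gapped (insertions in the partner) fall inside
    the span, which is intended: the region was never sequenced, so nothing
    can be said about indels there either.
    """
    ungapped_intervals: list[tuple[int, int]] = []
    if policy.n_run_min is not None:
        ungapped_intervals.extend(_n_run_intervals(stripped_row, policy.n_run_min))
    ungapped_intervals.extend(policy.intervals.get(species_id, ()))
    if not ungapped_intervals:
        return []
    cmap = coordinate_map_for_row(species_id, stripped_row)
    spans: list[tuple[int, int]] = []
    for s, e in _merge_intervals(ungapped_intervals):
        e = min(e, cmap.ungapped_length)
        if s >= e:
            continue
        spans.append((cmap.column_of(s), cmap.column_of(e - 1) + 1))
    return _merge_intervals(spans)


def extract_pair(
    msa: MSA,
    a: str,
    b: str,
    missing_policy: MissingSpec | None = None,
) -> PairAlignment:
    """Extract rows *a* and *b*, dropping columns gapped in both.

    Missing-data spans (per *missing_policy*) are recorded as column
    intervals in the stripped coordinate system.
    """
    policy = missing_policy or MissingSpec()
    row_a, row_b = msa.row(a), msa.row(b)
    kept = [
        (ca, cb) for ca, cb in zip(row_a, row_b) if not (ca == GAP and cb == GAP)
    ]
    seq_a = "".join(ca for ca, _ in kept)
    seq_b = "".join(cb for _, cb in kept)
    return PairAlignment(
        a, b, seq_a, seq_b,
        missing_a=_missing_columns(seq_a, a, policy),
        missing_b=_missing_columns(seq_b, b, policy),
    )


def in_any_interval(column: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= column < e for s, e in intervals)
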