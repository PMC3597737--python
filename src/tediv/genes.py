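"""Exon/intron gene models and their projection through an alignment.

Exon intervals live in ungapped species coordinates and are stored in
genomic order; ``strand`` says which direction transcription runs relative
to the alignment, and intron numbering follows transcription order (intron
4 of a minus-strand gene is the fourth gap between exons counted from the
transcription start, i.e. from the right end genomically).

Projection carries a reference transcript's exon boundaries through
alignment columns into another species.  A boundary that lands in a target
gap is moved toward the exon interior — exons shrink, introns never do —
which is the conservative choice for intron-length comparisons.  An exon
wholly deleted in the target projects to a zero-length interval and is
reported as degenerate rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import CoordinateError, ParameterError
from .msa import GAP, MSA, build_coordinate_map


@dataclass
class GeneModel:
    species_id: str
    gene_id: str
    strand: str  # transcription direction relative to the alignment: '+'|'-'
    exons: list[tuple[int, int]]  # genomic order, ungapped coords, half-open
    degenerate_exons: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ParameterError("a gene model needs at least one exon")
        if self.strand not in "+-":
            raise ParameterError(f"bad strand {self.strand!r}")
        prev_end = None
        for i, (s, e) in enumerate(self.exons):
            if s > e or (s == e and i not in self.degenerate_exons):
                raise CoordinateError(f"exon {i}: start {s} > end {e}")
            if prev_end is not None and s < prev_end:
                raise CoordinateError("exons overlap or are unsorted")
            prev_end = e

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def introns_genomic(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


def intron_length(model: GeneModel, intron_index: int) -> int:
    """Ungapped nucleotides of the *intron_index*-th intron (1-based,
    transcription order)."""
    if not 1 <= intron_index <= model.n_introns:
        raise ParameterError(
            f"intron {intron_index} out of range 1..{model.n_introns}"
        )
    introns = model.introns_genomic()
    if model.strand == "-":
        introns = introns[::-1]
    s, e = introns[intron_index - 1]
    return e - s


def intron_interval(model: GeneModel, intron_index: int) -> tuple[int, int]:
    """Genomic-coordinate interval of an intron addressed in transcription
    order (1-based)."""
    if not 1 <= intron_index <= model.n_introns:
        raise ParameterError(
            f"intron {intron_index} out of range 1..{model.n_introns}"
        )
    introns = model.introns_genomic()
    if model.strand == "-":
        introns = introns[::-1]
    return introns[intron_index - 1]


def project_exons(ref_model: GeneModel, msa: MSA, target_species: str) -> GeneModel:
    """Project a reference gene model onto another species through the MSA."""
    ref_cmap = build_coordinate_map(msa, ref_model.species_id)
    tgt_row = msa.row(target_species)
    tgt_cmap = build_coordinate_map(msa, target_species)

    def tgt_pos_right(col: int, limit: int) -> int | None:
        # first target base at or right of col, strictly before column limit
        while col < limit:
            if tgt_row[col] != GAP:
                return tgt_cmap.position_at(col)
            col += 1
        return None

    def tgt_pos_left(col: int, limit: int) -> int | None:
        # first target base at or left of col, strictly after column limit
        while col > limit:
            if tgt_row[col] != GAP:
                return tgt_cmap.position_at(col)
            col -= 1
        return None

    exons: list[tuple[int, int]] = []
    degenerate: list[int] = []
    last_end = 0
    for i, (s, e) in enumerate(ref_model.exons):
        if e > ref_cmap.ungapped_length:
            raise CoordinateError(
                f"exon {i} [{s},{e}) outside reference ungapped length"
            )
        col_s = ref_cmap.column_of(s)
        col_e = ref_cmap.column_of(e - 1)
        start = tgt_pos_right(col_s, col_e + 1)
        end_base = tgt_pos_left(col_e, col_s - 1)
        if start is None or end_base is None or end_base < start:
            anchor = tgt_pos_right(col_s, len(tgt_row))
            pos = anchor if anchor is not None else tgt_cmap.ungapped_length
            pos = max(pos, last_end)
            exons.append((pos, pos))
            degenerate.append(i)
            last_end = pos
        else:
            exons.append((start, end_base + 1))
            last_end = end_base + 1
    return GeneModel(
        species_id=target_species,
        gene_id=ref_model.gene_id,
        strand=ref_model.strand,
        exons=exons,
        degenerate_exons=degenerate,
    )


# --- I/O -------------------------------------------------------------------

def write_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (one line per model; exons as blocks)."""
    with open(path, "w") as fh:
        for m in models:
            chrom_start, chrom_end = m.span
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - chrom_start) for s, _ in m.exons) + ","
            fh.write(
                f"{m.species_id}\t{chrom_start}\t{chrom_end}\t{m.gene_id}\t0\t"
                f"{m.strand}\t{chrom_start}\t{chrom_end}\t0\t{len(m.exons)}\t"
                f"{sizes}\t{starts}\n"
            )


def read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom_start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            degenerate = [i for i, (s, e) in enumerate(exons) if s == e]
            models.append(
                GeneModel(
                    species_id=f[0], gene_id=f[3], strand=f[5], exons=exons,
                    degenerate_exons=degenerate,
                )
            )
    return models
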