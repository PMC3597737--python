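"""Transposable-element annotation: RepeatMasker ``.out`` parsing, projection
onto alignments, and the tallies built on top of it.

RepeatMasker reports 1-based inclusive query coordinates and encodes the
minus strand as ``C``; both are normalised here (0-based half-open, ``-``).
Element *uniqueness* between two species is decided by an explicit rule:
two elements are the same insertion if they share a class/family and
reciprocally overlap by at least half of the shorter element in alignment
columns (greedy matching, largest overlap first).  Orientation tallies split
elements into the Alu (class ``SINE/Alu``) and LTR (class ``LTR/*``)
categories and count strands relative to the host gene's transcription;
a manual-override list can exclude an element (e.g. one whose fixation
predates the gene family) or split one annotated element into two tallied
elements of opposite orientation (inverted tandem repeats).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import CoordinateError, ParseError
from .msa import CoordinateMap


@dataclass(frozen=True)
class RepeatElement:
    species_id: str
    name: str
    class_family: str
    start: int  # 0-based half-open, ungapped species coordinates
    end: int
    strand: str  # '+' or '-'
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CoordinateError(
                f"element {self.name}: start {self.start} >= end {self.end}"
            )
        if self.strand not in "+-":
            raise ParseError(f"element {self.name}: bad strand {self.strand!r}")
        if not self.class_family:
            raise ParseError(f"element {self.name}: empty class/family")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class OrientationTally:
    gene_id: str
    element_category: str  # 'Alu' or 'LTR'
    n_positive: int
    n_negative: int

    @property
    def percent_positive(self) -> float | None:
        total = self.n_positive + self.n_negative
        if total == 0:
            return None  # rendered as "N/A"
        return 100.0 * self.n_positive / total


@dataclass(frozen=True)
class ManualOverride:
    """Curation rule applied before orientation tallying.

    ``action`` is ``"exclude"`` (drop the element from the tally) or
    ``"split"`` (count it once in each orientation, for inverted tandem
    elements annotated as a single hit).  Elements are matched by repeat
    name and, if given, species.
    """

    name: str
    action: str  # 'exclude' | 'split'
    species_id: str | None = None

    def matches(self, e: RepeatElement) -> bool:
        return e.name == self.name and (
            self.species_id is None or e.species_id == self.species_id
        )


def parse_repeatmasker_out(
    path: str | Path,
    species_map: Mapping[str, str] | None = None,
) -> list[RepeatElement]:
    """Parse a RepeatMasker ``.out`` file.

    *species_map* translates the query-sequence name to a species id; when
    omitted, the query name is used verbatim.  An unknown query name (when a
    map is given) raises :class:`ParseError` with the line number.
    """
    elements: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if fields[0] in ("SW", "score") or stripped.startswith("There were no"):
                continue  # header / empty-result banner
            if len(fields) < 11:
                raise ParseError(
                    f"expected >= 11 whitespace-separated fields, got {len(fields)}",
                    lineno,
                )
            try:
                score = float(fields[0])
                query = fields[4]
                qstart = int(fields[5])
                qend = int(fields[6])
                strand_field = fields[8]
                name = fields[9]
                class_family = fields[10]
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            if strand_field == "C":
                strand = "-"
            elif strand_field == "+":
                strand = "+"
            else:
                raise ParseError(f"bad strand field {strand_field!r}", lineno)
            if species_map is not None:
                if query not in species_map:
                    raise ParseError(f"query name {query!r} not in species map", lineno)
                species_id = species_map[query]
            else:
                species_id = query
            elements.append(
                RepeatElement(
                    species_id=species_id,
                    name=name,
                    class_family=class_family,
                    start=qstart - 1,  # 1-based inclusive -> 0-based half-open
                    end=qend,
                    strand=strand,
                    score=score,
                )
            )
    return elements


def write_bed(elements: Iterable[RepeatElement], path: str | Path) -> None:
    """Export elements as BED6 (0-based half-open, strand in column 6)."""
    with open(path, "w") as fh:
        for e in elements:
            fh.write(
                f"{e.species_id}\t{e.start}\t{e.end}\t{e.name}\t"
                f"{int(e.score)}\t{e.strand}\n"
            )


def project_to_alignment(e: RepeatElement, cmap: CoordinateMap) -> tuple[int, int]:
    """Alignment-column interval [col(start), col(end-1)+1) of an element.

    Internal alignment gaps do not split the element; the span simply
    includes them.
    """
    if e.end > cmap.ungapped_length:
        raise CoordinateError(
            f"element {e.name} [{e.start},{e.end}) exceeds ungapped length "
            f"{cmap.ungapped_length} of {cmap.species_id}"
        )
    return (cmap.column_of(e.start), cmap.column_of(e.end - 1) + 1)


def project_from_alignment(
    columns: tuple[int, int], cmap: CoordinateMap
) -> tuple[int, int]:
    """Inverse of :func:`project_to_alignment` for spans that start and end
    on bases of the mapped species."""
    start_pos = cmap.position_at(columns[0])
    end_pos = cmap.position_at(columns[1] - 1)
    if start_pos is None or end_pos is None:
        raise CoordinateError("span boundary falls on a gap of this species")
    return (start_pos, end_pos + 1)


def count_elements(
    elements: Sequence[RepeatElement],
    span: tuple[int, int],
) -> tuple[int, dict[str, int]]:
    """Count elements whose midpoint lies in *span* (ungapped coordinates).

    Returns the total and a per-class/family breakdown.  The midpoint rule
    counts a boundary-straddling element exactly once.
    """
    s, e = span
    total = 0
    by_family: dict[str, int] = {}
    for el in elements:
        if s <= el.midpoint < e:
            total += 1
            by_family[el.class_family] = by_family.get(el.class_family, 0) + 1
    return total, dict(sorted(by_family.items()))


@dataclass
class SharedElements:
    shared: list[tuple[RepeatElement, RepeatElement]]
    unique_a: list[RepeatElement]
    unique_b: list[RepeatElement]

    @property
    def n_unique(self) -> int:
        return len(self.unique_a) + len(self.unique_b)


def unique_elements(
    ann_a: Sequence[RepeatElement],
    ann_b: Sequence[RepeatElement],
    cmap_a: CoordinateMap,
    cmap_b: CoordinateMap,
    min_reciprocal_overlap: float = 0.5,
) -> SharedElements:
    """Match elements of two species in shared alignment coordinates.

    Two elements are the same insertion when they have identical
    class/family and their alignment-column spans overlap reciprocally by
    at least *min_reciprocal_overlap* of the *shorter* span.  Matching is
    greedy by descending overlap; every unmatched element is unique.
    """
    spans_a = [project_to_alignment(e, cmap_a) for e in ann_a]
    spans_b = [project_to_alignment(e, cmap_b) for e in ann_b]
    candidates: list[tuple[int, int, int]] = []  # (overlap, i, j)
    for i, (ea, sa) in enumerate(zip(ann_a, spans_a)):
        for j, (eb, sb) in enumerate(zip(ann_b, spans_b)):
            if ea.class_family != eb.class_family:
                continue
            overlap = min(sa[1], sb[1]) - max(sa[0], sb[0])
            if overlap <= 0:
                continue
            shorter = min(sa[1] - sa[0], sb[1] - sb[0])
            if overlap >= min_reciprocal_overlap * shorter:
                candidates.append((overlap, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    shared: list[tuple[RepeatElement, RepeatElement]] = []
    for _, i, j in candidates:
        if i in matched_a or j in matched_b:
            continue
        matched_a.add(i)
        matched_b.add(j)
        shared.append((ann_a[i], ann_b[j]))
    return SharedElements(
        shared=shared,
        unique_a=[e for i, e in enumerate(ann_a) if i not in matched_a],
        unique_b=[e for j, e in enumerate(ann_b) if j not in matched_b],
    )


def element_category(e: RepeatElement) -> str | None:
    """'Alu' for class SINE/Alu, 'LTR' for class LTR/*, else None."""
    if e.class_family.startswith("SINE/Alu"):
        return "Alu"
    if e.class_family.startswith("LTR"):
        return "LTR"
    return None


def orientation_tally(
    elements: Sequence[RepeatElement],
    gene_id: str,
    gene_strand: str,
    overrides: Sequence[ManualOverride] = (),
) -> dict[str, OrientationTally]:
    """Tally Alu and LTR element orientations relative to gene transcription.

    An element is *positive* when its strand equals *gene_strand*.  Override
    rules are applied first: excluded elements are dropped; a split element
    contributes one positive and one negative count.
    """
    tallies = {
        cat: OrientationTally(gene_id, cat, 0, 0) for cat in ("Alu", "LTR")
    }
    for e in elements:
        cat = element_category(e)
        if cat is None:
            continue
        rule = next((o for o in overrides if o.matches(e)), None)
        if rule is not None and rule.action == "exclude":
            continue
        t = tallies[cat]
        if rule is not None and rule.action == "split":
            t.n_positive += 1
            t.n_negative += 1
            continue
        if e.strand == gene_strand:
            t.n_positive += 1
        else:
            t.n_negative += 1
    return tallies


def orientation_table(tallies: Iterable[OrientationTally]) -> str:
    """Human-readable TSV with columns gene, category, +, -, Percent Positive."""
    lines = ["gene\tcategory\t+\t-\tpercent_positive"]
    for t in tallies:
        pp = t.percent_positive
        pp_str = "N/A" if pp is None else f"{pp:.1f}".rstrip("0").rstrip(".")
        lines.append(
            f"{t.gene_id}\t{t.element_category}\t{t.n_positive}\t{t.n_negative}\t{pp_str}"
        )
    return "\n".join(lines) + "\n"


def family_content(
    elements: Sequence[RepeatElement],
    interval: tuple[int, int],
    class_family_prefix: str,
) -> int:
    """Nucleotides of a repeat family inside an ungapped interval.

    Overlapping annotated fragments are merged before summation, so the
    result never exceeds the interval length.
    """
    s, e = interval
    spans = sorted(
        (max(el.start, s), min(el.end, e))
        for el in elements
        if el.class_family.startswith(class_family_prefix)
        and el.start < e and el.end > s
    )
    total = 0
    cur_s: int | None = None
    cur_e = 0
    for a, b in spans:
        if cur_s is None:
            cur_s, cur_e = a, b
        elif a <= cur_e:
            cur_e = max(cur_e, b)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = a, b
    if cur_s is not None:
        total += cur_e - cur_s
    return total
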