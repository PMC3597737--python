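"""Pairwise divergence and indel statistics.

Four quantities summarise how two orthologous gene-region sequences have
diverged since their most recent common ancestor (MRCA), T million years
(Myr) ago:

* percent nucleotide identity — matching columns (plus missing-data columns,
  assumed identical) over all columns of the mutually de-gapped pair; a
  column where one sequence is gapped is a non-match, so large indels
  depress identity far below what substitutions alone could.
* substitution rate — mismatching both-base columns over all both-base
  columns, per Myr, as percent of sequence per Myr.  No multiple-hit
  correction is applied: raw proportions.
* indel change rate — nucleotides inside indels over all columns, per Myr
  (percent of sequence per Myr).
* indel creation rate — number of indel events per Myr.

An *indel event* is a maximal run of gap characters in one sequence while
the other carries bases (after mutual-gap stripping).  Runs that touch a
missing-data interval are suppressed: an unsequenced region is assumed to
match its partner exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .msa import GAP, PairAlignment, in_any_interval


@dataclass(frozen=True)
class IndelEvent:
    """A maximal one-sided gap run in a mutually de-gapped pair."""

    host: str  # 'a' or 'b': which sequence carries the gap
    start_column: int
    end_column: int  # half-open

    @property
    def size(self) -> int:
        return self.end_column - self.start_column


@dataclass
class PairMetrics:
    species_a: str
    species_b: str
    T: float
    percent_identity: float
    substitution_rate: float
    indel_change_rate: float
    indel_creation_rate: float
    n_indels: int
    indel_nt: int
    mean_indel_size: float | None
    median_indel_size: float | None


def call_indels(pair: PairAlignment) -> list[IndelEvent]:
    """Maximal one-sided gap runs outside missing intervals, in column order.

    Abutting runs hosted by opposite sequences are separate events.  A run
    overlapping a missing interval of either species is dropped entirely.
    Terminal runs count: alignments are expected to span a common region,
    with true terminal overhangs flagged as missing by the caller.
    """
    events: list[IndelEvent] = []
    a, b = pair.seq_a, pair.seq_b
    n = pair.length
    i = 0
    while i < n:
        if a[i] == GAP:
            host = "a"
        elif b[i] == GAP:
            host = "b"
        else:
            i += 1
            continue
        seq = a if host == "a" else b
        j = i
        while j < n and seq[j] == GAP:
            j += 1
        overlaps_missing = any(
            in_any_interval(col, pair.missing_a) or in_any_interval(col, pair.missing_b)
            for col in range(i, j)
        )
        if not overlaps_missing:
            events.append(IndelEvent(host, i, j))
        i = j
    return events


def _column_is_missing(pair: PairAlignment, col: int) -> bool:
    return in_any_interval(col, pair.missing_a) or in_any_interval(col, pair.missing_b)


def percent_identity(pair: PairAlignment) -> float:
    """100 x (matching columns + missing columns) / total columns."""
    if pair.length == 0:
        raise DegenerateDataError("percent identity undefined on empty pair")
    matches = 0
    for col, (ca, cb) in enumerate(zip(pair.seq_a, pair.seq_b)):
        if _column_is_missing(pair, col):
            matches += 1
        elif ca == cb and ca != GAP:
            matches += 1
    return 100.0 * matches / pair.length


def _check_T(T: float) -> None:
    if not T > 0:
        raise ParameterError(f"divergence time T must be positive, got {T}")


def substitution_rate(pair: PairAlignment, T: float) -> float:
    """Mismatching both-base columns / both-base columns / T, as %/Myr.

    Missing columns stay in the denominator but never count as mismatches
    (assumed identical).  Substitutions are undefined opposite a gap, so
    one-sided gap columns are excluded; their content is already measured
    by the indel change rate.
    """
    _check_T(T)
    both_base = 0
    mismatches = 0
    for col, (ca, cb) in enumerate(zip(pair.seq_a, pair.seq_b)):
        if ca == GAP or cb == GAP:
            continue
        both_base += 1
        if ca != cb and not _column_is_missing(pair, col):
            mismatches += 1
    if both_base == 0:
        raise DegenerateDataError("no both-base columns in pair")
    return 100.0 * mismatches / both_base / T


def indel_change_rate(pair: PairAlignment, T: float, events: Sequence[IndelEvent] | None = None) -> float:
    """100 x (total indel nucleotides) / (pair columns) / T, as %/Myr."""
    _check_T(T)
    if pair.length == 0:
        raise DegenerateDataError("indel change rate undefined on empty pair")
    if events is None:
        events = call_indels(pair)
    return 100.0 * sum(e.size for e in events) / pair.length / T


def indel_creation_rate(pair: PairAlignment, T: float, events: Sequence[IndelEvent] | None = None) -> float:
    """Number of indel events / T, in indels per Myr."""
    _check_T(T)
    if events is None:
        events = call_indels(pair)
    return len(events) / T


def indel_size_summary(events: Sequence[IndelEvent]) -> tuple[float | None, float | None]:
    """(mean, median) indel size in nt; (None, None) when there are no events.

    The even-count median is the average of the two central sizes.  Zero-indel
    pairs are undefined, never 0, so they can be excluded from size averages
    while still contributing rate 0 to rate averages.
    """
    sizes = sorted(e.size for e in events)
    if not sizes:
        return (None, None)
    n = len(sizes)
    mean = sum(sizes) / n
    if n % 2:
        median = float(sizes[n // 2])
    else:
        median = (sizes[n // 2 - 1] + sizes[n // 2]) / 2
    return (mean, median)


def bin_indels(events: Sequence[IndelEvent], bin_width: int = 100) -> dict[int, int]:
    """Histogram of indel sizes in closed bins of *bin_width* nt.

    Bin k (1-based) holds sizes in [(k-1)*width + 1, k*width]; a 100-nt
    indel falls in bin 1 and a 101-nt indel in bin 2.  Only occupied bins
    appear in the result.
    """
    if bin_width < 1:
        raise ParameterError("bin_width must be >= 1")
    hist: dict[int, int] = {}
    for e in events:
        k = (e.size - 1) // bin_width + 1
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def pair_metrics(pair: PairAlignment, T: float) -> PairMetrics:
    """All pairwise statistics from a single consistent indel call."""
    events = call_indels(pair)
    mean_size, median_size = indel_size_summary(events)
    return PairMetrics(
        species_a=pair.species_a,
        species_b=pair.species_b,
        T=T,
        percent_identity=percent_identity(pair),
        substitution_rate=substitution_rate(pair, T),
        indel_change_rate=indel_change_rate(pair, T, events),
        indel_creation_rate=indel_creation_rate(pair, T, events),
        n_indels=len(events),
        indel_nt=sum(e.size for e in events),
        mean_indel_size=mean_size,
        median_indel_size=median_size,
    )


# --- reporting -------------------------------------------------------------

_TSV_COLUMNS = [
    "species_a", "species_b", "T_myr", "pct_identity", "sub_rate",
    "indel_change_rate", "indel_creation_rate", "n_indels", "indel_nt",
    "mean_indel_size", "median_indel_size",
]


def metrics_frame(metrics: Iterable[PairMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        d = asdict(m)
        d["T_myr"] = d.pop("T")
        d["pct_identity"] = d.pop("percent_identity")
        d["sub_rate"] = d.pop("substitution_rate")
        rows.append(d)
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_metrics_tsv(metrics: Iterable[PairMetrics], path: str | Path) -> None:
    metrics_frame(metrics).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_metrics_json(metrics: Iterable[PairMetrics], path: str | Path) -> None:
    records = metrics_frame(metrics).to_dict(orient="records")
    for rec in records:
        for k, v in rec.items():
            if isinstance(v, float) and math.isnan(v):
                rec[k] = None
    Path(path).write_text(json.dumps(records, indent=2) + "\n")
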