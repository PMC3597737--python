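"""Gene-level orchestration: run the pairwise statistics over every species
pair of an alignment, overlay TE annotations, and assemble the group-level
comparisons across genes."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from .divergence import DivergenceTable
from .errors import ParameterError
from .genes import GeneModel, intron_interval, intron_length
from .metrics import (
    PairMetrics,
    call_indels,
    metrics_frame,
    pair_metrics,
)
from .msa import MSA, MissingSpec, build_coordinate_map, extract_pair, read_alignment
from .repeats import (
    ManualOverride,
    OrientationTally,
    RepeatElement,
    family_content,
    orientation_tally,
    unique_elements,
)
from .stats import BlockedMatrix, group_stats_table, spearman


@dataclass
class GeneAnalysis:
    gene_id: str
    metrics: list[PairMetrics]
    indel_bins: dict[int, int]
    indel_sizes: list[int]
    unique_te_counts: pd.DataFrame | None = None
    te_totals: pd.DataFrame | None = None
    orientation: dict[str, OrientationTally] | None = None
    intron_summary: pd.DataFrame | None = None

    @property
    def metrics_frame(self) -> pd.DataFrame:
        return metrics_frame(self.metrics)


def species_pairs(msa: MSA) -> list[tuple[str, str]]:
    return list(combinations(msa.species_ids, 2))


def analyze_gene(
    msa: MSA,
    dates: DivergenceTable,
    gene_id: str = "gene",
    missing_policy: MissingSpec | None = None,
    bin_width: int = 100,
    repeats: dict[str, list[RepeatElement]] | None = None,
    gene_models: dict[str, GeneModel] | None = None,
    gene_strand: str = "+",
    overlap_threshold: float = 0.5,
    overrides: Sequence[ManualOverride] = (),
    intron_of_interest: int = 4,
) -> GeneAnalysis:
    """All per-gene analyses: pairwise metrics, indel size spectrum, and —
    when annotations are provided — TE totals, per-pair unique-TE counts,
    orientation tallies, and intron summaries."""
    policy = missing_policy or MissingSpec()
    metrics: list[PairMetrics] = []
    sizes: list[int] = []
    for a, b in species_pairs(msa):
        pair = extract_pair(msa, a, b, policy)
        events = call_indels(pair)
        sizes.extend(e.size for e in events)
        metrics.append(pair_metrics(pair, dates.time(a, b)))
    bins = bin_indels_from_sizes(sizes, bin_width)
    analysis = GeneAnalysis(gene_id, metrics, bins, sizes)

    if repeats is not None:
        cmaps = {sid: build_coordinate_map(msa, sid) for sid in msa.species_ids}
        totals = []
        for sid in msa.species_ids:
            anns = repeats.get(sid, [])
            totals.append({"species": sid, "n_elements": len(anns)})
        analysis.te_totals = pd.DataFrame(totals)
        uniq_rows = []
        union_unique: list[RepeatElement] = []
        for a, b in species_pairs(msa):
            res = unique_elements(
                repeats.get(a, []), repeats.get(b, []), cmaps[a], cmaps[b],
                min_reciprocal_overlap=overlap_threshold,
            )
            uniq_rows.append(
                {"species_a": a, "species_b": b, "n_unique": res.n_unique,
                 "n_shared": len(res.shared)}
            )
            union_unique.extend(res.unique_a)
            union_unique.extend(res.unique_b)
        analysis.unique_te_counts = pd.DataFrame(uniq_rows)
        analysis.orientation = orientation_tally(
            _deduplicate(union_unique), gene_id, gene_strand, overrides
        )

    if gene_models is not None:
        rows = []
        for sid, model in gene_models.items():
            if model.n_introns < intron_of_interest:
                continue
            length = intron_length(model, intron_of_interest)
            l1_nt = None
            if repeats is not None:
                interval = intron_interval(model, intron_of_interest)
                l1_nt = family_content(repeats.get(sid, []), interval, "LINE/L1")
            rows.append(
                {"species": sid, "intron_index": intron_of_interest,
                 "intron_length_nt": length, "line_l1_nt": l1_nt}
            )
        analysis.intron_summary = pd.DataFrame(rows)
    return analysis


def _deduplicate(elements: list[RepeatElement]) -> list[RepeatElement]:
    seen = set()
    out = []
    for e in elements:
        key = (e.species_id, e.name, e.start, e.end, e.strand)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


def bin_indels_from_sizes(sizes: Sequence[int], bin_width: int = 100) -> dict[int, int]:
    if bin_width < 1:
        raise ParameterError("bin_width must be >= 1")
    hist: dict[int, int] = {}
    for s in sizes:
        k = (s - 1) // bin_width + 1
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def fraction_under(sizes: Sequence[int], threshold_nt: int = 10) -> float:
    """Fraction of indel events strictly smaller than *threshold_nt*."""
    if not sizes:
        raise ParameterError("no indel events")
    return sum(1 for s in sizes if s < threshold_nt) / len(sizes)


def cross_gene_stats(analyses: Sequence[GeneAnalysis]) -> pd.DataFrame:
    """Friedman + Dunn comparisons of every pairwise metric across genes,
    with species pairs as blocks."""
    frames = []
    for a in analyses:
        f = a.metrics_frame.copy()
        f["gene"] = a.gene_id
        frames.append(f)
    stacked = pd.concat(frames, ignore_index=True)
    stacked["pair"] = stacked["species_a"] + "|" + stacked["species_b"]
    matrices = {}
    for metric in (
        "pct_identity", "sub_rate", "indel_change_rate", "indel_creation_rate",
        "mean_indel_size",
    ):
        matrices[metric] = BlockedMatrix.from_frame(
            stacked, "pair", "gene", metric
        )
    return group_stats_table(matrices)


def identity_vs_indel_correlation(analysis: GeneAnalysis) -> tuple[float, float]:
    """Spearman correlation of percent identity against indel change rate."""
    f = analysis.metrics_frame
    return spearman(f["pct_identity"], f["indel_change_rate"])


def gene_alignment_statistics(
    path: str | Path,
    missing_policy: MissingSpec | None = None,
) -> dict[str, float]:
    """Identity and indel-size statistics of one aligned-FASTA gene region.

    Computes, over all species pairs: minimum and mean percent identity and
    the fraction of called indels under 10 nt.  Divergence dates are not
    needed for these time-free quantities.
    """
    msa = read_alignment(path)
    policy = missing_policy or MissingSpec()
    identities: list[float] = []
    sizes: list[int] = []
    from .metrics import percent_identity

    for a, b in species_pairs(msa):
        pair = extract_pair(msa, a, b, policy)
        identities.append(percent_identity(pair))
        sizes.extend(e.size for e in call_indels(pair))
    return {
        "n_pairs": float(len(identities)),
        "min_percent_identity": min(identities),
        "mean_percent_identity": sum(identities) / len(identities),
        "fraction_indels_under_10nt": fraction_under(sizes, 10),
        "n_indels": float(len(sizes)),
    }
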