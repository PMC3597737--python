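"""Sequence evolution with substitutions, short indels, and TE insertions
along a dated phylogeny.

Every nucleotide that ever exists carries a globally unique *site id*, so
homology is tracked exactly: the emitted multi-species alignment is the
true alignment (insertions open gap columns in non-carriers and are never
re-aligned), TE insertions are annotated at their realised leaf
coordinates, and a :class:`TruthLedger` records every event so that a
deterministic replay reproduces each leaf byte-for-byte.

The indel process mixes frequent short events (geometric sizes, mean a few
nt) with rare long insertions drawn from a TE library (>= 300 nt entries
carrying a repeat name, class/family, and strand), mirroring the empirical
size mixture in primate gene regions where the overwhelming majority of
indels are under 100 nt but the large ones are transposable elements.

Rates are *per lineage*: a pair of species separated by T Myr since their
MRCA accrues events over ~2T Myr of branch path, while the pairwise
estimators divide by T — recovery comparisons must therefore target twice
the per-lineage rate (see :func:`recovery_report`).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .divergence import DivergenceTable
from .errors import ParameterError
from .genes import GeneModel
from .msa import MSA
from .repeats import RepeatElement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TELibraryEntry:
    name: str
    class_family: str
    length: int


DEFAULT_TE_LIBRARY: tuple[TELibraryEntry, ...] = (
    TELibraryEntry("AluY", "SINE/Alu", 300),
    TELibraryEntry("AluSx", "SINE/Alu", 310),
    TELibraryEntry("L1PA4", "LINE/L1", 6000),
    TELibraryEntry("L1MB5", "LINE/L1", 2400),
    TELibraryEntry("LTR10D", "LTR/ERV1", 516),
    TELibraryEntry("MLT1C", "LTR/ERVL-MaLR", 480),
    TELibraryEntry("MER21B", "LTR/ERVL", 980),
)


@dataclass
class SimParams:
    """Simulation parameters; rates are per lineage.

    sub_rate is % of sites per Myr; indel_rate is short-indel events per
    100 nt per Myr; te_insert_rate is TE insertion events per branch per
    Myr (independent of length, emulating family activity bursts).
    """

    tree: str  # newick with branch lengths in Myr
    root_length: int = 10_000
    sub_rate: float = 0.15
    indel_rate: float = 0.02
    short_indel_mean: float = 3.0
    deletion_fraction: float = 0.5
    te_insert_rate: float = 0.05
    te_library: tuple[TELibraryEntry, ...] = DEFAULT_TE_LIBRARY
    te_positive_prob: float = 0.5
    missing_fraction: float = 0.0
    missing_span_nt: int = 500
    n_exons: int = 8
    exon_nt: int = 150
    gene_id: str = "gene"
    gene_strand: str = "+"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate", "te_insert_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("deletion_fraction", "te_positive_prob", "missing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.short_indel_mean < 1:
            raise ParameterError("short_indel_mean must be >= 1 nt")
        for entry in self.te_library:
            if entry.length < 300:
                raise ParameterError(
                    f"TE library entry {entry.name} shorter than 300 nt"
                )
        if self.root_length < self.n_exons * self.exon_nt:
            raise ParameterError("root too short for the requested exon layout")


# --- truth ledger ----------------------------------------------------------

@dataclass
class SubstitutionEvent:
    site_id: int
    old: str
    new: str


@dataclass
class IndelTruthEvent:
    kind: str  # 'insertion' | 'deletion' | 'te_insertion'
    size: int
    left_neighbor: int | None = None  # site id after which insertion goes
    site_ids: list[int] = field(default_factory=list)
    chars: str = ""  # inserted characters, '' for deletions
    te_name: str | None = None
    te_class_family: str | None = None
    te_strand: str | None = None


@dataclass
class BranchEvents:
    branch: str  # child-node label: leaf taxon, or sorted leaf set
    substitutions: list[SubstitutionEvent] = field(default_factory=list)
    indels: list[IndelTruthEvent] = field(default_factory=list)


@dataclass
class TruthLedger:
    root_site_ids: list[int]
    root_chars: str
    branches: list[BranchEvents]
    missing_spans: dict[str, tuple[int, int]]  # leaf -> ungapped span
    divergence: dict[str, float]  # "a|b" -> Myr since MRCA

    def to_json(self) -> str:
        payload = {
            "root_site_ids": self.root_site_ids,
            "root_chars": self.root_chars,
            "branches": [asdict(b) for b in self.branches],
            "missing_spans": {k: list(v) for k, v in self.missing_spans.items()},
            "divergence": self.divergence,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        d = json.loads(text)
        branches = [
            BranchEvents(
                branch=b["branch"],
                substitutions=[SubstitutionEvent(**s) for s in b["substitutions"]],
                indels=[IndelTruthEvent(**e) for e in b["indels"]],
            )
            for b in d["branches"]
        ]
        return cls(
            root_site_ids=d["root_site_ids"],
            root_chars=d["root_chars"],
            branches=branches,
            missing_spans={k: tuple(v) for k, v in d["missing_spans"].items()},
            divergence=d["divergence"],
        )


@dataclass
class SimResult:
    msa: MSA
    repeats: dict[str, list[RepeatElement]]
    gene_models: dict[str, GeneModel]
    divergence: DivergenceTable
    ledger: TruthLedger
    params: SimParams


# --- internal evolving state ----------------------------------------------

class _Lineage:
    """A sequence as an ordered list of site ids plus id -> base map."""

    __slots__ = ("ids", "chars")

    def __init__(self, ids: list[int], chars: dict[int, str]):
        self.ids = ids
        self.chars = chars

    def copy(self) -> "_Lineage":
        return _Lineage(list(self.ids), dict(self.chars))

    def string(self) -> str:
        return "".join(self.chars[i] for i in self.ids)

    def __len__(self) -> int:
        return len(self.ids)


class _IdAllocator:
    def __init__(self, start: int):
        self.next_id = start

    def take(self, n: int) -> list[int]:
        ids = list(range(self.next_id, self.next_id + n))
        self.next_id += n
        return ids


def _branch_rng(seed: int, branch_label: str) -> np.random.Generator:
    # Substream keyed by (seed, branch label) so editing one part of the
    # topology does not reshuffle unrelated branches.
    return np.random.default_rng([seed, zlib.crc32(branch_label.encode())])


def _node_label(node: dendropy.Node) -> str:
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return leaves[0] if len(leaves) == 1 else "|".join(leaves)


def _insert_into_master(
    master: list[int], left_neighbor: int | None, new_ids: list[int]
) -> None:
    if left_neighbor is None:
        master[0:0] = new_ids
    else:
        idx = master.index(left_neighbor)
        master[idx + 1 : idx + 1] = new_ids


def _evolve_branch(
    lineage: _Lineage,
    t: float,
    params: SimParams,
    rng: np.random.Generator,
    alloc: _IdAllocator,
    master: list[int],
    events: BranchEvents,
    te_origin: dict[int, IndelTruthEvent],
) -> None:
    """Mutate *lineage* in place over a branch of *t* Myr, recording events."""
    # substitutions: linear (no multiple hits along one branch), rates small
    p_sub = min(1.0, params.sub_rate / 100.0 * t)
    if p_sub > 0 and len(lineage) > 0:
        n_sub = rng.binomial(len(lineage), p_sub)
        positions = rng.choice(len(lineage), size=n_sub, replace=False)
        for pos in sorted(int(p) for p in positions):
            sid = lineage.ids[pos]
            old = lineage.chars[sid]
            choices = [b for b in "ACGT" if b != old]
            new = choices[int(rng.integers(len(choices)))]
            lineage.chars[sid] = new
            events.substitutions.append(SubstitutionEvent(sid, old, new))

    # short indels: Poisson in number, geometric in size
    lam = params.indel_rate * (len(lineage) / 100.0) * t
    n_indels = int(rng.poisson(lam)) if lam > 0 else 0
    for _ in range(n_indels):
        size = int(rng.geometric(1.0 / params.short_indel_mean))
        if rng.random() < params.deletion_fraction and len(lineage) > 0:
            start = int(rng.integers(len(lineage)))
            size = min(size, len(lineage) - start)
            removed = lineage.ids[start : start + size]
            for sid in removed:
                del lineage.chars[sid]
            del lineage.ids[start : start + size]
            events.indels.append(
                IndelTruthEvent(kind="deletion", size=size, site_ids=list(removed))
            )
        else:
            pos = int(rng.integers(len(lineage) + 1))
            left = lineage.ids[pos - 1] if pos > 0 else None
            new_ids = alloc.take(size)
            chars = "".join(_BASES[rng.integers(4, size=size)])
            for sid, ch in zip(new_ids, chars):
                lineage.chars[sid] = ch
            lineage.ids[pos:pos] = new_ids
            _insert_into_master(master, left, new_ids)
            events.indels.append(
                IndelTruthEvent(
                    kind="insertion", size=size, left_neighbor=left,
                    site_ids=new_ids, chars=chars,
                )
            )

    # TE insertions: Poisson per branch-Myr, drawn from the library
    lam_te = params.te_insert_rate * t
    n_te = int(rng.poisson(lam_te)) if lam_te > 0 else 0
    for _ in range(n_te):
        entry = params.te_library[int(rng.integers(len(params.te_library)))]
        strand = "+" if rng.random() < params.te_positive_prob else "-"
        pos = int(rng.integers(len(lineage) + 1))
        left = lineage.ids[pos - 1] if pos > 0 else None
        new_ids = alloc.take(entry.length)
        chars = "".join(_BASES[rng.integers(4, size=entry.length)])
        for sid, ch in zip(new_ids, chars):
            lineage.chars[sid] = ch
        lineage.ids[pos:pos] = new_ids
        _insert_into_master(master, left, new_ids)
        ev = IndelTruthEvent(
            kind="te_insertion", size=entry.length, left_neighbor=left,
            site_ids=new_ids, chars=chars, te_name=entry.name,
            te_class_family=entry.class_family, te_strand=strand,
        )
        events.indels.append(ev)
        for sid in new_ids:
            te_origin[sid] = ev


def _load_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ParameterError("tree edges must carry branch lengths in Myr")
    if len(tree.leaf_nodes()) < 2:
        raise ParameterError("tree needs at least two leaves")
    return tree


def _divergence_from_tree(tree: dendropy.Tree) -> DivergenceTable:
    pdm = tree.phylogenetic_distance_matrix()
    times: dict[tuple[str, str], float] = {}
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            # mean one-sided path from the MRCA = half the patristic distance
            times[(ta.label, tb.label)] = pdm.patristic_distance(ta, tb) / 2.0
    return DivergenceTable(times)


def simulate(params: SimParams) -> SimResult:
    """Run the simulator; deterministic for a fixed seed."""
    tree = _load_tree(params.tree)
    root_rng = np.random.default_rng([params.seed, zlib.crc32(b"root")])
    alloc = _IdAllocator(0)
    root_ids = alloc.take(params.root_length)
    root_chars = "".join(_BASES[root_rng.integers(4, size=params.root_length)])
    root = _Lineage(list(root_ids), dict(zip(root_ids, root_chars)))
    master = list(root_ids)

    # exon layout on the root: n_exons of exon_nt, introns equal-width
    n_introns = params.n_exons - 1
    intron_nt = (
        (params.root_length - params.n_exons * params.exon_nt) // max(1, n_introns)
        if n_introns
        else 0
    )
    exon_sites: list[list[int]] = []
    cursor = 0
    for _ in range(params.n_exons):
        exon_sites.append(root_ids[cursor : cursor + params.exon_nt])
        cursor += params.exon_nt + intron_nt

    branches: list[BranchEvents] = []
    te_origin: dict[int, IndelTruthEvent] = {}
    te_events_on_path: dict[str, list[IndelTruthEvent]] = {}
    leaf_states: dict[str, _Lineage] = {}

    def descend(node: dendropy.Node, state: _Lineage, path_te: list[IndelTruthEvent]) -> None:
        children = sorted(node.child_nodes(), key=_node_label)
        for child in children:
            label = _node_label(child)
            child_state = state.copy()
            events = BranchEvents(branch=label)
            rng = _branch_rng(params.seed, label)
            _evolve_branch(
                child_state, child.edge.length, params, rng, alloc, master,
                events, te_origin,
            )
            branches.append(events)
            child_te = path_te + [e for e in events.indels if e.kind == "te_insertion"]
            if child.is_leaf():
                leaf_states[child.taxon.label] = child_state
                te_events_on_path[child.taxon.label] = child_te
            else:
                descend(child, child_state, child_te)

    descend(tree.seed_node, root, [])

    # per-leaf missing spans (unsequenced stretches), recorded then masked
    missing_spans: dict[str, tuple[int, int]] = {}
    for leaf in sorted(leaf_states):
        rng = _branch_rng(params.seed, f"missing:{leaf}")
        state = leaf_states[leaf]
        if params.missing_fraction > 0 and rng.random() < params.missing_fraction:
            span = min(params.missing_span_nt, len(state))
            if span >= 1:
                start = int(rng.integers(len(state) - span + 1))
                for sid in state.ids[start : start + span]:
                    state.chars[sid] = "N"
                missing_spans[leaf] = (start, start + span)

    # true alignment: master order restricted to sites alive in >= 1 leaf
    leaf_order = [lf.taxon.label for lf in tree.leaf_node_iter()]
    alive: set[int] = set()
    for state in leaf_states.values():
        alive.update(state.ids)
    columns = [sid for sid in master if sid in alive]
    rows: list[tuple[str, str]] = []
    for leaf in leaf_order:
        chars = leaf_states[leaf].chars
        rows.append((leaf, "".join(chars.get(sid, "-") for sid in columns)))
    msa = MSA(rows)

    # leaf TE annotations at realised coordinates
    repeats: dict[str, list[RepeatElement]] = {}
    for leaf in leaf_order:
        state = leaf_states[leaf]
        index_of = {sid: i for i, sid in enumerate(state.ids)}
        anns: list[RepeatElement] = []
        for ev in te_events_on_path[leaf]:
            surviving = [index_of[sid] for sid in ev.site_ids if sid in index_of]
            if not surviving:
                continue
            anns.append(
                RepeatElement(
                    species_id=leaf,
                    name=ev.te_name or "TE",
                    class_family=ev.te_class_family or "Unknown",
                    start=min(surviving),
                    end=max(surviving) + 1,
                    strand=ev.te_strand or "+",
                    score=1000.0,
                )
            )
        repeats[leaf] = sorted(anns, key=lambda e: e.start)

    # leaf gene models from surviving exon sites
    gene_models: dict[str, GeneModel] = {}
    for leaf in leaf_order:
        state = leaf_states[leaf]
        index_of = {sid: i for i, sid in enumerate(state.ids)}
        exons: list[tuple[int, int]] = []
        degenerate: list[int] = []
        last_end = 0
        for i, sites in enumerate(exon_sites):
            surviving = [index_of[sid] for sid in sites if sid in index_of]
            if surviving:
                s, e = min(surviving), max(surviving) + 1
                s = max(s, last_end)
                e = max(e, s)
                exons.append((s, e))
                last_end = e
            else:
                exons.append((last_end, last_end))
                degenerate.append(i)
        gene_models[leaf] = GeneModel(
            species_id=leaf, gene_id=params.gene_id, strand=params.gene_strand,
            exons=exons, degenerate_exons=degenerate,
        )

    divergence = _divergence_from_tree(tree)
    ledger = TruthLedger(
        root_site_ids=root_ids,
        root_chars=root_chars,
        branches=branches,
        missing_spans=missing_spans,
        divergence={
            f"{a}|{b}": divergence.time(a, b) for a, b in divergence.pairs()
        },
    )
    return SimResult(msa, repeats, gene_models, divergence, ledger, params)


def replay(ledger: TruthLedger, newick: str) -> dict[str, str]:
    """Re-apply the ledger's recorded events along the tree.

    Returns leaf label -> ungapped sequence; equality with the simulator's
    emitted leaves is the replay invariant.
    """
    tree = _load_tree(newick)
    by_branch = {b.branch: b for b in ledger.branches}
    root = _Lineage(
        list(ledger.root_site_ids),
        dict(zip(ledger.root_site_ids, ledger.root_chars)),
    )
    out: dict[str, str] = {}

    def descend(node: dendropy.Node, state: _Lineage) -> None:
        for child in sorted(node.child_nodes(), key=_node_label):
            label = _node_label(child)
            child_state = state.copy()
            events = by_branch[label]
            for sub in events.substitutions:
                child_state.chars[sub.site_id] = sub.new
            for ev in events.indels:
                if ev.kind == "deletion":
                    doomed = set(ev.site_ids)
                    child_state.ids = [
                        sid for sid in child_state.ids if sid not in doomed
                    ]
                    for sid in ev.site_ids:
                        child_state.chars.pop(sid, None)
                else:
                    pos = (
                        0
                        if ev.left_neighbor is None
                        else child_state.ids.index(ev.left_neighbor) + 1
                    )
                    child_state.ids[pos:pos] = ev.site_ids
                    for sid, ch in zip(ev.site_ids, ev.chars):
                        child_state.chars[sid] = ch
            if child.is_leaf():
                leaf = child.taxon.label
                if leaf in ledger.missing_spans:
                    s, e = ledger.missing_spans[leaf]
                    for sid in child_state.ids[s:e]:
                        child_state.chars[sid] = "N"
                out[leaf] = child_state.string()
            else:
                descend(child, child_state)

    descend(tree.seed_node, root)
    return out


# --- recovery --------------------------------------------------------------

def expected_substitution_estimate(sub_rate: float, T: float) -> float:
    """Oracle for the pairwise substitution-rate estimate (%/Myr).

    Each lineage mutates a site with probability p = sub_rate/100 * T; the
    pair mismatches with probability 2p(1-p) + (2/3)p^2 (coincident hits
    agree 1/3 of the time); the estimator divides the percent mismatch by
    T, hence the factor-2 relationship to the per-lineage rate.
    """
    p = sub_rate / 100.0 * T
    mismatch = 2 * p * (1 - p) + (2.0 / 3.0) * p * p
    return 100.0 * mismatch / T


def expected_creation_estimate(
    indel_rate: float, te_insert_rate: float, root_length: int, T: float
) -> float:
    """Oracle for the indel-creation-rate estimate (indels/Myr).

    Events arrive as a Poisson process on both branches (2T Myr of path):
    short indels at indel_rate per 100 nt per Myr plus TE insertions at
    te_insert_rate per branch-Myr; the estimator divides the count by T.
    """
    per_myr = indel_rate * (root_length / 100.0) + te_insert_rate
    return 2.0 * per_myr


def recovery_report(result: SimResult, missing_policy=None) -> "pd.DataFrame":
    """True-vs-estimated rates for every leaf pair of a simulation."""
    import pandas as pd

    from .metrics import pair_metrics
    from .msa import MissingSpec, extract_pair

    policy = missing_policy or MissingSpec()
    params = result.params
    rows = []
    for a, b in result.divergence.pairs():
        T = result.divergence.time(a, b)
        m = pair_metrics(extract_pair(result.msa, a, b, policy), T)
        exp_sub = expected_substitution_estimate(params.sub_rate, T)
        exp_creation = expected_creation_estimate(
            params.indel_rate, params.te_insert_rate, params.root_length, T
        )
        for metric, est, expected in (
            ("substitution_rate", m.substitution_rate, exp_sub),
            ("indel_creation_rate", m.indel_creation_rate, exp_creation),
        ):
            rel = (est - expected) / expected if expected else float("nan")
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "T_myr": T,
                    "metric": metric,
                    "expected_estimate": expected,
                    "estimated": est,
                    "relative_error": rel,
                }
            )
    return pd.DataFrame(rows)


# --- on-disk emission ------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching"
    "       repeat            position in repeat\n"
    "score  div. del. ins.  sequence  begin end   (left)   repeat"
    "       class/family      begin end    (left)   ID\n"
    "\n"
)


def write_repeatmasker_out(
    elements: Sequence[RepeatElement], path: str | Path
) -> None:
    """Write annotations in RepeatMasker ``.out`` layout (1-based inclusive,
    'C' for minus strand)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, e in enumerate(elements, start=1):
            strand = "+" if e.strand == "+" else "C"
            fh.write(
                f"{int(e.score):>5} 0.0 0.0 0.0 {e.species_id} "
                f"{e.start + 1} {e.end} (0) {strand} {e.name} "
                f"{e.class_family} 1 {e.length} (0) {i}\n"
            )
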