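# Methods

This note documents the models, conventions, and numerical choices behind
`tediv`, and what the synthetic-data generator does and does not emulate.

## Pairwise divergence model

All pairwise statistics operate on a *pair alignment*: two rows of a
multiple alignment with every mutually gapped column removed, so that each
remaining gap is a one-sided (pairwise-informative) gap.  Coordinates are
0-based half-open everywhere internally; 1-based inclusive appears only at
RepeatMasker I/O and in human-readable reports.

With `T` the time (Myr) to the pair's most recent common ancestor:

| quantity | definition | units |
|---|---|---|
| percent identity | 100 · (matches + missing columns) / columns | % |
| substitution rate | 100 · mismatching both-base columns / both-base columns / T | % per Myr |
| indel change rate | 100 · Σ indel sizes / columns / T | % per Myr |
| indel creation rate | n_indels / T | events per Myr |

The denominators are **reconstructed** from the stated units of the
original formulas (which survive only as figure images in the source
material) together with the magnitudes they must reproduce: identity must
count one-sided gap columns as differences (substitutions alone cannot
push genomic identity to ~44%), substitutions are undefined opposite a gap
(and their nucleotides are already counted by the indel change rate, so
counting them again would double-dip), and the indel change rate spreads
indel nucleotides over all columns.  All four rates divide by `T` — time to
the MRCA, not the 2`T` of total branch path — uniformly, because the
indel-creation definition states it that way; see "factor-2 convention"
below for the consequence.

Ambiguity codes other than `N` are compared literally (a mismatch unless
identical): the reproducible choice where no rule was stated.

### Indel events

An indel event is a *maximal* run of `-` in one sequence opposite bases in
the other, after mutual-gap stripping.  Abutting runs hosted by opposite
sequences are separate events.  Terminal (leading/trailing) runs count as
indels: the alignments are expected to span a common transcribed region,
and true sequencing overhangs should be declared missing instead.  Event
calling is independent of orientation, so every pairwise statistic is
symmetric in the two species.

Indel size histograms use closed 100-nt bins: bin *k* holds sizes in
`[(k−1)·100+1, k·100]`, so a 100-nt indel is in bin 1 and a 101-nt indel in
bin 2.

Pairs with zero indels have *undefined* mean/median indel size (a sentinel,
never 0): they are excluded from size averages but contribute rate 0 to
rate averages.  In the blocked group tests this means listwise deletion of
any species-pair block with an undefined value.

### Missing data

Unsequenced regions are handled in the most conservative way: a missing
region is assumed to exactly match the partner sequence.  Concretely, a
`MissingSpec` flags runs of `N` of length ≥ 10 (configurable) and/or
explicit per-species intervals; flagged columns count as matches in the
identity numerator, stay in the substitution denominator but never count
as mismatches, and suppress entirely any gap run they overlap.  The column
span of a missing interval includes interior columns where the flagged
species is gapped — nothing can be said about indels in a region that was
never sequenced.

## TE annotation layer

RepeatMasker `.out` files are parsed positionally (3 header lines,
whitespace-separated fields); `C` in the strand field maps to `−`,
coordinates to 0-based half-open.  Elements project into alignment columns
through per-species coordinate maps; internal alignment gaps do not split
an element.

**Uniqueness rule.**  Whether an element in species A "is" the same
insertion as one in species B was judged by eye in the motivating study;
`tediv` substitutes an explicit, reproducible rule: identical class/family
and reciprocal alignment-column overlap ≥ 50% of the *shorter* element,
matched greedily by descending overlap.  Every unmatched element is unique.
The rule is symmetric, conservative (`shared·2 + unique = total`), and the
threshold is a parameter.

**Per-gene totals** count elements whose midpoint falls in the gene span —
each boundary-straddling element is counted exactly once.

**Orientation tallies** classify elements as Alu (class `SINE/Alu`) or LTR
(class `LTR/*`) and count strands relative to the host gene's
transcription.  A manual-override list reproduces curation decisions that
no automatic rule can: `split` counts one annotated element as one positive
plus one negative insertion (inverted tandem repeats annotated as a single
hit), and `exclude` drops elements whose fixation predates the gene family
(shared with outgroup mammals) from the "captured during primate
evolution" tally.  A zero denominator yields an `N/A` sentinel, never 0%.

**Family content** (e.g. nucleotides of LINE/L1 origin in intron 4) merges
overlapping annotated fragments before summing, so the result can never
exceed the interval length.

## Gene models and projection

Exon intervals live in ungapped species coordinates, stored in genomic
order; intron indices are 1-based in *transcription* order (intron 4 of a
minus-strand gene counts from the right end genomically).  A reference
transcript's exon boundaries project through alignment columns into any
other species; a boundary landing in a target gap moves toward the exon
interior — exons shrink, introns never do, which is conservative for
intron-length comparisons.  An exon wholly deleted in the target becomes a
zero-length interval flagged degenerate, not silently dropped.

## Group statistics

Gene-level differences are tested with the Friedman test (blocks = species
pairs, treatments = genes) on within-block mid-ranks, with the standard tie
correction; implemented directly (the scipy implementation is
algebraically identical but requires ≥ 3 treatments, while two-gene
comparisons are legitimate here) and cross-checked against scipy in the
test suite.  Dunn's post-test compares all gene pairs:
`z = |R̄_i − R̄_j| / sqrt(k(k+1)/(6n))`, two-sided normal p multiplied by
`k(k−1)/2` (Bonferroni, as Dunn prescribed — the convention of the graphing
software era; switchable in principle by post-processing the unadjusted z).
Significance stars follow the usual `*` < 0.05, `**` < 0.01, `***` < 0.001
mapping.  Spearman correlation uses mid-ranks with the t-approximation
p-value.  The suite verifies the test's type-I error is calibrated:
~5% rejections at α = 0.05 over 1000 null data sets of 45 blocks × 4
treatments.

## ΔΔC(t)

`ΔCt = Ct_target − Ct_reference` per (subject, treatment); `ΔΔCt =
ΔCt_drug − ΔCt_control`; `fold = 2^(−ΔΔCt)`.  Replicate wells are averaged
per cell before differencing; a subject missing any required Ct is excluded
with a warning rather than aborting the run.  Fold changes are summarised
as mean ± SEM on the linear scale, matching the usual bar-chart
presentation; a geometric (log2-scale) summary is available and labelled.
SEM can be taken over subjects or over any grouping the caller prepares —
the function is agnostic to whether replicates are experiments or subjects.

## The simulator

Sequences evolve along a dated newick tree.  Every nucleotide carries a
globally unique site id, so homology is exact: the emitted alignment is the
true alignment (insertions open gap columns in non-carriers and are never
re-aligned — curated input alignments are assumed correct, so the pipeline
is tested against gold homology, not against an aligner).

Per branch of length `t` Myr:

- **Substitutions**: each site mutates with probability `sub_rate/100 · t`
  to a uniformly chosen different base.  One hit per site per branch — a
  linear approximation appropriate for the small per-branch probabilities
  simulated here; recovery oracles use the two-lineage collision-corrected
  mismatch probability `2p(1−p) + (2/3)p²`.
- **Short indels**: Poisson-many events at `indel_rate` per 100 nt per Myr;
  each is a deletion with probability `deletion_fraction`, else an
  insertion; sizes geometric with configurable mean (default 3 nt, giving
  the empirical median of ~2 nt).
- **TE insertions**: Poisson at `te_insert_rate` per branch-Myr, drawn
  uniformly from a TE library of (name, class/family, length ≥ 300 nt)
  entries — the large-indel class is modelled as TE insertion, matching the
  observed bimodal size mixture (most indels ≤ 10 nt; essentially all
  > 300 nt events are TEs).  Strand is `+` with configurable probability.
- **Missing data**: each leaf independently carries one `N`-masked span
  with probability `missing_fraction`.

Default parameters are chosen to emulate a primate gene-region data set:
0.1–0.15 %/Myr substitution rates, indel rates of 0.01–0.06 events per
100 nt per Myr across a four-gene turnover hierarchy, a TE library spanning
Alu (~300 nt) through full-length L1 (6 kb), and dated splits from ~6.6 to
~43 Myr.  Root lengths default to 10 kb — the order of the real transcribed
regions — and are a stated choice of problem size, not a constraint of the
model.

**Determinism.**  Each branch evolves under its own RNG substream keyed by
`(seed, branch label)`, where a branch is labelled by its sorted descendant
leaf set: editing one subtree cannot reshuffle events elsewhere, and a
fixed seed reproduces every output byte-for-byte.

**Truth ledger.**  Every event (site id, old/new base, inserted ids and
characters, deleted ids, TE metadata) is recorded per branch.  Replaying
the ledger along the tree must reproduce each leaf exactly — an invariant
the test suite enforces — so recovery analyses can compare any estimate
against realised, not merely expected, event counts.

**Factor-2 convention.**  Simulator rates are per lineage, but a pair
separated by `T` Myr accrues events over ~`2T` Myr of branch path while the
pairwise estimators divide by `T`.  Recovery comparisons therefore target
twice the per-lineage rate (with the collision correction for
substitutions), and this is asserted explicitly rather than absorbed
silently: on a two-leaf, 100 kb, `T` = 10 Myr simulation the substitution
estimate lands within 10% and the indel-creation estimate within 15% of the
closed-form expectations.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: selection, site- and branch-heterogeneous rates,
CpG effects, target-site duplications, TE nesting, and alignment error.
Two consequences are worth naming.  First, because per-Myr rates are
homogeneous across lineages, the *within-gene* anticorrelation between
identity and indel change rate seen in real gene families (driven by
lineage-specific turnover) has no signal in simulated data; the acceptance
script therefore reports that correlation pooled across the four-gene
hierarchy, where rate differences are real.  Second, recovery tolerances
(10%/15%) cover sampling noise plus small biases from event collisions,
not model misspecification.

## Degenerate inputs and numerical conventions

- Zero-length pairs, constant vectors, all-tied blocks, and zero-indel size
  summaries raise typed errors or return `None` sentinels — never silent 0s.
- Even-count medians average the two central values.
- `T ≤ 0` is a parameter error everywhere.
- FASTA output wraps at 60 columns; `-` is the only gap character, `.` is
  rejected loudly.
- The Friedman statistic is undefined when every block is internally tied;
  the implementation raises rather than reporting 0.

## Problem sizes

The test suite and acceptance script run simulations of 3–10 kb roots for
multi-species analyses and a single 100 kb two-leaf run for parameter
recovery, 1000-replicate null calibrations, and 1000 randomised
oracle-equivalence checks — sizes at which binomial/Poisson sampling error
is well inside the stated tolerances while the whole suite stays fast.
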