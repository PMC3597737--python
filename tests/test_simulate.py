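"""Sequence-evolution simulator: process separation, determinism, the
truth-ledger replay invariant, and distributional properties of the
emitted events."""

import numpy as np
import pytest
from scipy import stats as sps

from tediv.errors import ParameterError
from tediv.msa import ungapped
from tediv.repeats import parse_repeatmasker_out
from tediv.simulate import (
    SimParams,
    TELibraryEntry,
    TruthLedger,
    expected_creation_estimate,
    expected_substitution_estimate,
    recovery_report,
    replay,
    simulate,
    write_repeatmasker_out,
)

TWO_LEAF = "(A:10,B:10);"
STAR5 = "(A:5,B:5,C:5,D:5,E:5);"


def params(**kw):
    defaults = dict(tree=TWO_LEAF, root_length=2000, seed=42, missing_fraction=0.0)
    defaults.update(kw)
    return SimParams(**defaults)


class TestParamsValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            params(sub_rate=-0.1)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            params(deletion_fraction=1.5)

    def test_te_library_entries_must_be_large_indels(self):
        with pytest.raises(ParameterError, match="300"):
            params(te_library=(TELibraryEntry("tiny", "SINE/Alu", 50),))

    def test_tree_without_dates_rejected(self):
        with pytest.raises(ParameterError, match="branch length"):
            simulate(params(tree="(A,B);"))


class TestNullAndSeparatedProcesses:
    def test_all_rates_zero_gives_identical_gap_free_leaves(self):
        r = simulate(params(sub_rate=0, indel_rate=0, te_insert_rate=0))
        rows = [seq for _, seq in r.msa.records]
        assert rows[0] == rows[1]
        assert "-" not in rows[0]

    def test_substitutions_only_keeps_alignment_gap_free(self):
        r = simulate(params(sub_rate=0.5, indel_rate=0, te_insert_rate=0))
        rows = [seq for _, seq in r.msa.records]
        assert "-" not in rows[0] + rows[1]
        assert rows[0] != rows[1]

    def test_indels_only_never_substitutes(self):
        r = simulate(params(sub_rate=0, indel_rate=0.05, te_insert_rate=0))
        a, b = (seq for _, seq in r.msa.records)
        mismatches = sum(
            1 for ca, cb in zip(a, b) if "-" not in (ca, cb) and ca != cb
        )
        assert mismatches == 0


class TestDeterminism:
    def test_fixed_seed_runs_are_byte_identical(self):
        r1 = simulate(params(missing_fraction=0.3))
        r2 = simulate(params(missing_fraction=0.3))
        assert r1.msa.records == r2.msa.records
        assert r1.repeats == r2.repeats
        assert r1.ledger.to_json() == r2.ledger.to_json()

    def test_different_seeds_differ(self):
        r1 = simulate(params(seed=1))
        r2 = simulate(params(seed=2))
        assert r1.msa.records != r2.msa.records

    def test_branch_substreams_stable_under_topology_edit(self):
        # renaming a taxon in the other subtree must not reshuffle events
        # on branches whose history is unchanged
        r1 = simulate(params(tree="((A:3,B:3):4,(C:5,D:5):2);"))
        r2 = simulate(params(tree="((A:3,B:3):4,(C:5,E:5):2);"))
        for branch in ("A", "B", "A|B"):
            e1 = next(b for b in r1.ledger.branches if b.branch == branch)
            e2 = next(b for b in r2.ledger.branches if b.branch == branch)
            assert e1 == e2
        assert ungapped(r1.msa.row("A")) == ungapped(r2.msa.row("A"))


class TestTruthLedger:
    @pytest.mark.parametrize("tree", [TWO_LEAF, STAR5, "((A:3,B:3):4,(C:5,D:5):2);"])
    def test_replay_reproduces_every_leaf_exactly(self, tree):
        p = params(tree=tree, missing_fraction=0.5, te_insert_rate=0.1)
        r = simulate(p)
        leaves = replay(r.ledger, tree)
        for sid in r.msa.species_ids:
            assert leaves[sid] == ungapped(r.msa.row(sid))

    def test_json_round_trip(self):
        r = simulate(params(missing_fraction=0.5))
        back = TruthLedger.from_json(r.ledger.to_json())
        assert back.to_json() == r.ledger.to_json()

    def test_divergence_table_matches_tree_depths(self):
        r = simulate(params(tree="((A:3,B:3):4,(C:5,D:5):2);"))
        assert r.divergence.time("A", "B") == pytest.approx(3.0)
        assert r.divergence.time("C", "D") == pytest.approx(5.0)
        assert r.divergence.time("A", "C") == pytest.approx(7.0)


class TestEventDistributions:
    def test_short_indel_sizes_follow_the_geometric_mixture(self):
        # >= 10,000 emitted events, chi-square GOF against the configured
        # geometric size law, alpha = 0.01
        p = params(
            root_length=10_000, indel_rate=5.0, sub_rate=0, te_insert_rate=0,
            short_indel_mean=3.0, seed=0,
        )
        r = simulate(p)
        sizes = [
            ev.size
            for b in r.ledger.branches
            for ev in b.indels
            if ev.kind == "insertion"  # insertions are never truncated
        ]
        assert len(sizes) >= 4000
        geom_p = 1 / 3.0
        cutoff = 12
        observed = np.array(
            [sum(1 for s in sizes if s == k) for k in range(1, cutoff)]
            + [sum(1 for s in sizes if s >= cutoff)]
        )
        probs = np.array(
            [sps.geom.pmf(k, geom_p) for k in range(1, cutoff)]
            + [float(sps.geom.sf(cutoff - 1, geom_p))]
        )
        stat, pval = sps.chisquare(observed, probs * len(sizes))
        assert pval > 0.01

    def test_te_strand_fraction_within_binomial_bounds(self):
        p = params(
            tree="(A:30,B:30);", te_insert_rate=2.0, indel_rate=0, sub_rate=0,
            te_positive_prob=0.7, root_length=1000, n_exons=2, exon_nt=100,
            seed=3,
        )
        r = simulate(p)
        strands = [
            ev.te_strand
            for b in r.ledger.branches
            for ev in b.indels
            if ev.kind == "te_insertion"
        ]
        n = len(strands)
        assert n > 100
        phat = strands.count("+") / n
        bound = 2.576 * np.sqrt(0.7 * 0.3 / n)  # binomial 99% band
        assert abs(phat - 0.7) <= bound

    def test_te_insertions_are_annotated_at_leaf_coordinates(self):
        p = params(te_insert_rate=0.3, indel_rate=0, sub_rate=0, seed=8)
        r = simulate(p)
        for sid in r.msa.species_ids:
            seq = ungapped(r.msa.row(sid))
            for e in r.repeats[sid]:
                assert 0 <= e.start < e.end <= len(seq)
                assert e.name in {t.name for t in p.te_library}

    def test_gene_models_partition_surviving_roots(self):
        r = simulate(params(n_exons=4, exon_nt=100))
        for sid, model in r.gene_models.items():
            assert model.species_id == sid
            assert len(model.exons) == 4
            s, e = model.span
            assert 0 <= s <= e <= len(ungapped(r.msa.row(sid)))


class TestRecovery:
    def test_null_process_recovers_zero(self):
        r = simulate(params(sub_rate=0, indel_rate=0, te_insert_rate=0))
        rep = recovery_report(r)
        assert (rep.estimated == 0).all()
        assert (rep.expected_estimate == 0).all()

    def test_two_leaf_binomial_and_poisson_oracles(self):
        p = params(
            root_length=100_000, sub_rate=0.1, indel_rate=0.01,
            te_insert_rate=0.05, seed=7,
        )
        r = simulate(p)
        rep = recovery_report(r).set_index("metric")
        sub = rep.loc["substitution_rate"]
        assert sub.expected_estimate == pytest.approx(
            expected_substitution_estimate(0.1, 10.0)
        )
        assert abs(sub.relative_error) < 0.10
        creation = rep.loc["indel_creation_rate"]
        assert creation.expected_estimate == pytest.approx(
            expected_creation_estimate(0.01, 0.05, 100_000, 10.0)
        )
        assert abs(creation.relative_error) < 0.15


class TestRepeatMaskerEmission:
    def test_round_trip_through_parser(self, tmp_path):
        r = simulate(params(te_insert_rate=0.3, seed=8))
        elements = [e for sid in r.msa.species_ids for e in r.repeats[sid]]
        assert elements
        path = tmp_path / "sim.out"
        write_repeatmasker_out(elements, path)
        back = parse_repeatmasker_out(path)
        assert [
            (e.species_id, e.name, e.class_family, e.start, e.end, e.strand)
            for e in back
        ] == [
            (e.species_id, e.name, e.class_family, e.start, e.end, e.strand)
            for e in elements
        ]
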