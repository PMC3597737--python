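"""RepeatMasker parsing, projection, and the TE tallies."""

import pytest

from tediv.errors import CoordinateError, ParseError
from tediv.msa import MSA, build_coordinate_map
from tediv.repeats import (
    ManualOverride,
    RepeatElement,
    count_elements,
    element_category,
    family_content,
    orientation_tally,
    parse_repeatmasker_out,
    project_from_alignment,
    project_to_alignment,
    unique_elements,
    write_bed,
)

RM_HEADER = (
    "   SW  perc perc perc  query      position in query  matching repeat\n"
    "score  div. del. ins.  sequence   begin end (left)   repeat class/family begin end (left) ID\n"
    "\n"
)


def element(species="s", name="AluY", cf="SINE/Alu", start=0, end=300, strand="+"):
    return RepeatElement(species, name, cf, start, end, strand)


class TestParseRepeatmaskerOut:
    def test_parses_coordinates_and_strand(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(
            RM_HEADER
            + "463 15.6 6.2 0.0 human_TRIM22 100 250 (500) + AluSx SINE/Alu 1 151 (161) 1\n"
        )
        (e,) = parse_repeatmasker_out(path)
        assert (e.start, e.end, e.strand, e.name) == (99, 250, "+", "AluSx")
        assert e.class_family == "SINE/Alu"
        assert e.species_id == "human_TRIM22"

    def test_c_maps_to_minus_strand(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(
            RM_HEADER
            + "463 15.6 6.2 0.0 q 100 250 (500) C LTR10D LTR/ERV1 1 151 (0) 1\n"
        )
        (e,) = parse_repeatmasker_out(path)
        assert e.strand == "-"

    def test_header_only_file_is_empty(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(RM_HEADER)
        assert parse_repeatmasker_out(path) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(RM_HEADER + "garbage line with too few fields\n")
        with pytest.raises(ParseError, match="line 4"):
            parse_repeatmasker_out(path)

    def test_unknown_query_name_is_a_mapping_error(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(
            RM_HEADER + "463 15.6 6.2 0.0 q 100 250 (500) + AluSx SINE/Alu 1 151 (0) 1\n"
        )
        with pytest.raises(ParseError, match="species map"):
            parse_repeatmasker_out(path, species_map={"other": "human"})
        (e,) = parse_repeatmasker_out(path, species_map={"q": "human"})
        assert e.species_id == "human"

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        path = tmp_path / "el.bed"
        write_bed([element(start=99, end=250)], path)
        assert path.read_text() == "s\t99\t250\tAluY\t0\t+\n"


class TestProjection:
    def test_projects_through_gaps(self):
        msa = MSA([("a", "A-CG"), ("b", "ACCG")])
        cmap = build_coordinate_map(msa, "a")
        e = element(start=1, end=3)
        assert project_to_alignment(e, cmap) == (2, 4)

    def test_round_trip_recovers_interval(self):
        msa = MSA([("a", "AC--GT-A"), ("b", "ACGTGTTA")])
        cmap = build_coordinate_map(msa, "a")
        for start in range(5):
            for end in range(start + 1, 6):
                cols = project_to_alignment(element(start=start, end=end), cmap)
                assert project_from_alignment(cols, cmap) == (start, end)

    def test_out_of_range_element_rejected(self):
        msa = MSA([("a", "ACG"), ("b", "ACG")])
        cmap = build_coordinate_map(msa, "a")
        with pytest.raises(CoordinateError):
            project_to_alignment(element(start=1, end=5), cmap)

    def test_zero_length_element_rejected_by_invariant(self):
        with pytest.raises(CoordinateError):
            element(start=5, end=5)


class TestCountElements:
    def test_midpoint_membership(self):
        els = [element(start=s, end=s + 10) for s in (0, 20, 40, 200)]
        total, by_family = count_elements(els, (0, 100))
        assert total == 3
        assert by_family == {"SINE/Alu": 3}

    def test_empty_annotation(self):
        assert count_elements([], (0, 100)) == (0, {})

    def test_every_element_counted_exactly_once_across_a_tiling(self):
        # brute force over placements of a 10-nt element against 3 spans
        spans = [(0, 10), (10, 20), (20, 30)]
        for start in range(-9, 30):
            e = element(start=start, end=start + 10)
            counted = sum(count_elements([e], span)[0] for span in spans)
            assert counted == (1 if 0 <= e.midpoint < 30 else 0)


class TestUniqueElements:
    def _cmaps(self, msa):
        return (
            build_coordinate_map(msa, "a"),
            build_coordinate_map(msa, "b"),
        )

    def test_identical_annotations_share_everything(self):
        msa = MSA([("a", "ACGT" * 100), ("b", "ACGT" * 100)])
        ca, cb = self._cmaps(msa)
        ann = [element(species="a", start=0, end=300)]
        res = unique_elements(ann, [element(species="b", start=0, end=300)], ca, cb)
        assert res.n_unique == 0
        assert len(res.shared) == 1

    def test_element_in_one_species_is_unique(self):
        msa = MSA([("a", "ACGT" * 100), ("b", "ACGT" * 100)])
        ca, cb = self._cmaps(msa)
        res = unique_elements([element(species="a")], [], ca, cb)
        assert res.n_unique == 1
        assert res.unique_a[0].name == "AluY"

    def test_overlap_below_threshold_leaves_both_unique(self):
        msa = MSA([("a", "A" * 1000), ("b", "C" * 1000)])
        ca, cb = self._cmaps(msa)
        # 40% reciprocal overlap of two 500-nt same-family elements
        ann_a = [element(species="a", start=0, end=500)]
        ann_b = [element(species="b", start=300, end=800)]
        res = unique_elements(ann_a, ann_b, ca, cb)
        assert res.n_unique == 2
        # exactly at 50% the pair is shared
        ann_b = [element(species="b", start=250, end=750)]
        res = unique_elements(ann_a, ann_b, ca, cb)
        assert res.n_unique == 0

    def test_different_family_never_matches(self):
        msa = MSA([("a", "A" * 400), ("b", "C" * 400)])
        ca, cb = self._cmaps(msa)
        res = unique_elements(
            [element(species="a", cf="SINE/Alu")],
            [element(species="b", cf="LTR/ERV1")],
            ca, cb,
        )
        assert res.n_unique == 2

    def test_conservation_and_symmetry(self):
        msa = MSA([("a", "A" * 2000), ("b", "C" * 2000)])
        ca, cb = self._cmaps(msa)
        ann_a = [element(species="a", start=s, end=s + 320) for s in (0, 400, 900)]
        ann_b = [element(species="b", start=s, end=s + 320) for s in (30, 905, 1500)]
        res = unique_elements(ann_a, ann_b, ca, cb)
        assert 2 * len(res.shared) + res.n_unique == len(ann_a) + len(ann_b)
        swapped = unique_elements(ann_b, ann_a, cb, ca)
        assert swapped.n_unique == res.n_unique
        assert unique_elements(ann_a, ann_a, ca, ca).n_unique == 0


class TestOrientationTally:
    def test_percent_positive_and_na_sentinel(self):
        els = [element(strand="+")] * 8 + [element(strand="-")] * 5
        tallies = orientation_tally(els, "gene", "+")
        assert tallies["Alu"].n_positive == 8
        assert tallies["Alu"].percent_positive == pytest.approx(61.5, abs=0.05)
        assert tallies["LTR"].percent_positive is None  # rendered N/A

    def test_orientation_is_relative_to_gene_strand(self):
        els = [element(cf="LTR/ERV1", strand="+")] * 3
        assert orientation_tally(els, "g", "-")["LTR"].n_negative == 3

    def test_split_override_counts_both_orientations(self):
        els = [element(name="MLT1C", cf="LTR/ERVL-MaLR", strand="+")]
        t = orientation_tally(
            els, "g", "+", overrides=[ManualOverride("MLT1C", "split")]
        )["LTR"]
        assert (t.n_positive, t.n_negative) == (1, 1)

    def test_exclude_override_drops_element(self):
        els = [
            element(name="LTR87", cf="LTR/ERVL", strand="+"),
            element(name="LTR10D", cf="LTR/ERV1", strand="+"),
        ]
        t = orientation_tally(
            els, "g", "+", overrides=[ManualOverride("LTR87", "exclude")]
        )["LTR"]
        assert (t.n_positive, t.n_negative) == (1, 0)

    def test_category_assignment(self):
        assert element_category(element(cf="SINE/Alu")) == "Alu"
        assert element_category(element(cf="LTR/ERVL-MaLR")) == "LTR"
        assert element_category(element(cf="LINE/L1")) is None


class TestFamilyContent:
    def test_fully_contained_element(self):
        els = [element(cf="LINE/L1", start=100, end=600)]
        assert family_content(els, (0, 1000), "LINE/L1") == 500

    def test_overlapping_fragments_merged(self):
        els = [
            element(cf="LINE/L1", start=0, end=300),
            element(cf="LINE/L1", start=200, end=600),
        ]
        assert family_content(els, (0, 1000), "LINE/L1") == 600

    def test_no_matching_family(self):
        els = [element(cf="SINE/Alu", start=0, end=300)]
        assert family_content(els, (0, 1000), "LINE/L1") == 0

    def test_never_exceeds_interval_length(self):
        els = [element(cf="LINE/L1", start=0, end=5000)]
        assert family_content(els, (100, 400), "LINE/L1") == 300
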