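"""Alignment diagnostics: SNPs, entropy, masking, regions, categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phyloconcord.alignment import (
    Alignment,
    RegionDefinition,
    SiteAnnotation,
    column_entropy,
    concatenate,
    count_snps,
    default_hvr_regions,
    entropy_mask,
    extract_region,
    extract_snp_category,
    read_fasta,
)


def _aln(ids, seqs):
    return Alignment.from_sequences(ids, seqs)


class TestConstruction:
    def test_rejects_unequal_lengths_and_duplicate_ids(self):
        with pytest.raises(ValueError, match="length"):
            _aln(["a", "b"], ["ACGT", "ACG"])
        with pytest.raises(ValueError, match="unique"):
            _aln(["a", "a"], ["ACGT", "ACGT"])

    def test_fasta_roundtrip(self, tmp_path):
        a = _aln(["s1", "s2"], ["ACGT-N" * 20, "TGCA-N" * 20])
        path = tmp_path / "x.fasta"
        a.write_fasta(path)
        b = read_fasta(path)
        assert b.ids == a.ids
        assert b.sequences() == a.sequences()


class TestSNPCounting:
    def test_invariant_alignment_has_zero(self):
        assert count_snps(_aln(["a", "b", "c"], ["ACGT", "ACGT", "ACGT"])) == 0

    def test_hand_planted_variants(self):
        # variants in columns 2 and 7 (1-based)
        seqs = ["AAAAAAAAAA",
                "ACAAAACAAA",
                "AAAAAAAAAA"]
        assert count_snps(_aln(list("abc"), seqs)) == 2

    def test_gap_only_variation_not_counted(self):
        assert count_snps(_aln(list("abcd"), ["A", "A", "-", "-"])) == 0
        assert count_snps(_aln(list("abcd"), ["A", "N", "A", "A"])) == 0

    def test_case_insensitive(self):
        assert count_snps(_aln(["a", "b"], ["acgt", "acga"])) == 1


class TestEntropy:
    @pytest.mark.parametrize("column,expected", [
        (["A", "A", "A", "A"], 0.0),
        (["A", "C", "G", "T"], 2.0),
        (["A", "A", "G", "G"], 1.0),
        (["-", "-", "-", "-"], 0.0),
        (["A", "A", "-", "-"], 0.0),
    ])
    def test_reference_values(self, column, expected):
        a = _aln([f"s{i}" for i in range(4)], column)
        assert column_entropy(a)[0] == pytest.approx(expected)

    @given(st.lists(st.sampled_from("ACGTN-"), min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_entropy_bounds(self, column):
        a = _aln([f"s{i}" for i in range(len(column))], column)
        h = column_entropy(a)[0]
        assert 0.0 <= h <= 2.0
        bases = {c for c in column if c in "ACGT"}
        assert (h == 0.0) == (len(bases) <= 1)


class TestEntropyMask:
    def test_masks_exact_ceil_count(self):
        a = _aln(["a", "b"], ["ACGT" * 25, "TGCA" * 25])
        res = entropy_mask(a, 0.10)
        assert len(res.masked_columns) == 10  # ceil(0.10 * 100)
        assert res.alignment.length == 100

    def test_known_top_columns_masked(self):
        # columns 0..4 maximally entropic (4 distinct), rest monomorphic
        rows = ["ACGTA" + "A" * 95,
                "CGTAC" + "A" * 95,
                "GTACG" + "A" * 95,
                "TACGT" + "A" * 95]
        res = entropy_mask(_aln(list("wxyz"), rows), 0.05)
        assert res.masked_columns == [0, 1, 2, 3, 4]

    def test_ties_break_to_lower_index(self):
        a = _aln(["a", "b"], ["ACAC", "AGAG"])  # columns 1 and 3 tie
        res = entropy_mask(a, 0.25)
        assert res.masked_columns == [1]

    def test_never_increases_snp_count(self, rng):
        ids = [f"s{i}" for i in range(6)]
        data = rng.choice(list("ACGT-"), size=(6, 80))
        a = Alignment(ids=ids, data=data.astype("U1"))
        res = entropy_mask(a, 0.10)
        assert count_snps(res.alignment) <= count_snps(a)

    def test_remask_masks_more_of_the_remainder(self):
        a = _aln(["a", "b"], ["ACGT" * 25, "TGCA" * 25])
        once = entropy_mask(a, 0.10)
        twice = entropy_mask(once.alignment, 0.10)
        assert len(set(twice.masked_columns) & set(once.masked_columns)) == 0

    def test_remove_mode_deletes_columns(self):
        a = _aln(["a", "b"], ["ACGT" * 25, "TGCA" * 25])
        res = entropy_mask(a, 0.10, mode="remove")
        assert res.alignment.length == 90

    def test_bad_fraction(self):
        a = _aln(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            entropy_mask(a, 1.0)


class TestExtractRegion:
    def test_whole_reference_is_identity(self):
        a = _aln(["r", "s"], ["ACGT", "TTTT"])
        out = extract_region(a, RegionDefinition("all", "r", 1, 4))
        assert out.sequences() == a.sequences()

    def test_gapped_reference_coordinate_walk(self):
        # reference "A-CG": ungapped positions 2..3 are C,G -> columns 3..4
        a = _aln(["r", "s", "t"], ["A-CG", "AACC", "GGGG"])
        out = extract_region(a, RegionDefinition("x", "r", 2, 3))
        assert out.sequences() == ["CG", "CC", "GG"]

    def test_internal_reference_gaps_retained(self):
        a = _aln(["r", "s"], ["AC--GT", "ACTTGT"])
        out = extract_region(a, RegionDefinition("x", "r", 2, 3))
        assert out.sequences() == ["C--G", "CTTG"]

    def test_out_of_range_errors(self):
        a = _aln(["r", "s"], ["A-CG", "AACC"])
        with pytest.raises(ValueError, match="exceeds"):
            extract_region(a, RegionDefinition("x", "r", 2, 9))
        with pytest.raises(ValueError, match="not in alignment"):
            extract_region(a, RegionDefinition("x", "zz", 1, 2))

    def test_adjacent_regions_compose(self):
        a = _aln(["r", "s"], ["ACGTACGTAC", "GTACGTACGT"])
        v3 = extract_region(a, RegionDefinition("V3", "r", 2, 5))
        v4 = extract_region(a, RegionDefinition("V4", "r", 6, 8))
        both = extract_region(a, RegionDefinition("V3-V4", "r", 2, 8))
        assert concatenate([v3, v4]).sequences() == both.sequences()

    def test_packaged_hvr_table_loads(self):
        regions = default_hvr_regions("ref")
        names = {r.name for r in regions}
        assert {"V1", "V4", "V9", "V1-V2", "V3-V4"} <= names
        v4 = next(r for r in regions if r.name == "V4")
        assert (v4.start, v4.end) == (576, 682)


class TestSNPCategories:
    def _cds(self, gene, category):
        # 9-column CDS with SNPs at codon positions 3, 6, 9 (third positions)
        seqs = ["ATGATGATG",
                "ATAATAATA",
                "ATGATGATG"]
        aln = _aln(list("abc"), seqs)
        annot = SiteAnnotation.for_coding_gene(gene, 9, category)
        return aln, annot

    def test_third_position_bookkeeping(self):
        aln, annot = self._cds("nr01", "NR")
        third = extract_snp_category([aln], [annot], "NR 3")
        assert third.length == 3
        onetwo = extract_snp_category([aln], [annot], "NR 1-2")
        assert onetwo.length == 0
        all_nr = extract_snp_category([aln], [annot], "NR")
        assert all_nr.length == 3

    def test_core_collects_everything(self):
        nr, nr_annot = self._cds("nr01", "NR")
        cr, cr_annot = self._cds("cr01", "CR")
        core = extract_snp_category([nr, cr], [nr_annot, cr_annot], "core")
        assert core.length == count_snps(nr) + count_snps(cr)

    def test_inconsistent_stem_columns_excluded(self):
        seqs = ["ACGT", "AGGA", "ACGA"]
        aln = _aln(list("abc"), seqs)  # SNPs at columns 1 and 3
        annot = SiteAnnotation.for_rrna_gene(
            "rrna_16S", 4,
            structure=["stem", "stem", "loop", "stem"],
            consistent=[True, True, True, False],
        )
        stems = extract_snp_category([aln], [annot], "16S stem")
        assert stems.length == 1  # column 3 stem SNP dropped as inconsistent
        loops = extract_snp_category([aln], [annot], "16S loop")
        assert loops.length == 0
        sixteen = extract_snp_category([aln], [annot], "16S")
        assert sixteen.length == 2  # consistency only gates stem/loop classes

    def test_disjoint_primitives_sum_to_core(self):
        nr, nr_annot = self._cds("nr01", "NR")
        cr, cr_annot = self._cds("cr01", "CR")
        rr = _aln(list("abc"), ["ACGT", "AGGT", "ACGA"])
        rr_annot = SiteAnnotation.for_rrna_gene(
            "rrna_16S", 4, ["stem"] * 4, [True] * 4)
        alns = [nr, cr, rr]
        annots = [nr_annot, cr_annot, rr_annot]
        total = sum(
            extract_snp_category(alns, annots, cat).length
            for cat in ("NR 1-2", "NR 3", "CR 1-2", "CR 3", "rRNA")
        )
        assert total == extract_snp_category(alns, annots, "core").length

    def test_taxa_mismatch_errors(self):
        a1, an1 = self._cds("nr01", "NR")
        a2 = _aln(list("abz"), ["ATGATGATG"] * 3)
        with pytest.raises(ValueError, match="mismatch"):
            extract_snp_category([a1, a2], [an1, an1], "core")


class TestConcatenate:
    def test_identity_and_lengths(self):
        a = _aln(["x", "y"], ["ACGT", "TGCA"])
        b = _aln(["y", "x"], ["GG", "CC"])
        out = concatenate([a, b])
        assert out.length == 6
        assert out.sequence("x") == "ACGTCC"
        assert out.sequence("y") == "TGCAGG"

    def test_snp_counts_add(self, rng):
        ids = [f"s{i}" for i in range(5)]
        parts = [
            Alignment(ids=ids,
                      data=rng.choice(list("ACGT"), size=(5, 30)).astype("U1"))
            for _ in range(3)
        ]
        assert count_snps(concatenate(parts)) == sum(map(count_snps, parts))

    def test_provenance_recorded(self):
        a = _aln(["x"], ["AC"])
        b = _aln(["x"], ["GGG"])
        out = concatenate([a, b], names=["g1", "g2"])
        assert out.column_sources == [("g1", 0), ("g1", 1),
                                      ("g2", 0), ("g2", 1), ("g2", 2)]

    def test_taxa_mismatch_lists_difference(self):
        a = _aln(["x", "y"], ["AC", "GT"])
        b = _aln(["x", "z"], ["AC", "GT"])
        with pytest.raises(ValueError, match="'y', 'z'|'z', 'y'"):
            concatenate([a, b])
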