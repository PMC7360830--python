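"""Region extraction, alignment, variability statistic, hotspot ranking."""

import copy

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastomics.hotspots import (
    RegionAlignment,
    RegionSet,
    align_region,
    combine_hotspot_sets,
    extract_shared_regions,
    import_alignment,
    pairwise_align,
    rank_hotspots,
    variability_percent,
)
from plastomics.simulate import build_ancestor, default_preset, evolve_along_tree


@pytest.fixture(scope="module")
def two_leaves():
    cfg = default_preset(tree="(L1:0.01,L2:0.01);")
    anc, truth = build_ancestor(cfg, 21)
    return evolve_along_tree(anc, truth, cfg, 22)


class TestExtractSharedRegions:
    def test_genes_and_spacers_present(self, two_leaves):
        regions = extract_shared_regions(two_leaves)
        names = set(regions)
        assert "psbZ" in names and "rpoX" in names
        assert any("-" in n for n in names)  # spacers named by flanking pair
        for r in regions.values():
            assert r.rtype in ("coding", "noncoding")
            assert len(r.seqs) == 2

    def test_gene_missing_in_one_genome_dropped(self, two_leaves):
        leaves = [copy.deepcopy(p) for p in two_leaves]
        victim = leaves[0].features[2].name
        leaves[0].features = [f for f in leaves[0].features if f.name != victim]
        regions = extract_shared_regions(leaves)
        assert victim not in regions
        assert all(victim not in name.split("-") for name in regions)

    def test_ir_duplicated_gene_single_region(self, two_leaves):
        regions = extract_shared_regions(two_leaves)
        # rrn9 is IR-duplicated in the preset; exactly one region results
        assert "rrn9" in regions
        assert len(regions["rrn9"].seqs) == len(two_leaves)

    def test_fewer_than_two_genomes_errors(self, two_leaves):
        with pytest.raises(ValueError):
            extract_shared_regions(two_leaves[:1])


class TestAlignRegion:
    def test_identical_sequences_gap_free(self):
        region = RegionSet("r", "coding", ["a", "b"], ["ACGTACGT", "ACGTACGT"])
        aln = align_region(region)
        assert aln.rows == ["ACGTACGT", "ACGTACGT"]

    def test_single_gap_column(self):
        a1, a2, _ = pairwise_align("ACGT", "AGT")
        assert a1 == "ACGT"
        assert a2 in ("A-GT", "AG-T")  # one 1-bp gap column
        assert sum(c == "-" for c in a2) == 1

    def test_import_verbatim(self):
        records = [("a", "AC-GT"), ("b", "ACCGT")]
        aln = import_alignment("x", "noncoding", records)
        assert aln.rows == ["AC-GT", "ACCGT"]

    def test_import_rejects_ragged(self):
        with pytest.raises(ValueError):
            import_alignment("x", "noncoding", [("a", "ACGT"), ("b", "AC")])

    def test_empty_input_errors(self):
        region = RegionSet("r", "coding", ["a", "b"], ["ACGT", ""])
        with pytest.raises(ValueError):
            align_region(region)

    def test_deterministic(self, rand_seq):
        seqs = [rand_seq(200), rand_seq(190), rand_seq(210)]
        region = RegionSet("r", "noncoding", ["a", "b", "c"], seqs)
        assert align_region(region).rows == align_region(region).rows


class TestVariabilityPercent:
    def test_identical_rows_zero(self):
        aln = RegionAlignment("x", "coding", ["a", "b"], ["A" * 500, "A" * 500])
        r = variability_percent(aln)
        assert (r.S, r.I, r.percent) == (0, 0, 0.0)

    def test_worked_example(self):
        aln = RegionAlignment(
            "x", "noncoding", ["a", "b"], ["ACGTACGTACGT", "ACCTAC--ACGT"]
        )
        r = variability_percent(aln)
        assert (r.S, r.I, r.L_aln, r.L_indel) == (1, 1, 12, 2)
        assert r.percent == pytest.approx(100.0 * 2 / 11)

    def test_upper_bound_all_polymorphic(self):
        aln = RegionAlignment("x", "coding", ["a", "b"], ["ACGT", "CGTA"])
        assert variability_percent(aln).percent == 100.0

    def test_row_permutation_invariance(self):
        rows = ["ACGTAC-TAC", "ACCTACGTAC", "ACGTACGTCC"]
        a = variability_percent(RegionAlignment("x", "coding", list("abc"), rows))
        b = variability_percent(
            RegionAlignment("x", "coding", list("cba"), rows[::-1])
        )
        assert a.percent == b.percent

    def test_duplicate_row_invariance(self):
        rows = ["ACGTAC-TAC", "ACCTACGTAC"]
        a = variability_percent(RegionAlignment("x", "coding", list("ab"), rows))
        b = variability_percent(
            RegionAlignment("x", "coding", list("abb"), rows + [rows[-1]])
        )
        assert a.percent == b.percent

    def test_invariant_column_decreases_percent(self):
        rows = ["ACGTAC-TAC", "ACCTACGTAC"]
        a = variability_percent(RegionAlignment("x", "coding", list("ab"), rows))
        rows2 = [r + "G" for r in rows]
        b = variability_percent(RegionAlignment("x", "coding", list("ab"), rows2))
        assert b.percent < a.percent

    def test_zero_iff_identical(self, rand_seq):
        s = rand_seq(80)
        same = variability_percent(RegionAlignment("x", "coding", list("ab"), [s, s]))
        assert same.percent == 0.0
        t = list(s)
        t[10] = "A" if t[10] != "A" else "C"
        diff = variability_percent(
            RegionAlignment("x", "coding", list("ab"), [s, "".join(t)])
        )
        assert diff.percent > 0.0

    def test_gap_plus_substitution_counts_indel_only(self):
        # column 2 has a gap in one row and a base difference among others
        rows = ["AAT", "AGT", "A-T"]
        r = variability_percent(RegionAlignment("x", "coding", list("abc"), rows))
        assert (r.S, r.I, r.L_indel) == (0, 1, 1)

    def test_zero_denominator_flagged(self):
        # only an empty alignment can zero the denominator (gap runs add I back)
        r = variability_percent(RegionAlignment("x", "coding", list("ab"), ["", ""]))
        assert r.undefined and r.percent == 0.0

    def test_single_gap_column_counts_one_event(self):
        r = variability_percent(RegionAlignment("x", "coding", list("ab"), ["-", "A"]))
        assert (r.S, r.I, r.L_indel, r.percent) == (0, 1, 1, 100.0)


class TestRankAndCombine:
    def _mk(self, name, percent, L=100):
        from plastomics.hotspots import VariabilityResult

        return VariabilityResult(name, "noncoding", 0, 0, L, 0, percent)

    def test_k_larger_than_list(self):
        res = [self._mk("a", 1.0), self._mk("b", 2.0)]
        assert len(rank_hotspots(res, k=7)) == 2

    def test_tie_break_by_length_then_name(self):
        res = [
            self._mk("bb", 5.0, L=100),
            self._mk("aa", 5.0, L=200),
            self._mk("cc", 5.0, L=100),
        ]
        ranked = [r.name for r, _ in rank_hotspots(res, k=3)]
        assert ranked == ["aa", "bb", "cc"]

    def test_threshold_flag(self):
        ranked = rank_hotspots([self._mk("a", 0.4), self._mk("b", 0.6)], k=2, threshold=0.5)
        flags = {r.name: f for r, f in ranked}
        assert flags == {"a": False, "b": True}

    def test_disjoint_sets(self):
        g = [f"g{i}" for i in range(7)]
        f = [f"f{i}" for i in range(7)]
        out = combine_hotspot_sets(g, f)
        assert out["n_intersection"] == 0 and out["n_union"] == 14

    def test_identical_sets(self):
        g = [f"g{i}" for i in range(7)]
        out = combine_hotspot_sets(g, list(g))
        assert out["n_intersection"] == 7 and out["n_union"] == 7

    def test_seven_plus_seven_overlap_three_gives_eleven(self):
        genus = ["psbK-psbI", "rpoB-trnC-GCA", "trnT-GGU-psbD", "trnT-UGU-trnL-UAA",
                 "ycf4-cemA", "trnP-UGG-psaJ", "ycf1"]
        family = ["rpoB-trnC-GCA", "trnT-GGU-psbD", "ycf1", "matK",
                  "trnK-UUU-rps16-trnQ-UUG", "rpl36-rps8", "ndhF"]
        out = combine_hotspot_sets(genus, family)
        assert out["n_intersection"] == 3
        assert out["n_union"] == 11
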