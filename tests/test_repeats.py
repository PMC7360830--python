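"""SSR, dispersed and tandem repeat detection."""

import numpy as np
import pytest

from oracles import brute_force_dispersed
from plastomics.model import Plastome, complement, revcomp
from plastomics.repeats import (
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    summarize_repeats,
)
from plastomics.simulate import build_ancestor, default_preset


def linear(seq: str) -> Plastome:
    return Plastome(id="t", seq=seq, circular=False)


class TestSSR:
    def test_below_mono_threshold(self, rand_seq):
        s = rand_seq(50).replace("A", "C") + "A" * 9 + rand_seq(50).replace("A", "C")
        assert [r for r in find_ssrs(linear(s)) if r.motif == "A"] == []

    def test_mono_12(self):
        recs = find_ssrs(linear("G" * 3 + "C" + "A" * 12 + "C" + "G" * 3))
        assert [(r.motif, r.copies) for r in recs] == [("A", 12)]

    def test_primitivity_at_smallest_unit(self):
        recs = find_ssrs(linear("GGG" + "AT" * 6 + "GGG"))
        assert [(r.motif, r.unit_len, r.copies) for r in recs] == [("AT", 2, 6)]

    def test_planted_recovery_50(self, rng):
        """50 planted SSRs of known classes are all recovered exactly."""
        motifs = ["A", "T", "AT", "AG", "AAC", "ACT", "ACGT", "AACCG", "ACGTAC"]
        plants = []
        for i in range(50):
            m = motifs[int(rng.integers(0, len(motifs)))]
            thr = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}[len(m)]
            plants.append((m, thr + int(rng.integers(0, 3))))
        cfg = default_preset(
            genes=[], planted_dispersed=[], planted_tandems=[], planted_ssrs=plants,
            genome_length=60000, ir_length=5000, ssc_length=6000,
        )
        plastome, truth = build_ancestor(cfg, 77)
        found = {(r.start, r.motif, r.copies) for r in find_ssrs(plastome)}
        for p in truth.planted_ssrs:
            assert (p["start"], p["motif"], p["copies"]) in found

    def test_rotation_invariance(self, test_ancestor, rng):
        _, plastome, _ = test_ancestor
        base = {
            ((r.start - 0) % len(plastome.seq), r.motif, r.copies)
            for r in find_ssrs(plastome)
        }
        off = int(rng.integers(1, len(plastome.seq)))
        rot = plastome.rotated(off)
        rotated = {
            ((r.start + off) % len(plastome.seq), r.motif, r.copies)
            for r in find_ssrs(rot)
        }
        assert base == rotated

    def test_runs_split_at_n(self):
        recs = find_ssrs(linear("C" * 4 + "A" * 11 + "N" + "A" * 11 + "C" * 4))
        assert [(r.motif, r.copies) for r in recs] == [("A", 11), ("A", 11)]

    def test_region_labels(self, test_ancestor):
        _, plastome, _ = test_ancestor
        for r in find_ssrs(plastome):
            assert r.region in ("LSC", "IRb", "SSC", "IRa")


def impl_tuples(seq, **kw):
    return {
        (r.category, r.pos1.start, r.pos2.start, r.length, r.mismatches)
        for r in find_dispersed_repeats(seq, max_out=None, **kw)
    }


class TestDispersed:
    def test_planted_forward_recovered(self, rand_seq):
        """A 35-bp exact segment at two loci is covered by a forward record.

        Maximal windows extend through up to max_mismatch flanking
        mismatches, so the reported record contains the planted copies
        (length >= 35) rather than equalling them exactly.
        """
        core = rand_seq(35)
        s = rand_seq(300) + core + rand_seq(500) + core + rand_seq(300)
        p1, p2 = 300, 300 + 35 + 500
        recs = [r for r in find_dispersed_repeats(s, max_out=None) if r.category == "forward"]
        covering = [
            r
            for r in recs
            if r.pos1.start <= p1
            and r.pos1.start + r.length >= p1 + 35
            and r.pos2.start <= p2
            and r.pos2.start + r.length >= p2 + 35
        ]
        assert covering and all(r.mismatches <= 3 for r in covering)

    def test_four_substitutions_absent(self, rng, rand_seq):
        core = rand_seq(30)
        mutated = list(core)
        for pos in (3, 10, 17, 24):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        s = rand_seq(200) + core + rand_seq(400) + "".join(mutated) + rand_seq(200)
        start1, start2 = 200, 200 + 30 + 400
        for r in find_dispersed_repeats(s, max_out=None):
            if r.category != "forward":
                continue
            # no reported window may cover both planted copies fully
            covers = r.pos1.start <= start1 and r.pos1.start + r.length >= start1 + 30
            covers &= r.pos2.start <= start2 and r.pos2.start + r.length >= start2 + 30
            assert not covers

    def test_planted_palindrome(self, rand_seq):
        core = rand_seq(40)
        s = rand_seq(300) + core + rand_seq(500) + revcomp(core) + rand_seq(300)
        p1, p2 = 300, 300 + 40 + 500
        recs = [
            r
            for r in find_dispersed_repeats(s, max_out=None)
            if r.category == "palindromic"
            and r.pos1.start <= p1
            and r.pos1.start + r.length >= p1 + 40
            and r.pos2.start <= p2
            and r.mismatches <= 3
        ]
        assert recs

    @pytest.mark.parametrize("category", ["forward", "reverse", "complement", "palindromic"])
    def test_oracle_equivalence_planted(self, rng, rand_seq, category):
        core = rand_seq(45)
        tr = {
            "forward": core,
            "reverse": core[::-1],
            "complement": complement(core),
            "palindromic": revcomp(core),
        }[category]
        s = rand_seq(400) + core + rand_seq(600) + tr + rand_seq(400)
        assert impl_tuples(s) == brute_force_dispersed(s)

    def test_oracle_equivalence_random(self, rng, rand_seq):
        for _ in range(5):
            s = rand_seq(2000)
            assert impl_tuples(s) == brute_force_dispersed(s)

    def test_ir_flagged(self, test_ancestor):
        _, plastome, _ = test_ancestor
        recs = find_dispersed_repeats(plastome, max_out=None)
        ir_hits = [r for r in recs if r.is_ir]
        assert len(ir_hits) == 1
        assert ir_hits[0].category == "palindromic"
        assert ir_hits[0].length >= 3000  # whole IR, plus budgeted flank slack

    def test_max_out_longest_kept(self, rand_seq):
        core = rand_seq(60)
        s = rand_seq(200) + core + rand_seq(300) + core + rand_seq(200)
        all_recs = find_dispersed_repeats(s, max_out=None)
        capped = find_dispersed_repeats(s, max_out=3)
        assert len(capped) == min(3, len(all_recs))
        assert [r.length for r in capped] == sorted(
            (r.length for r in all_recs), reverse=True
        )[: len(capped)]

    def test_self_verification(self, test_ancestor):
        """Re-extracting every record's coordinates satisfies its category's
        defining relation within the mismatch budget."""
        _, plastome, _ = test_ancestor
        seq = plastome.seq
        n = len(seq)
        for r in find_dispersed_repeats(plastome, max_out=None):
            s1 = plastome.slice(r.pos1)
            s2 = plastome.slice(r.pos2)
            expect = {
                "forward": s1,
                "reverse": s1[::-1],
                "complement": complement(s1),
                "palindromic": revcomp(s1),
            }[r.category]
            ham = sum(1 for a, b in zip(s2, expect) if a != b)
            assert len(s1) == len(s2) == r.length
            assert ham == r.mismatches <= 3


class TestTandem:
    def _sealed(self, rand_seq, motif, copies, mutate_at=None):
        arr = list(motif * copies)
        if mutate_at is not None:
            arr[mutate_at] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[mutate_at]]
        left = "C" if motif[-1] != "C" else "G"
        right = "C" if motif[0] != "C" else "G"
        return rand_seq(150) + left + "".join(arr) + right + rand_seq(150)

    def test_score_80_boundary_reported(self, rand_seq):
        s = self._sealed(rand_seq, "ACGTACGTAT", 4)
        recs = find_tandem_repeats(s)
        assert [(r.period, r.copies, r.score) for r in recs] == [(10, 4, 80)]

    def test_score_64_absent(self, rand_seq):
        s = self._sealed(rand_seq, "ACGTACGA", 4)
        assert find_tandem_repeats(s) == []

    def test_one_substitution_score_191(self, rand_seq):
        s = self._sealed(rand_seq, "ACGTACGTATACGTACGATC", 5, mutate_at=37)
        recs = find_tandem_repeats(s)
        assert [(r.period, r.copies, r.score) for r in recs] == [(20, 5, 191)]

    def test_planted_truth(self, test_ancestor):
        _, plastome, truth = test_ancestor
        recs = find_tandem_repeats(plastome)
        for p in truth.planted_tandems:
            match = [
                r
                for r in recs
                if r.pos1.start == p["start"] and r.period == p["period"]
            ]
            assert match and match[0].copies == p["copies"]


class TestSummaries:
    def test_empty_all_zero(self):
        row = summarize_repeats("g", [], [], [])
        assert row["total"] == row["n_ssrs"] == 0

    def test_planted_counts_and_additivity(self, test_ancestor):
        _, plastome, truth = test_ancestor
        ssrs = find_ssrs(plastome)
        disp = find_dispersed_repeats(plastome, max_out=None)
        tand = find_tandem_repeats(plastome)
        row = summarize_repeats(plastome.id, ssrs, disp, tand)
        assert row["total"] == row["dispersed_total"] + row["palindromic"] + row["tandem"]
        assert row["dispersed_total"] == row["forward"] + row["reverse"] + row["complement"]
        assert sum(row["ssr_by_unit"].values()) == row["n_ssrs"]
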