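import pytest

from imescan import (delineate_transposon, find_at_rich,
                     find_inverted_repeats, find_iterons, find_motif,
                     make_feature, make_plasmid, rank_hairpins, revcomp,
                     shannon_entropy)

from _oracles import inverted_repeats_oracle, motif_oracle
from conftest import make_replicon, random_sequence


class TestInvertedRepeats:
    def test_planted_arms_with_spacer(self, rng):
        arm = "GCATGC"
        seq = (random_sequence(rng, 39) + "A" + arm + "A"
               + random_sequence(rng, 18) + "A" + revcomp(arm) + "A"
               + random_sequence(rng, 39))
        # flanking As pin the pair: A never complements A, so the maximal
        # pair is exactly the planted 6 bp arms with a 20 nt spacer
        pairs = find_inverted_repeats(make_replicon(seq), min_arm=6,
                                      max_spacer=30)
        planted = [p for p in pairs
                   if (p.left_start, p.left_end) == (41, 46)]
        assert len(planted) == 1
        (pair,) = planted
        assert (pair.right_start, pair.right_end) == (67, 72)
        assert pair.spacer_bp == 20 and pair.mismatches == 0

    def test_perfect_hairpin(self):
        arm = "GGCGCGTC"
        seq = "A" * 30 + arm + "TTTT" + revcomp(arm) + "A" * 30
        pairs = find_inverted_repeats(make_replicon(seq), min_arm=8,
                                      max_spacer=10)
        assert any(p.arm_length == 8 and p.spacer_bp == 4 for p in pairs)

    def test_matches_quadratic_oracle_on_random_sequences(self, rng):
        for _ in range(15):
            seq = random_sequence(rng, int(rng.integers(200, 600)))
            got = {(p.left_start, p.left_end, p.right_start, p.right_end)
                   for p in find_inverted_repeats(make_replicon(seq),
                                                  min_arm=5, max_spacer=100)}
            assert got == inverted_repeats_oracle(seq, 5, 100)

    def test_reported_pairs_self_validate(self, rng):
        seq = random_sequence(rng, 1500)
        rep = make_replicon(seq)
        for p in find_inverted_repeats(rep, min_arm=5, max_spacer=200,
                                       max_mismatch=1):
            left = seq[p.left_start - 1:p.left_end]
            right = seq[p.right_start - 1:p.right_end]
            mm = sum(a != b for a, b in zip(left, revcomp(right)))
            assert mm == p.mismatches <= 1
            assert p.left_end < p.right_start
            assert p.spacer_bp == p.right_start - p.left_end - 1

    def test_wrapping_pair_on_circular_molecule(self):
        arm = "GGATCCGT"
        # left arm ends 4 bp before the origin, right arm lies after it
        seq = revcomp(arm) + "A" * 80 + arm + "TTTT"
        pairs = find_inverted_repeats(make_replicon(seq, circular=True),
                                      min_arm=8, max_spacer=10)
        assert any(p.spacer_bp == 4 and p.arm_length == 8 for p in pairs)

    def test_rank_hairpins_prefers_min_spacer_within_cluster(self):
        arm = "GGCGCGTC"
        seq = ("A" * 30 + arm + "TTTT" + revcomp(arm) + "A" * 30)
        pairs = find_inverted_repeats(make_replicon(seq), min_arm=4,
                                      max_spacer=60)
        ranked = rank_hairpins(pairs)
        assert ranked[0].spacer_bp == min(p.spacer_bp for p in pairs)


class TestIterons:
    def test_exact_tandem_array(self):
        seq = "C" * 30 + "ATGCA" * 3 + "C" * 30
        (arr,) = find_iterons(make_replicon(seq), unit_min=5, unit_max=8,
                              min_copies=3, max_mismatch_per_copy=0)
        assert (arr.unit_length, arr.copies, arr.start) == (5, 3, 31)
        assert arr.consensus == "ATGCA"

    def test_one_substitution_tolerated(self):
        seq = "C" * 30 + "ATGCA" + "ATACA" + "ATGCA" + "C" * 30
        (arr,) = find_iterons(make_replicon(seq), unit_min=5, unit_max=8,
                              min_copies=3, max_mismatch_per_copy=1)
        assert arr.copies == 3
        assert arr.per_copy_mismatches == (0, 1, 0)

    def test_homopolymer_suppressed_by_entropy_guard(self):
        assert find_iterons(make_replicon("A" * 40), unit_min=5, unit_max=8,
                            min_copies=3, max_mismatch_per_copy=0) == []
        assert shannon_entropy("AAAAA") == 0.0
        assert shannon_entropy("ATGCA") > 1.0

    def test_longest_span_wins_merge(self):
        unit = "ATGCAGGTCC"
        seq = "C" * 20 + unit * 4 + "A" * 20
        arrays = find_iterons(make_replicon(seq), unit_min=5, unit_max=21,
                              min_copies=3, max_mismatch_per_copy=0)
        (arr,) = arrays
        assert arr.unit_length == 10 and arr.copies == 4


class TestMotif:
    def test_planted_dnaa_box(self):
        seq = "GC" * 200 + "TTATCCACA" + "GC" * 200
        hits = find_motif(make_replicon(seq), "TTATCCACA", 0)
        assert hits == [(401, "+", 0)]

    def test_one_mismatch_found_and_counted(self):
        seq = "GC" * 200 + "TTATGCACA" + "GC" * 200
        hits = find_motif(make_replicon(seq), "TTATCCACA", 1)
        assert (401, "+", 1) in hits

    def test_agrees_with_position_scan_oracle(self, rng):
        seq = random_sequence(rng, 3000)
        for circular in (False, True):
            rep = make_replicon(seq, circular=circular)
            got = find_motif(rep, "TTATCCACA", 2)
            assert got == motif_oracle(seq, circular, "TTATCCACA", 2)


class TestAtRich:
    def test_planted_at_run_recovered_within_one_window(self):
        run = "AT" * 25
        seq = "GC" * 100 + run + "GC" * 100
        (iv,) = find_at_rich(make_replicon(seq), window_bp=30,
                             min_at_fraction=0.8)
        start, end = iv
        assert abs(start - 201) <= 30 and abs(end - 250) <= 30
        assert start <= 201 and end >= 250 - 30

    def test_uniform_sequence_has_no_windows(self):
        assert find_at_rich(make_replicon("ACGT" * 100), window_bp=30,
                            min_at_fraction=0.8) == []

    def test_zero_threshold_covers_whole_molecule(self):
        rep = make_replicon("ACGT" * 100, circular=True)
        assert find_at_rich(rep, window_bp=30, min_at_fraction=0.0) == [(1, 400)]


class TestTransposon:
    def test_three_copies_give_nested_units(self, small_spec):
        rep, truth = make_plasmid(small_spec)
        seed = truth.by_kind("terminal_repeat_seed")[0].payload
        scan = delineate_transposon(rep, seed)
        assert len(scan.copies) == 3
        outer = truth.one("transposon_outer")
        inner = truth.one("transposon_inner")
        spans = {(u.unit_start, u.unit_end) for u in scan.units}
        assert spans == {(outer.start, outer.end), (inner.start, inner.end)}

    def test_cargo_features_listed_between_bounds(self, small_spec):
        rep, truth = make_plasmid(small_spec)
        seed = truth.by_kind("terminal_repeat_seed")[0].payload
        scan = delineate_transposon(rep, seed)
        outer = max(scan.units, key=lambda u: u.unit_end - u.unit_start)
        assert len(outer.cargo_features) > 0

    def test_two_copies_one_unit(self, rng):
        seed = random_sequence(rng, 38)
        seq = (random_sequence(rng, 300) + seed + random_sequence(rng, 800)
               + revcomp(seed) + random_sequence(rng, 300))
        scan = delineate_transposon(make_replicon(seq), seed)
        assert len(scan.copies) == 2 and len(scan.units) == 1
        (unit,) = scan.units
        assert (unit.unit_start, unit.unit_end) == (301, 301 + 38 + 800 + 38 - 1)

    def test_single_copy_listed_but_no_unit(self, rng):
        seed = random_sequence(rng, 38)
        seq = random_sequence(rng, 300) + seed + random_sequence(rng, 300)
        scan = delineate_transposon(make_replicon(seq), seed)
        assert len(scan.copies) == 1 and scan.units == []

    def test_no_copy_empty_result(self, rng):
        seed = random_sequence(rng, 38)
        scan = delineate_transposon(make_replicon("ACGT" * 200), seed)
        assert scan.copies == [] and scan.units == []

    def test_de_novo_seed_recovers_units(self, small_spec):
        rep, truth = make_plasmid(small_spec)
        scan = delineate_transposon(rep)
        outer = truth.one("transposon_outer")
        assert len(scan.units) == 2
        best = max(scan.units, key=lambda u: u.unit_end - u.unit_start)
        assert abs(best.unit_start - outer.start) <= 2
        assert abs(best.unit_end - outer.end) <= 2
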