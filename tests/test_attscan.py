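import numpy as np
import pytest

from imescan import (AnnotatedReplicon, AttCandidate, AttScanParams,
                     build_trna_library, excise, filter_candidates,
                     find_att_candidates, integrate, make_feature, revcomp,
                     score_candidate, subsequence)
from imescan.seqio import TrnaEntry, TrnaLibrary

from _oracles import anchored_matches_oracle
from conftest import make_replicon, random_sequence


def library_from(seq, trna_id="tRNA1"):
    return TrnaLibrary([TrnaEntry("src", trna_id, "tRNA-Ser", seq,
                                  seq[-25:], "", "")])


def plant(rng, length, insert, at):
    background = random_sequence(rng, length)
    return background[:at] + insert + background[at + len(insert):]


class TestFindAttCandidates:
    def test_planted_terminus_found_once(self, rng):
        terminus = "GGTTCGACTCCG"
        trna = random_sequence(rng, 63) + "A" + terminus
        seq = plant(rng, 2000, terminus, 500)
        # pin the base left of the plant so the match cannot extend to 13 bp
        seq = seq[:499] + "C" + seq[500:]
        cands = find_att_candidates(library_from(trna), make_replicon(seq),
                                    AttScanParams(min_match_bp=10))
        hits = [c for c in cands if c.match_length >= 12]
        assert len(hits) == 1
        (c,) = hits
        assert (c.target_start, c.target_end) == (501, 512)
        assert c.target_strand == "+" and c.trna_end_offset == 0
        assert c.core_sequence == terminus

    def test_reverse_complement_plant_found_on_minus(self, rng):
        terminus = "GGTTCGACTCCG"
        trna = random_sequence(rng, 63) + "A" + terminus
        seq = plant(rng, 2000, revcomp(terminus), 500)
        # pin the base right of the plant (= left of the match on the minus
        # strand) so extension past 12 bp is impossible: it would need T
        seq = seq[:512] + "G" + seq[513:]
        cands = [c for c in find_att_candidates(library_from(trna),
                                                make_replicon(seq),
                                                AttScanParams())
                 if c.match_length >= 12]
        (c,) = cands
        assert c.target_strand == "-"
        assert (c.target_start, c.target_end) == (501, 512)
        assert c.core_sequence == terminus

    def test_below_threshold_not_reported(self):
        terminus = "GGTTCGACT"     # 9 bp shared suffix
        trna = "ACG" * 17 + "A" + terminus
        target = make_replicon("C" * 500 + terminus + "C" * 500)
        cands = find_att_candidates(library_from(trna), target,
                                    AttScanParams(min_match_bp=10))
        assert cands == []

    @pytest.mark.parametrize("circular", [False, True])
    def test_agrees_with_suffix_oracle(self, rng, circular):
        for _ in range(25):
            n = int(rng.integers(150, 1200))
            target_seq = random_sequence(rng, n)
            trna = random_sequence(rng, 40) + target_seq[
                int(rng.integers(0, n - 8)):][:8]   # bias toward real hits
            target = make_replicon(target_seq, circular=circular)
            got = {(c.target_strand, c.target_start, c.target_end,
                    c.match_length)
                   for c in find_att_candidates(library_from(trna), target,
                                                AttScanParams(min_match_bp=5))}
            assert got == anchored_matches_oracle(trna, target_seq, 5,
                                                  circular=circular)

    def test_candidates_are_maximal(self, rng):
        for _ in range(10):
            target_seq = random_sequence(rng, 800)
            trna = random_sequence(rng, 30) + target_seq[100:108]
            target = make_replicon(target_seq)
            for c in find_att_candidates(library_from(trna), target,
                                         AttScanParams(min_match_bp=5)):
                seg = subsequence(target, c.target_start, c.match_length,
                                  c.target_strand)
                assert seg == c.core_sequence
                # extending one base left on the tRNA must break the match
                if c.match_length < len(trna) and c.target_start > 1:
                    wider = subsequence(target, c.target_start - 1,
                                        c.match_length + 1, "+")
                    if c.target_strand == "-":
                        wider = subsequence(target, c.target_start - 1,
                                            c.match_length + 1, "-")
                    assert wider != trna[-(c.match_length + 1):]

    def test_relaxed_anchor_finds_offset_match(self, rng):
        trna = random_sequence(rng, 60)
        inner = trna[-20:-5]       # ends 5 bp before the 3' terminus
        target = make_replicon(plant(rng, 1000, inner, 300))
        anchored = find_att_candidates(library_from(trna), target,
                                       AttScanParams(min_match_bp=12))
        relaxed = find_att_candidates(
            library_from(trna), target,
            AttScanParams(min_match_bp=12, require_terminus_anchor=False,
                          max_terminus_offset=6))
        assert not any(c.match_length >= 15 for c in anchored)
        hits = [c for c in relaxed if c.trna_end_offset == 5
                and c.match_length >= 15]
        assert hits and hits[0].target_start == 301


class TestScoring:
    def test_uniform_composition_closed_form(self):
        target = make_replicon("ACGT" * 250)     # exactly uniform, 1 kb
        cand = AttCandidate("t", "x", 10, 0, 1, 10, "+", False, "ACGTACGTAC")
        expected = 2 * 1000 * 0.25 ** 10
        assert score_candidate(cand, target) == pytest.approx(expected)
        assert expected == pytest.approx(1.907e-3, rel=1e-3)

    def test_longer_core_scores_strictly_lower(self, rng):
        target = make_replicon(random_sequence(rng, 1000))
        core = "ACGTACGTACG"
        short = AttCandidate("t", "x", 10, 0, 1, 10, "+", False, core[:10])
        long = AttCandidate("t", "x", 11, 0, 1, 11, "+", False, core)
        assert score_candidate(long, target) < score_candidate(short, target)

    def test_single_strand_halves_the_score(self, rng):
        target = make_replicon(random_sequence(rng, 1000))
        cand = AttCandidate("t", "x", 10, 0, 1, 10, "+", False, "ACGTACGTAC")
        both = score_candidate(cand, target, AttScanParams())
        one = score_candidate(cand, target,
                              AttScanParams(search_both_strands=False))
        assert both == pytest.approx(2 * one)


class TestFiltering:
    def make_target(self, rng):
        feats = [make_feature("CDS", 400, 600, "+", {"product": "x"})]
        return make_replicon(random_sequence(rng, 1000), features=feats,
                             rid="target")

    def cand(self, start, end):
        return AttCandidate("t", "target", end - start + 1, 0, start, end,
                            "+", False, "A" * (end - start + 1))

    def test_overlapping_cds_is_not_intergenic(self, rng):
        target = self.make_target(rng)
        (c,) = filter_candidates([self.cand(501, 512)], target)
        assert c.intergenic is False

    def test_clear_of_features_is_intergenic(self, rng):
        target = self.make_target(rng)
        (c,) = filter_candidates([self.cand(700, 711)], target)
        assert c.intergenic is True

    def test_gi_interval_flag_and_wrong_molecule_warning(self, rng):
        target = self.make_target(rng)
        (c,) = filter_candidates([self.cand(700, 711)], target,
                                 gi_intervals=[("target", 1, 1000)])
        assert c.in_genomic_island is True
        with pytest.warns(UserWarning, match="does not match"):
            (c,) = filter_candidates([self.cand(700, 711)], target,
                                     gi_intervals=[("other", 1, 1000)])
        assert c.in_genomic_island is False

    def test_intergenic_only_drops_genic(self, rng):
        target = self.make_target(rng)
        kept = filter_candidates([self.cand(501, 512), self.cand(700, 711)],
                                 target,
                                 params=AttScanParams(intergenic_only=True))
        assert [(c.target_start) for c in kept] == [700]


class TestIntegration:
    def toy_pair(self, rng, core_len=12, host_len=200, plasmid_len=100):
        core = random_sequence(rng, core_len)
        host_seq = plant(rng, host_len, core, 100)
        plasmid_seq = plant(rng, plasmid_len, core, 40)
        host = make_replicon(host_seq, rid="host")
        plasmid = make_replicon(plasmid_seq, circular=True, rid="plasmid")
        attB = AttCandidate("t", "host", core_len, 0, 101, 100 + core_len,
                            "+", False, core)
        attP = AttCandidate("t", "plasmid", core_len, 0, 41, 40 + core_len,
                            "+", False, core)
        return plasmid, host, attP, attB, core

    def test_length_conserved_and_core_duplicated(self, rng):
        plasmid, host, attP, attB, core = self.toy_pair(rng)
        result = integrate(plasmid, host, attP, attB)
        assert result.cointegrate.length == 300
        assert result.cointegrate.sequence.count(core) == 2
        assert core in result.attL_junction and core in result.attR_junction

    def test_integrate_then_excise_restores_inputs(self, rng):
        plasmid, host, attP, attB, core = self.toy_pair(rng)
        result = integrate(plasmid, host, attP, attB)
        host_back, plasmid_back = excise(result.cointegrate, core)
        assert host_back == host.sequence
        assert len(plasmid_back) == plasmid.length
        assert plasmid_back in plasmid.sequence * 2   # rotation of the input

    def test_zero_flank_junction_is_bare_core(self, rng):
        plasmid, host, attP, attB, core = self.toy_pair(rng)
        result = integrate(plasmid, host, attP, attB, flank_bp=0)
        assert result.attL_junction == core
        assert result.attR_junction == core

    def test_differing_cores_rejected(self, rng):
        plasmid, host, attP, attB, core = self.toy_pair(rng)
        from dataclasses import replace
        with pytest.raises(ValueError, match="cores differ"):
            integrate(plasmid, host, attP, replace(attB, core_sequence="A" * 12))

    def test_minus_strand_attP_still_conserves_length(self, rng):
        plasmid, host, attP, attB, core = self.toy_pair(rng)
        flipped = AnnotatedReplicon("plasmid", revcomp(plasmid.sequence),
                                    circular=True)
        n = plasmid.length
        attP_minus = AttCandidate("t", "plasmid", attP.match_length, 0,
                                  n - attP.target_end + 1,
                                  n - attP.target_start + 1, "-", False, core)
        result = integrate(flipped, host, attP_minus, attB)
        assert result.cointegrate.length == 300
        assert result.cointegrate.sequence.count(core) == 2
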