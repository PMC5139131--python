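import numpy as np
import pytest

import satjunction as sj
from satjunction._dna import revcomp, BASES
from satjunction.architecture import (
    HitPair,
    classify_pair,
    detect_remnant_spacer,
    detect_tsd,
    pair_flanking_hits,
)
from satjunction.io_formats import GenomicFragment
from satjunction.scan import ArrayAnnotation, MonomerHit


def random_dna(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def make_hit(start, end, cstart, cend, strand="+", family="simfam"):
    h = MonomerHit(
        fragment_id="f", start=start, end=end, strand=strand, family=family,
        cstart=cstart, cend=cend, matches=end - start, columns=end - start,
    )
    h.classify(170)
    return h


class TestDetectTsd:
    def test_pentanucleotide_direct_repeat(self, rng):
        # ...TGATC [insert ... TGATC] ... — the duplicated pentanucleotide
        core = random_dna(rng, 100)
        seq = random_dna(rng, 40) + "TGATC" + core + "TGATC" + random_dna(rng, 40)
        insert = (45, 45 + 100 + 5)
        call = detect_tsd(GenomicFragment("f", seq), insert)
        assert call is not None
        assert call.sequence == "TGATC" and call.length == 5

    def test_longest_of_nested_repeats_wins(self, rng):
        tsd = "GATTACA"  # contains shorter bracketing repeats of itself
        core = random_dna(rng, 60)
        seq = random_dna(rng, 30) + tsd + core + tsd + random_dna(rng, 30)
        insert = (37, 37 + 60 + 7)
        call = detect_tsd(GenomicFragment("f", seq), insert)
        assert call.sequence == "GATTACA"

    def test_no_shared_flanking_kmer_gives_none(self):
        seq = "A" * 20 + "CGCGCGCG" + "T" * 20
        assert detect_tsd(GenomicFragment("f", seq), (20, 28)) is None

    def test_search_truncated_near_fragment_edge(self):
        seq = "ACACGTACGTACGT"
        # insert starts at position 2: only k <= 2 can be tested
        assert detect_tsd(GenomicFragment("f", seq), (2, 10)) is None

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            detect_tsd(GenomicFragment("f", "ACGTACGT"), (5, 20))


class TestClassifyPair:
    def test_zero_missing_is_split_insertion(self, family):
        up = make_hit(100, 200, 0, 100)
        down = make_hit(1006, 1076, 100, 170)
        ev = classify_pair(HitPair(up, down, 806, 0), family)
        assert ev is not None and ev.kind == "split_insertion"
        assert ev.insert_len == 806 and ev.missing_len == 0

    def test_similar_lengths_are_cut_and_replace(self, family):
        # a 63-bp missing monomer segment replaced by a 54-bp spacer
        up = make_hit(100, 197, 0, 97)
        down = make_hit(251, 261, 160, 170)
        ev = classify_pair(HitPair(up, down, 54, 63), family)
        assert ev is not None and ev.kind == "cut_and_replace"
        assert ev.missing_len == 63 and ev.length_delta == -9

    def test_grossly_mismatched_lengths_unclassified(self, family):
        up = make_hit(100, 197, 0, 97)
        down = make_hit(697, 707, 160, 170)
        assert classify_pair(HitPair(up, down, 500, 63), family) is None


class TestPairing:
    def test_contiguous_hits_do_not_pair(self, family):
        hits = [make_hit(0, 170, 0, 170), make_hit(170, 340, 0, 170)]
        assert pair_flanking_hits(hits, family) == []

    def test_opposite_strands_do_not_pair(self, family):
        hits = [make_hit(0, 170, 0, 170), make_hit(400, 570, 0, 170, strand="-")]
        assert pair_flanking_hits(hits, family) == []

    def test_separated_same_strand_hits_pair(self, family):
        hits = [make_hit(0, 100, 0, 100), make_hit(400, 470, 100, 170)]
        pairs = pair_flanking_hits(hits, family)
        assert len(pairs) == 1
        assert pairs[0].gap_bp == 300
        assert pairs[0].missing_raw == 0


class TestRemnantSpacer:
    def build(self, family, remnant_iv, remnant_phases, spacer, array_phase):
        """Array starting at the given phase, remnant left of it."""
        rs, re_ = remnant_iv
        rem = make_hit(rs, re_, *remnant_phases)
        a_start = re_ + spacer
        members = [make_hit(a_start, a_start + (170 - array_phase),
                            array_phase, 170)]
        array = ArrayAnnotation("f", family.name, "+", members, 5)
        return array, rem

    def test_remnant_spacer_39_54_63_geometry(self, family):
        # 39-bp remnant, 54-bp spacer, 63-bp missing monomer segment
        array, rem = self.build(
            family, (100, 139), (6, 45), spacer=54, array_phase=108
        )
        events = detect_remnant_spacer(array, [rem], family)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "remnant_spacer"
        assert ev.remnant_len == 39
        assert ev.spacer_len == 54
        assert ev.missing_len == 63

    def test_out_of_phase_remnant_gives_no_event(self, family):
        array, rem = self.build(
            family, (100, 139), (6, 45), spacer=54, array_phase=44
        )
        # missing would be (44 - 45) mod 170 = 169: not phase-continuous
        assert detect_remnant_spacer(array, [rem], family) == []

    def test_no_remnants_no_events(self, family):
        array, _ = self.build(family, (100, 139), (6, 45), 54, 108)
        assert detect_remnant_spacer(array, [], family) == []

    def test_distant_remnant_exceeds_max_spacer(self, family):
        array, rem = self.build(
            family, (100, 139), (6, 45), spacer=300, array_phase=108
        )
        assert detect_remnant_spacer(array, [rem], family, max_spacer=100) == []


class TestPlantedRecovery:
    def test_split_insertions_recovered_with_tsd(self):
        from satjunction.evaluation import split_insertion_recovery

        res = split_insertion_recovery(21, n_fragments=40)
        assert res["recall"] >= 0.9
        assert res["tsd_exact"] >= 0.8

    def test_cut_and_replace_classified(self):
        from satjunction.evaluation import cut_and_replace_recovery

        res = cut_and_replace_recovery(22, n_fragments=40)
        assert res["recall"] >= 0.8

    def test_large_delta_interruptions_never_called_cut(self, family, rng):
        # an interruption much longer than the missing segment must not be
        # classified as a replacement
        mon = sj.mutate_monomer(family.consensus, 0.05, rng)
        insert = random_dna(rng, 500)
        seq = (random_dna(rng, 150) + mon[:60] + insert + mon[123:]
               + random_dna(rng, 150))
        result = sj.analyze_fragments(
            [GenomicFragment("f", seq)], [family], seed=0
        )
        kinds = [e.kind for e in result.all_events]
        assert "cut_and_replace" not in kinds

    def test_classification_invariant_under_reverse_complement(self):
        cfg = sj.SimConfig(seed=77, n_fragments=6, monomer_divergence=(0.05, 0.08),
                           event_rates={"split_insertion": 0.5,
                                        "cut_and_replace": 0.5})
        frags, truths, fam = sj.generate_dataset(cfg)
        fwd = sj.analyze_fragments(frags, [fam], seed=1)
        flipped = [
            GenomicFragment(f.id, revcomp(f.sequence), source="synthetic")
            for f in frags
        ]
        rev = sj.analyze_fragments(flipped, [fam], seed=1)
        for f in frags:
            n = len(f.sequence)
            fwd_evs = sorted(
                (e.kind, e.insert_interval[0], e.insert_interval[1])
                for e in fwd.per_fragment[f.id].events
            )
            rev_evs = sorted(
                (e.kind, n - e.insert_interval[1], n - e.insert_interval[0])
                for e in rev.per_fragment[f.id].events
            )
            kinds_fwd = [k for k, *_ in fwd_evs]
            kinds_rev = [k for k, *_ in rev_evs]
            assert kinds_fwd == kinds_rev
            for (kf, sf, ef), (kr, sr, er) in zip(fwd_evs, rev_evs):
                assert abs(sf - sr) <= 2 and abs(ef - er) <= 2
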