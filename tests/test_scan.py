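import numpy as np
import pytest

import satjunction as sj
from satjunction._dna import revcomp, BASES
from satjunction.io_formats import GenomicFragment
from satjunction.scan import (
    MonomerHit,
    find_remnants,
    make_multimer,
    scan_fragment,
    segment_arrays,
)


def random_dna(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def make_hit(start, end, cstart, cend, strand="+", family="simfam",
             fragment_id="f"):
    h = MonomerHit(
        fragment_id=fragment_id, start=start, end=end, strand=strand,
        family=family, cstart=cstart, cend=cend,
        matches=end - start, columns=end - start,
    )
    h.classify(170)
    return h


class TestMultimer:
    def test_dimer_and_trimer(self, family):
        assert make_multimer(family, 2) == family.consensus * 2
        assert len(make_multimer(family, 3)) == 3 * family.length

    def test_monomer_order_rejected(self, family):
        with pytest.raises(ValueError):
            make_multimer(family, 1)


class TestScanFragment:
    def test_exact_tandem_trimer_gives_three_complete_hits(self, family):
        frag = GenomicFragment("t", family.consensus * 3)
        hits = scan_fragment(frag, family)
        assert len(hits) == 3
        assert all(h.completeness == "complete" for h in hits)
        assert all(h.percent_identity == 1.0 for h in hits)
        assert [h.cstart for h in hits] == [0, 0, 0]
        assert [(h.start, h.end) for h in hits] == [
            (0, 170), (170, 340), (340, 510)
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sequence_yields_no_hits(self, family, seed):
        rng = np.random.default_rng(seed)
        frag = GenomicFragment("r", random_dna(rng, 1000))
        assert scan_fragment(frag, family, min_identity=0.7, min_len=30) == []

    def test_diverged_nine_copy_array_counted_correctly(self, family):
        # nine consecutive diverged monomers form
        # one array; a mutated terminal base occasionally costs a copy
        # (boundary genuinely ambiguous), so count over replicates
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            monomers = [
                sj.mutate_monomer(family.consensus, 0.03, rng) for _ in range(9)
            ]
            seq = random_dna(rng, 150) + "".join(monomers) + random_dna(rng, 150)
            frag = GenomicFragment("ninecopy", seq)
            result = sj.analyze_fragments([frag], [family], seed=0)
            arrays = result.per_fragment["ninecopy"].arrays[family.name]
            assert len(arrays) == 1
            counts.append(arrays[0].copy_number)
        assert all(c in (8, 9) for c in counts)
        assert sum(c == 9 for c in counts) >= 8

    def test_strand_symmetry(self, family, rng):
        monomers = [sj.mutate_monomer(family.consensus, 0.05, rng) for _ in range(3)]
        seq = random_dna(rng, 120) + "".join(monomers) + random_dna(rng, 120)
        frag = GenomicFragment("fwd", seq)
        mirror = GenomicFragment("rev", revcomp(seq))
        n = len(seq)
        fwd = scan_fragment(frag, family)
        rev = scan_fragment(mirror, family)
        mirrored = sorted(
            (n - h.end, n - h.start, "+-"[h.strand == "+"], h.cstart, h.cend)
            for h in rev
        )
        direct = sorted((h.start, h.end, h.strand, h.cstart, h.cend) for h in fwd)
        assert direct == mirrored

    def test_phase_congruence_within_arrays(self, family, rng):
        monomers = [sj.mutate_monomer(family.consensus, 0.10, rng) for _ in range(6)]
        seq = random_dna(rng, 100) + "".join(monomers) + random_dna(rng, 100)
        hits = scan_fragment(GenomicFragment("f", seq), family)
        arrays = segment_arrays(hits)
        L = family.length
        for array in arrays:
            for a, b in zip(array.members, array.members[1:]):
                gap = b.start - a.end
                assert (b.cstart - (a.cend % L)) % L <= gap + array.max_gap_bp


class TestSegmentArrays:
    def test_distant_hits_form_two_arrays(self):
        hits = [make_hit(0, 170, 0, 170), make_hit(470, 640, 0, 170)]
        arrays = segment_arrays(hits)
        assert len(arrays) == 2
        assert [a.copy_number for a in arrays] == [1, 1]

    def test_single_hit_is_an_array_of_one(self):
        arrays = segment_arrays([make_hit(10, 180, 0, 170)])
        assert len(arrays) == 1
        assert arrays[0].copy_number == 1

    def test_adjacent_hits_chain(self):
        hits = [make_hit(0, 170, 0, 170), make_hit(172, 342, 0, 170)]
        arrays = segment_arrays(hits, max_gap_bp=5)
        assert len(arrays) == 1
        assert arrays[0].copy_number == 2

    def test_hits_from_multiple_fragments_rejected(self):
        hits = [
            make_hit(0, 170, 0, 170, fragment_id="a"),
            make_hit(0, 170, 0, 170, fragment_id="b"),
        ]
        with pytest.raises(ValueError):
            segment_arrays(hits)

    def test_empty_input(self):
        assert segment_arrays([]) == []


class TestRemnants:
    def test_planted_consensus_fragment_is_found(self, family, rng):
        piece = family.consensus[6:45]  # 39 bp, exact
        seq = random_dna(rng, 150) + piece + random_dna(rng, 150)
        rems = find_remnants(GenomicFragment("f", seq), family, [])
        assert len(rems) == 1
        rem = rems[0]
        # local alignment may extend a few bases into chance-matching flank
        assert rem.start <= 150 and rem.end >= 189
        assert rem.span <= 39 + 12
        assert rem.cstart <= 6 and rem.cend >= 45
        assert rem.percent_identity >= 0.85

    @pytest.mark.parametrize("seed", range(4))
    def test_random_flank_yields_none(self, family, seed):
        rng = np.random.default_rng(100 + seed)
        rems = find_remnants(
            GenomicFragment("f", random_dna(rng, 400)),
            family, [], min_len=19, min_identity=0.9,
        )
        assert rems == []

    def test_excluded_intervals_are_not_rescanned(self, family, rng):
        seq = random_dna(rng, 100) + family.consensus + random_dna(rng, 100)
        rems = find_remnants(
            GenomicFragment("f", seq), family, [(100, 270)]
        )
        assert rems == []
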