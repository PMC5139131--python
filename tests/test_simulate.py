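import numpy as np
import pytest
from scipy import stats

import satjunction as sj
from satjunction._dna import is_palindrome
from satjunction.simulate import SimConfig, generate_dataset, read_truth_table


class TestConfigValidation:
    def test_bad_event_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, event_rates={"split_insertion": 1.5})

    def test_event_rates_must_sum_to_at_most_one(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, event_rates={"split_insertion": 0.6,
                                           "cut_and_replace": 0.6})

    def test_odd_palindrome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, palindrome_lengths=(9,))

    def test_palindrome_longer_than_monomer_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, monomer_length=100, palindrome_lengths=(200,))

    def test_divergence_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, monomer_divergence=(0.1, 0.5))

    def test_bad_breakpoint_mode(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, breakpoint_mode="clumped")


class TestFamilyGeneration:
    def test_planted_palindromes_verify(self, family):
        assert sorted(e - s for s, e in family.palindromes) == [10, 12]
        for s, e in family.palindromes:
            assert is_palindrome(family.consensus[s:e])

    def test_same_seed_gives_identical_family(self):
        a = sj.generate_family(SimConfig(seed=4))
        b = sj.generate_family(SimConfig(seed=4))
        assert a.consensus == b.consensus
        assert a.palindromes == b.palindromes

    def test_two_conserved_blocks_planted(self, family):
        assert sorted(e - s for s, e in family.conserved_blocks) == [15, 20]


class TestMutateMonomer:
    def test_zero_divergence_is_identity(self, family, rng):
        assert sj.mutate_monomer(family.consensus, 0.0, rng) == family.consensus

    def test_divergence_matches_binomial_expectation(self, family, rng):
        L = family.length
        diffs = []
        for _ in range(50):
            m = sj.mutate_monomer(family.consensus, 0.3, rng)
            diffs.append(sum(a != b for a, b in zip(m, family.consensus)))
        mean_div = np.mean(diffs) / L
        assert abs(mean_div - 0.3) < 0.03

    def test_out_of_range_divergence_rejected(self, family, rng):
        with pytest.raises(ValueError):
            sj.mutate_monomer(family.consensus, 0.5, rng)

    def test_protected_blocks_mutate_less(self, family, rng):
        s, e = family.conserved_blocks[1]
        inside = outside = 0
        for _ in range(60):
            m = sj.mutate_monomer(
                family.consensus, 0.3, rng, protected=[(s, e)]
            )
            inside += sum(
                m[i] != family.consensus[i] for i in range(s, e)
            )
            outside += sum(
                m[i] != family.consensus[i] for i in range(0, s)
            )
        assert inside / (60 * (e - s)) < 0.12
        assert outside / (60 * s) > 0.2


class TestFragments:
    def test_clean_array_truth_lists_two_junctions(self):
        cfg = SimConfig(seed=5, n_fragments=3, copy_number_range=(9, 9),
                        event_rates={})
        frags, truths, fam = generate_dataset(cfg)
        for t in truths:
            assert len(t.junctions) == 2
            assert t.arrays[0]["n_complete"] == 9
            assert not t.events

    def test_dataset_regeneration_is_byte_identical(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        generate_dataset(SimConfig(seed=5, n_fragments=4), out_dir=a)
        generate_dataset(SimConfig(seed=5, n_fragments=4), out_dir=b)
        for name in ("fragments.fasta", "truth.tsv", "family.yaml"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_truth_table_round_trip(self, tmp_path):
        cfg = SimConfig(seed=8, n_fragments=5)
        _, truths, _ = generate_dataset(cfg, out_dir=tmp_path)
        back = read_truth_table(tmp_path / "truth.tsv")
        assert [t.fragment_id for t in back] == [t.fragment_id for t in truths]
        assert back[0].junctions == truths[0].junctions

    def test_zero_fragments_gives_empty_outputs(self, tmp_path):
        generate_dataset(SimConfig(seed=1, n_fragments=0), out_dir=tmp_path)
        assert (tmp_path / "fragments.fasta").read_text() == ""
        assert len((tmp_path / "truth.tsv").read_text().splitlines()) == 1


@pytest.fixture(scope="module")
def batch():
    cfg = SimConfig(
        seed=23, n_fragments=30,
        event_rates={"split_insertion": 0.34, "cut_and_replace": 0.33,
                     "remnant_spacer": 0.33},
    )
    return generate_dataset(cfg)


class TestTruthConsistency:
    """Planted coordinates must be re-derivable from the emitted sequence."""

    def test_intervals_within_fragment(self, batch):
        frags, truths, fam = batch
        for f, t in zip(frags, truths):
            n = len(f.sequence)
            for a in t.arrays:
                assert 0 <= a["start"] < a["end"] <= n
            for j in t.junctions:
                assert 0 <= j["fragment_pos"] <= n
                assert 0 <= j["consensus_pos"] < fam.length

    def test_tsd_bracket_present_in_sequence(self, batch):
        frags, truths, _ = batch
        checked = 0
        for f, t in zip(frags, truths):
            for ev in t.events:
                if ev["kind"] != "split_insertion":
                    continue
                tsd = ev["tsd_realized"]
                k = len(tsd)
                # canonical frame: rightmost maximal bracketing repeat
                found = False
                for delta in range(-10, 11):
                    s = ev["insert_start"] + delta
                    e = ev["insert_end"] + delta
                    if (0 <= s - k and e <= len(f.sequence)
                            and f.sequence[s - k : s] == tsd
                            and f.sequence[e - k : e] == tsd):
                        found = True
                        break
                assert found
                checked += 1
        assert checked >= 3

    def test_array_sequence_matches_consensus_at_planted_phases(self, batch):
        frags, truths, fam = batch
        L = fam.length
        for f, t in zip(frags, truths):
            a = t.arrays[0]
            span = min(60, a["end"] - a["start"])
            matches = sum(
                f.sequence[a["start"] + i]
                == fam.consensus[(a["phase_start"] + i) % L]
                for i in range(span)
            )
            assert matches / span > 0.75

    def test_remnant_phases_consistent(self, batch):
        frags, truths, fam = batch
        L = fam.length
        for f, t in zip(frags, truths):
            for ev in t.events:
                if ev["kind"] != "remnant_spacer":
                    continue
                r_len = ev["remnant_len"]
                matches = sum(
                    f.sequence[ev["remnant_start"] + i]
                    == fam.consensus[(ev["remnant_cstart"] + i) % L]
                    for i in range(r_len)
                )
                assert matches / r_len > 0.7


class TestBreakpointModes:
    def test_uniform_junctions_pass_chi_square(self):
        cfg = SimConfig(seed=31, n_fragments=500, event_rates={})
        _, truths, fam = generate_dataset(cfg)
        positions = [
            j["consensus_pos"] for t in truths for j in t.junctions
        ]
        assert len(positions) == 1000
        counts, _ = np.histogram(positions, bins=10, range=(0, fam.length))
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_clustered_junctions_stay_in_interval(self):
        cfg = SimConfig(seed=32, n_fragments=50, event_rates={},
                        breakpoint_mode=("clustered", (40, 52)))
        _, truths, _ = generate_dataset(cfg)
        for t in truths:
            for j in t.junctions:
                assert 40 <= j["consensus_pos"] < 52
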