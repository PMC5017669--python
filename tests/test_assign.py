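from __future__ import annotations

import numpy as np
import pytest

import aavsrna as a
from aavsrna.simulate import _random_seq

from oracles import naive_placements, naive_revcomp


def _mutate_at(seq: str, positions: list[int]) -> str:
    chars = list(seq)
    for p in positions:
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    return "".join(chars)


class TestEnumeratePlacements:
    def test_plus_strand_exact_window(self):
        rng = np.random.default_rng(1)
        ref = a.ReferenceSequence("r", _random_seq(rng, 200), "v", "genome")
        read = ref.sequence[9:30]  # 1-based 10..30
        (pl,) = [p for p in a.enumerate_placements(read, [ref], 0) if p.strand == "+"]
        assert (pl.start, pl.end, pl.mismatches, pl.five_prime) == (10, 30, 0, 10)

    def test_minus_strand_five_prime_is_high_coordinate(self):
        rng = np.random.default_rng(2)
        ref = a.ReferenceSequence("r", _random_seq(rng, 200), "v", "genome")
        read = naive_revcomp(ref.sequence[49:70])  # window 50..70
        (pl,) = [p for p in a.enumerate_placements(read, [ref], 0) if p.strand == "-"]
        assert (pl.start, pl.end, pl.five_prime) == (50, 70, 70)

    def test_n_never_matches(self):
        ref = a.ReferenceSequence("r", "AAAAAAAAAAAAAAAAAAAA", "v", "genome")
        read = "AAAAAAAANAAAAAAA"  # N at offset 8: one forced mismatch
        assert a.enumerate_placements(read, [ref], 0) == []
        assert all(
            p.mismatches >= 1 for p in a.enumerate_placements(read, [ref], 1)
        )

    def test_short_read_rejected(self):
        ref = a.ReferenceSequence("r", "ACGT" * 20, "v", "genome")
        with pytest.raises(ValueError):
            a.enumerate_placements("ACGTACGTACGTACG", [ref], 0)

    @pytest.mark.parametrize("tier", [0, 1, 2])
    def test_bit_exact_against_naive_hamming_scan(self, tier):
        """Seed-and-verify index must equal the exhaustive per-position scan."""
        rng = np.random.default_rng(100 + tier)
        refs = [
            a.ReferenceSequence(f"r{i}", _random_seq(rng, 600), "v", "genome")
            for i in range(2)
        ]
        reads = []
        for _ in range(15):
            reads.append(_random_seq(rng, int(rng.integers(16, 31))))
        for _ in range(15):  # planted windows, some mutated, some reverse-complemented
            ref = refs[int(rng.integers(2))]
            L = int(rng.integers(16, 31))
            s = int(rng.integers(0, ref.length - L))
            window = ref.sequence[s : s + L]
            n_mut = int(rng.integers(0, 3))
            window = _mutate_at(window, list(rng.choice(L, n_mut, replace=False)))
            if rng.random() < 0.5:
                window = naive_revcomp(window)
            reads.append(window)
        reads.append(refs[0].sequence[:16].replace("A", "N", 1))
        for read in reads:
            assert a.enumerate_placements(read, refs, tier) == naive_placements(
                read, refs, tier
            )


class TestTierSchedule:
    def test_validation(self):
        a.TierSchedule((0, 1, 2))
        with pytest.raises(ValueError):
            a.TierSchedule(())
        with pytest.raises(ValueError):
            a.TierSchedule((1, 0))
        with pytest.raises(ValueError):
            a.TierSchedule((0, 3))


@pytest.fixture(scope="module")
def cascade_fixture():
    """Host and two viral genomes with planted reads at known mismatch tiers."""
    rng = np.random.default_rng(42)
    host_seq = list(_random_seq(rng, 400))
    v1_seq = list(_random_seq(rng, 400))
    v2_seq = list(_random_seq(rng, 400))

    shared = _random_seq(rng, 21)  # exactly in host AND v1
    host_seq[100:121] = shared
    v1_seq[100:121] = shared

    viral_only = _random_seq(rng, 21)  # exactly in v1; 1 mismatch in host
    v1_seq[200:221] = viral_only
    host_seq[200:221] = _mutate_at(viral_only, [10])

    near_host = _random_seq(rng, 21)  # 1 mismatch in host, 1 mismatch in v1
    host_seq[300:321] = _mutate_at(near_host, [5])
    v1_seq[300:321] = _mutate_at(near_host, [7])

    far_viral = _random_seq(rng, 21)  # 2 mismatches in v1 only
    v1_seq[50:71] = _mutate_at(far_viral, [3, 15])

    cross = _random_seq(rng, 21)  # exactly in v1 AND v2
    v1_seq[350:371] = cross
    v2_seq[150:171] = cross

    host = [a.ReferenceSequence("host1", "".join(host_seq), "host", "genome")]
    v1 = [a.ReferenceSequence("v1g", "".join(v1_seq), "v1", "genome")]
    v2 = [a.ReferenceSequence("v2g", "".join(v2_seq), "v2", "genome")]
    reads = dict(
        shared=shared, viral_only=viral_only, near_host=near_host,
        far_viral=far_viral, cross=cross, nothing=_random_seq(rng, 21),
    )
    return host, {"v1": v1, "v2": v2}, reads


class TestHierarchicalAssign:
    def _assign(self, fixture, schedule, names):
        host, viral, reads = fixture
        collapsed = [a.CollapsedRead(reads[n], 1) for n in names]
        recs = a.hierarchical_assign(collapsed, host, viral, a.TierSchedule(schedule))
        return {reads[n]: r for n, r in zip(names, recs)}

    def test_host_always_wins_at_equal_tier(self, cascade_fixture):
        _, _, reads = cascade_fixture
        recs = self._assign(cascade_fixture, (0,), ["shared"])
        assert recs[reads["shared"]].category == "human"

    def test_unmatched_read_is_unknown_at_tier_zero(self, cascade_fixture):
        _, _, reads = cascade_fixture
        recs = self._assign(cascade_fixture, (0,), ["nothing", "near_host"])
        assert recs[reads["nothing"]].category == "unknown"
        assert recs[reads["near_host"]].category == "unknown"  # only 1-mm matches

    def test_tier_ordering_viral_tier0_beats_host_tier1(self, cascade_fixture):
        _, _, reads = cascade_fixture
        recs = self._assign(
            cascade_fixture, (0, 1), ["viral_only", "near_host", "far_viral"]
        )
        # tier-0 viral match wins although the host matches at tier 1
        r = recs[reads["viral_only"]]
        assert r.category == "virus:v1" and r.tier == 0
        # no tier-0 match anywhere: host claims it at tier 1
        r = recs[reads["near_host"]]
        assert r.category == "human" and r.tier == 1
        # 2-mismatch viral match is out of reach under (0, 1)
        assert recs[reads["far_viral"]].category == "unknown"

    def test_two_mismatch_tier_recovers_viral_read(self, cascade_fixture):
        _, _, reads = cascade_fixture
        recs = self._assign(cascade_fixture, (0, 1, 2), ["far_viral"])
        r = recs[reads["far_viral"]]
        assert r.category == "virus:v1" and r.tier == 2

    def test_cross_species_flagged_and_counted_per_species(self, cascade_fixture):
        host, viral, reads = cascade_fixture
        recs = self._assign(cascade_fixture, (0,), ["cross"])
        r = recs[reads["cross"]]
        assert r.viral_species == ("v1", "v2") and r.cross_species_ambiguous
        summary = a.assignment_summary("s", [r], 1, 1, viral_species=["v1", "v2"])
        assert summary.viral == {"v1": 1, "v2": 1}
        assert summary.n_cross_species == 1

    def test_mirna_subflag_from_pre_mirna_placement(self, host_small):
        refs, catalog = host_small
        collapsed = [a.CollapsedRead(catalog[0].sequence, 4)]
        (rec,) = a.hierarchical_assign(collapsed, refs, {})
        assert rec.category == "human_mirna" and rec.count == 4


class TestEquivalenceClasses:
    def test_single_placement_is_its_own_canonical(self):
        p = a.Placement("r", "+", 10, 30, 0)
        rec = a.AssignmentRecord("A" * 21, 1, "virus:v", 0, (p,))
        group = a.equivalence_classes(rec)
        assert group.size == 1 and group.canonical == p

    def test_itr_arm_read_groups_across_strands(self, itr_genome):
        genome, _ = itr_genome
        read = genome.sequence[:20]
        placements = tuple(a.enumerate_placements(read, [genome], 0))
        rec = a.AssignmentRecord(read, 1, "virus:aav", 0, placements)
        group = a.equivalence_classes(rec)
        assert group.size >= 2
        assert {p.strand for p in group.members} == {"+", "-"}
        # the terminal-resolution equivalence: 5'=1 (+) pairs with 5'=2*arm (-)
        fives = {(p.strand, p.five_prime) for p in group.members}
        assert ("+", 1) in fives and ("-", 124) in fives
        assert group.canonical.five_prime == 1 and group.canonical.strand == "+"

    def test_exhaustive_scan_confirms_group(self, itr_genome):
        genome, _ = itr_genome
        read = genome.sequence[4:24]
        ours = a.enumerate_placements(read, [genome], 0)
        assert ours == naive_placements(read, [genome], 0)
        assert len(ours) >= 2


class TestAssignmentSummary:
    def test_all_host_fixture(self, host_small):
        refs, catalog = host_small
        collapsed = [a.CollapsedRead(c.sequence, 2) for c in catalog[:3]]
        recs = a.hierarchical_assign(collapsed, refs, {"v": []})
        row = a.assignment_summary("s", recs, 10, 6, viral_species=["v"])
        assert row.n_human == 6 and row.n_human_mirna == 6
        assert row.viral == {"v": 0} and row.n_unknown == 0

    def test_partition_violation_raises(self):
        rec = a.AssignmentRecord("A" * 21, 3, "unknown", None, ())
        with pytest.raises(ValueError):
            a.assignment_summary("s", [rec], 5, 7)

    def test_unknown_monotonically_non_increasing_with_tiers(self, host_small):
        refs, _ = host_small
        rng = np.random.default_rng(9)
        genome = a.ReferenceSequence("v", _random_seq(rng, 800), "v", "genome")
        reads = []
        for _ in range(60):  # genome windows with 0-2 substitutions
            L = int(rng.integers(18, 25))
            s = int(rng.integers(0, genome.length - L))
            w = genome.sequence[s : s + L]
            reads.append(_mutate_at(w, list(rng.choice(L, int(rng.integers(0, 3)), replace=False))))
        collapsed = a.collapse(reads)
        unknowns = []
        for tiers in [(0,), (0, 1), (0, 1, 2)]:
            recs = a.hierarchical_assign(collapsed, refs, {"v": [genome]}, a.TierSchedule(tiers))
            unknowns.append(sum(r.count for r in recs if r.category == "unknown"))
        assert unknowns[0] >= unknowns[1] >= unknowns[2]
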