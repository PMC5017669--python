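from __future__ import annotations

import numpy as np
import pytest

import aavsrna as a
from aavsrna.simulate import DEFAULT_ADAPTER

from oracles import naive_placements, naive_revcomp


class TestHostReference:
    def test_mature_arm_is_exact_substring_of_hairpin(self):
        refs, catalog = a.make_host_reference(n_premirnas=5, seed=3)
        hairpins = {r.id: r for r in refs if r.role == "pre_mirna"}
        assert len(hairpins) == 5 and len(catalog) == 5
        for m in catalog:
            assert m.sequence in hairpins[m.premirna_id].sequence

    def test_arm_reverse_complement_in_three_prime_half(self):
        refs, catalog = a.make_host_reference(n_premirnas=4, seed=8)
        hairpins = {r.id: r for r in refs if r.role == "pre_mirna"}
        for m in catalog:
            seq = hairpins[m.premirna_id].sequence
            half = len(seq) // 2
            assert naive_revcomp(m.sequence) in seq[half:]

    def test_deterministic_given_seed(self):
        one = a.make_host_reference(seed=9)
        two = a.make_host_reference(seed=9)
        assert one == two

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            a.make_host_reference(n_decoys=0)


class TestItrGenome:
    def test_terminal_pair_found_by_annotation(self, itr_genome):
        genome, annotations = itr_genome
        found = a.annotate_terminal_repeats(genome, 10)
        assert any(
            ann.relation == "reverse_complement" and ann.width == 145 for ann in found
        )
        assert annotations[0].verify(genome)

    def test_terminal_read_has_mirror_at_twice_arm_length(self, itr_genome):
        """The 5'=1 (+) species coincides with the 5'=2*arm (-) species."""
        genome, _ = itr_genome
        for L in (16, 20):
            read = genome.sequence[:L]
            placements = naive_placements(read, [genome], 0)
            fives = {(p.strand, p.five_prime) for p in placements}
            assert ("+", 1) in fives and ("-", 124) in fives

    def test_cross_itr_equivalents_exist(self, itr_genome):
        genome, _ = itr_genome
        read = genome.sequence[29:50]  # inside the palindromic arm
        placements = naive_placements(read, [genome], 0)
        refs_hit = {(p.strand, p.start) for p in placements}
        assert len(refs_hit) >= 2
        assert any(p.start > genome.length - 145 for p in placements)

    def test_deterministic_and_validated(self):
        g1, _ = a.make_itr_genome(500, seed=4)
        g2, _ = a.make_itr_genome(500, seed=4)
        assert g1.sequence == g2.sequence
        with pytest.raises(ValueError):
            a.make_itr_genome(500, itr_len=100, arm_len=62)
        with pytest.raises(ValueError):
            a.make_itr_genome(0)


class TestSampleDesign:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            a.SampleDesign("s", 100, {"host_other": 0.5, "junk": 0.4})
        with pytest.raises(ValueError):
            a.SampleDesign("s", 100, {"mystery": 1.0})
        with pytest.raises(ValueError):
            a.SampleDesign("s", 0, {"junk": 1.0})


@pytest.fixture(scope="module")
def tiny_refs():
    refs, catalog = a.make_host_reference(
        n_decoys=2, decoy_len=600, n_premirnas=4, seed=21
    )
    genome, _ = a.make_itr_genome(400, seed=22)
    specs = [a.HotspotSpec(genome.id, "+", 300, {20: 0.5, 21: 0.5}, 1000)]
    return refs, catalog, genome, specs


class TestSimulateSample:

    def test_zero_virus_fraction_means_no_viral_truth_rows(self, tiny_refs):
        refs, catalog, genome, specs = tiny_refs
        design = a.SampleDesign(
            "s", 500, {"host_mirna": 0.4, "host_other": 0.4, "junk": 0.2}, seed=1
        )
        sim = a.simulate_sample(design, refs, catalog, {"aav": genome}, {"aav": specs})
        assert not sim.truth["source"].str.startswith("virus").any()
        assert len(sim.truth) == 500 == len(sim.reads)

    def test_zero_noise_hotspot_count_equals_truth_exactly(self, tiny_refs):
        refs, catalog, genome, specs = tiny_refs
        design = a.SampleDesign(
            "s",
            4000,
            {"host_other": 0.5, "virus:aav": 0.4, "junk": 0.1},
            error_rate=0.0,
            seed=2,
            viral_background=0.0,
        )
        sim = a.simulate_sample(design, refs, catalog, {"aav": genome}, {"aav": specs})
        viral_truth = sim.truth[sim.truth["source"] == "virus:aav"]
        truth_n = int((viral_truth["five_prime"] == 300).sum())
        result = a.process_reads(
            "s", [s for _, s in sim.reads], refs, {"aav": [genome]}, design.adapter
        )
        track = a.pileup_five_prime(result.viral_records("aav"), genome.id, "+")
        assert track.counts.get(300, 0) == truth_n > 0

    def test_planted_abundance_within_multinomial_bound(self, tiny_refs):
        refs, catalog, genome, specs = tiny_refs
        # viral reads = 0.5 * 16000; hotspot share = ab / (ab + bg) with bg ~1%
        expected = 0.5 * 16000 * (1000 / (1000 * 1.01))
        design = a.SampleDesign(
            "s",
            16000,
            {"host_other": 0.4, "virus:aav": 0.5, "junk": 0.1},
            error_rate=0.0,
            seed=3,
            viral_background=0.01,
        )
        sim = a.simulate_sample(design, refs, catalog, {"aav": genome}, {"aav": specs})
        viral_truth = sim.truth[sim.truth["source"] == "virus:aav"]
        observed = int((viral_truth["five_prime"] == 300).sum())
        assert abs(observed - expected) <= 4 * np.sqrt(expected)

    def test_byte_identical_fastq_for_identical_seeds(self, tiny_refs, tmp_path):
        refs, catalog, genome, specs = tiny_refs
        design = a.SampleDesign(
            "s", 300, {"host_other": 0.6, "virus:aav": 0.2, "junk": 0.2}, seed=7
        )
        paths = []
        for i in (1, 2):
            sim = a.simulate_sample(design, refs, catalog, {"aav": genome}, {"aav": specs})
            p = tmp_path / f"run{i}.fastq"
            sim.write_fastq(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_machine_reads_are_fixed_length(self, tiny_refs):
        refs, catalog, genome, specs = tiny_refs
        design = a.SampleDesign("s", 100, {"host_other": 1.0}, seed=4)
        sim = a.simulate_sample(design, refs, catalog, {}, {})
        assert {len(seq) for _, seq in sim.reads} == {51}


class TestHotspotSpec:
    def test_weight_and_bounds_validation(self):
        with pytest.raises(ValueError):
            a.HotspotSpec("g", "+", 1, {20: 0.5, 21: 0.4}, 10)
        with pytest.raises(ValueError):
            a.HotspotSpec("g", "+", 1, {15: 1.0}, 10)
        ref = a.ReferenceSequence("g", "ACGT" * 10, "v", "genome")
        spec = a.HotspotSpec("g", "+", 30, {20: 1.0}, 10)
        with pytest.raises(ValueError):
            spec.validate(ref)

    def test_minus_strand_insert_is_reverse_complement(self):
        ref = a.ReferenceSequence("g", "ACGTACGTACGTACGTACGTACGT", "v", "genome")
        spec = a.HotspotSpec("g", "-", 20, {16: 1.0}, 5)
        assert spec.insert(ref, 16) == naive_revcomp(ref.sequence[4:20])


class TestStudyDesign:
    def test_eight_samples_with_unit_fractions(self):
        designs, refs = a.study_design(total_reads=1000, seed=1)
        assert len(designs) == 8
        for d in designs:
            assert abs(sum(d.fractions.values()) - 1.0) < 1e-9
        assert set(refs.viral_genomes) == {"aav", "ad2", "hsv1"}
        for sp, specs in refs.hotspot_specs.items():
            for spec in specs:
                spec.validate(refs.viral_genomes[sp])

    def test_helper_coinfection_boosts_viral_mass_two_orders(self):
        designs, _ = a.study_design(total_reads=1000, seed=1)
        frac = {d.name: d.fractions["virus:aav"] for d in designs}
        assert frac["aav2_ad2_27hpi"] > 100 * frac["aav2_27hpi"]
        assert frac["aav2_hsv1_8hpi"] > 100 * frac["aav2_8hpi"]


class TestMiRNACounts:
    def test_catalog_size_and_determinism(self):
        table1, dep1 = a.simulate_mirna_counts(n_mirnas=200, seed=5)
        table2, dep2 = a.simulate_mirna_counts(n_mirnas=200, seed=5)
        assert table1.catalog_size == 200 and dep1 == dep2
        assert table1.counts.equals(table2.counts)

    def test_planted_depletion_is_deep_and_representative(self):
        table, depleted = a.simulate_mirna_counts(n_mirnas=300, seed=6)
        row = table.counts.loc[depleted]
        assert row["uninfected"] >= 100
        assert row["uninfected"] > 5 * row["aav2"]

    def test_depletion_must_exceed_band(self):
        with pytest.raises(ValueError):
            a.simulate_mirna_counts(depletion=4.0)
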