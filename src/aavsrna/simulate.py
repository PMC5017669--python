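"""Synthetic small RNA-Seq data emulating an eight-sample infection study.

The generator reproduces the statistical structure the analysis assumes, not
real biology: a host reference made of random decoy "genome" sequences plus
hairpin pre-miRNAs carrying known mature arms; an AAV-like viral genome with
145-nt-scale palindromic inverted terminal repeats (ITRs) that produce
genuinely ambiguous read placements; planted viral 5'-end hotspots with
stated length distributions (mode 21 nt; 16-23 nt; 18-19 nt); a diffuse
uniform background over the viral genome; a 3' sequencing adapter with
read-through to a fixed 51-nt machine read length; and per-base substitution
errors.  Every read is logged in a truth table, so pipeline output can be
compared against ground truth exactly (at zero error rate) or within
sampling noise.

All randomness flows from a single numpy Generator seeded by the design, so
identical seeds produce byte-identical FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    PromoterMark,
    ReferenceSequence,
    RepeatAnnotation,
    _rc,
)

#: Illumina TruSeq small RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Machine read length of a 1x51 sequencing run; small RNA inserts are shorter,
#: so every read reads through into the 3' adapter and trimming is exercised.
DEFAULT_MACHINE_READ_LENGTH = 51

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ALT = {b: "ACGT".replace(b, "") for b in "ACGT"}
_ALT["N"] = "N"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only error model (downstream alignment is ungapped)."""
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    subs = rng.integers(0, 3, hits.size)
    for i, s in zip(hits, subs):
        chars[i] = _ALT[chars[i]][s]
    return "".join(chars)


@dataclass(frozen=True)
class HotspotSpec:
    """A planted viral 5'-end hotspot.

    ``five_prime_start`` is the 1-based plus-strand coordinate of the 5'
    terminal nucleotide; on the minus strand a read of length L spans
    ``[five_prime_start - L + 1, five_prime_start]``.  ``abundance`` is the
    expected read count and acts as the relative weight when viral reads are
    multinomially allocated within a sample.
    """

    ref_id: str
    strand: str
    five_prime_start: int
    length_weights: dict[int, float]
    abundance: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if abs(sum(self.length_weights.values()) - 1.0) > 1e-9:
            raise ValueError("length_weights must sum to 1")
        if any(l < 16 for l in self.length_weights):
            raise ValueError("all read lengths must be >= 16")
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")

    def validate(self, ref: ReferenceSequence) -> None:
        max_len = max(self.length_weights)
        if self.strand == "+":
            if not (1 <= self.five_prime_start <= ref.length - max_len + 1):
                raise ValueError(f"hotspot at {self.five_prime_start} overruns {ref.id}")
        else:
            if not (max_len <= self.five_prime_start <= ref.length):
                raise ValueError(f"hotspot at {self.five_prime_start} overruns {ref.id}")

    def insert(self, ref: ReferenceSequence, length: int) -> str:
        if self.strand == "+":
            return ref.fetch(self.five_prime_start, self.five_prime_start + length - 1)
        return ref.fetch(self.five_prime_start - length + 1, self.five_prime_start, "-")


@dataclass(frozen=True)
class SampleDesign:
    """One sample of the simulated design.

    ``fractions`` maps read sources to proportions summing to 1; keys are
    ``host_mirna``, ``host_other``, ``virus:<species>`` and ``junk``.  Junk
    reads are random sequences of 10-30 nt, so some fall below the 16-nt
    filter and the rest surface as "unknown" in the assignment summary.
    ``viral_background`` is the fraction of each species' reads drawn as
    diffuse uniform background over its genome rather than from the planted
    hotspots.  ``junk_short_fraction`` controls how much of the junk falls
    below 16 nt (lost to the length filter) versus surfacing as "unknown".
    """

    name: str
    total_reads: int
    fractions: dict[str, float]
    error_rate: float = 0.002
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0
    viral_background: float = 0.01
    junk_short_fraction: float = 0.3
    machine_read_length: int = DEFAULT_MACHINE_READ_LENGTH

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        for key in self.fractions:
            if key not in ("host_mirna", "host_other", "junk") and not key.startswith(
                "virus:"
            ):
                raise ValueError(f"unknown source {key!r}")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.viral_background < 1:
            raise ValueError("viral_background must be in [0, 1)")
        if not 0 <= self.junk_short_fraction <= 1:
            raise ValueError("junk_short_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature-arm catalog entry: the 5' arm of a synthetic hairpin."""

    name: str
    premirna_id: str
    sequence: str
    start: int = 1  # 1-based position of the arm within the pre-miRNA


def make_host_reference(
    n_decoys: int = 4,
    decoy_len: int = 5000,
    n_premirnas: int = 25,
    seed: int = 0,
    arm_len: int = 21,
    loop_len: int = 15,
) -> tuple[list[ReferenceSequence], list[MatureMiRNA]]:
    """Random decoy host "genome" records plus hairpin pre-miRNAs.

    Each pre-miRNA is arm + loop + reverse_complement(arm), so the mature arm
    occurs as an exact substring and its reverse complement sits in the 3'
    half of the hairpin.  Deterministic given the seed.
    """
    if min(n_decoys, decoy_len, n_premirnas, arm_len, loop_len) <= 0:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    refs = [
        ReferenceSequence(f"decoy{i + 1}", _random_seq(rng, decoy_len), "host", "genome")
        for i in range(n_decoys)
    ]
    catalog: list[MatureMiRNA] = []
    for i in range(n_premirnas):
        arm = _random_seq(rng, arm_len)
        loop = _random_seq(rng, loop_len)
        pid = f"syn-mir-{i + 1}"
        refs.append(ReferenceSequence(pid, arm + loop + _rc(arm), "host", "pre_mirna"))
        catalog.append(MatureMiRNA(f"syn-miR-{i + 1}", pid, arm))
    return refs, catalog


def make_itr_genome(
    core_len: int,
    itr_len: int = 145,
    arm_len: int = 62,
    seed: int = 0,
    ref_id: str = "synthetic_aav",
    species: str = "aav",
) -> tuple[ReferenceSequence, list[RepeatAnnotation]]:
    """AAV-like genome with palindromic inverted terminal repeats.

    The left ITR is P + reverse_complement(P) + D (internal palindrome of arm
    length ``arm_len`` plus a unique D segment); the right ITR is the reverse
    complement of the left.  By construction a read equal to the genome
    prefix of length L <= arm_len also places on the minus strand with its 5'
    end at 2*arm_len (the terminal-resolution-site equivalence where the
    species starting at position 1 coincides with the one ending the
    palindrome), and every left-ITR read has a mirrored placement in the
    right ITR.
    """
    if itr_len < 2 * arm_len:
        raise ValueError("itr_len must be >= 2 * arm_len")
    if core_len <= 0:
        raise ValueError("core_len must be positive")
    rng = np.random.default_rng(seed)
    p = _random_seq(rng, arm_len)
    d = _random_seq(rng, itr_len - 2 * arm_len)
    left = p + _rc(p) + d
    core = _random_seq(rng, core_len)
    # pin the core ends so the terminal repeat relation cannot extend into the core
    core = "A" + core[1:-1] + "A" if core_len >= 2 else "A"
    genome = ReferenceSequence(ref_id, left + core + _rc(left), species, "genome")
    n = genome.length
    annotation = RepeatAnnotation(
        ref_id, (1, itr_len), (n - itr_len + 1, n), "reverse_complement"
    )
    assert annotation.verify(genome)
    return genome, [annotation]


@dataclass
class SimulatedSample:
    """Simulated reads plus the per-read ground-truth table."""

    design: SampleDesign
    reads: list[tuple[str, str]]  # (read id, 51-nt machine read)
    truth: pd.DataFrame  # read_id, source, ref_id, strand, five_prime, length

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


_BG_LENGTHS = np.arange(18, 25)  # diffuse viral background read lengths


def simulate_sample(
    design: SampleDesign,
    host_refs: Sequence[ReferenceSequence],
    mature_catalog: Sequence[MatureMiRNA],
    viral_genomes: Mapping[str, ReferenceSequence],
    hotspot_specs: Mapping[str, Sequence[HotspotSpec]] | None = None,
) -> SimulatedSample:
    """Emit ``design.total_reads`` reads with a truth row per read.

    Source counts are multinomial over the design fractions; within a viral
    species, reads are multinomial over the planted hotspot abundances plus a
    diffuse-background pseudo-source weighted by ``design.viral_background``.
    Substitution errors are applied to the insert+adapter portion, the 3'
    adapter is appended and the read padded/truncated to the machine read
    length.
    """
    hotspot_specs = hotspot_specs or {}
    rng = np.random.default_rng(design.seed)
    genome_hosts = [r for r in host_refs if r.role == "genome"]
    premirnas = {r.id: r for r in host_refs if r.role == "pre_mirna"}
    for sp, specs in hotspot_specs.items():
        for spec in specs:
            spec.validate(viral_genomes[sp])

    keys = [k for k in ("host_mirna", "host_other") if k in design.fractions]
    keys += sorted(k for k in design.fractions if k.startswith("virus:"))
    if "junk" in design.fractions:
        keys.append("junk")
    probs = np.array([design.fractions[k] for k in keys], dtype=float)
    counts = rng.multinomial(design.total_reads, probs / probs.sum())

    # truth tuples (source, ref_id, strand, five_prime, length, insert)
    drawn: list[tuple[str, str, str, int, int, str]] = []
    for key, n in zip(keys, counts):
        if n == 0:
            continue
        if key == "host_mirna":
            picks = rng.integers(0, len(mature_catalog), n)
            for i in picks:
                m = mature_catalog[i]
                drawn.append(
                    ("host_mirna", m.premirna_id, "+", m.start, len(m.sequence), m.sequence)
                )
        elif key == "host_other":
            ref_picks = rng.integers(0, len(genome_hosts), n)
            lengths = rng.integers(16, 29, n)
            strands = rng.integers(0, 2, n)
            for ri, L, si in zip(ref_picks, lengths, strands):
                ref = genome_hosts[ri]
                L = int(L)
                start = int(rng.integers(1, ref.length - L + 2))
                end = start + L - 1
                strand = "+" if si == 0 else "-"
                five = start if strand == "+" else end
                drawn.append(
                    ("host_other", ref.id, strand, five, L, ref.fetch(start, end, strand))
                )
        elif key.startswith("virus:"):
            sp = key.split(":", 1)[1]
            genome = viral_genomes[sp]
            specs = list(hotspot_specs.get(sp, ()))
            weights = [s.abundance for s in specs]
            if specs and design.viral_background > 0:
                bg_weight = (
                    design.viral_background
                    / (1 - design.viral_background)
                    * sum(weights)
                )
            elif specs:
                bg_weight = 0.0
            else:
                bg_weight = 1.0
            w = np.array(weights + [bg_weight], dtype=float)
            alloc = rng.multinomial(n, w / w.sum())
            source = f"virus:{sp}"
            for spec, m in zip(specs, alloc[:-1]):
                if m == 0:
                    continue
                lens = np.array(sorted(spec.length_weights))
                lw = np.array([spec.length_weights[l] for l in lens], dtype=float)
                for L in rng.choice(lens, size=m, p=lw / lw.sum()):
                    L = int(L)
                    drawn.append(
                        (
                            source,
                            genome.id,
                            spec.strand,
                            spec.five_prime_start,
                            L,
                            spec.insert(genome, L),
                        )
                    )
            n_bg = int(alloc[-1])
            if n_bg:
                lengths = rng.choice(_BG_LENGTHS, size=n_bg)
                strands = rng.integers(0, 2, n_bg)
                for L, si in zip(lengths, strands):
                    L = int(L)
                    start = int(rng.integers(1, genome.length - L + 2))
                    end = start + L - 1
                    strand = "+" if si == 0 else "-"
                    five = start if strand == "+" else end
                    drawn.append(
                        (source, genome.id, strand, five, L, genome.fetch(start, end, strand))
                    )
        else:  # junk
            short = rng.random(n) < design.junk_short_fraction
            for is_short in short:
                L = int(rng.integers(10, 16) if is_short else rng.integers(16, 31))
                drawn.append(("junk", ".", ".", 0, L, _random_seq(rng, L)))

    order = rng.permutation(len(drawn))
    mlen = design.machine_read_length
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for out_i, draw_i in enumerate(order):
        source, ref_id, strand, five, L, insert = drawn[draw_i]
        s = insert + design.adapter
        s = _mutate(rng, s, design.error_rate)
        if len(s) >= mlen:
            s = s[:mlen]
        else:
            s = s + _random_seq(rng, mlen - len(s))
        rid = f"{design.name}:{out_i:07d}"
        reads.append((rid, s))
        truth_rows.append((rid, source, ref_id, strand, five, L))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "source", "ref_id", "strand", "five_prime", "length"],
    )
    return SimulatedSample(design, reads, truth)


# ---------------------------------------------------------------------------
# Study-scale designs and benchmark scenarios
# ---------------------------------------------------------------------------

#: Per-sample composition magnitudes of the emulated eight-sample design.
#: g: fraction of reads >= 16 nt; h: human fraction of >=16-nt reads;
#: m: human-miRNA fraction of >=16-nt reads; u: unknown (unmappable) fraction
#: of >=16-nt reads; per-virus fractions of >=16-nt reads.
_STUDY_COMPOSITION: dict[str, dict[str, float]] = {
    "cells_27hpi": dict(g=0.899, h=0.841, m=0.275, u=0.046, aav=1e-6, ad2=2e-5, hsv1=3e-7),
    "aav2_27hpi": dict(g=0.897, h=0.821, m=0.360, u=0.064, aav=7.4e-5, ad2=7.5e-5, hsv1=5.5e-7),
    "aav2_ad2_27hpi": dict(g=0.882, h=0.597, m=0.176, u=0.114, aav=0.0144, ad2=0.1406, hsv1=6e-7),
    "ad2_27hpi": dict(g=0.974, h=0.502, m=0.212, u=0.251, aav=1e-6, ad2=0.2203, hsv1=6e-7),
    "cells_8hpi": dict(g=0.960, h=0.833, m=0.329, u=0.126, aav=7e-7, ad2=1.4e-5, hsv1=6e-7),
    "aav2_8hpi": dict(g=0.983, h=0.822, m=0.377, u=0.160, aav=8e-6, ad2=2.2e-5, hsv1=5e-7),
    "aav2_hsv1_8hpi": dict(g=0.908, h=0.787, m=0.345, u=0.099, aav=0.0070, ad2=1.9e-4, hsv1=0.0052),
    "hsv1_8hpi": dict(g=0.933, h=0.798, m=0.466, u=0.125, aav=6.7e-7, ad2=1.6e-5, hsv1=0.0059),
}

#: Promoter landmarks of the AAV-like genome (display decoration for tracks).
AAV_PROMOTERS = (
    PromoterMark("p5", 287, "+"),
    PromoterMark("p19", 882, "+"),
    PromoterMark("p40", 1853, "+"),
    PromoterMark("anti-p5", 294, "-"),
)


@dataclass
class StudyReferences:
    host_refs: list[ReferenceSequence]
    mature_catalog: list[MatureMiRNA]
    viral_genomes: dict[str, ReferenceSequence]
    hotspot_specs: dict[str, list[HotspotSpec]]
    aav_repeats: list[RepeatAnnotation]


def make_study_references(seed: int = 0) -> StudyReferences:
    """References for the eight-sample design: host + AAV-like + two helpers."""
    rng = np.random.default_rng(seed)
    host_refs, catalog = make_host_reference(seed=int(rng.integers(2**31)))
    aav, repeats = make_itr_genome(
        core_len=4389, itr_len=145, arm_len=62, seed=int(rng.integers(2**31))
    )
    ad2 = ReferenceSequence("synthetic_ad2", _random_seq(rng, 6000), "ad2", "genome")
    hsv1 = ReferenceSequence("synthetic_hsv1", _random_seq(rng, 8000), "hsv1", "genome")
    mode21 = {20: 0.2, 21: 0.55, 22: 0.25}
    specs = {
        "aav": [
            HotspotSpec(aav.id, "+", 1, {20: 0.25, 21: 0.5, 22: 0.25}, 3170),
            HotspotSpec(aav.id, "+", 108, dict(mode21), 12002),
            HotspotSpec(aav.id, "-", 271, {l: 0.125 for l in range(16, 24)}, 12737),
            HotspotSpec(aav.id, "+", 1862, {18: 0.5, 19: 0.5}, 3780),
        ],
        "ad2": [
            HotspotSpec(ad2.id, "+", 3000, dict(mode21), 60),
            HotspotSpec(ad2.id, "+", 4500, dict(mode21), 40),
        ],
        "hsv1": [
            HotspotSpec(hsv1.id, "+", 2000, dict(mode21), 50),
            HotspotSpec(hsv1.id, "-", 6000, dict(mode21), 50),
        ],
    }
    return StudyReferences(
        host_refs, catalog, {"aav": aav, "ad2": ad2, "hsv1": hsv1}, specs, repeats
    )


def study_design(
    total_reads: int = 20000, seed: int = 0
) -> tuple[list[SampleDesign], StudyReferences]:
    """The eight-sample design (mock / AAV / AAV+helper / helper, 8 & 27 hpi).

    Fractions follow the composition magnitudes of the emulated study.  The
    share of each sample's >=16-nt reads not accounted for by its human,
    viral and unknown columns is folded into the host_other component, so
    the simulated assignment summary lands near the stated column values;
    junk covers the <16-nt reads plus the unmappable "unknown" reads, split
    by ``junk_short_fraction``.
    """
    refs = make_study_references(seed)
    designs = []
    for i, (name, c) in enumerate(_STUDY_COMPOSITION.items()):
        g = c["g"]
        viral = c["aav"] + c["ad2"] + c["hsv1"]
        residual = max(0.0, 1.0 - c["h"] - c["u"] - viral)
        fractions = {
            "host_mirna": g * c["m"],
            "host_other": g * (c["h"] - c["m"] + residual),
            "virus:aav": g * c["aav"],
            "virus:ad2": g * c["ad2"],
            "virus:hsv1": g * c["hsv1"],
        }
        f_junk = 1.0 - sum(fractions.values())  # = (1 - g) + g * u
        fractions["junk"] = f_junk
        designs.append(
            SampleDesign(
                name=name,
                total_reads=total_reads,
                fractions=fractions,
                seed=(seed * 1000003 + i) % 2**31,
                junk_short_fraction=(1.0 - g) / f_junk if f_junk > 0 else 0.0,
            )
        )
    return designs, refs


def _adapter_like_free(seq: str, adapter: str, seed_len: int = 8, max_mm: int = 1) -> bool:
    """True if no window of ``seq`` (either strand) is within ``max_mm``
    mismatches of the adapter-prefix trimming seed."""
    prefix = adapter[:seed_len]
    for s in (seq, _rc(seq)):
        for i in range(len(s) - seed_len + 1):
            mm = 0
            for a, b in zip(s[i : i + seed_len], prefix):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm:
                return False
    return True


@dataclass
class HotspotBenchmark:
    """A single-sample planted-hotspot scenario with ground truth."""

    host_refs: list[ReferenceSequence]
    mature_catalog: list[MatureMiRNA]
    genome: ReferenceSequence
    repeats: list[RepeatAnnotation]
    specs: list[HotspotSpec]
    design: SampleDesign
    species: str = "aav"


def hotspot_benchmark(
    seed: int,
    total_reads: int = 200_000,
    core_len: int = 2000,
    itr_len: int = 145,
    arm_len: int = 62,
    error_rate: float = 0.0,
    background_per_position: float = 30.0,
    include_itr_hotspot: bool = False,
    adapter: str = DEFAULT_ADAPTER,
) -> HotspotBenchmark:
    """One viral-rich sample with three planted hotspots over diffuse background.

    Abundances (~12,000 / ~12,700 / ~3,800 reads) sit roughly 100-fold above
    the per-position background depth (default 30).  The genome seed is
    re-rolled deterministically until (a) no genomic window resembles the
    adapter trimming seed, so zero-error reads always trim back to their true
    insert, and (b) the planted hotspot sequences have no host placement, so
    the host-first cascade cannot capture them.  With ``include_itr_hotspot``
    a fourth hotspot is planted at position 1 inside the palindromic ITR arm,
    whose reads are intrinsically multi-placed.
    """
    from .assign import enumerate_placements  # deferred: avoids import cycle

    host_refs, catalog = make_host_reference(
        n_decoys=3, decoy_len=4000, n_premirnas=15, seed=seed % 2**31
    )
    genome = None
    repeats: list[RepeatAnnotation] = []
    specs: list[HotspotSpec] = []
    for attempt in range(200):
        g_seed = (seed + 7919 * (attempt + 1)) % 2**31
        cand, cand_repeats = make_itr_genome(core_len, itr_len, arm_len, g_seed)
        if not _adapter_like_free(cand.sequence, adapter):
            continue
        cand_specs = [
            HotspotSpec(cand.id, "+", 700, {20: 0.2, 21: 0.55, 22: 0.25}, 12002),
            HotspotSpec(cand.id, "-", 271, {l: 0.125 for l in range(16, 24)}, 12737),
            HotspotSpec(cand.id, "+", 1862, {18: 0.5, 19: 0.5}, 3780),
        ]
        if include_itr_hotspot:
            cand_specs.append(
                HotspotSpec(cand.id, "+", 1, {20: 0.3, 21: 0.4, 22: 0.3}, 4000)
            )
        inserts = [
            s.insert(cand, l) for s in cand_specs for l in s.length_weights
        ]
        if any(enumerate_placements(ins, host_refs, 2) for ins in inserts):
            continue
        core_specs = cand_specs[:3]
        unique = all(
            len(enumerate_placements(s.insert(cand, max(s.length_weights)), [cand], 0)) == 1
            for s in core_specs
        )
        if not unique:
            continue
        genome, repeats, specs = cand, cand_repeats, cand_specs
        break
    if genome is None:
        raise RuntimeError("could not construct a clean benchmark genome")

    planted_mass = sum(s.abundance for s in specs)
    bg_mass = background_per_position * 2 * genome.length
    viral_total = planted_mass + bg_mass
    f_viral = viral_total / total_reads
    if f_viral > 0.97:
        raise ValueError("total_reads too small for the requested hotspot masses")
    rest = 1.0 - f_viral
    fractions = {
        "virus:aav": f_viral,
        "host_mirna": 0.35 * rest,
        "host_other": 0.45 * rest,
        "junk": 0.20 * rest,
    }
    design = SampleDesign(
        name="hotspot_benchmark",
        total_reads=total_reads,
        fractions=fractions,
        error_rate=error_rate,
        adapter=adapter,
        seed=seed % 2**31,
        viral_background=bg_mass / viral_total,
    )
    return HotspotBenchmark(host_refs, catalog, genome, repeats, specs, design)


def simulate_mirna_counts(
    n_mirnas: int = 979,
    seed: int = 0,
    depletion: float = 8.0,
    depleted_mean: float = 700.0,
) -> tuple["MiRNACountTable", str]:
    """Paired miRNA count table with one planted depleted miRNA.

    Both samples draw Poisson counts around a shared log-normal expression
    level per miRNA (no biological regulation), except one planted miRNA
    whose infected-sample mean is divided by ``depletion`` — emulating a
    single strongly down-regulated species against an otherwise flat profile.
    Library sizes are proportional to the column sums, as if miRNAs were a
    fixed share of each library.
    """
    from .diffexpr import MiRNACountTable  # deferred: avoids import cycle

    if depletion <= 5.0:
        raise ValueError("planted depletion must exceed the 5-fold band")
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean=math.log(80.0), sigma=1.6, size=n_mirnas)
    names = [f"mir-{i + 1:04d}" for i in range(n_mirnas)]
    depleted_idx = int(rng.integers(0, n_mirnas))
    mu[depleted_idx] = depleted_mean
    a = rng.poisson(mu)
    mu_b = mu.copy()
    mu_b[depleted_idx] = depleted_mean / depletion
    b = rng.poisson(mu_b)
    counts = pd.DataFrame({"uninfected": a, "aav2": b}, index=pd.Index(names, name="mirna"))
    libs = pd.Series(
        {"uninfected": int(a.sum()) * 3, "aav2": int(b.sum()) * 3}, name="library_size"
    )
    return MiRNACountTable(counts, libs), names[depleted_idx]
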