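"""Strand-specific 5'-end pileups, binned tracks and hotspot calling.

A viral small RNA species is identified by the genomic position of its 5'
terminal nucleotide: all reads are piled up by 5' end at single-nucleotide
resolution, and every position whose count strictly exceeds the calling
threshold becomes a hotspot named ``sR-<5' start>``.  The default absolute
threshold is 3,000 reads, roughly 100-fold above a typical diffuse
background; a relative mode derives the threshold as a fold factor over the
median of the non-zero position counts.

Reads that fall inside inverted terminal repeats admit several equivalent
placements.  Display pileups default to ``all_placements`` weighting, where a
read contributes its count at every placement of its equivalence group (the
convention of assigning ambiguous repeat reads to either end); species totals
use ``canonical_only`` weighting, where each read is counted exactly once at
its canonical placement.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assign import AssignmentRecord, Placement, equivalence_classes


@dataclass
class LengthStats:
    """Read-length histogram with mean (1 decimal), median and mode."""

    histogram: dict[int, int]
    mean: float
    median: float
    mode: int


@dataclass(frozen=True)
class PileupTrack:
    """Per-reference, per-strand counts of read 5' ends."""

    ref_id: str
    strand: str
    counts: dict[int, int]
    weighting: str = "all_placements"

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class BinnedTrack:
    """Fixed-width binned form of a pileup track; sum-preserving."""

    ref_id: str
    strand: str
    width: int
    bins: dict[int, int]

    def total(self) -> int:
        return sum(self.bins.values())


@dataclass(frozen=True)
class HotspotConfig:
    """Hotspot-calling configuration.

    ``absolute`` mode compares position counts against ``absolute_threshold``
    (strictly greater).  ``relative`` mode sets the effective threshold to
    ``relative_factor`` times the background estimate, defined as the median
    of the non-zero position counts of the track.
    """

    mode: str = "absolute"
    absolute_threshold: float = 3000
    relative_factor: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.absolute_threshold <= 0 or self.relative_factor <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class Hotspot:
    """A called 5'-end peak, named sR-<start> after its 5' position."""

    name: str
    ref_id: str
    strand: str
    five_prime: int
    count: int
    length_stats: LengthStats | None = None
    equivalence_partners: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.name != f"sR-{self.five_prime}":
            raise ValueError("hotspot name must match its 5' position")


def pileup_five_prime(
    records: Iterable[AssignmentRecord],
    ref_id: str,
    strand: str,
    weighting: str = "all_placements",
) -> PileupTrack:
    """Pile up read 5' ends on one strand of one reference.

    ``all_placements``: each placement of a record's equivalence group adds
    the record's count at its 5' end.  ``canonical_only``: each record adds
    its count once, at the 5' end of its canonical placement.
    """
    if weighting not in ("all_placements", "canonical_only"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts: dict[int, int] = defaultdict(int)
    for rec in records:
        if not rec.placements:
            continue
        if weighting == "all_placements":
            for p in rec.placements:
                if p.ref_id == ref_id and p.strand == strand:
                    counts[p.five_prime] += rec.count
        else:
            canon = equivalence_classes(rec).canonical
            if canon.ref_id == ref_id and canon.strand == strand:
                counts[canon.five_prime] += rec.count
    return PileupTrack(ref_id, strand, dict(counts), weighting)


def bin_track(track: PileupTrack, width: int) -> BinnedTrack:
    """Sum a pileup into closed intervals [1..w], [w+1..2w], ...

    Bin keys are the 1-based interval starts; width 1 is the identity.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    bins: dict[int, int] = defaultdict(int)
    for pos, n in track.counts.items():
        bins[((pos - 1) // width) * width + 1] += n
    return BinnedTrack(track.ref_id, track.strand, width, dict(bins))


def effective_threshold(track: PileupTrack, config: HotspotConfig) -> float:
    if config.mode == "absolute":
        return config.absolute_threshold
    nonzero = [n for n in track.counts.values() if n > 0]
    if not nonzero:
        return float("inf")
    background = float(pd.Series(nonzero).median())
    return config.relative_factor * background


def call_hotspots(track: PileupTrack, config: HotspotConfig) -> list[Hotspot]:
    """Call every position whose count strictly exceeds the threshold.

    A position with a count exactly equal to the threshold is NOT a hotspot.
    Results are sorted by count descending (ties by position ascending).
    """
    threshold = effective_threshold(track, config)
    called = [
        Hotspot(f"sR-{pos}", track.ref_id, track.strand, pos, n)
        for pos, n in track.counts.items()
        if n > threshold
    ]
    called.sort(key=lambda h: (-h.count, h.five_prime))
    return called


def supporting_records(
    records: Iterable[AssignmentRecord], hotspot: Hotspot
) -> list[AssignmentRecord]:
    """Records with a placement whose 5' end sits at the hotspot position."""
    return [
        r
        for r in records
        if any(
            p.ref_id == hotspot.ref_id
            and p.strand == hotspot.strand
            and p.five_prime == hotspot.five_prime
            for p in r.placements
        )
    ]


def hotspot_length_stats(records: Sequence[AssignmentRecord]) -> LengthStats:
    """Length histogram and summary statistics of hotspot-supporting reads.

    The mean is rounded to one decimal; the mode is the most frequent length
    (smallest on ties).
    """
    if not records:
        raise ValueError("no supporting reads")
    histogram: dict[int, int] = defaultdict(int)
    for r in records:
        histogram[len(r.sequence)] += r.count
    lengths = sorted(histogram)
    total = sum(histogram.values())
    mean = round(sum(l * n for l, n in histogram.items()) / total, 1)
    expanded = pd.Series(
        [l for l in lengths for _ in range(histogram[l])], dtype=float
    )
    median = float(expanded.median())
    mode = min(lengths, key=lambda l: (-histogram[l], l))
    return LengthStats(dict(sorted(histogram.items())), mean, median, mode)


def annotate_length_stats(
    hotspots: Sequence[Hotspot], records: Sequence[AssignmentRecord]
) -> None:
    for h in hotspots:
        sup = supporting_records(records, h)
        if sup:
            h.length_stats = hotspot_length_stats(sup)


@dataclass(frozen=True)
class HotspotGroup:
    """Hotspots linked through shared read equivalence groups.

    ``unique_read_count`` counts the shared reads once, the value to use in
    species totals (linked hotspots pile the same reads at both positions).
    """

    hotspots: tuple[Hotspot, ...]
    unique_read_count: int

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(h.name for h in self.hotspots)


def link_equivalent_hotspots(
    hotspots: Sequence[Hotspot], records: Sequence[AssignmentRecord]
) -> list[HotspotGroup]:
    """Link hotspots whose supporting read sets share equivalence groups.

    Union-find over hotspots keyed by supporting read sequences; every linked
    hotspot gets its partners recorded in ``equivalence_partners``.
    """
    support: list[set[str]] = []
    seq_count: dict[str, int] = {}
    for h in hotspots:
        sup = supporting_records(records, h)
        support.append({r.equivalence_group for r in sup})
        for r in sup:
            seq_count[r.equivalence_group] = r.count
    parent = list(range(len(hotspots)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(hotspots)):
        for j in range(i + 1, len(hotspots)):
            if support[i] & support[j]:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(hotspots)):
        groups[find(i)].append(i)
    out: list[HotspotGroup] = []
    for members in groups.values():
        hs = tuple(hotspots[i] for i in sorted(members))
        for h in hs:
            h.equivalence_partners = tuple(x.name for x in hs if x is not h)
        shared = set().union(*(support[i] for i in members))
        out.append(HotspotGroup(hs, sum(seq_count[s] for s in shared)))
    out.sort(key=lambda g: -max(h.count for h in g.hotspots))
    return out


def top_n_table(
    records: Sequence[AssignmentRecord], ref_id: str, n: int = 100
) -> pd.DataFrame:
    """Ranked table of the top-n 5' positions on both strands of a reference.

    Columns: name, ref_id, strand, five_prime, count, median_length and a
    representative sequence (the most abundant supporting read, ties broken
    lexicographically).  Ranking is by count descending, ties by position
    ascending with '+' before '-'.
    """
    rows = []
    for strand in ("+", "-"):
        track = pileup_five_prime(records, ref_id, strand, "all_placements")
        for pos, count in track.counts.items():
            sup = supporting_records(
                records, Hotspot(f"sR-{pos}", ref_id, strand, pos, count)
            )
            stats = hotspot_length_stats(sup)
            rep = min(sup, key=lambda r: (-r.count, r.sequence)).sequence
            rows.append(
                {
                    "name": f"sR-{pos}",
                    "ref_id": ref_id,
                    "strand": strand,
                    "five_prime": pos,
                    "count": count,
                    "median_length": stats.median,
                    "sequence": rep,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "name",
            "ref_id",
            "strand",
            "five_prime",
            "count",
            "median_length",
            "sequence",
        ],
    )
    if df.empty:
        return df
    df["_minus"] = (df["strand"] == "-").astype(int)
    df = df.sort_values(
        ["count", "five_prime", "_minus"], ascending=[False, True, True]
    ).drop(columns="_minus")
    return df.head(n).reset_index(drop=True)


def write_hotspots_bed(hotspots: Sequence[Hotspot], path: str | Path) -> None:
    """BED6 export of called hotspots (0-based half-open at the boundary only)."""
    with open(path, "w") as fh:
        for h in hotspots:
            fh.write(
                f"{h.ref_id}\t{h.five_prime - 1}\t{h.five_prime}\t{h.name}"
                f"\t{h.count}\t{h.strand}\n"
            )


def write_bedgraph(track: PileupTrack | BinnedTrack, path: str | Path) -> None:
    """bedGraph export of a single-nucleotide or binned track."""
    with open(path, "w") as fh:
        if isinstance(track, BinnedTrack):
            for start in sorted(track.bins):
                fh.write(
                    f"{track.ref_id}\t{start - 1}\t{start - 1 + track.width}"
                    f"\t{track.bins[start]}\n"
                )
        else:
            for pos in sorted(track.counts):
                fh.write(f"{track.ref_id}\t{pos - 1}\t{pos}\t{track.counts[pos]}\n")
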