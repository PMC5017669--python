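"""Ungapped placement enumeration and hierarchical host-first read assignment.

Reads are assigned by a cascade that mirrors the mapping strategy of small
RNA-Seq studies of virus-infected cells: at each mismatch tier, reads with any
host placement (genome, transcriptome or pre-miRNA set) are assigned to the
host; only the reads left unmapped are then tested against each viral genome
independently.  A read matching the host and a virus is therefore never
counted as viral.  The primary analyses use a single zero-mismatch tier;
graded one- and two-mismatch tiers recover reads lost to sequencing error.

Placement enumeration is exhaustive: ALL full-length, ungapped placements on
both strands of every reference with Hamming distance at most ``max_mm`` are
returned.  N never matches any base, on either side.  The implementation uses
a seed-and-verify k-mer index and is required (and tested) to agree
bit-exactly with a naive per-position Hamming scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome import ReferenceSequence, _rc
from .preprocess import CollapsedRead

MIN_READ_LEN = 16
MAX_SEED_LEN = 12


@dataclass(frozen=True)
class Placement:
    """One full-length ungapped alignment of a read.

    ``start``/``end`` are 1-based inclusive plus-strand coordinates with
    ``start <= end``.  The 5' end of the placed read is ``start`` on the plus
    strand and ``end`` on the minus strand.
    """

    ref_id: str
    strand: str
    start: int
    end: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TierSchedule:
    """Ordered mismatch allowances; primary analyses use (0,) only."""

    tiers: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ValueError("schedule must contain at least one tier")
        if any(t not in (0, 1, 2) for t in self.tiers):
            raise ValueError("tiers must be drawn from {0, 1, 2}")
        if list(self.tiers) != sorted(set(self.tiers)):
            raise ValueError("tiers must be strictly increasing")


@dataclass(frozen=True)
class AssignmentRecord:
    """A collapsed read with its category, tier and placements.

    ``category`` is ``"human"``, ``"human_mirna"``, ``"virus:<species>"`` or
    ``"unknown"``.  ``tier`` is the minimal scheduled tier that yielded any
    placement for the assigned species set (None for unknown reads).
    ``placements`` holds all placements at that tier on the assigned species'
    references; they jointly form the read's equivalence group.  A read
    matching two or more viral species at the same tier lists all of them in
    ``viral_species`` and is flagged cross-species ambiguous.
    """

    sequence: str
    count: int
    category: str
    tier: int | None
    placements: tuple[Placement, ...]
    viral_species: tuple[str, ...] = ()
    cross_species_ambiguous: bool = False

    def __post_init__(self) -> None:
        if (self.category == "unknown") != (len(self.placements) == 0):
            raise ValueError("category 'unknown' iff placements are empty")

    @property
    def equivalence_group(self) -> str:
        """Group identifier shared by all placements of this read sequence."""
        return self.sequence

    @property
    def is_human(self) -> bool:
        return self.category in ("human", "human_mirna")


class ReferenceIndex:
    """Lazy per-reference k-mer tables for seed-and-verify placement search."""

    def __init__(self, references: Sequence[ReferenceSequence]):
        self.references = tuple(references)
        self._tables: dict[tuple[int, int], dict[str, list[int]]] = {}

    def table(self, ref_pos: int, k: int) -> dict[str, list[int]]:
        key = (ref_pos, k)
        tab = self._tables.get(key)
        if tab is None:
            seq = self.references[ref_pos].sequence
            tab = {}
            for p in range(len(seq) - k + 1):
                kmer = seq[p : p + k]
                if "N" in kmer:
                    continue  # N never matches; an N-kmer can never seed
                tab.setdefault(kmer, []).append(p)
            self._tables[key] = tab
        return tab


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count with N-never-matches; early exit past ``limit``."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def enumerate_placements(
    sequence: str,
    references: Sequence[ReferenceSequence],
    max_mm: int,
    index: ReferenceIndex | None = None,
) -> list[Placement]:
    """All full-length ungapped placements of ``sequence`` at <= ``max_mm``.

    Results are deterministically ordered by (reference order, start, strand)
    with '+' before '-'.  Seed length is ``min(12, L // (max_mm + 1))`` with
    ``max_mm + 1`` non-overlapping seeds, so by pigeonhole every placement
    within the mismatch budget is guaranteed to be seeded.
    """
    L = len(sequence)
    if L < MIN_READ_LEN:
        raise ValueError(f"sequence shorter than {MIN_READ_LEN} nt")
    if max_mm not in (0, 1, 2):
        raise ValueError("max_mm must be in {0, 1, 2}")
    if index is None:
        index = ReferenceIndex(references)
    k = min(MAX_SEED_LEN, L // (max_mm + 1))
    offsets = [t * k for t in range(max_mm + 1)]
    results: list[Placement] = []
    rc_seq = _rc(sequence)
    for ref_pos, ref in enumerate(index.references):
        if ref.length < L:
            continue
        tab = index.table(ref_pos, k)
        hits: list[tuple[int, str, int]] = []  # (start0, strand, mm)
        for strand, query in (("+", sequence), ("-", rc_seq)):
            seen: set[int] = set()
            for off in offsets:
                for p in tab.get(query[off : off + k], ()):
                    s = p - off
                    if s < 0 or s + L > ref.length or s in seen:
                        continue
                    seen.add(s)
                    mm = _hamming(query, ref.sequence[s : s + L], max_mm)
                    if mm <= max_mm:
                        hits.append((s, strand, mm))
        hits.sort(key=lambda h: (h[0], h[1] == "-"))
        results.extend(
            Placement(ref.id, strand, s + 1, s + L, mm) for s, strand, mm in hits
        )
    return results


def hierarchical_assign(
    collapsed_reads: Iterable[CollapsedRead],
    host_refs: Sequence[ReferenceSequence],
    viral_ref_sets: Mapping[str, Sequence[ReferenceSequence]],
    schedule: TierSchedule = TierSchedule(),
) -> list[AssignmentRecord]:
    """Assign collapsed reads host-first, virus-second, tier by tier.

    For each tier in order: reads with any host placement are assigned to the
    host (``human_mirna`` if any placement lies on a pre-miRNA reference);
    only still-unassigned reads are tested against each viral species.  Reads
    surviving all tiers are ``unknown``.
    """
    host_index = ReferenceIndex(host_refs)
    viral_indexes = {
        sp: ReferenceIndex(refs) for sp, refs in sorted(viral_ref_sets.items())
    }
    pre_mirna_ids = {r.id for r in host_refs if r.role == "pre_mirna"}
    records: list[AssignmentRecord] = []
    for cr in collapsed_reads:
        rec: AssignmentRecord | None = None
        for tier in schedule.tiers:
            host_pl = enumerate_placements(cr.sequence, host_refs, tier, host_index)
            if host_pl:
                category = (
                    "human_mirna"
                    if any(p.ref_id in pre_mirna_ids for p in host_pl)
                    else "human"
                )
                rec = AssignmentRecord(
                    cr.sequence, cr.count, category, tier, tuple(host_pl)
                )
                break
            viral_hits: dict[str, list[Placement]] = {}
            for sp, vindex in viral_indexes.items():
                pl = enumerate_placements(
                    cr.sequence, vindex.references, tier, vindex
                )
                if pl:
                    viral_hits[sp] = pl
            if viral_hits:
                species = tuple(sorted(viral_hits))
                placements = tuple(p for sp in species for p in viral_hits[sp])
                rec = AssignmentRecord(
                    cr.sequence,
                    cr.count,
                    f"virus:{species[0]}",
                    tier,
                    placements,
                    viral_species=species,
                    cross_species_ambiguous=len(species) > 1,
                )
                break
        if rec is None:
            rec = AssignmentRecord(cr.sequence, cr.count, "unknown", None, ())
        records.append(rec)
    return records


@dataclass(frozen=True)
class EquivalenceGroup:
    """All placements of one read sequence, with a canonical representative.

    The canonical placement is the lowest by (reference order, 5' position,
    '+' preferred over '-').  This mirrors how reads falling in inverted
    terminal repeats admit several equivalent placements ("assigned to either
    end"); the canonical member is used wherever each read must be counted
    exactly once.
    """

    group_id: str
    canonical: Placement
    members: tuple[Placement, ...]

    @property
    def size(self) -> int:
        return len(self.members)


def equivalence_classes(
    record: AssignmentRecord, ref_order: Sequence[str] | None = None
) -> EquivalenceGroup:
    """Group the record's placements and pick the canonical representative."""
    if not record.placements:
        raise ValueError("record has no placements")
    if ref_order is None:
        order: list[str] = []
        for p in record.placements:
            if p.ref_id not in order:
                order.append(p.ref_id)
        ref_order = order
    rank = {rid: i for i, rid in enumerate(ref_order)}
    canonical = min(
        record.placements,
        key=lambda p: (rank.get(p.ref_id, len(rank)), p.five_prime, p.strand == "-"),
    )
    return EquivalenceGroup(record.equivalence_group, canonical, record.placements)


def assignment_summary(
    sample: str,
    records: Iterable[AssignmentRecord],
    n_total: int,
    n_ge16: int,
    viral_species: Sequence[str] | None = None,
):
    """Aggregate assignment records into one summary-table row.

    Human counts include genome, transcriptome and miRNA placements; the
    miRNA column is the subset with any pre-miRNA placement.  Per-virus
    columns count each species independently, so a cross-species-ambiguous
    read appears in every matching column (the double count is reported
    separately and excluded from the partition check).
    """
    from .report import SummaryRow  # local import to avoid a cycle

    records = list(records)
    n_human = sum(r.count for r in records if r.is_human)
    n_mirna = sum(r.count for r in records if r.category == "human_mirna")
    n_unknown = sum(r.count for r in records if r.category == "unknown")
    species = list(viral_species) if viral_species is not None else sorted(
        {sp for r in records for sp in r.viral_species}
    )
    viral = {
        sp: sum(r.count for r in records if sp in r.viral_species) for sp in species
    }
    n_viral_once = sum(r.count for r in records if r.viral_species)
    n_cross = sum(r.count for r in records if r.cross_species_ambiguous)
    if n_human + n_viral_once + n_unknown != n_ge16:
        raise ValueError(
            "categories do not partition the >=16-nt reads: "
            f"{n_human} human + {n_viral_once} viral + {n_unknown} unknown != {n_ge16}"
        )
    return SummaryRow(
        sample=sample,
        n_total=n_total,
        n_ge16=n_ge16,
        n_human=n_human,
        n_human_mirna=n_mirna,
        viral=viral,
        n_unknown=n_unknown,
        n_cross_species=n_cross,
    )
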