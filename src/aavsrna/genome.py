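"""Reference-sequence containers, coordinate conventions and terminal-repeat annotation.

Coordinates throughout the package are 1-based, inclusive, and expressed on the
plus strand.  A minus-strand feature's 5' end is its largest plus-strand
coordinate: a small RNA spanning 252..271 on the minus strand has its 5'
terminal nucleotide at position 271.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: IUPAC nucleotide one-letter codes accepted on input.  Anything outside the
#: unambiguous alphabet (plus U) is collapsed to N; N never matches any base
#: during alignment.
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}; N maps to N."""
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ValueError(f"invalid nucleotide character(s): {bad!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def _rc(seq: str) -> str:
    # unchecked fast path for internal callers that already validated
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """A named nucleotide sequence with a species tag and a role.

    Parameters
    ----------
    id : str
        Record label (FASTA id).
    sequence : str
        Uppercase nucleotide string over {A,C,G,T,N}.
    species : str
        ``"host"`` or a named virus (e.g. ``"aav2"``).
    role : str
        One of ``"genome"``, ``"transcriptome"``, ``"pre_mirna"``.
    """

    id: str
    sequence: str
    species: str
    role: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.id!r}: empty sequence")
        if not set(self.sequence) <= VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise ValueError(f"reference {self.id!r}: invalid characters {bad!r}")
        if self.role not in ("genome", "transcriptome", "pre_mirna"):
            raise ValueError(f"reference {self.id!r}: unknown role {self.role!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sub-sequence at 1-based inclusive plus-strand coordinates.

        For ``strand == "-"`` the reverse complement of the window is returned,
        i.e. the sequence read 5'->3' on the minus strand.
        """
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"window {start}..{end} outside [1, {self.length}] on {self.id!r}"
            )
        window = self.sequence[start - 1 : end]
        return _rc(window) if strand == "-" else window


@dataclass(frozen=True)
class RepeatAnnotation:
    """A pair of equal-width terminal intervals with an exact sequence relation.

    ``relation`` is ``"identical"`` (prefix equals suffix) or
    ``"reverse_complement"`` (prefix equals the reverse complement of the
    suffix, the inverted-terminal-repeat case).
    """

    ref_id: str
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    relation: str

    def __post_init__(self) -> None:
        (a1, a2), (b1, b2) = self.interval_a, self.interval_b
        if a2 - a1 != b2 - b1:
            raise ValueError("repeat intervals must have equal widths")
        if self.relation not in ("identical", "reverse_complement"):
            raise ValueError(f"unknown relation {self.relation!r}")

    @property
    def width(self) -> int:
        return self.interval_a[1] - self.interval_a[0] + 1

    def verify(self, ref: ReferenceSequence) -> bool:
        """Check the stated relation by direct substring comparison."""
        (a1, a2), (b1, b2) = self.interval_a, self.interval_b
        if not (1 <= a1 <= a2 <= ref.length and 1 <= b1 <= b2 <= ref.length):
            return False
        a = ref.sequence[a1 - 1 : a2]
        b = ref.sequence[b1 - 1 : b2]
        return a == b if self.relation == "identical" else a == _rc(b)


@dataclass(frozen=True)
class PromoterMark:
    """A named transcription start site on a reference (e.g. p5, p19, p40, anti-p5)."""

    name: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError("tss must be a positive 1-based position")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def validate(self, ref: ReferenceSequence) -> None:
        if self.tss > ref.length:
            raise ValueError(
                f"promoter {self.name!r} tss {self.tss} beyond {ref.id!r} length {ref.length}"
            )


def load_references(
    fasta_path: str | Path, species: str, role: str
) -> list[ReferenceSequence]:
    """Load a multi-record FASTA as :class:`ReferenceSequence` objects.

    Sequences are uppercased, U is converted to T, and ambiguous IUPAC codes
    are collapsed to N (with a logged warning).  Non-IUPAC characters raise.
    """
    records: list[ReferenceSequence] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        extra = set(seq) - VALID_BASES
        if extra:
            if not extra <= IUPAC_CODES:
                bad = sorted(extra - IUPAC_CODES)
                raise ValueError(f"record {rec.id!r}: non-IUPAC characters {bad!r}")
            logger.warning(
                "record %r: collapsing ambiguous IUPAC codes %s to N",
                rec.id,
                sorted(extra),
            )
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        records.append(ReferenceSequence(rec.id, seq, species, role))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return records


def annotate_terminal_repeats(
    genome: ReferenceSequence, min_len: int = 10
) -> list[RepeatAnnotation]:
    """Find the maximal terminal repeat pair(s) of a genome.

    Compares the genome prefix against the genome suffix at every width from
    ``len(genome) // 2`` down to ``min_len`` and reports, for each relation
    (identical / reverse_complement), the widest width at which the relation
    holds exactly.  Returns an empty list if no terminal relation of at least
    ``min_len`` exists.
    """
    if min_len < 10:
        raise ValueError("min_len must be >= 10")
    seq = genome.sequence
    n = len(seq)
    found: list[RepeatAnnotation] = []
    for relation in ("identical", "reverse_complement"):
        for k in range(n // 2, min_len - 1, -1):
            prefix = seq[:k]
            suffix = seq[n - k :]
            target = suffix if relation == "identical" else _rc(suffix)
            if prefix == target:
                found.append(
                    RepeatAnnotation(genome.id, (1, k), (n - k + 1, n), relation)
                )
                break
    return found


def write_fasta(references: Iterable[ReferenceSequence], path: str | Path) -> None:
    """Write references to a FASTA file (plain text, 70-column wrap)."""
    with open(path, "w") as fh:
        for ref in references:
            fh.write(f">{ref.id}\n")
            for i in range(0, ref.length, 70):
                fh.write(ref.sequence[i : i + 70] + "\n")
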