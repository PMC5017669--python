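"""Adapter trimming, minimum-length filtering and exact-sequence read collapsing.

The 3' sequencing adapter is removed by locating the leftmost read position at
which a prefix of the adapter (at least ``min_overlap`` long, at most
``max_mm`` mismatches) matches to the end of the read.  Reads shorter than the
minimum insert length (default 16 nt) after trimming are discarded, matching
the convention that small-RNA reads below 16 nt are not informative for
mapping.  Surviving reads are collapsed to unique sequences with
multiplicities; every downstream count is re-expanded by multiplicity so that
reported numbers are read counts, not unique-sequence counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its multiplicity in the sample."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a Phred33 FASTQ file (qualities are ignored)."""
    with open(path) as fh:
        return [seq.upper() for _, seq, _ in FastqGeneralIterator(fh)]


def trim_3prime_adapter(
    read: str, adapter: str, min_overlap: int = 8, max_mm: int = 1
) -> str:
    """Trim the 3' adapter from a single read.

    Scans read offsets left to right; at offset ``i`` the window ``read[i:]``
    is compared against the adapter prefix of the same length (capped at the
    adapter length).  The leftmost offset whose window is at least
    ``min_overlap`` long and mismatches the adapter prefix at most ``max_mm``
    times wins, and ``read[:i]`` is returned.  A read without any qualifying
    match is returned unchanged.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    n = len(read)
    alen = len(adapter)
    for i in range(0, n - min_overlap + 1):
        k = min(alen, n - i)
        mm = 0
        ok = True
        for j in range(k):
            if read[i + j] != adapter[j]:
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            return read[:i]
    return read


def trim_reads(
    reads: Sequence[str], adapter: str, min_overlap: int = 8, max_mm: int = 1
) -> list[str]:
    """Vectorised batch equivalent of :func:`trim_3prime_adapter`.

    Groups reads by length and resolves each group with a single numpy pass
    per offset; output is element-wise identical to the scalar function.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    out: list[str | None] = [None] * len(reads)
    by_len: dict[int, list[int]] = {}
    for idx, r in enumerate(reads):
        by_len.setdefault(len(r), []).append(idx)
    ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
    for n, idxs in by_len.items():
        if n < min_overlap:
            for idx in idxs:
                out[idx] = reads[idx]
            continue
        if len(idxs) < 32:  # numpy overhead not worth it for small groups
            for idx in idxs:
                out[idx] = trim_3prime_adapter(reads[idx], adapter, min_overlap, max_mm)
            continue
        block = np.frombuffer(
            "".join(reads[idx] for idx in idxs).encode(), dtype=np.uint8
        ).reshape(len(idxs), n)
        cut = np.full(len(idxs), -1, dtype=np.int64)
        for i in range(0, n - min_overlap + 1):
            k = min(len(ad), n - i)
            mm = (block[:, i : i + k] != ad[:k]).sum(axis=1)
            hit = (mm <= max_mm) & (cut < 0)
            if hit.any():
                cut[hit] = i
            if (cut >= 0).all():
                break
        for row, idx in enumerate(idxs):
            c = cut[row]
            out[idx] = reads[idx] if c < 0 else reads[idx][:c]
    return out  # type: ignore[return-value]


def filter_min_length(
    reads: Iterable[str], min_len: int = 16
) -> tuple[list[str], int]:
    """Keep reads of length >= ``min_len``; also return the discarded count."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[str] = []
    n_discarded = 0
    for r in reads:
        if len(r) >= min_len:
            kept.append(r)
        else:
            n_discarded += 1
    return kept, n_discarded


def collapse(reads: Iterable[str]) -> list[CollapsedRead]:
    """Collapse reads to unique sequences, lexicographically ordered.

    The sum of multiplicities equals the number of input reads.
    """
    counts = Counter(reads)
    return [CollapsedRead(seq, n) for seq, n in sorted(counts.items())]


def write_collapsed(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for cr in collapsed:
            fh.write(f"{cr.sequence}\t{cr.count}\n")


def read_collapsed(path: str | Path) -> list[CollapsedRead]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{path}: expected a 'sequence\\tcount' header")
        for line in fh:
            seq, n = line.rstrip("\n").split("\t")
            out.append(CollapsedRead(seq, int(n)))
    return out
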