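"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package internals: the placement
oracle is a per-position Hamming scan, the trimming oracle a plain sliding
window, and the terminal-repeat oracle an exhaustive prefix/suffix
comparison.
"""

from __future__ import annotations

from aavsrna import Placement, ReferenceSequence

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_placements(
    sequence: str, references, max_mm: int
) -> list[Placement]:
    """Every full-length ungapped placement at <= max_mm, by exhaustive scan."""
    out: list[Placement] = []
    L = len(sequence)
    queries = {"+": sequence, "-": naive_revcomp(sequence)}
    for ref in references:
        hits = []
        for s in range(ref.length - L + 1):
            window = ref.sequence[s : s + L]
            for strand in ("+", "-"):
                mm = sum(
                    1
                    for x, y in zip(queries[strand], window)
                    if x != y or x == "N" or y == "N"
                )
                if mm <= max_mm:
                    hits.append((s, strand, mm))
        hits.sort(key=lambda h: (h[0], h[1] == "-"))
        out.extend(
            Placement(ref.id, strand, s + 1, s + L, mm) for s, strand, mm in hits
        )
    return out


def naive_trim(read: str, adapter: str, min_overlap: int = 8, max_mm: int = 1) -> str:
    """Leftmost suffix-anchored adapter-prefix match by sliding window."""
    for i in range(len(read) - min_overlap + 1):
        k = min(len(adapter), len(read) - i)
        if k < min_overlap:
            break
        mm = sum(1 for x, y in zip(read[i : i + k], adapter[:k]) if x != y)
        if mm <= max_mm:
            return read[:i]
    return read


def naive_terminal_repeats(
    genome: ReferenceSequence, min_len: int
) -> dict[str, int | None]:
    """Maximal terminal-pair width per relation, by checking every width."""
    seq = genome.sequence
    n = len(seq)
    best: dict[str, int | None] = {"identical": None, "reverse_complement": None}
    for k in range(min_len, n // 2 + 1):
        prefix, suffix = seq[:k], seq[n - k :]
        if prefix == suffix:
            best["identical"] = k
        if prefix == naive_revcomp(suffix):
            best["reverse_complement"] = k
    return best
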