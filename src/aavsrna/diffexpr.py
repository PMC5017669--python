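"""Host miRNA count comparison with a representativeness floor and fold bands.

The comparison follows the convention of plotting per-miRNA read counts of an
infected sample against an uninfected control and classifying each miRNA by
its fold change into regulation bands at 2x and 5x.  miRNAs whose raw read
counts fall below a floor (default 100 reads) in both samples are excluded
from interpretation as "not representative": read counts that low are
dominated by sampling noise.  Counts may be depth-normalised to CPM (counts
per million >=16-nt reads) or compared raw; a pseudocount (default 0.5)
guards against zero counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class MiRNACountTable:
    """Raw per-sample miRNA read counts plus per-sample library sizes.

    ``counts`` is indexed by miRNA id with one integer column per sample;
    ``library_sizes`` holds the >=16-nt read total of each sample, the
    denominator of CPM normalisation.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"library sizes missing for samples {sorted(missing)}")

    @property
    def catalog_size(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class DiffConfig:
    floor: float = 100
    bands: tuple[float, float] = (2.0, 5.0)
    normalization: str = "cpm"
    pseudocount: float = 0.5
    #: "both": excluded only if BOTH raw counts are below the floor (the
    #: dashed exclusion square bounds both axes); "either" for the stricter rule.
    floor_rule: str = "both"

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if not self.bands[0] < self.bands[1]:
            raise ValueError("bands must be increasing")
        if self.normalization not in ("cpm", "raw"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.floor_rule not in ("both", "either"):
            raise ValueError(f"unknown floor_rule {self.floor_rule!r}")


@dataclass(frozen=True)
class FoldChangeRecord:
    mirna: str
    count_a: int
    count_b: int
    norm_a: float
    norm_b: float
    fold_change: float  # b over a, pseudocounted
    classification: str  # not_representative | within_2fold | band_2_to_5 | beyond_5fold
    direction: str  # up | down | none


def normalize_counts(table: MiRNACountTable, config: DiffConfig) -> pd.DataFrame:
    """CPM mode: count * 1e6 / library size; raw mode: identity (as float)."""
    if config.normalization == "raw":
        return table.counts.astype(float)
    libs = table.library_sizes[table.counts.columns]
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive for CPM normalisation")
    return table.counts * 1e6 / libs


def _classify(fc: float, raw_a: float, raw_b: float, config: DiffConfig) -> str:
    if config.floor_rule == "both":
        floored = raw_a < config.floor and raw_b < config.floor
    else:
        floored = raw_a < config.floor or raw_b < config.floor
    if floored:
        return "not_representative"
    magnitude = max(fc, 1.0 / fc)
    lo, hi = config.bands
    if magnitude <= lo:
        return "within_2fold"
    if magnitude <= hi:
        return "band_2_to_5"
    return "beyond_5fold"


def compute_fold_changes(
    table: MiRNACountTable,
    sample_a: str,
    sample_b: str,
    config: DiffConfig = DiffConfig(),
) -> list[FoldChangeRecord]:
    """Per-miRNA fold change of ``sample_b`` over ``sample_a`` with banding.

    fc = (norm_b + pseudocount) / (norm_a + pseudocount).  A miRNA below the
    representativeness floor is never classified into a regulation band,
    regardless of its fold change.
    """
    for s in (sample_a, sample_b):
        if s not in table.counts.columns:
            raise KeyError(f"sample {s!r} not in count table")
    norm = normalize_counts(table, config)
    pc = config.pseudocount
    out: list[FoldChangeRecord] = []
    for mirna in table.counts.index:
        a = int(table.counts.at[mirna, sample_a])
        b = int(table.counts.at[mirna, sample_b])
        na = float(norm.at[mirna, sample_a])
        nb = float(norm.at[mirna, sample_b])
        fc = (nb + pc) / (na + pc)
        cls = _classify(fc, a, b, config)
        direction = "up" if fc > 1 else ("down" if fc < 1 else "none")
        out.append(FoldChangeRecord(str(mirna), a, b, na, nb, fc, cls, direction))
    return out


def scatter_table(
    records: Sequence[FoldChangeRecord], pseudocount: float = 0.5
) -> pd.DataFrame:
    """Plot-ready table: log10 normalized values, class and highlight flag."""
    return pd.DataFrame(
        {
            "mirna": [r.mirna for r in records],
            "log10_a": [float(np.log10(r.norm_a + pseudocount)) for r in records],
            "log10_b": [float(np.log10(r.norm_b + pseudocount)) for r in records],
            "classification": [r.classification for r in records],
            "highlight": [r.classification == "beyond_5fold" for r in records],
        }
    )


def fold_change_frame(records: Sequence[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [r.mirna for r in records],
            "count_a": [r.count_a for r in records],
            "count_b": [r.count_b for r in records],
            "norm_a": [r.norm_a for r in records],
            "norm_b": [r.norm_b for r in records],
            "fold_change": [r.fold_change for r in records],
            "classification": [r.classification for r in records],
            "direction": [r.direction for r in records],
        }
    )
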