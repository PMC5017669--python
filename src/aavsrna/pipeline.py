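"""End-to-end per-sample processing: trim, filter, collapse, assign, summarise."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .assign import AssignmentRecord, TierSchedule, assignment_summary, hierarchical_assign
from .genome import ReferenceSequence
from .preprocess import CollapsedRead, collapse, filter_min_length, read_fastq, trim_reads
from .report import SummaryRow

logger = logging.getLogger(__name__)


@dataclass
class SampleResult:
    sample: str
    n_total: int
    n_discarded_short: int
    n_ge16: int
    collapsed: list[CollapsedRead]
    records: list[AssignmentRecord]
    summary: SummaryRow

    def viral_records(self, species: str) -> list[AssignmentRecord]:
        return [r for r in self.records if species in r.viral_species]


def process_reads(
    sample: str,
    reads: Sequence[str],
    host_refs: Sequence[ReferenceSequence],
    viral_ref_sets: Mapping[str, Sequence[ReferenceSequence]],
    adapter: str,
    min_len: int = 16,
    schedule: TierSchedule = TierSchedule(),
    min_overlap: int = 8,
    max_adapter_mm: int = 1,
) -> SampleResult:
    """Run the full pipeline on raw machine reads.

    Conservation holds at every stage: n_total = discarded short reads +
    sum of collapsed multiplicities, and the assignment categories partition
    the >=16-nt reads.
    """
    n_total = len(reads)
    trimmed = trim_reads(reads, adapter, min_overlap, max_adapter_mm)
    kept, n_short = filter_min_length(trimmed, min_len)
    collapsed = collapse(kept)
    logger.info(
        "%s: %d reads, %d short (<%d nt) discarded, %d kept, %d unique sequences",
        sample, n_total, n_short, min_len, len(kept), len(collapsed),
    )
    records = hierarchical_assign(collapsed, host_refs, viral_ref_sets, schedule)
    summary = assignment_summary(
        sample, records, n_total, len(kept), viral_species=sorted(viral_ref_sets)
    )
    logger.info(
        "%s: %d human (%d miRNA), %s viral, %d unknown",
        sample, summary.n_human, summary.n_human_mirna, summary.viral, summary.n_unknown,
    )
    return SampleResult(sample, n_total, n_short, len(kept), collapsed, records, summary)


def process_fastq(
    sample: str,
    fastq_path: str | Path,
    host_refs: Sequence[ReferenceSequence],
    viral_ref_sets: Mapping[str, Sequence[ReferenceSequence]],
    adapter: str,
    **kwargs,
) -> SampleResult:
    return process_reads(
        sample, read_fastq(fastq_path), host_refs, viral_ref_sets, adapter, **kwargs
    )
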