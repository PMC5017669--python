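"""Summary-table rendering with the read-assignment percentage conventions.

The per-sample summary mirrors the published assignment tables of small
RNA-Seq studies: raw read counts with a percentage in parentheses.  Two
denominator conventions apply and were fixed arithmetically from the
published counts: the ">=16 nt" column is expressed as a percentage of total
reads, while every other percentage column (human, human miRNA, per-virus,
unknown) is expressed as a percentage of the >=16-nt reads.  Percentages are
rounded to one decimal; a non-zero count whose percentage rounds to 0.0 is
rendered "<0.1", and a true zero renders "0".

:func:`render_percent` is the single formatting authority; no percentage is
formatted anywhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


def render_percent(numerator: int | float, denominator: int | float) -> str:
    """Format ``100 * numerator / denominator`` to one decimal.

    Non-zero values rounding to 0.0 render as "<0.1"; exact zeros as "0".
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    if numerator == 0:
        return "0"
    pct = round(100.0 * numerator / denominator, 1)
    if pct == 0.0:
        return "<0.1"
    return f"{pct:.1f}"


@dataclass(frozen=True)
class SummaryRow:
    """One sample's assignment accounting (raw read counts)."""

    sample: str
    n_total: int
    n_ge16: int
    n_human: int
    n_human_mirna: int
    viral: dict[str, int]
    n_unknown: int
    n_cross_species: int = 0


def _cell(count: int, denominator: int) -> str:
    return f"{count:,} ({render_percent(count, denominator)})"


def render_summary(rows: Sequence[SummaryRow]) -> tuple[pd.DataFrame, str]:
    """Render summary rows as a formatted DataFrame and a plain-text table.

    The ">=16 nt" column uses total reads as denominator; all other
    percentage columns use the >=16-nt read count of the sample.
    """
    if not rows:
        raise ValueError("no summary rows")
    species = list(dict.fromkeys(sp for r in rows for sp in r.viral))
    table = []
    for r in rows:
        rec = {
            "sample": r.sample,
            "total_reads": f"{r.n_total:,}",
            "reads_ge16": _cell(r.n_ge16, r.n_total),
            "human": _cell(r.n_human, r.n_ge16),
            "human_mirna": _cell(r.n_human_mirna, r.n_ge16),
        }
        for sp in species:
            rec[sp] = _cell(r.viral.get(sp, 0), r.n_ge16)
        rec["unknown"] = _cell(r.n_unknown, r.n_ge16)
        table.append(rec)
    df = pd.DataFrame(table)
    return df, df.to_string(index=False)


def summary_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Numeric (unformatted) counts table, one row per sample."""
    species = list(dict.fromkeys(sp for r in rows for sp in r.viral))
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "n_total": r.n_total,
                "n_ge16": r.n_ge16,
                "n_human": r.n_human,
                "n_human_mirna": r.n_human_mirna,
                **{sp: r.viral.get(sp, 0) for sp in species},
                "n_unknown": r.n_unknown,
            }
            for r in rows
        ]
    )


def write_summary(rows: Sequence[SummaryRow], path: str | Path) -> None:
    df, _ = render_summary(rows)
    df.to_csv(path, sep="\t", index=False)


_PUBLISHED = "read_assignment_counts.tsv"


def load_published_assignment_counts() -> list[SummaryRow]:
    """Published read-assignment counts of the eight-sample AAV2 co-infection
    small RNA-Seq study (mock / AAV2 / AAV2+helper / helper at 8 and 27 hpi).

    Counts only; every percentage is recomputed by the renderer.
    """
    with resources.files("aavsrna.data").joinpath(_PUBLISHED).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        SummaryRow(
            sample=r["sample"],
            n_total=int(r["n_total"]),
            n_ge16=int(r["n_ge16"]),
            n_human=int(r["n_human"]),
            n_human_mirna=int(r["n_human_mirna"]),
            viral={"aav2": int(r["aav2"]), "ad2": int(r["ad2"]), "hsv1": int(r["hsv1"])},
            n_unknown=int(r["n_unknown"]),
        )
        for _, r in df.iterrows()
    ]
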