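"""Splicing-event detection: alignment gaps aggregated into supported junctions.

A splicing event is a contiguous reference gap of more than ``min_gap - 1``
bases within one read alignment (default: gaps of >= 10 nt, i.e. "greater
than 9 bases").  Identical gaps are aggregated across reads into a
:class:`SpliceEvent` carrying total and per-condition read support, and
events are then filtered on superset support (default >= 10 reads).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .alignment_io import AlignmentRecord
from .gene_model import Junction

__all__ = [
    "SpliceEvent",
    "extract_gaps",
    "aggregate",
    "filter_support",
    "events_to_frame",
    "write_events_tsv",
]

DEFAULT_MIN_GAP = 10
DEFAULT_MIN_SUPPORT = 10


@dataclass(frozen=True)
class SpliceEvent:
    """A junction with its read support, and (once classified) label and locus."""

    junction: Junction
    support_total: int
    support_by_condition: dict[str, int] = field(default_factory=dict)
    label: Optional["ASLabel"] = None  # set by splicegaps.as_classify
    locus_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.support_by_condition:
            total = sum(self.support_by_condition.values())
            if total != self.support_total:
                raise ValueError(
                    f"support_total {self.support_total} != per-condition sum {total}"
                )


def extract_gaps(record: AlignmentRecord, min_gap: int = DEFAULT_MIN_GAP,
                 strand: str = "+") -> list[Junction]:
    """Junctions for every inter-block gap of length >= ``min_gap`` in a read.

    Coordinates are 1-based inclusive over the gapped span; a single-block
    record yields nothing.
    """
    out = []
    blocks = record.blocks
    for (_, left_end), (right_start, _) in zip(blocks, blocks[1:]):
        gap_len = right_start - left_end
        if gap_len >= min_gap:
            out.append(Junction(record.chrom, left_end + 1, right_start, strand))
    return out


def aggregate(records: Iterable[AlignmentRecord],
              min_gap: int = DEFAULT_MIN_GAP,
              strand: str = "+",
              conditions: Sequence[str] = ()) -> list[SpliceEvent]:
    """Aggregate identical gaps across reads into supported events.

    Support counts read alignments (each mate independently).  Output is
    sorted by (gap_start, gap_end).  All records must share one chromosome.
    """
    chrom = None
    counts: dict[tuple[int, int], dict[str, int]] = {}
    for rec in records:
        if chrom is None:
            chrom = rec.chrom
        elif rec.chrom != chrom:
            raise ValueError(
                f"records span multiple chromosomes ({chrom} and {rec.chrom}); "
                f"aggregate one region at a time"
            )
        for j in extract_gaps(rec, min_gap=min_gap, strand=strand):
            per_cond = counts.setdefault(j.key(), {})
            per_cond[rec.condition] = per_cond.get(rec.condition, 0) + 1
    cond_order = list(conditions) or sorted({c for d in counts.values() for c in d})
    events = []
    for (gs, ge) in sorted(counts):
        per_cond_raw = counts[(gs, ge)]
        per_cond = {c: per_cond_raw.get(c, 0) for c in cond_order}
        for c in per_cond_raw:  # keep any condition missing from the given order
            per_cond.setdefault(c, per_cond_raw[c])
        events.append(
            SpliceEvent(
                junction=Junction(chrom, gs, ge, strand),
                support_total=sum(per_cond.values()),
                support_by_condition=per_cond,
            )
        )
    return events


def filter_support(events: Sequence[SpliceEvent],
                   min_support: int = DEFAULT_MIN_SUPPORT) -> list[SpliceEvent]:
    """Retain events whose **superset** support is >= ``min_support``."""
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    return [ev for ev in events if ev.support_total >= min_support]


def events_to_frame(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    """Tabulate events (one row per junction, one support column per condition)."""
    conditions: list[str] = []
    for ev in events:
        for c in ev.support_by_condition:
            if c not in conditions:
                conditions.append(c)
    rows = []
    for ev in events:
        row: dict = {
            "locus_id": ev.locus_id if ev.locus_id is not None else -1,
            "chrom": ev.junction.chrom,
            "gap_start": ev.junction.gap_start,
            "gap_end": ev.junction.gap_end,
            "strand": ev.junction.strand,
            "category": ev.label.category.value if ev.label else "",
            "novel_end_context": ev.label.novel_end_context if ev.label else "",
            "skipped_exon_indices": ",".join(
                str(i) for i in (ev.label.skipped_exon_indices if ev.label else ())
            ),
            "support_total": ev.support_total,
        }
        for c in conditions:
            row[f"support_{c}"] = ev.support_by_condition.get(c, 0)
        rows.append(row)
    cols = ["locus_id", "chrom", "gap_start", "gap_end", "strand", "category",
            "novel_end_context", "skipped_exon_indices", "support_total"]
    cols += [f"support_{c}" for c in conditions]
    return pd.DataFrame(rows, columns=cols)


def write_events_tsv(events: Sequence[SpliceEvent], path: str | os.PathLike) -> None:
    events_to_frame(events).to_csv(os.fspath(path), sep="\t", index=False)
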