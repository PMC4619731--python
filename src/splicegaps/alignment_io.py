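"""Region-restricted streaming of primary spliced alignments from SAM/BAM.

Each yielded :class:`AlignmentRecord` reduces a read alignment to its
reference-aligned blocks plus sample/condition provenance.  Both skip (``N``)
and deletion (``D``) CIGAR operations separate blocks, so a downstream gap
threshold — not the operation code — decides what counts as a splicing event.
Insertions and clips do not advance the reference and never split a block.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pysam

__all__ = [
    "AlignmentRecord",
    "SampleEntry",
    "SampleSheet",
    "read_sample_sheet",
    "cigar_blocks",
    "load_region",
    "merge_groups",
]

# CIGAR operation codes (pysam numeric encoding)
_REF_ALIGNED = {0, 7, 8}  # M, =, X
_REF_GAP = {2, 3}         # D, N


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary read alignment reduced to reference-aligned blocks."""

    read_id: str
    sample_id: str
    condition: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]  # 0-based half-open, strictly increasing
    is_primary: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    path: str
    condition: str


@dataclass(frozen=True)
class SampleSheet:
    entries: tuple[SampleEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_id(s) in sample sheet: {sorted(dupes)}")

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        seen: list[str] = []
        for e in self.entries:
            if e.condition not in seen:
                seen.append(e.condition)
        return seen

    def n_samples(self, condition: str) -> int:
        return sum(1 for e in self.entries if e.condition == condition)


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read a 3-column TSV (sample_id, path, condition) with a header line.

    Relative alignment paths are resolved against the sheet's directory.
    """
    path = os.fspath(path)
    base = os.path.dirname(os.path.abspath(path))
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:3]] != ["sample_id", "path", "condition"]:
            raise ValueError(
                f"sample sheet {path} must start with header 'sample_id\\tpath\\tcondition'"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"sample sheet line {lineno}: expected 3 columns")
            sid, p, cond = fields[0], fields[1], fields[2]
            if not os.path.isabs(p):
                p = os.path.join(base, p)
            if not os.path.exists(p):
                raise FileNotFoundError(f"sample sheet line {lineno}: missing file {p}")
            entries.append(SampleEntry(sid, p, cond))
    return SampleSheet(tuple(entries))


def cigar_blocks(cigartuples: Sequence[tuple[int, int]], pos: int
                 ) -> tuple[tuple[int, int], ...]:
    """Reference-aligned blocks of an alignment starting at 0-based ``pos``.

    Blocks break at D and N operations; adjacent gap operations merge into
    one gap; blocks separated only by insertions merge back together.
    """
    blocks: list[list[int]] = []
    ref = pos
    for op, length in cigartuples:
        if op in _REF_ALIGNED:
            if blocks and blocks[-1][1] == ref:
                blocks[-1][1] = ref + length
            else:
                blocks.append([ref, ref + length])
            ref += length
        elif op in _REF_GAP:
            ref += length
        # I (1), S (4), H (5), P (6): no reference advance
    return tuple((s, e) for s, e in blocks)


def load_region(path: str | os.PathLike,
                region: tuple[str, int, int],
                sample_id: str,
                condition: str,
                min_mapq: int = 0) -> Iterator[AlignmentRecord]:
    """Yield primary, mapped alignments overlapping ``region`` from SAM/BAM.

    ``region`` is (chrom, start, end), 0-based half-open.  Reads partially
    overlapping the boundary are kept whole.  BAM files with an index are
    queried randomly; SAM (and unsorted use) falls back to a sequential scan.
    """
    path = os.fspath(path)
    chrom, start, end = region
    if end <= start:
        raise ValueError(f"empty region {region}")
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as af:
        if chrom not in af.references:
            raise ValueError(
                f"region chromosome {chrom!r} absent from header of {path} "
                f"(references: {list(af.references)[:5]}...)"
            )
        if mode == "rb":
            try:
                it = af.fetch(chrom, start, end)
            except ValueError as exc:
                raise ValueError(
                    f"{path} has no index for random access; create one with "
                    f"'samtools index {path}' or provide SAM input"
                ) from exc
        else:
            it = iter(af)
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if aln.reference_name != chrom:
                continue
            if aln.reference_end <= start or aln.reference_start >= end:
                continue
            blocks = cigar_blocks(aln.cigartuples, aln.reference_start)
            if not blocks:
                continue
            yield AlignmentRecord(
                read_id=aln.query_name + ("/2" if aln.is_read2 else "/1"),
                sample_id=sample_id,
                condition=condition,
                chrom=chrom,
                blocks=blocks,
            )


def merge_groups(sheet: SampleSheet, region: tuple[str, int, int],
                 min_mapq: int = 0
                 ) -> tuple[dict[str, list[AlignmentRecord]], list[AlignmentRecord]]:
    """Merge samples into per-condition collections plus the all-sample superset.

    Returns ``(by_condition, superset)``.  Provenance (sample, condition) is
    preserved on every record; the superset is the concatenation of the
    per-condition collections, so sizes are additive by construction.
    """
    by_condition: dict[str, list[AlignmentRecord]] = {c: [] for c in sheet.conditions}
    for entry in sheet.entries:
        recs = list(load_region(entry.path, region, entry.sample_id,
                                entry.condition, min_mapq=min_mapq))
        by_condition[entry.condition].extend(recs)
    superset = [r for cond in sheet.conditions for r in by_condition[cond]]
    return by_condition, superset
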