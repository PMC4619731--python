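"""Pipeline orchestration and standard-format outputs (TSV, junction BED).

The junction BED uses the two-anchor-block BED12 dialect familiar from
junction viewers: each record spans a fixed-width anchor on either side of
the gap, with the gap itself as the inter-block space.  The writer/reader
pair round-trips junction coordinates exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

from . import __version__
from .alignment_io import SampleSheet, merge_groups, read_sample_sheet
from .as_classify import classify_events, count_alternative, group_loci
from .coverage_profile import count_bases, plot_coverage, summarize, write_coverage_tsv
from .gene_model import GeneModel, Junction, parse_annotation, derive_features
from .junction_extract import (
    DEFAULT_MIN_GAP,
    DEFAULT_MIN_SUPPORT,
    SpliceEvent,
    aggregate,
    filter_support,
    write_events_tsv,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "write_junction_bed",
    "read_junction_bed",
]

DEFAULT_ANCHOR = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    annotation: str
    transcript_id: str
    sheet: str
    out_dir: str
    gene_id: str = ""
    region: Optional[tuple[str, int, int]] = None  # default: annotated gene span
    min_gap: int = DEFAULT_MIN_GAP
    min_support: int = DEFAULT_MIN_SUPPORT
    min_mapq: int = 0
    anchor: int = DEFAULT_ANCHOR
    locus_pad: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.min_gap < 1 or self.min_support < 1:
            raise ValueError("min_gap and min_support must be >= 1")


def write_junction_bed(events: Sequence[SpliceEvent], path: str | os.PathLike,
                       anchor: int = DEFAULT_ANCHOR) -> None:
    """BED12, one record per junction: two anchor blocks flanking the gap.

    ``chromStart = gap_start - 1 - anchor``; score caps at 1000; name is
    ``category:gap_start-gap_end``.  Records are sorted by coordinate.
    """
    if anchor < 1:
        raise ValueError("anchor width must be >= 1")
    lines = []
    for ev in sorted(events, key=lambda e: e.junction.key()):
        j = ev.junction
        chrom_start = (j.gap_start - 1) - anchor
        chrom_end = j.gap_end + anchor
        category = ev.label.category.value if ev.label else "Unclassified"
        name = f"{category}:{j.gap_start}-{j.gap_end}"
        score = min(ev.support_total, 1000)
        block_starts = f"0,{anchor + j.length}"
        lines.append(
            "\t".join(
                [
                    j.chrom, str(chrom_start), str(chrom_end), name, str(score),
                    j.strand, str(chrom_start), str(chrom_end), "0,0,0", "2",
                    f"{anchor},{anchor}", block_starts,
                ]
            )
        )
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_junction_bed(path: str | os.PathLike
                      ) -> list[tuple[Junction, str, int]]:
    """Inverse of :func:`write_junction_bed`: (junction, category, score) rows."""
    out = []
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"junction BED line {lineno}: expected 12 fields")
            chrom, chrom_start, strand = f[0], int(f[1]), f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != 2 or len(starts) != 2:
                raise ValueError(f"junction BED line {lineno}: expected 2 blocks")
            gap_start = chrom_start + sizes[0] + 1  # 1-based first gapped base
            gap_end = chrom_start + starts[1]       # 1-based last gapped base
            category = f[3].split(":", 1)[0]
            out.append((Junction(chrom, gap_start, gap_end, strand),
                        category, int(f[4])))
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run annotation -> merge -> junctions -> classification -> coverage.

    Writes ``events.tsv``, ``junctions.bed``, ``coverage.tsv``, ``run_log.json``
    (plus figures when requested) into ``config.out_dir``; on any stage
    failure partial outputs are removed and a :class:`PipelineError` is
    raised naming the stage.  Returns a summary dict (also saved as the log).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    produced: list[str] = []

    def _out(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        produced.append(p)
        return p

    stage = "parse_annotation"
    try:
        model = parse_annotation(config.annotation, config.gene_id,
                                 config.transcript_id)
        region = config.region or (model.chrom, *model.span)

        stage = "load_alignments"
        sheet = read_sample_sheet(config.sheet)
        by_condition, superset = merge_groups(sheet, region,
                                              min_mapq=config.min_mapq)

        stage = "extract_junctions"
        events = aggregate(superset, min_gap=config.min_gap,
                           strand=model.strand, conditions=sheet.conditions)
        n_detected = len(events)
        events = filter_support(events, min_support=config.min_support)

        stage = "classify"
        events = classify_events(events, model)
        loci = group_loci(events, pad=config.locus_pad)
        events = [ev for locus in loci for ev in locus.members]

        stage = "coverage"
        features = derive_features(model)
        counts, outside = count_bases(superset, features)
        coverage = summarize(counts, sheet, features)

        stage = "write_outputs"
        write_events_tsv(events, _out("events.tsv"))
        write_junction_bed(events, _out("junctions.bed"), anchor=config.anchor)
        write_coverage_tsv(coverage, _out("coverage.tsv"))
        if config.make_plots:
            plot_coverage(coverage, _out("coverage.png"),
                          title=model.gene_id or config.transcript_id)

        log = {
            "version": __version__,
            "config": {
                **{k: v for k, v in dataclasses.asdict(config).items()},
            },
            "inputs": {
                "annotation_sha256": _sha256(config.annotation),
                "sheet_sha256": _sha256(config.sheet),
                "alignments_sha256": {
                    e.sample_id: _sha256(e.path) for e in sheet.entries
                },
            },
            "region": list(region),
            "counts": {
                "records_superset": len(superset),
                "records_by_condition": {c: len(v) for c, v in by_condition.items()},
                "junctions_detected": n_detected,
                "junctions_reported": len(events),
                "alternative_events": count_alternative(events),
                "loci": len(loci),
                "outside_span_bases": outside,
            },
        }
        with open(_out("run_log.json"), "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
        return log
    except Exception as exc:
        for p in produced:
            if os.path.exists(p):
                os.remove(p)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
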