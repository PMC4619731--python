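"""Canonical gene model: exon/intron feature ladder and canonical junctions.

A single canonical transcript (e.g. GENCODE HTT-001 for the huntingtin gene)
defines the reference against which observed splice junctions are classified
and over which per-feature coverage is binned.

Coordinate conventions
----------------------
* Internally every interval is **0-based half-open** ``(start, end)``, the
  BED/pysam convention.
* Reported junction coordinates are **1-based inclusive** first/last gapped
  (intronic) base, the same convention as STAR's ``SJ.out.tab``.  For an
  intron occupying 0-based ``[s, e)`` the junction is ``(s + 1, e)``.
* Exons and introns are numbered from 1 in transcription order: genomic
  order on the ``+`` strand, reversed on ``-``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils

__all__ = [
    "AnnotationError",
    "GeneModel",
    "Feature",
    "Junction",
    "parse_annotation",
    "derive_features",
    "canonical_junctions",
    "write_bed12",
    "model_from_junctions",
]


class AnnotationError(ValueError):
    """Raised for malformed or incomplete gene annotations."""


@dataclass(frozen=True, order=True)
class Junction:
    """A splice junction: the gapped (intronic) span of a spliced alignment.

    ``gap_start``/``gap_end`` are the 1-based first and last gapped bases.
    """

    chrom: str
    gap_start: int
    gap_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.gap_end < self.gap_start:
            raise ValueError(f"gap_end < gap_start: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.gap_end - self.gap_start + 1

    @property
    def gap0(self) -> tuple[int, int]:
        """The gap as a 0-based half-open interval."""
        return (self.gap_start - 1, self.gap_end)

    @property
    def donor_coord(self) -> int:
        """1-based coordinate of the gap end on the 5' (donor) side."""
        return self.gap_start if self.strand == "+" else self.gap_end

    @property
    def acceptor_coord(self) -> int:
        """1-based coordinate of the gap end on the 3' (acceptor) side."""
        return self.gap_end if self.strand == "+" else self.gap_start

    def key(self) -> tuple[int, int]:
        return (self.gap_start, self.gap_end)


@dataclass(frozen=True)
class Feature:
    """One exon or intron of the canonical transcript.

    ``index`` is 1-based in transcription order; ``start``/``end`` are
    0-based half-open genomic coordinates.
    """

    kind: str  # "exon" | "intron"
    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"feature kind must be exon/intron: {self.kind!r}")
        if self.end <= self.start:
            raise ValueError(f"empty feature interval: {self}")
        if self.index < 1:
            raise ValueError(f"feature index must be >= 1: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.kind}{self.index}"


@dataclass(frozen=True)
class GeneModel:
    """A canonical transcript: ordered exons on one chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    canonical_transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be + or -: {self.strand!r}")
        if len(self.exons) < 2:
            raise AnnotationError(
                f"transcript {self.canonical_transcript_id or self.gene_id!r} has "
                f"{len(self.exons)} exon(s); at least 2 are required to define junctions"
            )
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"empty exon interval ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"exons overlap or are unsorted near ({s}, {e}) in "
                    f"{self.canonical_transcript_id or self.gene_id}"
                )
            if prev_end is not None and s == prev_end:
                raise AnnotationError(
                    f"adjacent exons touch at {s}; merge them in the annotation"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval from first exon start to last exon end."""
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """0-based half-open intron intervals, in genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def derive_features(model: GeneModel) -> list[Feature]:
    """Alternate exon/intron ladder in transcription order (2E-1 features)."""
    exons = list(model.exons)
    introns = list(model.introns)
    genomic: list[Feature] = []
    n = len(exons)
    for gi, (s, e) in enumerate(exons):
        idx = gi + 1 if model.strand == "+" else n - gi
        genomic.append(Feature("exon", idx, s, e))
    for gi, (s, e) in enumerate(introns):
        idx = gi + 1 if model.strand == "+" else n - 1 - gi
        genomic.append(Feature("intron", idx, s, e))
    if model.strand == "+":
        genomic.sort(key=lambda f: f.start)
    else:
        genomic.sort(key=lambda f: -f.start)
    return genomic


def canonical_junctions(model: GeneModel) -> set[Junction]:
    """One junction per intron of the canonical transcript (E-1 junctions)."""
    return {
        Junction(model.chrom, s + 1, e, model.strand) for s, e in model.introns
    }


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def parse_annotation(path: str | os.PathLike, gene_id: str = "",
                     transcript_id: str = "") -> GeneModel:
    """Parse a GTF (GENCODE dialect) or BED12 annotation into a :class:`GeneModel`.

    The format is chosen by extension (``.bed`` → BED12, otherwise GTF).
    ``transcript_id`` selects the canonical transcript: the GTF
    ``transcript_id`` attribute, or the BED ``name`` column.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise AnnotationError(f"annotation file not found: {path}")
    if path.endswith((".bed", ".bed12")):
        return _parse_bed12(path, gene_id, transcript_id)
    return _parse_gtf(path, gene_id, transcript_id)


def _parse_gtf(path: str, gene_id: str, transcript_id: str) -> GeneModel:
    # Pre-scan for structurally broken lines so failures carry a line number;
    # semantic parsing is then delegated to gffutils.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            nfields = len(line.rstrip("\n").split("\t"))
            if nfields < 9:
                raise AnnotationError(
                    f"malformed GTF line {lineno} in {path}: "
                    f"expected 9 tab-separated fields, found {nfields}"
                )
    try:
        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc

    exons = []
    strand = None
    chrom = None
    gid = gene_id
    for feat in db.features_of_type("exon"):
        tids = feat.attributes.get("transcript_id", [])
        if transcript_id and transcript_id not in tids:
            continue
        exons.append((feat.start - 1, feat.end))  # GTF is 1-based inclusive
        strand = feat.strand
        chrom = feat.seqid
        if not gid:
            gid = (feat.attributes.get("gene_id") or [""])[0]
    if not exons:
        raise AnnotationError(
            f"transcript {transcript_id!r} not found (no exon records) in {path}"
        )
    exons.sort()
    return GeneModel(
        gene_id=gid, chrom=chrom, strand=strand,
        exons=tuple(exons), canonical_transcript_id=transcript_id,
    )


def _parse_bed12(path: str, gene_id: str, transcript_id: str) -> GeneModel:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"malformed BED12 line {lineno} in {path}: "
                    f"expected 12 fields, found {len(fields)}"
                )
            name = fields[3]
            if transcript_id and name != transcript_id:
                continue
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(
                    f"malformed BED12 line {lineno} in {path}: {exc}"
                ) from exc
            if not (len(sizes) == len(starts) == block_count):
                raise AnnotationError(
                    f"malformed BED12 line {lineno} in {path}: blockCount "
                    f"{block_count} does not match blockSizes/blockStarts"
                )
            exons = tuple(
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            return GeneModel(
                gene_id=gene_id or name, chrom=chrom, strand=strand,
                exons=exons, canonical_transcript_id=transcript_id or name,
            )
    raise AnnotationError(f"transcript {transcript_id!r} not found in {path}")


def write_bed12(model: GeneModel, path: str | os.PathLike,
                rgb: str = "0,0,255") -> None:
    """Write the canonical model as one BED12 record (for genome browsers)."""
    start, end = model.span
    sizes = ",".join(str(e - s) for s, e in model.exons)
    starts = ",".join(str(s - start) for s, _ in model.exons)
    name = model.canonical_transcript_id or model.gene_id
    with open(os.fspath(path), "w") as fh:
        fh.write(
            "\t".join(
                [
                    model.chrom, str(start), str(end), name, "0", model.strand,
                    str(start), str(end), rgb, str(model.n_exons), sizes, starts,
                ]
            )
            + "\n"
        )


def model_from_junctions(chrom: str, strand: str,
                         junctions: Iterable[tuple[int, int]],
                         span: tuple[int, int],
                         gene_id: str = "reference") -> GeneModel:
    """Build a gene model whose introns are exactly the given junctions.

    Useful when only a set of canonical junctions is known (e.g. a published
    junction table) rather than a full annotation: exons fill the complement
    of the junction gaps within ``span``.  Junction coordinates are 1-based
    inclusive, ``span`` is 0-based half-open and must contain every junction.
    """
    introns = sorted((gs - 1, ge) for gs, ge in junctions)
    lo, hi = span
    exons: list[tuple[int, int]] = []
    cur = lo
    for s, e in introns:
        if s < cur:
            raise AnnotationError(
                f"junctions overlap or extend outside span near ({s}, {e})"
            )
        exons.append((cur, s))
        cur = e
    if cur >= hi:
        raise AnnotationError("span must extend past the last junction")
    exons.append((cur, hi))
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     exons=tuple(exons), canonical_transcript_id=gene_id)
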