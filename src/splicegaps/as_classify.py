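"""Alternative-splicing classification of junctions against a canonical model.

Every observed junction receives exactly one category by a deterministic
decision cascade:

1. exact match to a canonical junction            -> ``Canonical``
2. both ends are ends of two *different* canonical
   junctions, downstream one later                -> ``SkippedExon``
3. one end canonical, the novel end strictly inside
   the same canonical intron, with a reciprocal
   partner junction forming a novel internal exon -> ``AddedExon`` (both partners)
4. one end shared with a canonical junction       -> ``Acceptor`` or ``Donor``
   (by which side is novel; donor = 5' side of the gap, strand-aware)
5. neither end shared                             -> ``Acceptor`` composite,
   with both end contexts recorded in ``notes``

The ``AddedExon`` call deliberately requires the reciprocal partner junction:
a lone junction landing mid-intron is indistinguishable, from coordinates
alone, from an alternative acceptor/donor, and is labelled as such with
``novel_end_context='intronic'``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from .gene_model import Feature, GeneModel, Junction, canonical_junctions, derive_features
from .junction_extract import SpliceEvent

__all__ = [
    "Category",
    "ASLabel",
    "Locus",
    "classify",
    "classify_events",
    "group_loci",
    "count_alternative",
]


class Category(str, Enum):
    CANONICAL = "Canonical"
    ACCEPTOR = "Acceptor"
    DONOR = "Donor"
    SKIPPED_EXON = "SkippedExon"
    ADDED_EXON = "AddedExon"


@dataclass(frozen=True)
class ASLabel:
    category: Category
    novel_end_context: str = "none"  # exonic | intronic | none
    skipped_exon_indices: tuple[int, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category is Category.CANONICAL:
            if self.novel_end_context != "none" or self.skipped_exon_indices:
                raise ValueError("Canonical label cannot carry novel-end context")
        if self.category is Category.SKIPPED_EXON and not self.skipped_exon_indices:
            raise ValueError("SkippedExon label requires skipped exon indices")


@dataclass(frozen=True)
class Locus:
    locus_id: int
    chrom: str
    start: int  # 0-based half-open span covering member junction gaps
    end: int
    members: tuple[SpliceEvent, ...]


def _end_context(pos0: int, features: Sequence[Feature], model: GeneModel) -> str:
    """exonic/intronic context of a single 0-based position.

    Positions outside the gene span resolve against the flanking feature,
    which is always a terminal exon.
    """
    lo, hi = model.span
    if pos0 < lo or pos0 >= hi:
        return "exonic"
    for f in features:
        if f.start <= pos0 < f.end:
            return f.kind + "ic"
    raise AssertionError("feature ladder is contiguous; unreachable")


def _containing_intron(pos0: int, model: GeneModel) -> tuple[int, int] | None:
    for s, e in model.introns:
        if s <= pos0 < e:
            return (s, e)
    return None


def classify(junction: Junction, model: GeneModel,
             all_junctions: Iterable[Junction] = ()) -> ASLabel:
    """Label one junction against the canonical junction set of ``model``.

    ``all_junctions`` supplies the full observed junction set, consulted only
    by the reciprocal added-exon test; the classified junction itself need
    not be a member.
    """
    canon = sorted(canonical_junctions(model), key=Junction.key)
    canon_keys = {j.key() for j in canon}
    gs, ge = junction.key()

    if (gs, ge) in canon_keys:
        return ASLabel(Category.CANONICAL)

    features = derive_features(model)
    left_idx = {j.gap_start: i for i, j in enumerate(canon)}   # genomic order index
    right_idx = {j.gap_end: i for i, j in enumerate(canon)}

    # (2) skipped exon(s): left end of canonical intron i, right end of j > i
    if gs in left_idx and ge in right_idx and right_idx[ge] > left_idx[gs]:
        gap_lo, gap_hi = junction.gap0
        skipped = tuple(
            f.index for f in features
            if f.kind == "exon" and f.start >= gap_lo and f.end <= gap_hi
        )
        if skipped:
            return ASLabel(Category.SKIPPED_EXON, "none",
                           tuple(sorted(skipped)))

    observed = {j.key() for j in all_junctions}

    # (3) reciprocal added-exon pair inside one canonical intron
    if gs in left_idx:
        host = canon[left_idx[gs]]
        if ge < host.gap_end:  # novel right end strictly inside the intron
            for (ogs, oge) in observed:
                if oge == host.gap_end and ge + 2 <= ogs <= host.gap_end:
                    return ASLabel(Category.ADDED_EXON, "intronic",
                                   notes=f"partner={ogs}-{oge}")
    if ge in right_idx:
        host = canon[right_idx[ge]]
        if gs > host.gap_start:  # novel left end strictly inside the intron
            for (ogs, oge) in observed:
                if ogs == host.gap_start and host.gap_start <= oge <= gs - 2:
                    return ASLabel(Category.ADDED_EXON, "intronic",
                                   notes=f"partner={ogs}-{oge}")

    # (4) one shared end -> alternative acceptor or donor, strand-aware
    shared_left = gs in left_idx
    shared_right = ge in right_idx
    if shared_left != shared_right:
        if shared_left:
            novel_pos0 = ge - 1            # novel right end (last gapped base)
            novel_is_acceptor = junction.strand == "+"
        else:
            novel_pos0 = gs - 1            # novel left end (first gapped base)
            novel_is_acceptor = junction.strand == "-"
        ctx = _end_context(novel_pos0, features, model)
        cat = Category.ACCEPTOR if novel_is_acceptor else Category.DONOR
        return ASLabel(cat, ctx)

    # (5) neither end canonical: composite, reported as Acceptor
    ctx_left = _end_context(gs - 1, features, model)
    ctx_right = _end_context(ge - 1, features, model)
    acceptor_ctx = ctx_right if junction.strand == "+" else ctx_left
    donor_ctx = ctx_left if junction.strand == "+" else ctx_right
    return ASLabel(Category.ACCEPTOR, acceptor_ctx,
                   notes=f"novel donor ({donor_ctx}) and acceptor ({acceptor_ctx})")


def classify_events(events: Sequence[SpliceEvent], model: GeneModel,
                    extra_junctions: Iterable[Junction] = ()) -> list[SpliceEvent]:
    """Classify every event; the observed set plus ``extra_junctions`` feeds
    the reciprocal added-exon test."""
    all_j = [ev.junction for ev in events] + list(extra_junctions)
    return [replace(ev, label=classify(ev.junction, model, all_j)) for ev in events]


def group_loci(events: Sequence[SpliceEvent], pad: int = 0) -> list[Locus]:
    """Single-linkage grouping of junction gaps that overlap after padding.

    Locus ids are assigned from 1 in coordinate order; every event lands in
    exactly one locus.  Returns loci; the events inside carry their locus_id.
    """
    if not events:
        return []
    chroms = {ev.junction.chrom for ev in events}
    if len(chroms) > 1:
        raise ValueError(f"events span multiple chromosomes: {sorted(chroms)}")
    order = sorted(events, key=lambda ev: ev.junction.key())
    clusters: list[list[SpliceEvent]] = []
    cur: list[SpliceEvent] = []
    cur_end = None
    for ev in order:
        s, e = ev.junction.gap0
        s, e = s - pad, e + pad
        if cur and s < cur_end:
            cur.append(ev)
            cur_end = max(cur_end, e)
        else:
            if cur:
                clusters.append(cur)
            cur = [ev]
            cur_end = e
    clusters.append(cur)
    loci = []
    for i, members in enumerate(clusters, start=1):
        tagged = tuple(replace(ev, locus_id=i) for ev in members)
        start = min(ev.junction.gap0[0] for ev in members)
        end = max(ev.junction.gap0[1] for ev in members)
        loci.append(Locus(i, members[0].junction.chrom, start, end, tagged))
    return loci


def count_alternative(events: Sequence[SpliceEvent]) -> int:
    """Number of classified events whose category is not Canonical."""
    for ev in events:
        if ev.label is None:
            raise ValueError(
                f"unclassified event {ev.junction.key()}; run classify_events first"
            )
    return sum(1 for ev in events if ev.label.category is not Category.CANONICAL)
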