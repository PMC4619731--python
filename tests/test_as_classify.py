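"""Decision cascade for AS classification, locus grouping, strand symmetry."""

import pytest
from hypothesis import given, settings, strategies as st

from splicegaps.as_classify import (
    ASLabel,
    Category,
    classify,
    classify_events,
    count_alternative,
    group_loci,
)
from splicegaps.gene_model import GeneModel, Junction, canonical_junctions, model_from_junctions
from splicegaps.junction_extract import SpliceEvent
from splicegaps.synthetic_data import build_toy_gene


def J(gs, ge, chrom="chr4", strand="+"):
    return Junction(chrom, gs, ge, strand)


def event(gs, ge, support=10, chrom="chr1", strand="+"):
    return SpliceEvent(J(gs, ge, chrom, strand), support, {"A": support})


@pytest.fixture(scope="module")
def htt_like_model():
    """Reference built from published huntingtin canonical junctions."""
    canonical = [(3122936, 3125548), (3173131, 3174720),
                 (3189093, 3199731), (3199939, 3204006)]
    return model_from_junctions("chr4", "+", canonical, (3120000, 3210000))


class TestCascade:
    def test_exact_match_is_canonical(self, htt_like_model):
        lab = classify(J(3122936, 3125548), htt_like_model)
        assert lab == ASLabel(Category.CANONICAL)

    def test_shared_donor_novel_acceptor(self, htt_like_model):
        lab = classify(J(3122936, 3124249), htt_like_model)
        assert lab.category is Category.ACCEPTOR
        assert lab.novel_end_context == "intronic"

    def test_shared_acceptor_novel_donor(self, htt_like_model):
        lab = classify(J(3173218, 3174720), htt_like_model)
        assert lab.category is Category.DONOR
        assert lab.novel_end_context == "intronic"

    def test_exon_skip_joins_two_canonical_junctions(self, htt_like_model):
        lab = classify(J(3189093, 3204006), htt_like_model)
        assert lab.category is Category.SKIPPED_EXON
        assert len(lab.skipped_exon_indices) == 1

    def test_reciprocal_pair_is_added_exon_for_both(self):
        model = GeneModel("G", "c", "+", ((100, 200), (1000, 1100)))
        left = J(201, 400, "c")    # canonical donor -> intronic acceptor
        right = J(501, 1000, "c")  # intronic donor -> canonical acceptor
        both = [left, right]
        assert classify(left, model, both).category is Category.ADDED_EXON
        assert classify(right, model, both).category is Category.ADDED_EXON

    def test_without_partner_degrades_to_alternative_site(self):
        model = GeneModel("G", "c", "+", ((100, 200), (1000, 1100)))
        lab = classify(J(201, 400, "c"), model, [J(201, 400, "c")])
        assert lab.category is Category.ACCEPTOR
        assert lab.novel_end_context == "intronic"

    def test_skip_takes_precedence_over_added_exon(self):
        # joins donor of intron 1 to acceptor of intron 2: a skip, even though
        # a reciprocal-looking partner exists
        model = GeneModel("G", "c", "+",
                          ((100, 200), (300, 400), (500, 600)))
        skip = J(201, 500, "c")
        lab = classify(skip, model, [skip, J(301, 500, "c")])
        assert lab.category is Category.SKIPPED_EXON
        assert lab.skipped_exon_indices == (2,)

    def test_neither_end_shared_reports_composite(self):
        model = GeneModel("G", "c", "+", ((100, 200), (1000, 1100)))
        lab = classify(J(301, 400, "c"), model)
        assert lab.category is Category.ACCEPTOR
        assert "donor" in lab.notes and "acceptor" in lab.notes

    def test_novel_end_outside_gene_span_resolves_exonic(self):
        model = GeneModel("G", "c", "+", ((100, 200), (1000, 1100)))
        lab = classify(J(201, 1500, "c"), model)
        assert lab.category is Category.ACCEPTOR
        assert lab.novel_end_context == "exonic"

    def test_exonic_novel_acceptor_context(self):
        model = GeneModel("G", "c", "+", ((100, 200), (1000, 1100)))
        lab = classify(J(201, 1050, "c"), model)
        assert (lab.category, lab.novel_end_context) == (Category.ACCEPTOR,
                                                         "exonic")


class TestToyGeneTruthLabels:
    def test_classifier_reproduces_hand_assigned_labels(self):
        """Dual route: hand-constructed truth vs the decision cascade."""
        model, _, labels = build_toy_gene()
        all_junctions = (
            [J(gs, ge, "chrT") for gs, ge in labels]
            + sorted(canonical_junctions(model), key=Junction.key)
        )
        for (gs, ge), expected in labels.items():
            got = classify(J(gs, ge, "chrT"), model, all_junctions)
            assert got.category is expected.category, (gs, ge)
            assert got.novel_end_context == expected.novel_end_context
            assert got.skipped_exon_indices == expected.skipped_exon_indices

    def test_canonical_iff_in_canonical_set(self):
        model, _, labels = build_toy_gene()
        canon = canonical_junctions(model)
        for j in canon:
            assert classify(j, model).category is Category.CANONICAL
        for gs, ge in labels:
            assert (gs, ge) not in {c.key() for c in canon}
            assert classify(J(gs, ge, "chrT"), model).category \
                is not Category.CANONICAL


class TestStrandSymmetry:
    def test_mirroring_swaps_acceptor_and_donor(self):
        """Reflecting gene + junctions through a pivot (same strand label)
        reverses transcription order relative to the structure, so Acceptor
        and Donor swap while structural categories persist."""
        model, _, labels = build_toy_gene()
        pivot = 20000
        mirrored_exons = tuple(sorted((pivot - e, pivot - s)
                                      for s, e in model.exons))
        mirrored = GeneModel("M", "chrT", "+", mirrored_exons)

        def mirror_j(gs, ge):
            lo, hi = gs - 1, ge  # 0-based gap
            mlo, mhi = pivot - hi, pivot - lo
            return J(mlo + 1, mhi, "chrT")

        all_m = [mirror_j(gs, ge) for gs, ge in labels] + [
            mirror_j(j.gap_start, j.gap_end)
            for j in canonical_junctions(model)
        ]
        swap = {Category.ACCEPTOR: Category.DONOR,
                Category.DONOR: Category.ACCEPTOR}
        for (gs, ge), expected in labels.items():
            got = classify(mirror_j(gs, ge), mirrored, all_m)
            want = swap.get(expected.category, expected.category)
            assert got.category is want, (gs, ge)

    def test_minus_strand_shared_left_end_is_donor(self):
        plus = GeneModel("G", "c", "+", ((100, 200), (1000, 1100)))
        minus = GeneModel("G", "c", "-", ((100, 200), (1000, 1100)))
        assert classify(J(201, 400, "c", "+"), plus).category \
            is Category.ACCEPTOR
        assert classify(J(201, 400, "c", "-"), minus).category \
            is Category.DONOR


class TestTotality:
    @given(st.integers(50, 9000), st.integers(1, 2000))
    @settings(max_examples=200, deadline=None)
    def test_every_junction_gets_exactly_one_category(self, gs0, length):
        model, _, _ = build_toy_gene()
        lab = classify(J(gs0, gs0 + length - 1, "chrT"), model)
        assert lab.category in Category


class TestGroupLoci:
    def test_overlapping_junctions_share_a_locus(self):
        loci = group_loci([event(100, 200), event(150, 300)])
        assert len(loci) == 1 and len(loci[0].members) == 2

    def test_disjoint_junctions_split(self):
        loci = group_loci([event(100, 200), event(250, 300)], pad=0)
        assert len(loci) == 2

    def test_padding_can_join_neighbours(self):
        loci = group_loci([event(100, 200), event(250, 300)], pad=30)
        assert len(loci) == 1

    def test_every_event_in_exactly_one_locus(self):
        events = [event(s, s + 80) for s in range(0, 1000, 50)]
        loci = group_loci(events)
        assert sum(len(l.members) for l in loci) == len(events)
        ids = [l.locus_id for l in loci]
        assert ids == sorted(ids) == list(range(1, len(loci) + 1))

    def test_published_locus_e_junctions_group_together(self):
        coords = [(3189093, 3199731), (3189093, 3204006), (3199939, 3202976),
                  (3199939, 3202981), (3199939, 3204006), (3199939, 3204009)]
        loci = group_loci([event(gs, ge, chrom="chr4") for gs, ge in coords])
        assert len(loci) == 1 and len(loci[0].members) == 6


class TestCountAlternative:
    def test_counts_non_canonical(self):
        model = GeneModel("G", "c", "+", ((100, 200), (1000, 1100)))
        events = classify_events(
            [event(201, 1000, chrom="c"), event(201, 500, chrom="c")], model)
        assert count_alternative(events) == 1

    def test_empty_is_zero(self):
        assert count_alternative([]) == 0

    def test_unclassified_rejected(self):
        with pytest.raises(ValueError, match="unclassified"):
            count_alternative([event(100, 200)])
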