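"""Simulator contracts: determinism, projection, analytic truth, bias model."""

import numpy as np
import pysam
import pytest

from splicegaps.alignment_io import load_region, merge_groups, read_sample_sheet
from splicegaps.as_classify import Category
from splicegaps.coverage_profile import count_bases
from splicegaps.gene_model import GeneModel, canonical_junctions, derive_features
from splicegaps.junction_extract import aggregate, extract_gaps
from splicegaps.synthetic_data import (
    IsoformSpec,
    SampleDef,
    SimConfig,
    build_toy_gene,
    compute_truth,
    simulate,
    toy_cohort_config,
)


def small_config(**kw):
    defaults = dict(n_fragments=1500, group_sizes=(1, 1, 1), seed=5)
    defaults.update(kw)
    return toy_cohort_config(**defaults)


class TestDeterminism:
    def test_same_seed_byte_identical_sam(self, tmp_path):
        config, labels = small_config()
        r1 = simulate(config, tmp_path / "run1", truth_labels=labels)
        r2 = simulate(config, tmp_path / "run2", truth_labels=labels)
        for sid in r1.sam_paths:
            b1 = open(r1.sam_paths[sid], "rb").read()
            b2 = open(r2.sam_paths[sid], "rb").read()
            assert b1 == b2

    def test_different_seed_differs(self, tmp_path):
        c1, labels = small_config(seed=5)
        c2, _ = small_config(seed=6)
        r1 = simulate(c1, tmp_path / "a", truth_labels=labels)
        r2 = simulate(c2, tmp_path / "b", truth_labels=labels)
        sid = next(iter(r1.sam_paths))
        assert open(r1.sam_paths[sid], "rb").read() != \
            open(r2.sam_paths[sid], "rb").read()


class TestSamValidity:
    def test_sorted_parseable_paired(self, tmp_path):
        config, labels = small_config(n_fragments=400)
        res = simulate(config, tmp_path, truth_labels=labels)
        sid = config.samples[0].sample_id
        with pysam.AlignmentFile(res.sam_paths[sid]) as af:
            assert af.header["HD"]["SO"] == "coordinate"
            positions, n = [], 0
            for aln in af:
                n += 1
                positions.append(aln.reference_start)
                assert aln.is_paired and aln.is_proper_pair
                assert aln.cigarstring is not None
        assert n == 2 * config.samples[0].n_fragments
        assert positions == sorted(positions)

    def test_no_spurious_gaps(self, tmp_path):
        """Error-free alignments contain exactly the truth junctions."""
        config, labels = small_config(n_fragments=2500)
        res = simulate(config, tmp_path, truth_labels=labels)
        sheet = read_sample_sheet(res.sheet_path)
        _, superset = merge_groups(sheet, (config.model.chrom,
                                           *config.model.span))
        observed = {e.junction.key() for e in aggregate(superset, strand="+")}
        assert observed <= set(res.truth.junctions)


class TestTranscriptProjection:
    def test_minus_strand_junction_matches_canonical(self, tmp_path):
        model = GeneModel("G", "c", "-", ((100, 300), (800, 1000)))
        config = SimConfig(
            model=model,
            isoforms=(IsoformSpec("canonical", model.exons, 1.0),),
            samples=(SampleDef("s1", "A", 300),),
            read_length=50, frag_mean=120, frag_sd=10, three_prime_bias=0.0,
            seed=2,
        )
        res = simulate(config, tmp_path)
        recs = list(load_region(res.sam_paths["s1"], ("c", 0, 2000), "s1", "A"))
        gapped = [r for r in recs if len(r.blocks) > 1]
        assert gapped, "some mates must span the junction"
        (canon,) = canonical_junctions(model)
        for r in gapped:
            (j,) = extract_gaps(r, min_gap=10, strand="-")
            assert j.key() == canon.key()

    def test_all_blocks_inside_isoform_intervals(self, tmp_path):
        config, labels = small_config(n_fragments=300)
        res = simulate(config, tmp_path, truth_labels=labels)
        allowed = set()
        for iso in config.isoforms:
            for s, e in iso.exon_chain:
                allowed.update(range(s, e))
        sheet = read_sample_sheet(res.sheet_path)
        _, superset = merge_groups(sheet, (config.model.chrom,
                                           *config.model.span))
        for rec in superset[:500]:
            for s, e in rec.blocks:
                assert s in allowed and (e - 1) in allowed


class TestAnalyticTruth:
    def test_supports_within_3_sigma(self, cohort):
        config, labels, res, sheet, by_cond, superset = cohort
        observed = {e.junction.key(): e.support_total
                    for e in aggregate(superset, strand="+")}
        for key in res.truth.junctions:
            mean, sd = res.truth.expected_support(key)
            assert abs(observed.get(key, 0) - mean) <= 3 * sd, key

    def test_skip_isoform_support_scales_with_weight(self, cohort):
        """The single-exon-skip junction's expected support reflects its
        0.02 mixture weight relative to canonical junction flow."""
        config, labels, res, *_ = cohort
        skip_mean, _ = res.truth.expected_support((3201, 5000))
        canon_mean, _ = res.truth.expected_support((4201, 5000))
        # canonical junction 4 is carried by isoforms totalling 0.96 weight
        assert skip_mean / (skip_mean + canon_mean) == pytest.approx(
            0.02 / 0.98, rel=0.15)

    def test_uniform_coverage_when_bias_disabled(self, tmp_path):
        """lambda = 0: interior exons are covered evenly (analytically), and
        observation tracks the analytic expectation within 3 sigma."""
        config, labels = small_config(n_fragments=3000, three_prime_bias=0.0,
                                      seed=8)
        res = simulate(config, tmp_path, truth_labels=labels)
        means, sds = res.truth.expected_feature_bases()
        feats = res.truth.features
        interior = [m / f.length for f, m in zip(feats, means)
                    if f.kind == "exon" and 3 <= f.index <= 7]
        assert max(interior) / min(interior) < 1.05
        sheet = read_sample_sheet(res.sheet_path)
        _, superset = merge_groups(sheet, (config.model.chrom,
                                           *config.model.span))
        counts, _ = count_bases(superset, derive_features(config.model))
        total = sum(counts.values())
        for i in range(len(feats)):
            if sds[i] == 0:
                assert total[i] == 0
            else:
                assert abs(total[i] - means[i]) <= 3 * sds[i], feats[i]


class TestUnsplicedBackground:
    def test_premrna_raises_intron_coverage_without_new_junctions(self, tmp_path):
        base_cfg, labels = small_config(n_fragments=2500, seed=9)
        pre_cfg, _ = small_config(n_fragments=2500, seed=9,
                                  premrna_weight=0.08)
        base = simulate(base_cfg, tmp_path / "base", truth_labels=labels)
        pre = simulate(pre_cfg, tmp_path / "pre", truth_labels=labels)
        assert set(pre.truth.junctions) == set(base.truth.junctions)

        def intron_cov(res, cfg):
            sheet = read_sample_sheet(res.sheet_path)
            _, sup = merge_groups(sheet, (cfg.model.chrom, *cfg.model.span))
            feats = derive_features(cfg.model)
            counts, _ = count_bases(sup, feats)
            total = sum(counts.values())
            juncs = {e.junction.key() for e in aggregate(sup, strand="+")}
            return ({f.index: int(total[i]) for i, f in enumerate(feats)
                     if f.kind == "intron"}, juncs)

        cov_base, j_base = intron_cov(base, base_cfg)
        cov_pre, j_pre = intron_cov(pre, pre_cfg)
        assert j_pre == j_base  # no junction gained or lost
        # 3'-biased sampling concentrates the pre-mRNA signal in 3' introns;
        # the 3'-most intron is silent without pre-mRNA and covered with it
        assert cov_base[7] == 0 and cov_pre[7] > 0
        assert sum(cov_pre.values()) > 2 * sum(cov_base.values())


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        model, isoforms, _ = build_toy_gene()
        with pytest.raises(ValueError, match="sum"):
            SimConfig(model=model,
                      isoforms=(IsoformSpec("c", model.exons, 0.5),),
                      samples=(SampleDef("s", "A", 10),))

    def test_fragment_mean_below_read_length_rejected(self):
        model, _, _ = build_toy_gene()
        with pytest.raises(ValueError, match="read_length"):
            SimConfig(model=model,
                      isoforms=(IsoformSpec("c", model.exons, 1.0),),
                      samples=(SampleDef("s", "A", 10),),
                      read_length=101, frag_mean=80)

    def test_transcript_shorter_than_fragment_fails(self, tmp_path):
        model = GeneModel("G", "c", "+", ((0, 60), (100, 160)))
        config = SimConfig(model=model,
                           isoforms=(IsoformSpec("c", model.exons, 1.0),),
                           samples=(SampleDef("s", "A", 10),),
                           read_length=50, frag_mean=200, frag_sd=10)
        with pytest.raises(ValueError, match="shorter"):
            simulate(config, tmp_path)

    def test_overlapping_chain_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            IsoformSpec("bad", ((0, 100), (50, 200)), 1.0)
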