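"""Shared fixtures: tiny annotation files and the simulated toy cohort."""

from __future__ import annotations

import pytest

from splicegaps.alignment_io import merge_groups, read_sample_sheet
from splicegaps.gene_model import GeneModel
from splicegaps.synthetic_data import simulate, toy_cohort_config

THREE_EXON = ((100, 200), (300, 400), (500, 600))


@pytest.fixture
def three_exon_model() -> GeneModel:
    return GeneModel("G1", "chr1", "+", THREE_EXON, "G1-001")


def write_gtf(path, exons=THREE_EXON, chrom="chr1", strand="+",
              gene_id="G1", transcript_id="G1-001") -> str:
    """GENCODE-style GTF with one exon record per interval (1-based)."""
    lines = []
    for s, e in exons:
        attrs = f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'
        lines.append("\t".join(
            [chrom, "test", "exon", str(s + 1), str(e), ".", strand, ".", attrs]
        ))
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def write_bed12_line(path, exons=THREE_EXON, chrom="chr1", strand="+",
                     name="G1-001") -> str:
    start, end = exons[0][0], exons[-1][1]
    sizes = ",".join(str(e - s) for s, e in exons)
    starts = ",".join(str(s - start) for s, _ in exons)
    path.write_text("\t".join(
        [chrom, str(start), str(end), name, "0", strand, str(start),
         str(end), "0", str(len(exons)), sizes, starts]
    ) + "\n")
    return str(path)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """The standard toy cohort: 3 groups of (2, 2, 4) samples x 20,000 fragments.

    Simulated once per session; returns (config, truth_labels, sim_result,
    sheet, by_condition, superset).
    """
    out = tmp_path_factory.mktemp("cohort")
    config, labels = toy_cohort_config(n_fragments=20000, seed=0)
    result = simulate(config, out, truth_labels=labels)
    sheet = read_sample_sheet(result.sheet_path)
    region = (config.model.chrom, *config.model.span)
    by_condition, superset = merge_groups(sheet, region)
    return config, labels, result, sheet, by_condition, superset
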