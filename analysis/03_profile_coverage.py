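#!/usr/bin/env python
"""Per-feature coverage profile of the cohort and the pre-mRNA contrast.

Writes the exon/intron coverage table for the simulated cohort (showing the
3'-biased rightward skew), then re-simulates a small cohort with an
unspliced pre-mRNA background isoform to show that intronic coverage rises
while the junction table is unchanged — the signature that distinguishes
pre-mRNA (or retained-intron) signal from genuine splicing events.
"""

import pathlib

import pandas as pd

from splicegaps.alignment_io import merge_groups, read_sample_sheet
from splicegaps.coverage_profile import count_bases, summarize, write_coverage_tsv
from splicegaps.gene_model import derive_features
from splicegaps.junction_extract import aggregate
from splicegaps.synthetic_data import simulate, toy_cohort_config

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config, labels = toy_cohort_config(n_fragments=20000, seed=0)
    sheet = read_sample_sheet(SCRATCH / "cohort" / "sample_sheet.tsv")
    _, superset = merge_groups(sheet, (config.model.chrom, *config.model.span))
    feats = derive_features(config.model)
    counts, _ = count_bases(superset, feats)
    cov = summarize(counts, sheet, feats)
    write_coverage_tsv(cov, RESULTS / "cohort_coverage.tsv")
    exon_cov = [sum(fc.mean_coverage_per_sample_by_condition.values())
                for fc in cov if fc.feature.kind == "exon"]
    print(f"per-exon mean coverage 5'->3': "
          f"{[round(c, 1) for c in exon_cov]}")
    print(f"3'/5' exon coverage ratio {exon_cov[-1] / exon_cov[0]:.1f} "
          f"(rightward skew from the 3'-biased positional model)")

    rows = []
    for weight, name in ((0.0, "no_premrna"), (0.08, "premrna_0.08")):
        cfg, _ = toy_cohort_config(n_fragments=2500, group_sizes=(1, 1, 1),
                                   seed=2, premrna_weight=weight)
        res = simulate(cfg, SCRATCH / name, truth_labels=labels)
        sh = read_sample_sheet(res.sheet_path)
        _, sup = merge_groups(sh, (cfg.model.chrom, *cfg.model.span))
        total = sum(count_bases(sup, feats)[0].values())
        introns = sum(int(t) for f, t in zip(feats, total)
                      if f.kind == "intron")
        rows.append({"run": name, "intron_bases": introns,
                     "n_junctions": len(aggregate(sup, strand="+"))})
    contrast = pd.DataFrame(rows)
    contrast.to_csv(RESULTS / "premrna_contrast.tsv", sep="\t", index=False)
    print(contrast.to_string(index=False))
    print("pre-mRNA background raises intron coverage with an unchanged "
          "junction count")


if __name__ == "__main__":
    main()
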