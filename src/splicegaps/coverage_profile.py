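"""Per-feature (exon/intron) aligned-base counting and coverage summaries.

Every reference-aligned base of every read is assigned to the unique feature
containing it ("every aligned base is counted"); gapped positions contribute
nothing.  Mean per-sample coverage divides the per-condition base count first
by feature length and then by the number of samples in the condition.  Bases
upstream/downstream of the gene span are excluded from feature totals but
reported in an ``outside`` bucket for diagnostics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_io import AlignmentRecord, SampleSheet
from .gene_model import Feature

__all__ = [
    "FeatureCoverage",
    "count_bases",
    "summarize",
    "coverage_frame",
    "write_coverage_tsv",
    "plot_coverage",
]


@dataclass(frozen=True)
class FeatureCoverage:
    feature: Feature
    aligned_bases_by_condition: dict[str, int]
    mean_coverage_per_sample_by_condition: dict[str, float]


def count_bases(records: Iterable[AlignmentRecord],
                features: Sequence[Feature],
                ) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Count aligned bases per feature per condition.

    Returns ``(counts, outside)`` where ``counts[condition]`` is an int array
    aligned with ``features`` (same order) and ``outside[condition]`` counts
    aligned bases falling outside the contiguous feature span.
    """
    feats = list(features)
    genomic = sorted(range(len(feats)), key=lambda i: feats[i].start)
    starts = np.array([feats[i].start for i in genomic])
    ends = np.array([feats[i].end for i in genomic])
    if np.any(starts[1:] != ends[:-1]):
        raise ValueError("features must be contiguous and non-overlapping")
    lo, hi = int(starts[0]), int(ends[-1])

    counts: dict[str, np.ndarray] = {}
    outside: dict[str, int] = {}
    for rec in records:
        cond = rec.condition
        if cond not in counts:
            counts[cond] = np.zeros(len(feats), dtype=np.int64)
            outside[cond] = 0
        arr = counts[cond]
        for s, e in rec.blocks:
            if e <= lo or s >= hi:
                outside[cond] += e - s
                continue
            cs, ce = max(s, lo), min(e, hi)
            outside[cond] += (cs - s) + (e - ce)
            i0 = int(np.searchsorted(starts, cs, side="right")) - 1
            i1 = int(np.searchsorted(starts, ce - 1, side="right")) - 1
            if i0 == i1:
                arr[genomic[i0]] += ce - cs
            else:
                for i in range(i0, i1 + 1):
                    ov = min(ce, int(ends[i])) - max(cs, int(starts[i]))
                    arr[genomic[i]] += ov
    return counts, outside


def summarize(counts: dict[str, np.ndarray],
              sheet: SampleSheet,
              features: Sequence[Feature]) -> list[FeatureCoverage]:
    """Two-step normalization: bases / feature length / samples-per-condition."""
    feats = list(features)
    conditions = sheet.conditions
    for cond in counts:
        if cond not in conditions:
            raise ValueError(f"condition {cond!r} not present in sample sheet")
    for cond in conditions:
        if sheet.n_samples(cond) == 0:
            raise ValueError(f"condition {cond!r} has zero samples")
    out = []
    for i, f in enumerate(feats):
        bases = {c: int(counts[c][i]) if c in counts else 0 for c in conditions}
        mean_cov = {
            c: bases[c] / (f.length * sheet.n_samples(c)) for c in conditions
        }
        out.append(FeatureCoverage(f, bases, mean_cov))
    return out


def coverage_frame(cov: Sequence[FeatureCoverage]) -> pd.DataFrame:
    if not cov:
        return pd.DataFrame()
    conditions = list(cov[0].aligned_bases_by_condition)
    rows = []
    for fc in cov:
        row: dict = {
            "kind": fc.feature.kind,
            "index": fc.feature.index,
            "start": fc.feature.start,
            "end": fc.feature.end,
            "length": fc.feature.length,
        }
        for c in conditions:
            row[f"bases_{c}"] = fc.aligned_bases_by_condition[c]
        for c in conditions:
            row[f"mean_cov_{c}"] = fc.mean_coverage_per_sample_by_condition[c]
        rows.append(row)
    return pd.DataFrame(rows)


def write_coverage_tsv(cov: Sequence[FeatureCoverage],
                       path: str | os.PathLike) -> None:
    coverage_frame(cov).to_csv(os.fspath(path), sep="\t", index=False,
                               float_format="%.6g")


def plot_coverage(cov: Sequence[FeatureCoverage], path: str | os.PathLike,
                  title: str = "") -> None:
    """Paired bar chart: per-exon coverage above, per-intron below."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = list(cov[0].aligned_bases_by_condition) if cov else []
    exons = [fc for fc in cov if fc.feature.kind == "exon"]
    introns = [fc for fc in cov if fc.feature.kind == "intron"]
    fig, (ax_top, ax_bot) = plt.subplots(
        2, 1, figsize=(max(6, 0.35 * len(exons) * max(1, len(conditions))), 6),
        sharex=False,
    )
    width = 0.8 / max(1, len(conditions))
    for axis, group, label in ((ax_top, exons, "exon"), (ax_bot, introns, "intron")):
        x = np.arange(len(group))
        for k, c in enumerate(conditions):
            vals = [fc.mean_coverage_per_sample_by_condition[c] for fc in group]
            axis.bar(x + k * width, vals, width=width, label=c)
        axis.set_xticks(x + 0.4 - width / 2)
        axis.set_xticklabels([str(fc.feature.index) for fc in group], fontsize=7)
        axis.set_ylabel(f"mean coverage / sample ({label}s)")
    ax_bot.invert_yaxis()
    ax_top.legend(fontsize=8)
    if title:
        ax_top.set_title(title)
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=120)
    plt.close(fig)
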