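"""Seeded simulator of spliced paired-end alignments with analytic ground truth.

Reads are generated directly as alignments (SAM), not as sequences: the
pipeline under test consumes alignments, so sequencing-error and aligner
models are deliberately out of scope.  A fragment is drawn by

1. choosing an isoform by mixture weight,
2. choosing the fragment **3' end** position ``e`` along the isoform's
   transcript with probability proportional to ``exp(-lambda * d3)`` where
   ``d3`` is the distance from the transcript 3' end (``lambda = 0`` gives
   uniform coverage; ``lambda > 0`` emulates the 3' bias of poly-A selected
   libraries),
3. choosing the fragment length from a discretised normal; (end, length)
   pairs whose fragment would not fit upstream of ``e`` are redrawn, so the
   joint distribution is the independent product restricted to fitting pairs
   (at ``lambda = 0`` this is uniform placement of a fitting fragment).

Both mates (``read_length`` nt each, possibly overlapping) are projected
through the isoform's exon chain onto the reference, producing N-gapped
CIGAR alignments.  Because the sampling distributions are discrete and
fully specified, the expected read support of every junction and the
expected aligned-base count of every exon/intron feature — with exact
per-fragment variances — are computed analytically and shipped as the
:class:`TruthSet`.  Identical seeds give byte-identical SAM output.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam
from scipy.stats import norm

from .as_classify import ASLabel, Category, classify
from .gene_model import Feature, GeneModel, Junction, derive_features
from .alignment_io import SampleEntry, SampleSheet

__all__ = [
    "IsoformSpec",
    "SampleDef",
    "SimConfig",
    "TruthJunction",
    "TruthSet",
    "SimResult",
    "simulate",
    "compute_truth",
    "build_toy_gene",
    "toy_cohort_config",
]

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class IsoformSpec:
    """One transcript isoform of the mixture.

    ``exon_chain`` lists the genomic intervals (0-based half-open, increasing)
    spliced together in the mature molecule; an ``unspliced`` isoform models
    pre-mRNA background (a single interval spanning introns is typical).
    """

    name: str
    exon_chain: tuple[tuple[int, int], ...]
    weight: float
    unspliced: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"isoform {self.name}: weight must be in [0, 1]")
        prev = None
        for s, e in self.exon_chain:
            if e <= s:
                raise ValueError(f"isoform {self.name}: empty interval ({s}, {e})")
            if prev is not None and s <= prev:
                raise ValueError(
                    f"isoform {self.name}: exon_chain must be strictly increasing "
                    f"and non-touching near ({s}, {e})"
                )
            prev = e


@dataclass(frozen=True)
class SampleDef:
    sample_id: str
    condition: str
    n_fragments: int


@dataclass(frozen=True)
class SimConfig:
    model: GeneModel
    isoforms: tuple[IsoformSpec, ...]
    samples: tuple[SampleDef, ...]
    read_length: int = 101
    frag_mean: float = 300.0
    frag_sd: float = 50.0
    three_prime_bias: float = 0.001  # exponential decay rate per nt from 3' end
    seed: int = 0
    chrom_length: int = 0  # 0: derived from the gene span

    def __post_init__(self) -> None:
        total = sum(i.weight for i in self.isoforms)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isoform weights must sum to 1, got {total}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.frag_mean < self.read_length:
            raise ValueError("fragment mean must be >= read_length")
        if self.three_prime_bias < 0:
            raise ValueError("three_prime_bias must be >= 0")

    @property
    def weights(self) -> np.ndarray:
        return np.array([i.weight for i in self.isoforms])

    @property
    def reference_length(self) -> int:
        return self.chrom_length or self.model.span[1] + 1000

    def n_fragments_by_condition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.samples:
            out[s.condition] = out.get(s.condition, 0) + s.n_fragments
        return out


# ---------------------------------------------------------------------------
# Transcript coordinate machinery
# ---------------------------------------------------------------------------

class _Transcript:
    """Transcript-coordinate view of an isoform chain (strand-aware)."""

    def __init__(self, iso: IsoformSpec, strand: str):
        self.iso = iso
        self.strand = strand
        chain = list(iso.exon_chain)
        self.order = chain if strand == "+" else chain[::-1]  # transcription order
        lens = [e - s for s, e in self.order]
        self.cum = np.concatenate([[0], np.cumsum(lens)])
        self.T = int(self.cum[-1])

    def tx_to_ref_blocks(self, ts: int, te: int) -> tuple[tuple[int, int], ...]:
        """Map transcript interval [ts, te) to genomic blocks (sorted)."""
        blocks = []
        for k, (a, b) in enumerate(self.order):
            c0, c1 = int(self.cum[k]), int(self.cum[k + 1])
            lo, hi = max(ts, c0), min(te, c1)
            if hi <= lo:
                continue
            if self.strand == "+":
                blocks.append((a + (lo - c0), a + (hi - c0)))
            else:
                blocks.append((b - (hi - c0), b - (lo - c0)))
        blocks.sort()
        return tuple(blocks)

    def ref_to_tx_intervals(self, s: int, e: int) -> list[tuple[int, int]]:
        """Transcript intervals covered by genomic interval [s, e)."""
        out = []
        for k, (a, b) in enumerate(self.order):
            lo, hi = max(s, a), min(e, b)
            if hi <= lo:
                continue
            c0 = int(self.cum[k])
            if self.strand == "+":
                out.append((c0 + (lo - a), c0 + (hi - a)))
            else:
                out.append((c0 + (b - hi), c0 + (b - lo)))
        return out

    def junctions(self, chrom: str) -> list[tuple[Junction, int]]:
        """(junction, transcript boundary) for each splice in the chain.

        A mate supports the junction iff it covers transcript positions
        ``boundary - 1`` and ``boundary``.
        """
        out = []
        for k in range(len(self.order) - 1):
            a1, b1 = self.order[k]
            a2, b2 = self.order[k + 1]
            if self.strand == "+":
                gap = (b1, a2)
            else:
                gap = (b2, a1)
            out.append((Junction(chrom, gap[0] + 1, gap[1], self.strand),
                        int(self.cum[k + 1])))
        return out


def _grids(T: int, cfg: SimConfig):
    """Discrete fragment-length and 3'-end distributions for one transcript."""
    L = cfg.read_length
    lmin = max(L, int(round(cfg.frag_mean - 4 * cfg.frag_sd)))
    lmax = min(int(round(cfg.frag_mean + 4 * cfg.frag_sd)), T)
    if lmin > lmax:
        raise ValueError(
            f"transcript of length {T} nt is shorter than the minimum fragment "
            f"length {lmin} nt; cannot place fragments"
        )
    len_grid = np.arange(lmin, lmax + 1)
    len_pmf = norm.pdf(len_grid, cfg.frag_mean, cfg.frag_sd)
    len_pmf /= len_pmf.sum()
    e_grid = np.arange(lmin - 1, T)
    e_pmf = np.exp(-cfg.three_prime_bias * (T - 1 - e_grid).astype(float))
    e_pmf /= e_pmf.sum()
    return len_grid, len_pmf, e_grid, e_pmf


def _joint_weight(len_grid, len_pmf, e_grid, e_pmf) -> np.ndarray:
    """W[e, l]: exact joint pmf of (3' end, length).

    The product distribution is restricted to pairs that fit the transcript
    (``l <= e + 1``) and renormalised globally — the distribution obtained by
    redrawing non-fitting (end, length) pairs.  At ``lambda = 0`` this is
    uniform placement of a normal-length fragment conditioned to fit, giving
    flat coverage away from the transcript edges.
    """
    fits = len_grid[None, :] <= e_grid[:, None] + 1
    W = e_pmf[:, None] * len_pmf[None, :] * fits
    return W / W.sum()


# ---------------------------------------------------------------------------
# Analytic truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthJunction:
    junction: Junction
    label: ASLabel
    source_isoforms: tuple[str, ...]
    mean_per_fragment: float  # E[mates spanning] per sequenced fragment
    var_per_fragment: float


@dataclass(frozen=True)
class TruthSet:
    """Analytic expectations for the simulated cohort.

    Per-fragment moments are exact under the sampling scheme; scaling by the
    fragment count of a condition (or the whole cohort) gives mean and
    variance of observed junction supports and per-feature base counts.
    """

    junctions: dict[tuple[int, int], TruthJunction]
    features: tuple[Feature, ...]
    feature_mean_per_fragment: np.ndarray
    feature_var_per_fragment: np.ndarray
    n_by_condition: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.n_by_condition.values())

    def _n(self, condition: Optional[str]) -> int:
        return self.n_total if condition is None else self.n_by_condition[condition]

    def expected_support(self, key: tuple[int, int],
                         condition: Optional[str] = None) -> tuple[float, float]:
        """(mean, sd) of the read support of a truth junction."""
        tj = self.junctions[key]
        n = self._n(condition)
        return n * tj.mean_per_fragment, float(np.sqrt(n * tj.var_per_fragment))

    def expected_feature_bases(self, condition: Optional[str] = None
                               ) -> tuple[np.ndarray, np.ndarray]:
        """(means, sds) of aligned-base counts per feature (truth order)."""
        n = self._n(condition)
        return (n * self.feature_mean_per_fragment,
                np.sqrt(n * self.feature_var_per_fragment))


def compute_truth(config: SimConfig,
                  truth_labels: Optional[dict[tuple[int, int], ASLabel]] = None
                  ) -> TruthSet:
    """Exact expected supports and feature base counts for ``config``."""
    model = config.model
    L = config.read_length
    features = tuple(derive_features(model))
    nfeat = len(features)

    junc_mean: dict[tuple[int, int], float] = {}
    junc_m2: dict[tuple[int, int], float] = {}
    junc_src: dict[tuple[int, int], list[str]] = {}
    junc_obj: dict[tuple[int, int], Junction] = {}
    feat_mean = np.zeros(nfeat)
    feat_m2 = np.zeros(nfeat)

    for iso in config.isoforms:
        tx = _Transcript(iso, model.strand)
        len_grid, len_pmf, e_grid, e_pmf = _grids(tx.T, config)
        W = _joint_weight(len_grid, len_pmf, e_grid, e_pmf)
        S = e_grid[:, None] - len_grid[None, :] + 1  # mate1 start (tx coords)
        w = iso.weight

        for junction, p in tx.junctions(model.chrom):
            spans1 = (S >= p - L + 1) & (S <= p - 1)
            spans2 = ((e_grid >= p) & (e_grid <= p + L - 2))[:, None]
            X = spans1.astype(np.int64) + spans2
            key = junction.key()
            junc_mean[key] = junc_mean.get(key, 0.0) + w * float((W * X).sum())
            junc_m2[key] = junc_m2.get(key, 0.0) + w * float((W * X * X).sum())
            junc_src.setdefault(key, []).append(iso.name)
            junc_obj[key] = junction

        m2start = e_grid[:, None] - L + 1  # mate2 start (tx coords)
        for fi, f in enumerate(features):
            ivs = tx.ref_to_tx_intervals(f.start, f.end)
            if not ivs:
                continue
            D = np.zeros_like(W)
            for c, d in ivs:
                D += np.clip(np.minimum(S + L, d) - np.maximum(S, c), 0, None)
                D += np.clip(np.minimum(m2start + L, d) - np.maximum(m2start, c),
                             0, None)
            feat_mean[fi] += w * float((W * D).sum())
            feat_m2[fi] += w * float((W * D * D).sum())

    all_truth_junctions = list(junc_obj.values())
    truth: dict[tuple[int, int], TruthJunction] = {}
    for key, jct in junc_obj.items():
        if truth_labels and key in truth_labels:
            label = truth_labels[key]
        else:
            label = classify(jct, model, all_truth_junctions)
        truth[key] = TruthJunction(
            junction=jct,
            label=label,
            source_isoforms=tuple(junc_src[key]),
            mean_per_fragment=junc_mean[key],
            var_per_fragment=junc_m2[key] - junc_mean[key] ** 2,
        )

    return TruthSet(
        junctions=truth,
        features=features,
        feature_mean_per_fragment=feat_mean,
        feature_var_per_fragment=feat_m2 - feat_mean ** 2,
        n_by_condition=config.n_fragments_by_condition(),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimResult:
    sam_paths: dict[str, str]
    sheet_path: str
    truth_junctions_path: str
    truth_features_path: str
    config_path: str
    truth: TruthSet
    sheet: SampleSheet


def _cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = [f"{blocks[0][1] - blocks[0][0]}M"]
    for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
        parts.append(f"{s1 - e0}N")
        parts.append(f"{e1 - s1}M")
    return "".join(parts)


def _sample_fragments(rng: np.random.Generator, n: int,
                      grids) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (3' end, length) draws for ``n`` fragments of one isoform.

    Pairs are drawn independently and redrawn together while the fragment
    does not fit upstream of its 3' end, matching :func:`_joint_weight`.
    """
    len_grid, len_pmf, e_grid, e_pmf = grids
    e = rng.choice(e_grid, size=n, p=e_pmf)
    length = rng.choice(len_grid, size=n, p=len_pmf)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = length > e + 1
        if not bad.any():
            return e, length
        nbad = int(bad.sum())
        e[bad] = rng.choice(e_grid, size=nbad, p=e_pmf)
        length[bad] = rng.choice(len_grid, size=nbad, p=len_pmf)
    raise RuntimeError(
        "exceeded resampling budget drawing fragments that fit the "
        "transcript; check fragment length parameters against transcript length"
    )


def simulate(config: SimConfig, out_dir: str | os.PathLike,
             truth_labels: Optional[dict[tuple[int, int], ASLabel]] = None,
             ) -> SimResult:
    """Write one coordinate-sorted SAM per sample, a sample sheet and truth TSVs."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    model = config.model
    L = config.read_length
    txs = [_Transcript(iso, model.strand) for iso in config.isoforms]
    grids = [_grids(tx.T, config) for tx in txs]
    truth = compute_truth(config, truth_labels=truth_labels)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": model.chrom, "LN": config.reference_length}],
    }
    root = np.random.SeedSequence(config.seed)
    child_seeds = root.spawn(len(config.samples))

    sam_paths: dict[str, str] = {}
    sheet_entries = []
    for sample, ss in zip(config.samples, child_seeds):
        rng = np.random.default_rng(ss)
        iso_idx = rng.choice(len(config.isoforms), size=sample.n_fragments,
                             p=config.weights)
        reads = []  # (pos, qname, flag, cigar, mate_pos, tlen)
        frag_no = 0
        for k, tx in enumerate(txs):
            n_k = int((iso_idx == k).sum())
            if n_k == 0:
                continue
            e, length = _sample_fragments(rng, n_k, grids[k])
            s = e - length + 1
            for j in range(n_k):
                ts1, te1 = int(s[j]), int(s[j]) + L
                ts2, te2 = int(e[j]) + 1 - L, int(e[j]) + 1
                b1 = tx.tx_to_ref_blocks(ts1, te1)
                b2 = tx.tx_to_ref_blocks(ts2, te2)
                qname = f"{sample.sample_id}.{frag_no:07d}"
                frag_no += 1
                left_first = b1[0][0] <= b2[0][0]
                span_lo = min(b1[0][0], b2[0][0])
                span_hi = max(b1[-1][1], b2[-1][1])
                tlen = span_hi - span_lo
                f1 = 99 if left_first else 83
                f2 = 147 if left_first else 163
                reads.append((b1[0][0], qname, f1, _cigar(b1), b2[0][0],
                              tlen if left_first else -tlen))
                reads.append((b2[0][0], qname, f2, _cigar(b2), b1[0][0],
                              -tlen if left_first else tlen))
        reads.sort(key=lambda r: (r[0], r[1], r[2]))

        path = os.path.join(out_dir, f"{sample.sample_id}.sam")
        with pysam.AlignmentFile(path, "w", header=header) as af:
            for pos, qname, flag, cigar, mate_pos, tlen in reads:
                a = pysam.AlignedSegment(af.header)
                a.query_name = qname
                a.flag = flag
                a.reference_id = 0
                a.reference_start = pos
                a.mapping_quality = 255
                a.cigarstring = cigar
                a.next_reference_id = 0
                a.next_reference_start = mate_pos
                a.template_length = tlen
                af.write(a)
        sam_paths[sample.sample_id] = path
        sheet_entries.append(SampleEntry(sample.sample_id, path, sample.condition))

    sheet = SampleSheet(tuple(sheet_entries))
    sheet_path = os.path.join(out_dir, "sample_sheet.tsv")
    with open(sheet_path, "w") as fh:
        fh.write("sample_id\tpath\tcondition\n")
        for entry in sheet_entries:
            fh.write(f"{entry.sample_id}\t{os.path.basename(entry.path)}\t"
                     f"{entry.condition}\n")

    tj_path = os.path.join(out_dir, "truth_junctions.tsv")
    with open(tj_path, "w") as fh:
        fh.write("chrom\tgap_start\tgap_end\tstrand\tcategory\t"
                 "expected_support\tsd_support\tsource_isoforms\n")
        for key in sorted(truth.junctions):
            tj = truth.junctions[key]
            mean, sd = truth.expected_support(key)
            fh.write(
                f"{tj.junction.chrom}\t{tj.junction.gap_start}\t"
                f"{tj.junction.gap_end}\t{tj.junction.strand}\t"
                f"{tj.label.category.value}\t{mean:.4f}\t{sd:.4f}\t"
                f"{','.join(tj.source_isoforms)}\n"
            )

    tf_path = os.path.join(out_dir, "truth_features.tsv")
    means, sds = truth.expected_feature_bases()
    with open(tf_path, "w") as fh:
        fh.write("kind\tindex\tstart\tend\texpected_bases\tsd_bases\n")
        for f, m, sd in zip(truth.features, means, sds):
            fh.write(f"{f.kind}\t{f.index}\t{f.start}\t{f.end}\t"
                     f"{m:.4f}\t{sd:.4f}\n")

    cfg_path = os.path.join(out_dir, "sim_config.json")
    with open(cfg_path, "w") as fh:
        json.dump(
            {
                "gene_id": model.gene_id,
                "chrom": model.chrom,
                "strand": model.strand,
                "exons": list(model.exons),
                "isoforms": [
                    {"name": i.name, "exon_chain": list(i.exon_chain),
                     "weight": i.weight, "unspliced": i.unspliced}
                    for i in config.isoforms
                ],
                "samples": [
                    {"sample_id": s.sample_id, "condition": s.condition,
                     "n_fragments": s.n_fragments}
                    for s in config.samples
                ],
                "read_length": config.read_length,
                "frag_mean": config.frag_mean,
                "frag_sd": config.frag_sd,
                "three_prime_bias": config.three_prime_bias,
                "seed": config.seed,
            },
            fh, indent=1,
        )

    return SimResult(sam_paths, sheet_path, tj_path, tf_path, cfg_path,
                     truth, sheet)


# ---------------------------------------------------------------------------
# Toy cohort: a compact multi-locus gene exercising every AS pattern
# ---------------------------------------------------------------------------

def build_toy_gene() -> tuple[GeneModel, tuple[IsoformSpec, ...],
                              dict[tuple[int, int], ASLabel]]:
    """A compact 8-exon gene with one instance of each detectable AS pattern.

    Alternative isoforms (mixture weights set by :func:`toy_cohort_config`):

    * alternative acceptor with an intronic novel end,
    * alternative acceptor with an exonic novel end (on the double-skip isoform),
    * alternative donor,
    * single and double exon skips,
    * a novel internal ("added") exon producing a reciprocal junction pair.

    Returns the model, the isoform specs (weights filled by the cohort
    config) and the hand-assigned truth label of every novel junction.
    """
    e = [(1000, 1200), (2000, 2200), (3000, 3200), (4000, 4200),
         (5000, 5200), (6000, 6200), (7000, 7200), (8000, 8600)]
    model = GeneModel("TOYG", "chrT", "+", tuple(e), "TOYG-001")
    isoforms = (
        IsoformSpec("canonical", tuple(e), 0.0),
        IsoformSpec("alt_acceptor_intronic",
                    (e[0], e[1], (2600, 3200), e[3], e[4], e[5], e[6], e[7]), 0.0),
        IsoformSpec("alt_donor",
                    (e[0], e[1], e[2], e[3], (5000, 5300), e[5], e[6], e[7]), 0.0),
        IsoformSpec("skip_exon4",
                    (e[0], e[1], e[2], e[4], e[5], e[6], e[7]), 0.0),
        IsoformSpec("skip_exons67_alt_acceptor",
                    (e[0], (2050, 2200), e[2], e[3], e[4], e[7]), 0.0),
        IsoformSpec("added_exon",
                    (e[0], e[1], e[2], e[3], e[4], e[5], (6500, 6580), e[6], e[7]),
                    0.0),
    )
    labels = {
        (2201, 2600): ASLabel(Category.ACCEPTOR, "intronic"),
        (5301, 6000): ASLabel(Category.DONOR, "intronic"),
        (3201, 5000): ASLabel(Category.SKIPPED_EXON, "none", (4,)),
        (1201, 2050): ASLabel(Category.ACCEPTOR, "exonic"),
        (5201, 8000): ASLabel(Category.SKIPPED_EXON, "none", (6, 7)),
        (6201, 6500): ASLabel(Category.ADDED_EXON, "intronic",
                              notes="partner=6581-7000"),
        (6581, 7000): ASLabel(Category.ADDED_EXON, "intronic",
                              notes="partner=6201-6500"),
    }
    return model, isoforms, labels


def toy_cohort_config(n_fragments: int = 20000,
                      group_sizes: tuple[int, int, int] = (2, 2, 4),
                      seed: int = 0,
                      premrna_weight: float = 0.0,
                      three_prime_bias: float = 0.001,
                      ) -> tuple[SimConfig, dict[tuple[int, int], ASLabel]]:
    """The standard toy cohort: 3 condition groups of unequal size.

    The canonical isoform carries weight ``0.90 - premrna_weight`` and each
    of the five alternative isoforms 0.02, mirroring a dominant canonical
    form with low-abundance alternatives; ``premrna_weight > 0`` adds an
    unspliced pre-mRNA background isoform spanning the whole gene.
    """
    model, iso_specs, labels = build_toy_gene()
    alt_w = 0.02
    canonical_w = 1.0 - 5 * alt_w - premrna_weight
    isoforms = [
        IsoformSpec(iso_specs[0].name, iso_specs[0].exon_chain, canonical_w),
    ]
    isoforms += [
        IsoformSpec(i.name, i.exon_chain, alt_w) for i in iso_specs[1:]
    ]
    if premrna_weight > 0:
        isoforms.append(
            IsoformSpec("premrna", (model.span,), premrna_weight, unspliced=True)
        )
    conditions = ("HD", "PD", "C")
    samples = []
    for cond, size in zip(conditions, group_sizes):
        for i in range(size):
            samples.append(SampleDef(f"{cond}{i + 1}", cond, n_fragments))
    config = SimConfig(
        model=model,
        isoforms=tuple(isoforms),
        samples=tuple(samples),
        seed=seed,
        three_prime_bias=three_prime_bias,
    )
    return config, labels
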