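# Methods

## Scope and model

`splicegaps` analyses spliced short-read alignments restricted to one gene
locus. Three computations make up the pipeline, each usable on its own:

1. **Junction extraction.** A read alignment is reduced to its
   reference-aligned blocks; every inter-block gap of length ≥ `min_gap`
   (default 10 nt, i.e. "greater than 9 bases") is a splicing event,
   identified by the 1-based coordinates of its first and last gapped base.
   Both `N` (skip) and `D` (deletion) CIGAR operations delimit blocks, and
   adjacent gap operations merge into one contiguous gap: the event is
   defined on the *gap in reference coverage*, not on the operation code,
   because aligners are free to encode short gaps as deletions. Insertions
   and clips never split a block. Identical gaps are aggregated across
   reads — each mate of a pair counts independently — into events carrying
   total and per-condition support; events with pooled ("superset")
   support ≥ `min_support` (default 10 reads) are reported.

2. **AS classification.** Each junction is labelled against the canonical
   transcript's junction set by a deterministic cascade (first match wins):
   exact canonical match; skipped exon (both ends are ends of two
   *different* canonical introns, the downstream one later in transcription
   order, with ≥ 1 exon wholly inside the gap); added exon (novel end
   strictly inside a canonical intron *and* a reciprocal partner junction
   completing a novel internal exon — both partners are labelled
   AddedExon); alternative acceptor/donor (exactly one end shared; the
   novel side names the category, strand-aware, donor being the 5′ side of
   the gap); otherwise a composite novel-donor-and-acceptor, reported as
   Acceptor with both end contexts recorded in notes. Novel ends are
   annotated `exonic`/`intronic` by the feature that contains them;
   positions outside the gene span resolve against the flanking terminal
   exon. Requiring the reciprocal partner for AddedExon is deliberate: a
   lone mid-intron junction is indistinguishable by coordinates from an
   alternative splice site, so without a partner it degrades to
   Acceptor/Donor with `novel_end_context = intronic`. Events are grouped
   into loci by single-linkage overlap of their gap intervals (optional
   symmetric padding, default 0).

3. **Coverage profiling.** The canonical transcript defines an alternating
   exon/intron feature ladder (2E−1 features for E exons, numbered in
   transcription order). Every reference-aligned base of every read is
   assigned to the unique feature containing it; gapped positions
   contribute nothing, and bases outside the span go to a diagnostic
   `outside` bucket. Mean per-sample coverage divides each per-condition
   count first by feature length, then by the number of samples in the
   condition (the two normalisations commute; the order is fixed for
   documentation's sake).

## Worked example on the published junction table

A published table of 20 junctions from the *HTT* locus (chr4, + strand;
8 canonical, 12 alternative) is embedded as data. The reference gene model
is reconstructed *from the table itself*: its Canonical rows become the
introns, exons fill the complement. This reference is deliberately
truncated (the table shows 6 of 11 loci), with two deterministic
consequences, both treated as documented label mappings rather than
special cases:

* "Added Exon" rows have no printed partner junction and degrade to
  Acceptor/intronic; supplying a partner (the *extended* variant, with a
  clearly-synthetic placeholder) upgrades them to AddedExon.
* One "Skipped Exon" row lands on the acceptor of a canonical intron that
  the table does not print; it degrades to Acceptor until the extended
  variant supplies a synthetic stand-in for that intron, after which it
  classifies SkippedExon.

Under the basic variant all 12 alternative calls are recovered and all
rows match the reported types under this mapping; under the extended
variant every reported AS type is reproduced exactly. Synthetic reference
coordinates are placeholders, marked as such in the source, and never
asserted against.

## Synthetic cohort

The simulator emulates the study design the pipeline targets: a multi-exon
gene with a dominant canonical isoform, several low-abundance alternative
isoforms, optional unspliced pre-mRNA background, 101 nt paired-end reads
from ~300 nt fragments, 3′-biased positional sampling, and unequal
condition groups. Specifics:

* **Fragment model.** Per fragment: isoform ~ mixture weights; 3′-end
  position `e` on the isoform's transcript with weight ∝ `exp(−λ(T−1−e))`;
  length from a normal (mean 300, sd 50) discretised on ±4 sd and capped
  by the transcript; `(e, length)` pairs whose fragment would not fit are
  redrawn jointly (bounded rounds), so the realised joint distribution is
  the independent product restricted to fitting pairs. At λ = 0 this is
  uniform placement of a fitting fragment — flat coverage away from the
  transcript edges (the ~fragment-length edge deficits at both ends are a
  property of any finite transcript, not of the bias model). Transcripts
  shorter than the minimum fragment length are rejected up front.
* **Why λ = 0.001/nt by default.** Poly-A selection depletes 5′ coverage
  severely in long genes; a decay length of 1 kb reproduces a ~8-fold
  3′/5′ per-exon coverage ratio on the 2 kb toy transcript — strong enough
  that per-exon mean coverage is monotone toward the 3′ end despite edge
  effects, comparable in character to published brain mRNA-Seq profiles.
* **Alignments, not sequences.** Mates are projected through the isoform
  chain into N-gapped CIGAR records (SEQ omitted); sequencing-error and
  aligner behaviour are out of scope, so alignments are error-free and the
  only gaps ≥ `min_gap` are true junctions. Per-sample RNG streams are
  spawned from one root seed; output SAM is coordinate-sorted and
  byte-identical for identical seeds.
* **Analytic truth.** Because all sampling distributions are discrete, the
  exact per-fragment probability grid over `(e, length)` yields closed-form
  means *and variances* for every junction's support (a mate supports a
  junction iff it covers the transcript boundary) and every feature's
  aligned-base count. Observed statistics are checked at 3σ against these
  expectations; junction supports of ~300 have relative sd ≈ 5 %, so the
  checks are sharp. The truth labels of novel junctions are hand-assigned
  at construction and independently cross-checked against the classifier.
* **Standard toy cohort.** 8 exons (last one long, UTR-like; total
  transcript 2 kb), canonical weight 0.90, five alternative isoforms at
  0.02 each jointly exercising intronic/exonic alternative acceptors, an
  alternative donor, single and double exon skips and a reciprocal
  added-exon pair; 3 condition groups of 2/2/4 samples × 20,000 fragments
  (≈ 320,000 alignments), sized to keep a full run in seconds while
  leaving every truth junction's expected support ≫ the 10-read filter.

**What passing these tests does not show.** The simulator omits sequencing
error, mismapping, multimapper ambiguity, duplicate fragments, GC bias and
between-sample library-size variation; real data would additionally
stress the upstream aligner and the support threshold's robustness to
noise, which are outside this package's scope. Condition labels affect
only bookkeeping (per-condition supports, per-sample normalisation) — no
differential test between conditions is attempted anywhere.

## Numerical and design choices

* Coordinates are 0-based half-open internally; junctions are reported
  1-based inclusive over the gapped span. The published table's convention
  is not stated by its authors; this choice is self-consistent and may
  differ by ±1 at each end from theirs.
* "Aligning primarily" = SAM primary flag (not secondary/supplementary);
  no MAPQ filter by default (configurable); no duplicate handling; reads
  partially overlapping the region are kept whole, with coverage clipped
  to the feature span.
* The junction BED uses two anchor blocks of configurable width flanking
  the gap; `chromStart = gap_start − 1 − anchor`, and the writer/reader
  pair round-trips coordinates exactly while satisfying BED12 block
  invariants (`blockStarts[0] = 0`,
  `chromStart + blockStarts[last] + blockSizes[last] = chromEnd`).
  Scores cap at 1000 per the BED specification.
* Ties and ordering: all outputs are sorted by `(gap_start, gap_end)`;
  locus ids are assigned in coordinate order; identical inputs give
  byte-identical outputs.
* Degenerate inputs: empty alignment sets produce empty event tables and
  zero-filled coverage (success); single-exon transcripts, overlapping
  exons, duplicate sample ids, mixed-chromosome aggregation and
  sub-minimum thresholds fail fast with descriptive errors; pipeline
  failures remove partial outputs and name the failing stage.

## Known limitations

* One canonical transcript defines the reference; multi-isoform references
  and genome-wide annotation handling are out of scope.
* Intron-retention frequency is not estimated: with ~300 nt fragments and
  101 nt reads, intronic coverage cannot be attributed to retained introns
  versus pre-mRNA, so the package only *profiles* intronic coverage.
* No differential splice-usage statistics between conditions, and no
  library-size normalisation across samples.
* The AddedExon/SkippedExon calls depend on the completeness of the
  reference junction set, as the worked example's truncation behaviour
  makes explicit.
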