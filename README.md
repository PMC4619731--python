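# splicegaps

Detection, classification and coverage profiling of alternative splicing
(AS) events in a single gene locus from spliced short-read alignments —
built around the analysis style used to survey *HTT* (huntingtin) splice
forms in post-mortem human brain mRNA-Seq, where a dominant canonical
isoform coexists with many low-abundance alternative splice patterns.

## Who this is for

Transcriptomics analysts who have region-restricted BAM/SAM alignments for
one locus of interest (e.g. all reads mapping primarily to a disease gene)
across samples in several condition groups, and who want:

* every **splice junction** observed in the reads, with read support per
  condition and over the pooled "superset" of all samples;
* each junction **classified** against a canonical transcript as
  Canonical, alternative Acceptor, alternative Donor, Skipped Exon or
  Added (novel internal) Exon;
* **per-exon / per-intron coverage** by condition, to see intronic
  transcription and the 3′ bias of poly-A-selected libraries.

Because patient alignments are usually access-controlled, the package also
ships a seeded simulator that generates spliced paired-end alignments from
a configurable isoform mixture together with *analytic* expectations for
every junction support and feature base count, so the entire pipeline is
testable end to end without protected data.

## Method

* A **splicing event** is a contiguous reference gap of more than 9 nt
  (`min_gap = 10`) inside one read alignment; both skip (`N`) and deletion
  (`D`) CIGAR operations delimit gaps. Identical gaps `(gap_start, gap_end)`
  (1-based first/last gapped base, the STAR `SJ.out.tab` convention) are
  aggregated across reads; events with superset support ≥ 10 reads
  (`min_support`) are reported.
* **Classification cascade** against the canonical junction set: exact
  match → Canonical; both ends match ends of two different canonical
  introns → SkippedExon (with the indices of the excised exons); a novel
  end strictly inside a canonical intron with a reciprocal partner
  junction → AddedExon (both partners); one shared end → Acceptor or Donor
  by which side is novel (donor = 5′ side of the gap, strand-aware);
  neither end shared → composite, reported as Acceptor with both end
  contexts in the notes.
* **Coverage**: every aligned base is assigned to the unique exon/intron
  feature containing it; per condition, counts are divided by feature
  length and then by the number of samples, giving mean per-sample
  coverage per feature.
* **Simulator**: fragments are drawn per isoform by choosing the fragment
  3′ end with probability ∝ exp(−λ·d₃′) (λ = 0 ⇒ uniform), and a
  discretised-normal length (default 300 ± 50 nt, 101 nt mates); both
  mates are projected through the isoform's exon chain into N-gapped SAM
  records. Expected junction supports and per-feature base counts, with
  exact per-fragment variances, are computed from the same discrete
  distributions.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic
data (`python analysis/01_simulate_cohort.py`, then 02–04). The worked
classification example re-labels a published table of 20 *HTT* junctions
(chr4, + strand) using only the table's own Canonical rows as reference:

```
$ python analysis/04_reported_junctions.py
[basic] 12/20 junctions classify as alternative; all rows match the reported
AS type under the documented mapping: True -> results/reported_events_basic.tsv
[extended] reported AS types reproduced exactly: True
```

i.e. exactly the 12 reported alternative events are recovered, and with the
extended reference (synthetic stand-ins for the entries the published table
truncates) every reported AS type — Acceptor, Donor, Skipped Exon, Added
Exon — is reproduced coordinate-for-coordinate. On the simulated cohort
(8 samples × 20,000 fragments, canonical weight 0.90, five 0.02
alternatives):

```
$ python analysis/02_detect_and_classify.py
14 junctions detected, 14 pass the 10-read superset filter, 7 alternative, 4 loci
labels match truth for all events: True
largest |z| vs analytic expectation: 2.49
```

and the coverage profile shows the poly-A 3′ skew
(`analysis/03_profile_coverage.py`: 3′/5′ exon coverage ratio ≈ 7.8, and a
12-fold rise in intron bases when an unspliced pre-mRNA background is
added, with the junction table unchanged).

## Command line

`splicegaps run|simulate|classify|coverage` wraps the same library; see
`splicegaps --help`. `run` produces `events.tsv` (classified junctions with
per-condition supports), `junctions.bed` (BED12 two-anchor junction track),
`coverage.tsv` and a `run_log.json` recording thresholds and input
checksums.

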