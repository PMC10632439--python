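# Methods

## Model and procedure

The screen treats a splice junction as suspect when the sequences flanking
its donor and acceptor resemble each other *and* occur repeatedly in the
genome.  The reasoning mirrors how the artifact arises: a spliced aligner
will bridge two repeat copies with a phantom intron only if it can place
mismatch-free anchors on both sides of the "junction", which requires local
sequence identity between the two flanks; and the alignment is only
ambiguous if that sequence is not unique.

Per junction (0-based, half-open intron [d, a) on contig c):

1. **Flank extraction.** REF = genome[d−w, d+w), QRY = genome[a−w, a+w),
   w = overhang = 50 bp, both on the forward strand.  Minus-strand
   junctions are not reverse-complemented: self-similarity and occurrence
   counts are strand-symmetric, and forward-strand extraction makes the
   screen independent of (often missing or wrong) strand tags.  Windows
   truncated by a contig edge make the geometric criteria undefined; such
   junctions are retained with category BOUNDARY rather than risk a false
   removal.
2. **Flank alignment.** Local alignment of REF vs QRY: match +3,
   mismatch −4, two-piece gap cost min(12 + 2L, 32 + L) — the long-gap
   piece keeps extended indels affordable so diverged homologs still align.
   Search is gated on the existence of an exact shared 3-mer (a full seed
   index, i.e. a superset of any minimizer sampling with window 2, so no
   seeded optimum is missed), then solved exactly by Smith–Waterman with
   dual gap states per sequence and full traceback.  Alignments scoring
   below 25 are not reported.  Among co-optimal alignments the one with the
   smallest (ref_start, query_start, ref_end, query_end) is reported.
   `N` never matches anything, including another `N`; seeds containing `N`
   are discarded.
3. **Classification.**  Two-anchor iff both starts ≤ w − k, both last
   aligned offsets ≥ w + k − 1 (END_RULE: the alignment covers at least
   k = anchor = 7 exonic bases past each splice site, 0-based; offset 55
   fails, 56 passes), and |ref_start − query_start| < 2k.  Everything else
   is one-anchor.
4. **Occurrence probing.**  Three 30 bp probes: one centered on the aligned
   span midpoint in each window (re-fetched from genomic coordinates;
   probes truncated by a contig edge, or with > len/3 ambiguous bases, are
   invalid and force retention), and a hybrid = 15 bp ending at the donor +
   15 bp starting at the acceptor.  Counting is end-to-end Hamming matching
   with ≤ 1 mismatch, no gaps, both strands, all contigs, overlapping
   occurrences included, capped at 11 (strictly above every decision
   threshold, so the cap can never change a verdict).  This contract is
   deterministic and oracle-verifiable, and for 30 bp probes it is at least
   as sensitive as a seeded read mapper capped at 10 reported hits.
5. **Verdict.**  Two-anchor: spurious if both central probes multi-map
   (count > 1) or the hybrid occurs anywhere (the junction sequence exists
   contiguously elsewhere — by construction the chimeric hybrid has no
   occurrence at its own locus).  One-anchor: first the duplicated-exon
   rescue — signed shift query_start − ref_start ≥ w − k with hybrid count
   0 means the alignment is confined to exonic regions, the signature of a
   real intron between duplicated exons (the signed form is used because
   only a rightward query shift produces that geometry); otherwise spurious
   iff *both* probes occur ≥ 10 times (an `--either-probe` switch relaxes
   this, and "strictly more than 10" is threshold 11).  The hybrid test is
   not applied to the one-anchor high-frequency branch.

Filtering removes an alignment record iff any of its reference-skip gaps
equals a spurious junction key exactly (aligner-reported gaps are exact by
construction, so no fuzz window).  Mates of removed records are kept by
default — their own alignments are not evidence of the spurious junction —
and pairing flags are left untouched; `--drop-mates` removes them instead.
NH/MAPQ recomputation after removal is out of scope.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| overhang (w) | 50 | bp | flank window half-width; exonic overhang |
| anchor (k) | 7 | bp | minimum anchor a spliced aligner needs; sets 43/56/14 geometry |
| match / mismatch | +3 / −4 | score | permissive similarity detection |
| gap open/extend (short) | 12 / 2 | score | short-gap piece |
| gap open/extend (long) | 32 / 1 | score | long-gap piece |
| seed k-mer / window | 3 / 2 | bp | seeding gate |
| min chain score | 25 | score | minimum reportable alignment |
| probe length | 30 | bp | occurrence probes (hybrid = 15 + 15) |
| max mismatches | 1 | count | Hamming tolerance in probing |
| multi-map threshold | > 1 | count | two-anchor repeat evidence |
| high-frequency threshold | ≥ 10 | count | one-anchor repeat evidence |
| count cap | 11 | count | scan early-stop; above all thresholds |

## Synthetic scenarios

The generator emulates, with planted ground truth, the mechanisms that
produce phantom junctions and the genuine configurations that must survive
the screen: tandem repeats with `GT…AG`-mimicking unit boundaries (60 bp
unit × 6 by default), VNTR micro-introns (54 bp unit × 5, flank windows
genomically overlapping), diverged transposable-element pairs, processed
pseudogenes, duplicated exons (50 bp exon, equal to the overhang, giving
the confined-to-exons alignment with shift 50), and unique introns.
Background sequence is i.i.d. uniform ACGT; reads are 100 bp with ≥ 7 bp
anchors and i.i.d. substitutions at a configurable rate; identical seeds
give byte-identical files.

Two generator choices deserve emphasis:

* **Diverged TE pairs carry a conserved 60 bp core** centered on the
  junction point; i.i.d. divergence (default 10%, tested to 15%) applies
  only outside it.  Uniform divergence at these levels would leave no
  stretch of exact identity — but without such a stretch a spliced aligner
  could not place mismatch-free anchors there and the misalignment being
  modelled would not occur, and no occurrence test with a realistic
  mismatch budget could see the second copy.  The core *is* the modelled
  phenomenon (homologous copies retain locally exact runs); the scenario
  parameter controls arm divergence.
* **Rejection sampling enforces scenario definitions.**  Random 100 bp
  flank pairs reach the chain score by chance a few percent of the time;
  draws of the unique-intron and pseudogene scenarios (defined by *absence*
  of flank similarity) are therefore redrawn with a deterministically
  incremented seed until the defining property holds, as is a
  duplicated-exon draw whose hybrid 30-mer accidentally occurs elsewhere.

What the generator does not emulate: base-quality structure, indel
sequencing errors, expression-level variation, non-uniform genomic base
composition, and repeat families older or more fragmented than the planted
copies.  Passing the planted-truth suite therefore demonstrates the
decision logic and its thresholds, not recovery rates on real libraries,
where anchor-length distributions and polymorphism drive the artifact
frequency.

## Numerical and design notes

* All internal coordinates are 0-based half-open; GTF (1-based inclusive)
  is converted at the readers/writers only.
* Junction identity is the strand-free key (contig, start, end); motif is
  reporting-only.  Secondary/supplementary records count toward support by
  default (filtering acts on records, not reads), with a primary-only
  switch.
* The alignment DP is exact (no banding); windows are ≤ 100 bp so the
  O(nm) sweep with traceback costs ~1 ms per junction in pure Python.
* Ambiguity codes collapse to `N` on genome load so real genomes pass
  through; `N`-rich probes invalidate a spuriousness call rather than
  silently matching.
* Degenerate inputs: empty flank windows and sub-threshold alignments are
  "no alignment" (retained); empty interval fetches and inverted BED
  intervals are rejected; an undefined precision (empty prediction) is
  reported as 0 with a flag; percent change from a zero baseline is NaN.
* Problem sizes in the test and acceptance runs — 3 kb scenario genomes,
  20 seeds per mechanism, 500 oracle alignment pairs, ~200 oracle probe
  scans with one ~60 kb genome — were chosen so the whole suite verifies
  every contract in well under a minute while still exercising overlapping
  tandem occurrences, contig-edge clipping, and both strands.

## Known limitations

* Flank alignment considers the forward orientation only; inverted repeats
  are not detected (reverse-complement screening would be a
  straightforward extension but is unvalidated here).
* Exact-coordinate junction matching means a spurious junction reported
  with ±1 bp wobble by an aligner would be missed; in practice spliced
  aligners emit exact gaps.
* Removing records does not recompute the NH/MAPQ of surviving alignments
  of the same read, and kept mates of removed records retain their pairing
  flags.
* The annotation audit flags transcripts; it does not emit corrected
  transcript models.
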