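# splicescreen

Detect and remove repeat-induced spurious splice junctions from spliced
alignments (SAM/BAM) and transcript annotations (GTF).

## The problem

Spliced aligners must place reads across introns using short exonic anchors
(5–7 bp).  Repeated sequence defeats this: when two copies of a repeat
flank a locus, a read carrying a mismatch to both copies can be "rescued"
by a mismatch-free *spliced* alignment that jumps from one copy to the
other — manufacturing an intron that does not exist.  Tandem repeats whose
unit boundaries happen to read `GT…AG` are especially pernicious (VNTR
loci produce unit-length phantom micro-introns), as are diverged
transposable-element pairs and duplicated exons.  These phantom junctions
propagate into transcript assemblies and even curated annotation catalogs.

`splicescreen` is for people running RNA-seq alignment/assembly pipelines
(bulk or single-cell) and for annotation curators: it classifies every
candidate junction, removes alignment records that support spurious ones,
and audits GTFs for transcripts built on them.

## The method

For a junction with donor *d* and acceptor *a* (0-based, half-open intron
[*d*, *a*)), the screen extracts two windows on the forward genome strand:
REF = [*d*−w, *d*+w) and QRY = [*a*−w, *a*+w), with overhang w = 50 bp.
REF and QRY are locally aligned to each other under a permissive scheme —
match +3, mismatch −4, two-piece gap cost min(12 + 2L, 32 + L) — seeded by
exact 3-mers; alignments scoring < 25 are not reported.

An alignment is **two-anchor** when, with anchor length k = 7:

* both start offsets ≤ w − k (43),
* both last aligned offsets ≥ w + k − 1 (56, 0-based), and
* |ref_start − query_start| < 2k (14);

otherwise **one-anchor**.  Three 30 bp probes are then counted genome-wide
(end-to-end, both strands, ≤ 1 mismatch): one centered on the aligned span
of each window, and a *hybrid* concatenating the 15 bp before the donor
with the 15 bp after the acceptor.  A junction is **spurious** when:

* two-anchor and both central probes multi-map (count > 1), or the hybrid
  occurs anywhere (the "junction" matches real contiguous sequence); or
* one-anchor and both probes are high-frequency repeats (count ≥ 10) —
  unless the alignment shows the duplicated-exon pattern (query start
  shifted ≥ 43 with a unique hybrid), which is rescued.

Junctions with no flank alignment, clipped windows, or duplicated-exon
geometry are retained.  Records supporting spurious junctions are removed
from the alignment file; annotations are audited per transcript.  Assembly
agreement is summarized by sensitivity TP/(TP+FN), precision TP/(TP+FP),
and percent change (x_f − x_i)/x_i × 100.

## Worked example

`examples/01_flag_junctions.py` builds a genome with six tandem copies of a
60 bp unit engineered so the inter-copy gap mimics a canonical intron, plus
a control intron in unique sequence, and judges both:

```
TANDEM_REPEAT   chr1:1954-2014 (motif GTAG) -> SPURIOUS/TWO_ANCHOR [TA_MULTIMAP|TA_HYBRID]
                flank alignment score=300 span ref[0,100) qry[0,100); probe occurrences up=5 down=5 hybrid=5
UNIQUE_INTRON   chr1:1051-1251 (motif GTAG) -> RETAINED/NO_ALIGNMENT [NOALN]
```

The phantom intron's flank windows are identical (full-length alignment,
score 300 = 100 matches × 3), its central probes occur at five unit
boundaries, and the hybrid sequence exists contiguously in the repeat —
spurious on both grounds.  The genuine intron's flanks share no similarity,
so no alignment is reported and it is left alone.  The other examples show
filtering a SAM (`02`), auditing a GTF (`03`), agreement metrics (`04`),
and the step-by-step anatomy of a duplicated-exon rescue (`05`).

The same pipeline is available from the shell:

```sh
splicescreen simulate --kind TANDEM_REPEAT --seed 3 --out-dir fix
splicescreen filter --reference fix/genome.fa --bam fix/reads.sam --out-dir run
splicescreen audit  --reference fix/genome.fa --gtf fix/annotation.gtf --out-dir audit
```

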