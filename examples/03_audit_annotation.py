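"""Audit a transcript annotation for repeat-induced phantom introns.

A tandemly duplicated locus is annotated here as a single gene with two
spliced transcripts, both containing the intron that "bridges" two repeat
copies — the signature of a duplicated gene mis-modelled as one spliced
gene.  The audit flags the bridging intron in every transcript that carries
it.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from splicescreen import (
    ScenarioSpec, audit_gtf, judge_all, junctions_from_gtf, make_genome,
)

scenario = make_genome(ScenarioSpec(kind="TANDEM_REPEAT", seed=3))
with TemporaryDirectory() as tmp:
    gtf = Path(tmp) / "annotation.gtf"
    gtf.write_text(scenario.gtf)
    junctions = junctions_from_gtf(str(gtf), scenario.genome)
    verdicts = judge_all(junctions, scenario.genome)
    rows, summary = audit_gtf(str(gtf), verdicts)

for r in rows:
    print(f"{r.gene_id}\t{r.transcript_id}\t{r.contig}:{r.start}-{r.end}"
          f"\t{r.reason}\t{r.evidence}")
print(f"summary: {summary['spurious_introns']} spurious intron(s) in "
      f"{summary['affected_transcripts']} transcript(s) of "
      f"{summary['affected_genes']} gene(s)")
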