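"""Look inside the screen: flank windows, alignment geometry, probes.

Walks one duplicated-exon junction through the pipeline step by step to
show why it is rescued: the flank-vs-flank alignment exists but is confined
to the exonic regions (large start shift), and the hybrid probe is unique —
so this is a real intron between duplicated exons, not a repeat artifact.
"""

from splicescreen import (
    GeometryParams, OccurrenceParams, ScenarioSpec, ScoringParams,
    align_flanks, classify, extract_flanks, make_genome, make_probes,
)
from splicescreen.probes import fill_counts

g, s, p = GeometryParams(), ScoringParams(), OccurrenceParams()
scenario = make_genome(ScenarioSpec(kind="DUPLICATED_EXON", seed=4))
(j,) = scenario.junctions

fp = extract_flanks(j, scenario.genome, g)
print(f"junction {j.contig}:{j.start}-{j.end}, intron length {j.length}")
print(f"ref window  [{fp.ref_origin}, {fp.ref_origin + len(fp.ref_seq)}) "
      f"(donor-centered)")
print(f"qry window  [{fp.query_origin}, {fp.query_origin + len(fp.query_seq)}) "
      f"(acceptor-centered)")

a = align_flanks(fp, s)
print(f"alignment   score={a.score} cigar={a.cigar}")
print(f"offsets     ref[{a.ref_start},{a.ref_end}) qry[{a.query_start},{a.query_end})"
      f"  shift={a.query_start - a.ref_start}")
print(f"class       {classify(a, g)}")

ps = fill_counts(make_probes(j, a, fp, scenario.genome, g), scenario.genome, p)
print(f"probes      up={ps.up.count} down={ps.down.count} hybrid={ps.hybrid.count}")
print("verdict     RETAINED/DUPLICATED_EXON: shift >= 43 and unique hybrid")
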