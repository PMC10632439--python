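"""Flag spurious splice junctions in a tandem-repeat locus.

Builds a synthetic genome in which six copies of a 60 bp repeat unit sit in
tandem, each ending ...AG and starting GT... — so the gap between two copies
looks exactly like a canonical GT..AG intron to a spliced aligner.  The
screen should call that unit-length pseudo-intron SPURIOUS, and a control
intron in unique sequence RETAINED.
"""

from splicescreen import ScenarioSpec, judge, make_genome

for kind in ("TANDEM_REPEAT", "UNIQUE_INTRON"):
    scenario = make_genome(ScenarioSpec(kind=kind, seed=1))
    for j in scenario.junctions:
        v = judge(j, scenario.genome)
        a, ps = v.alignment, v.probes
        print(f"{kind:15s} {j.contig}:{j.start}-{j.end} (motif {j.motif}) "
              f"-> {v.status}/{v.category} [{v.reason}]")
        if a is not None:
            print(f"{'':15s} flank alignment score={a.score} "
                  f"span ref[{a.ref_start},{a.ref_end}) qry[{a.query_start},{a.query_end}); "
                  f"probe occurrences up={ps.up.count} down={ps.down.count} "
                  f"hybrid={ps.hybrid.count}")

# The tandem junction is spurious on both grounds: its central 30 bp probes
# occur in every repeat copy (counts > 1) and the hybrid sequence across the
# "intron" exists contiguously at every unit boundary (count >= 1).  The
# unique intron produces no flank alignment at all — the normal outcome for
# genuine splicing.
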