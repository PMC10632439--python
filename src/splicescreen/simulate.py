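"""Synthetic genomes, annotations, and spliced alignments with planted truth.

Each scenario embeds one misalignment mechanism (or a genuine-splicing
control) in random background sequence and records the expected verdict for
every planted junction, so the whole pipeline is testable without any
external data:

* ``TANDEM_REPEAT`` — consecutive repeat units engineered to end ``…AG``
  and begin ``GT…``, so the unit-length gap between copies looks like a
  canonical intron.  Expected: SPURIOUS (two-anchor).
* ``VNTR_MICROINTRON`` — the same mechanism with a short (54 bp) unit,
  producing a unit-length phantom micro-intron whose flank windows overlap
  genomically.  Expected: SPURIOUS (two-anchor).
* ``DIVERGED_TE_PAIR`` — two copies of a transposable element separated by
  unique sequence, diverged by i.i.d. substitutions except in a conserved
  core centered on the junction point.  The core models the stretch of
  exact matching bases that lets a spliced aligner place mismatch-free
  anchors there in the first place — without local exact homology the
  misalignment this scenario reproduces cannot arise.  Expected: SPURIOUS
  (two-anchor).
* ``PSEUDOGENE`` — a two-exon gene plus a contiguous exon1+exon2 copy on
  another contig.  The genuine intron's flanks share no similarity, so the
  screen must leave it alone.  Expected: RETAINED (NO_ALIGNMENT).
* ``DUPLICATED_EXON`` — the same exon sequence twice, separated by a unique
  intron: the flank-vs-flank alignment is confined to the exonic regions
  with a large start shift, the duplicated-exon pattern.  Expected:
  RETAINED (DUPLICATED_EXON).
* ``UNIQUE_INTRON`` — a canonical intron in non-repetitive sequence.
  Expected: RETAINED (NO_ALIGNMENT).

Background sequence is i.i.d. uniform over ACGT.  For the two scenarios
whose defining property is *absence* of flank similarity, draws in which
the background accidentally produces a chain-score-level flank alignment
(a few percent of random 100 bp pairs) are rejected and regenerated with a
deterministically incremented seed — the scenario definition, not the
screen's behavior, is what is being enforced.  The duplicated-exon draw
likewise rejects accidental contiguous occurrences of its hybrid 30-mer.
Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .flank import FlankPair, GeometryParams, ScoringParams, align_flanks
from .genome_io import GenomeIndex
from .junctions import Junction
from .probes import OccurrenceParams, count_occurrences
from .verdict import DUPLICATED_EXON, NO_ALIGNMENT, RETAINED, SPURIOUS
from .flank import TWO_ANCHOR

TANDEM_REPEAT = "TANDEM_REPEAT"
DIVERGED_TE_PAIR = "DIVERGED_TE_PAIR"
PSEUDOGENE = "PSEUDOGENE"
DUPLICATED_EXON_KIND = "DUPLICATED_EXON"
VNTR_MICROINTRON = "VNTR_MICROINTRON"
UNIQUE_INTRON = "UNIQUE_INTRON"
KINDS = (TANDEM_REPEAT, DIVERGED_TE_PAIR, PSEUDOGENE, DUPLICATED_EXON_KIND,
         VNTR_MICROINTRON, UNIQUE_INTRON)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ScenarioSpec:
    """Controls for one planted scenario; defaults are the study conditions."""

    kind: str
    seed: int = 0
    unit_len: int | None = None      # repeat unit; 60 (tandem) / 54 (VNTR)
    copies: int | None = None        # repeat copies; 6 (tandem) / 5 (VNTR)
    divergence: float = 0.10         # substitution fraction between TE copies
    te_len: int = 160                # transposable-element length
    core_len: int = 60               # conserved core around the TE junction point
    exon_len: int = 120              # pseudogene exon 1
    exon2_len: int = 130             # pseudogene exon 2
    intron_len: int = 400
    dup_exon_len: int = 50           # duplicated-exon scenario exon size
    background_len: int = 3000

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")
        if self.kind in (TANDEM_REPEAT, VNTR_MICROINTRON) and self.resolved_copies < 2:
            raise ValueError("repeat scenarios need at least 2 copies")

    @property
    def resolved_unit_len(self) -> int:
        if self.unit_len is not None:
            return self.unit_len
        return 54 if self.kind == VNTR_MICROINTRON else 60

    @property
    def resolved_copies(self) -> int:
        if self.copies is not None:
            return self.copies
        return 5 if self.kind == VNTR_MICROINTRON else 6


@dataclass
class PlantedScenario:
    """A generated genome with its ground truth and annotation."""

    genome: GenomeIndex
    junctions: list[Junction]
    truth: dict[tuple[str, int, int], tuple[str, str]]  # key -> (status, category)
    gtf: str
    spec: ScenarioSpec


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protect: tuple[int, int] | None = None) -> str:
    """i.i.d. substitutions at ``rate``; positions in ``protect`` are untouched."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = np.zeros(arr.size, dtype=np.int8)
    for i, b in enumerate(_BASES):
        codes[arr == b] = i
    hit = rng.random(arr.size) < rate
    if protect is not None:
        hit[protect[0]:protect[1]] = False
    shifts = rng.integers(1, 4, arr.size)
    new_codes = (codes + shifts) % 4
    arr[hit] = _BASES[new_codes[hit]]
    return arr.tobytes().decode()


def _gtf_text(entries) -> str:
    """entries: (gene_id, tx_id, contig, strand, [(start, end) 0-based half-open])."""
    lines = []
    for gene, tx, contig, strand, exons in entries:
        for start, end in sorted(exons):
            attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
            lines.append(
                f"{contig}\tsynthetic\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"
            )
    return "\n".join(lines) + "\n"


def _flanks_dissimilar(genome: GenomeIndex, contig: str, start: int, end: int,
                       g: GeometryParams, s: ScoringParams) -> bool:
    """True when the junction's flank windows do not reach the chain score."""
    seq = genome.contigs[contig]
    fp = FlankPair(
        ref_seq=seq[start - g.overhang:start + g.overhang],
        query_seq=seq[end - g.overhang:end + g.overhang],
        ref_origin=start - g.overhang,
        query_origin=end - g.overhang,
        contig=contig,
        clipped=False,
    )
    return align_flanks(fp, s) is None


def make_genome(spec: ScenarioSpec, max_attempts: int = 50) -> PlantedScenario:
    """Generate the scenario genome, planted junctions, truth, and GTF."""
    g, s = GeometryParams(), ScoringParams()
    for attempt in range(max_attempts):
        rng = np.random.default_rng((spec.seed + 1_000_003 * attempt) % 2**31)
        built = _build(spec, rng)
        if built is None:
            continue
        genome, junctions, truth, gtf = built
        if spec.kind in (UNIQUE_INTRON, PSEUDOGENE):
            j = junctions[0]
            if not _flanks_dissimilar(genome, j.contig, j.start, j.end, g, s):
                continue  # accidental background homology: redraw
        return PlantedScenario(genome, junctions, truth, gtf, spec)
    raise RuntimeError(f"could not generate scenario {spec.kind} in {max_attempts} draws")


def _build(spec: ScenarioSpec, rng: np.random.Generator):
    kind = spec.kind
    L = spec.background_len
    bg = _random_seq(rng, L)

    if kind in (TANDEM_REPEAT, VNTR_MICROINTRON):
        unit_len, copies = spec.resolved_unit_len, spec.resolved_copies
        if unit_len < 8:
            raise ValueError("unit_len too short to carry splice motifs")
        unit = "GT" + _random_seq(rng, unit_len - 4) + "AG"
        p = int(rng.integers(600, L - copies * unit_len - 600))
        seq = bg[:p] + unit * copies + bg[p:]
        b = copies // 2
        start = p + b * unit_len
        end = start + unit_len
        genome = GenomeIndex({"chr1": seq})
        j = Junction("chr1", start, end, motif="GTAG", support=1)
        truth = {j.key: (SPURIOUS, TWO_ANCHOR)}
        gtf = _gtf_text([
            ("g1", "t1", "chr1", "+", [(start - 80, start), (end, end + 80)]),
            ("g1", "t2", "chr1", "+", [(start - 60, start), (end, end + 60)]),
        ])
        return genome, [j], truth, gtf

    if kind == DIVERGED_TE_PAIR:
        te_len, core = spec.te_len, spec.core_len
        o = te_len // 2
        te = _random_seq(rng, te_len)
        copy2 = _mutate(te, spec.divergence, rng, protect=(o - core // 2, o + core // 2))
        gap = 300
        p1 = int(rng.integers(600, L - 2 * te_len - gap - 600))
        p2 = p1 + te_len + gap
        seq = bg[:p1] + te + bg[p1:p1 + gap] + copy2 + bg[p1 + gap:]
        genome = GenomeIndex({"chr1": seq})
        start, end = p1 + o, p2 + o
        j = Junction("chr1", start, end,
                     motif=seq[start:start + 2] + seq[end - 2:end], support=1)
        truth = {j.key: (SPURIOUS, TWO_ANCHOR)}
        gtf = _gtf_text([("g1", "t1", "chr1", "+", [(start - 80, start), (end, end + 80)])])
        return genome, [j], truth, gtf

    if kind == PSEUDOGENE:
        exon1 = _random_seq(rng, spec.exon_len)
        exon2 = _random_seq(rng, spec.exon2_len)
        intron = "GT" + _random_seq(rng, spec.intron_len - 4) + "AG"
        p_gene = int(rng.integers(600, L - len(exon1) - len(intron) - len(exon2) - 600))
        chr1 = bg[:p_gene] + exon1 + intron + exon2 + bg[p_gene:]
        bg2 = _random_seq(rng, 1500)
        p_ps = 600
        chr2 = bg2[:p_ps] + exon1 + exon2 + bg2[p_ps:]
        genome = GenomeIndex({"chr1": chr1, "chr2": chr2})
        start = p_gene + len(exon1)
        end = start + len(intron)
        j = Junction("chr1", start, end, motif="GTAG", support=1)
        truth = {j.key: (RETAINED, NO_ALIGNMENT)}
        gtf = _gtf_text([
            ("g1", "t1", "chr1", "+",
             [(p_gene, start), (end, end + len(exon2))]),
        ])
        return genome, [j], truth, gtf

    if kind == DUPLICATED_EXON_KIND:
        e_len = spec.dup_exon_len
        exon = _random_seq(rng, e_len)
        intron = "GT" + _random_seq(rng, 296) + "AG"
        p1 = int(rng.integers(600, L - 2 * e_len - len(intron) - 600))
        seq = bg[:p1] + exon + intron + exon + bg[p1:]
        genome = GenomeIndex({"chr1": seq})
        start = p1 + e_len
        end = start + len(intron)
        # hybrid 30-mer must be absent elsewhere for the rescue to be the truth
        hybrid = exon[-15:] + exon[:15]
        if count_occurrences(hybrid, genome, OccurrenceParams()) != 0:
            return None
        j = Junction("chr1", start, end, motif="GTAG", support=1)
        truth = {j.key: (RETAINED, DUPLICATED_EXON)}
        gtf = _gtf_text([("g1", "t1", "chr1", "+", [(p1, start), (end, end + e_len)])])
        return genome, [j], truth, gtf

    # UNIQUE_INTRON
    exon1 = _random_seq(rng, 100)
    exon2 = _random_seq(rng, 100)
    intron = "GT" + _random_seq(rng, 196) + "AG"
    p = int(rng.integers(600, L - 400 - 600))
    seq = bg[:p] + exon1 + intron + exon2 + bg[p:]
    genome = GenomeIndex({"chr1": seq})
    start = p + 100
    end = start + len(intron)
    j = Junction("chr1", start, end, motif="GTAG", support=1)
    truth = {j.key: (RETAINED, NO_ALIGNMENT)}
    gtf = _gtf_text([("g1", "t1", "chr1", "+", [(p, start), (end, end + 100)])])
    return genome, [j], truth, gtf


def write_fasta(genome: GenomeIndex, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth_tsv(truth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstatus\tcategory\n")
        for (c, s, e), (status, category) in sorted(truth.items()):
            fh.write(f"{c}\t{s}\t{e}\t{status}\t{category}\n")


def make_spliced_alignments(
    genome: GenomeIndex,
    junctions,
    path: str,
    n_per_junction: int = 5,
    n_background: int = 10,
    mismatch_rate: float = 0.0,
    read_len: int = 100,
    min_anchor: int = 7,
    seed: int = 0,
) -> str:
    """Write a SAM of spliced records spanning each junction plus contiguous
    background records.

    Each spliced record has CIGAR aM bN cM with a, c ≥ min_anchor and the
    splice gap exactly at the junction; sequences are copied from the genome
    with i.i.d. substitutions at ``mismatch_rate``.
    """
    rng = np.random.default_rng(seed)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": genome.lengths[name]} for name in genome.contigs],
    }
    tid = {name: i for i, name in enumerate(genome.contigs)}
    keys = [j.key if isinstance(j, Junction) else tuple(j) for j in junctions]
    counter = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for contig, jstart, jend in keys:
            clen = genome.lengths[contig]
            lo = max(min_anchor, read_len - (clen - jend))
            hi = min(read_len - min_anchor, jstart)
            if lo > hi:
                raise ValueError(
                    f"junction {contig}:{jstart}-{jend} leaves no room for a "
                    f"{read_len} bp read with {min_anchor} bp anchors"
                )
            for _ in range(n_per_junction):
                a = int(rng.integers(lo, hi + 1))
                c = read_len - a
                seq = (genome.contigs[contig][jstart - a:jstart]
                       + genome.contigs[contig][jend:jend + c])
                seq = _mutate(seq, mismatch_rate, rng) if mismatch_rate > 0 else seq
                rec = pysam.AlignedSegment()
                rec.query_name = f"sim{counter}"
                counter += 1
                rec.query_sequence = seq
                rec.flag = 0
                rec.reference_id = tid[contig]
                rec.reference_start = jstart - a
                rec.mapping_quality = 60
                rec.cigarstring = f"{a}M{jend - jstart}N{c}M"
                out.write(rec)
        contig_names = list(genome.contigs)
        for _ in range(n_background):
            contig = contig_names[int(rng.integers(0, len(contig_names)))]
            clen = genome.lengths[contig]
            pos = int(rng.integers(0, clen - read_len + 1))
            seq = genome.contigs[contig][pos:pos + read_len]
            seq = _mutate(seq, mismatch_rate, rng) if mismatch_rate > 0 else seq
            rec = pysam.AlignedSegment()
            rec.query_name = f"sim{counter}"
            counter += 1
            rec.query_sequence = seq
            rec.flag = 0
            rec.reference_id = tid[contig]
            rec.reference_start = pos
            rec.mapping_quality = 60
            rec.cigarstring = f"{read_len}M"
            out.write(rec)
    return str(path)
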