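"""Synthetic TE landscapes, reads, and truth alignments for validation.

The simulator plants TE copies (and optional single-copy genes) into
non-repetitive random backgrounds, one background per haploid genome.  Copies
carry independent per-base substitutions at a configured divergence, and
structural variants — internal deletions and terminal truncations — at exact
population frequencies.  From the resulting landscape one can sample uniform
sequencing reads (FASTQ, optionally with substitution/indel errors), or emit
*truth alignments*: SAM records derived directly from the manifest with exact
coordinates and CIGARs, bypassing any aligner.  Truth alignments emulate the
one aligner behaviour that matters for deletion-frequency estimation: a flank
shorter than the aligner's minimum sub-alignment (m, default 30 bp) is
reported soft-clipped, so the junction is invisible for that read.

Every sampled quantity is reproducible from the seed; structural-variant
carriers are exactly round(frequency x copies) copies, so manifest frequencies
are exact, not binomial draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam

from .core_io import ConsensusLibrary, TE_FAMILY, SINGLE_COPY_GENE, TescopeError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def random_dna(n: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated TE landscape.

    ``coverage`` is the sequencing depth per haploid genome; a family present
    once per genome therefore pools to ``n_haploid_genomes x coverage`` on its
    consensus.  ``divergence`` is the per-base substitution probability applied
    independently to every copy.  ``internal_deletions`` and ``truncations``
    carry exact population frequencies (fraction of copies carrying the
    variant).  ``indel_rate`` is a read-level indel error rate; substitution
    read errors use ``read_error_rate``.
    """

    seed: int
    te_consensus: str
    background_length: int = 4000
    n_haploid_genomes: int = 20
    copies_per_genome: int = 1
    divergence: float = 0.0
    indel_rate: float = 0.0
    internal_deletions: list[tuple[int, int, float]] = field(default_factory=list)
    truncations: list[tuple[str, int, float]] = field(default_factory=list)
    snps: list[tuple[int, str, float]] = field(default_factory=list)  # planted SNPs
    read_length: int = 100
    coverage: float = 30.0
    read_error_rate: float = 0.0
    family_name: str = "TEfam"
    genes: list[tuple[str, int]] = field(default_factory=list)  # (name, length)

    def __post_init__(self) -> None:
        L = len(self.te_consensus)
        if not 0 <= self.divergence <= 1:
            raise TescopeError("divergence must be in [0,1]")
        for s, e, f in self.internal_deletions:
            if not (0 <= s < e <= L):
                raise TescopeError(f"deletion [{s},{e}) outside consensus of length {L}")
            if not 0 <= f <= 1:
                raise TescopeError("deletion frequency must be in [0,1]")
        for side, pos, f in self.truncations:
            if side not in ("left", "right") or not (0 < pos < L) or not 0 <= f <= 1:
                raise TescopeError(f"invalid truncation ({side},{pos},{f})")
        for pos, alt, f in self.snps:
            if not (0 <= pos < L) or alt not in "ACGT" or not 0 <= f <= 1:
                raise TescopeError(f"invalid planted SNP ({pos},{alt},{f})")
            if alt == self.te_consensus[pos].upper():
                raise TescopeError(f"planted SNP at {pos} equals the consensus base")


@dataclass
class CopyRecord:
    genome: int
    family: str
    substitutions: list[tuple[int, str]]           # (0-based consensus pos, alt base)
    deletions: list[tuple[int, int]]               # applied internal deletions
    truncation: tuple[str, int] | None             # applied terminal deletion
    kept: list[tuple[int, int]]                    # retained consensus intervals
    seq: str = ""

    def kept_length(self) -> int:
        return sum(e - s for s, e in self.kept)


@dataclass
class PlacedElement:
    kind: str  # 'te' | 'gene'
    name: str
    genome: int
    genome_start: int
    genome_end: int
    copy: CopyRecord | None = None


@dataclass
class GroundTruth:
    """Machine-readable manifest of everything the simulator did."""

    family: str
    consensus_length: int
    n_haploid_genomes: int
    copies_per_genome: int
    nominal_divergence: float
    realized_divergence: float       # substitutions on retained bases / retained bases
    deletion_truth: list[dict]       # start, end, frequency, carriers
    truncation_truth: list[dict]
    snp_truth: list[dict]            # pos (0-based), alt, true frequency among copies
    copies: list[CopyRecord] = field(default_factory=list)
    gene_names: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        for c in payload["copies"]:
            c.pop("seq", None)
        path.write_text(json.dumps(payload, indent=1))
        return path


@dataclass
class Landscape:
    config: SimulationConfig
    genomes: list[str]
    placements: list[PlacedElement]
    library: ConsensusLibrary
    truth: GroundTruth

    def genome_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for i, g in enumerate(self.genomes):
                fh.write(f">genome_{i}\n")
                for j in range(0, len(g), 80):
                    fh.write(g[j : j + 80] + "\n")
        return path


def _apply_variants(length: int, deletions, truncation) -> list[tuple[int, int]]:
    """Retained consensus intervals after truncation + internal deletions."""
    lo, hi = 0, length
    if truncation is not None:
        side, pos = truncation
        if side == "left":
            lo = pos
        else:
            hi = pos
    cuts = sorted((max(s, lo), min(e, hi)) for s, e in deletions)
    kept = []
    cur = lo
    for s, e in cuts:
        if e <= cur:
            continue
        if s > cur:
            kept.append((cur, s))
        cur = max(cur, e)
    if cur < hi:
        kept.append((cur, hi))
    return kept


def simulate_landscape(config: SimulationConfig) -> Landscape:
    """Build per-genome templates, the consensus library, and the manifest."""
    rng = np.random.default_rng(config.seed)
    cons = config.te_consensus.upper()
    L = len(cons)
    n_copies = config.n_haploid_genomes * config.copies_per_genome

    # random background substitutions per copy
    copy_subs: list[dict[int, str]] = []
    copies: list[CopyRecord] = []
    for gi in range(config.n_haploid_genomes):
        for _ in range(config.copies_per_genome):
            subs: dict[int, str] = {}
            if config.divergence > 0:
                hits = np.where(rng.random(L) < config.divergence)[0]
                for p in hits:
                    alts = [b for b in "ACGT" if b != cons[p]]
                    subs[int(p)] = alts[rng.integers(3)]
            copy_subs.append(subs)
            copies.append(CopyRecord(gi, config.family_name, [], [], None, []))

    # planted SNPs at exact population frequencies override random substitutions
    for pos, alt, f in config.snps:
        k = int(round(f * n_copies))
        carriers = rng.choice(n_copies, size=k, replace=False) if k else []
        for ci in carriers:
            copy_subs[int(ci)][pos] = alt
    for c, subs in zip(copies, copy_subs):
        c.substitutions = sorted(subs.items())

    # assign structural variants to exact carrier counts
    deletion_truth, truncation_truth = [], []
    for s, e, f in config.internal_deletions:
        k = int(round(f * n_copies))
        carriers = rng.choice(n_copies, size=k, replace=False) if k else []
        for ci in carriers:
            copies[int(ci)].deletions.append((s, e))
        deletion_truth.append(
            {"start": s, "end": e, "frequency": k / n_copies if n_copies else 0.0,
             "carriers": int(k)}
        )
    for side, pos, f in config.truncations:
        k = int(round(f * n_copies))
        carriers = rng.choice(n_copies, size=k, replace=False) if k else []
        for ci in carriers:
            copies[int(ci)].truncation = (side, pos)
        truncation_truth.append(
            {"side": side, "pos": pos, "frequency": k / n_copies if n_copies else 0.0,
             "carriers": int(k)}
        )

    # realize copy sequences
    total_subs = total_kept = 0
    snp_counter: dict[tuple[int, str], int] = {}
    kept_counter = np.zeros(L, dtype=int)
    for c in copies:
        c.kept = _apply_variants(L, c.deletions, c.truncation)
        mutated = list(cons)
        for p, alt in c.substitutions:
            mutated[p] = alt
        c.seq = "".join("".join(mutated[s:e]) for s, e in c.kept)
        kept_mask = np.zeros(L, dtype=bool)
        for s, e in c.kept:
            kept_mask[s:e] = True
        kept_counter += kept_mask
        total_kept += c.kept_length()
        for p, alt in c.substitutions:
            if kept_mask[p]:
                total_subs += 1
                snp_counter[(p, alt)] = snp_counter.get((p, alt), 0) + 1
    snp_truth = [
        {"pos": p, "alt": alt, "frequency": n / kept_counter[p]}
        for (p, alt), n in sorted(snp_counter.items())
        if kept_counter[p] > 0
    ]

    # gene sequences (shared across genomes: single copy per genome)
    gene_seqs = {name: random_dna(glen, rng) for name, glen in config.genes}

    # place elements into per-genome backgrounds with spacing >= read_length+10
    spacing = config.read_length + 10
    genomes, placements = [], []
    for gi in range(config.n_haploid_genomes):
        bg = random_dna(config.background_length, rng)
        elements = [
            ("te", config.family_name, c)
            for c in copies[gi * config.copies_per_genome : (gi + 1) * config.copies_per_genome]
        ] + [("gene", name, None) for name in gene_seqs]
        offsets = _draw_offsets(rng, config.background_length, len(elements), spacing)
        parts, pos, shift = [], 0, 0
        for off, (kind, name, copy) in zip(offsets, elements):
            parts.append(bg[pos:off])
            seq = copy.seq if kind == "te" else gene_seqs[name]
            g_start = off + shift
            parts.append(seq)
            placements.append(
                PlacedElement(kind, name, gi, g_start, g_start + len(seq), copy)
            )
            shift += len(seq)
            pos = off
        parts.append(bg[pos:])
        genomes.append("".join(parts))

    entries = {config.family_name: (cons, TE_FAMILY)}
    for name, seq in gene_seqs.items():
        entries[name] = (seq, SINGLE_COPY_GENE)
    library = ConsensusLibrary(entries)
    truth = GroundTruth(
        family=config.family_name,
        consensus_length=L,
        n_haploid_genomes=config.n_haploid_genomes,
        copies_per_genome=config.copies_per_genome,
        nominal_divergence=config.divergence,
        realized_divergence=total_subs / total_kept if total_kept else 0.0,
        deletion_truth=deletion_truth,
        truncation_truth=truncation_truth,
        snp_truth=snp_truth,
        copies=copies,
        gene_names=list(gene_seqs),
    )
    return Landscape(config, genomes, placements, library, truth)


def _draw_offsets(
    rng: np.random.Generator, bg_len: int, n: int, spacing: int, max_tries: int = 1000
) -> list[int]:
    """Insertion offsets into the background, pairwise >= spacing apart."""
    lo, hi = spacing, bg_len - spacing
    if hi <= lo or (n > 0 and (hi - lo) < n * spacing):
        raise TescopeError(
            "background too short for the requested insertions at this read length"
        )
    for _ in range(max_tries):
        offs = sorted(int(x) for x in rng.integers(lo, hi, size=n))
        if all(b - a >= spacing for a, b in zip(offs, offs[1:])):
            return offs
    raise TescopeError("could not place non-overlapping insertions; enlarge background")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    landscape: Landscape,
    out_fastq: str | Path,
    read_length: int | None = None,
    coverage: float | None = None,
    error_rate: float | None = None,
    indel_rate: float | None = None,
    seed: int | None = None,
) -> Path:
    """Uniformly sample reads from every haploid genome; write FASTQ.

    Expected read count per genome is coverage x genome_length / read_length.
    Substitution errors are explicit (qualities are constant Q40); indel
    errors insert or delete single bases at ``indel_rate`` per position.
    """
    cfg = landscape.config
    L = cfg.read_length if read_length is None else read_length
    C = cfg.coverage if coverage is None else coverage
    err = cfg.read_error_rate if error_rate is None else error_rate
    ind = cfg.indel_rate if indel_rate is None else indel_rate
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    out_fastq = Path(out_fastq)
    with open(out_fastq, "w") as fh:
        for gi, genome in enumerate(landscape.genomes):
            if L > len(genome):
                raise TescopeError("read length exceeds genome template length")
            # interior positions (>= L-1 from either template end) then see
            # expected depth exactly C; planted elements are always interior
            n_reads = int(round(C * (len(genome) - L + 1) / L))
            starts = rng.integers(0, len(genome) - L + 1, size=n_reads)
            strands = rng.random(n_reads) < 0.5
            for k, (s, minus) in enumerate(zip(starts, strands)):
                frag = genome[s : s + L]
                frag = _mutate_read(frag, err, ind, rng)
                if minus:
                    frag = revcomp(frag)
                fh.write(f"@g{gi}_r{k}\n{frag}\n+\n{'I' * len(frag)}\n")
    return out_fastq


def _mutate_read(seq: str, err: float, ind: float, rng: np.random.Generator) -> str:
    if err <= 0 and ind <= 0:
        return seq
    out = []
    for ch in seq:
        if ind > 0 and rng.random() < ind:
            if rng.random() < 0.5:
                out.append(ch)
                out.append("ACGT"[rng.integers(4)])  # insertion after this base
            # else: deletion (skip base)
            continue
        if err > 0 and rng.random() < err:
            alts = [b for b in "ACGT" if b != ch]
            out.append(alts[rng.integers(3)])
        else:
            out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# truth alignments
# ---------------------------------------------------------------------------

@dataclass
class TruthAlignments:
    sam_path: Path
    expected_base_cov: dict[str, np.ndarray]
    expected_phys_cov: dict[str, np.ndarray]
    n_reads: int
    n_mapped: int


def emit_truth_alignments(
    landscape: Landscape,
    out_sam: str | Path,
    read_length: int | None = None,
    coverage: float | None = None,
    seed: int | None = None,
    min_segment: int = 30,
    error_rate: float = 0.0,
    min_internal_deletion: int = 30,
) -> TruthAlignments:
    """Write exact SAM alignments straight from the manifest (no aligner).

    Each read's placement is known, so its CIGAR is exact: aligned consensus
    segments become M runs, skipped deletion intervals become D runs, and
    background overhang becomes soft clips.  Aligned segments shorter than
    ``min_segment`` read bases are clipped instead — exactly how a local
    aligner would fail to report them — so junction reads with an off-centre
    breakpoint lose their junction and the detection correction is exercised.
    Background-only reads are emitted as unmapped records.

    Returns the independently tallied expected per-position base and physical
    coverage, against which the pipeline can be checked exactly.
    """
    cfg = landscape.config
    L = cfg.read_length if read_length is None else read_length
    C = cfg.coverage if coverage is None else coverage
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    out_sam = Path(out_sam)

    lib = landscape.library
    names = list(lib.entries)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": lib.length(n)} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    exp_base = {n: np.zeros(lib.length(n), dtype=np.int64) for n in names}
    exp_phys = {n: np.zeros(lib.length(n), dtype=np.int64) for n in names}

    placements_by_genome: dict[int, list[PlacedElement]] = {}
    for pl in landscape.placements:
        placements_by_genome.setdefault(pl.genome, []).append(pl)
    for pls in placements_by_genome.values():
        pls.sort(key=lambda p: p.genome_start)

    n_reads = n_mapped = 0
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as out:
        for gi, genome in enumerate(landscape.genomes):
            n = int(round(C * (len(genome) - L + 1) / L))
            starts = rng.integers(0, len(genome) - L + 1, size=n)
            strands = rng.random(n) < 0.5
            for k, (s, minus) in enumerate(zip(starts, strands)):
                n_reads += 1
                name = f"g{gi}_r{k}"
                frag = genome[s : s + L]
                if error_rate > 0:
                    frag = _mutate_read(frag, error_rate, 0.0, rng)
                rec = _make_record(
                    name, frag, int(s), gi, placements_by_genome.get(gi, []),
                    lib, tid, minus, min_segment, min_internal_deletion,
                    exp_base, exp_phys,
                )
                if rec is None:
                    rec = pysam.AlignedSegment()
                    rec.query_name = name
                    rec.flag = 4
                    rec.query_sequence = revcomp(frag) if minus else frag
                    rec.query_qualities = pysam.qualitystring_to_array("I" * len(frag))
                else:
                    n_mapped += 1
                out.write(rec)
    return TruthAlignments(out_sam, exp_base, exp_phys, n_reads, n_mapped)


def _make_record(
    name, frag, s, gi, placements, lib, tid, minus, m, min_del,
    exp_base, exp_phys,
) -> pysam.AlignedSegment | None:
    L = len(frag)
    e = s + L
    hit = None
    for pl in placements:
        if pl.genome_start < e and s < pl.genome_end:
            hit = pl
            break
    if hit is None:
        return None
    # read-local interval overlapping the element, and element-local interval
    r0 = max(0, hit.genome_start - s)
    r1 = min(L, hit.genome_end - s)
    u0 = max(0, s - hit.genome_start)
    u1 = u0 + (r1 - r0)
    contig = hit.name if hit.kind == "gene" else hit.copy.family

    # map element-local [u0,u1) onto consensus segments: (cons_start, cons_end,
    # read_offset), read offsets in reference orientation
    if hit.kind == "gene":
        cons_segs = [(u0, u1, r0)]
    else:
        cons_segs = []
        cum = 0
        for ks, ke in hit.copy.kept:
            seg_len = ke - ks
            a, b = max(u0, cum), min(u1, cum + seg_len)
            if b > a:
                cons_segs.append((ks + (a - cum), ks + (b - cum), r0 + (a - u0)))
            cum += seg_len
    # enforce the aligner's minimum sub-alignment length
    cons_segs = [seg for seg in cons_segs if seg[1] - seg[0] >= m]
    if not cons_segs:
        return None
    # dropping a short middle segment leaves a mid-read unaligned gap, which a
    # local aligner reports as a single alignment of the longest piece
    contiguous = all(
        b[2] == a[2] + (a[1] - a[0]) for a, b in zip(cons_segs, cons_segs[1:])
    )
    if not contiguous:
        return _single_longest(name, frag, cons_segs, contig, tid, minus, exp_base)
    # build CIGAR in reference orientation
    cigar = []
    lead = cons_segs[0][2]
    if lead:
        cigar.append((4, lead))
    prev = None
    for cs, ce, roff in cons_segs:
        if prev is not None:
            gap_ref = cs - prev[1]
            cigar.append((2, gap_ref))
            if gap_ref >= min_del:
                exp_phys[contig][prev[1]:cs] += 1
        cigar.append((0, ce - cs))
        exp_base[contig][cs:ce] += 1
        prev = (cs, ce, roff)
    trail = L - (prev[2] + (prev[1] - prev[0]))
    if trail:
        cigar.append((4, trail))

    rec = pysam.AlignedSegment()
    rec.query_name = name
    rec.reference_id = tid[contig]
    rec.reference_start = cons_segs[0][0]
    rec.mapping_quality = 60
    rec.flag = 16 if minus else 0
    rec.cigartuples = cigar
    rec.query_sequence = frag  # reference orientation
    rec.query_qualities = pysam.qualitystring_to_array("I" * L)
    return rec


def _single_longest(name, frag, cons_segs, contig, tid, minus, exp_base):
    """Fallback for reads whose middle segment was unalignably short: keep the
    longest segment only, soft-clipping the rest (what a local aligner reports)."""
    cs, ce, roff = max(cons_segs, key=lambda t: t[1] - t[0])
    L = len(frag)
    cigar = []
    if roff:
        cigar.append((4, roff))
    cigar.append((0, ce - cs))
    trail = L - (roff + (ce - cs))
    if trail:
        cigar.append((4, trail))
    exp_base[contig][cs:ce] += 1
    rec = pysam.AlignedSegment()
    rec.query_name = name
    rec.reference_id = tid[contig]
    rec.reference_start = cs
    rec.mapping_quality = 60
    rec.flag = 16 if minus else 0
    rec.cigartuples = cigar
    rec.query_sequence = frag
    rec.query_qualities = pysam.qualitystring_to_array("I" * L)
    return rec
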