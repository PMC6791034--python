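"""Input/output primitives: consensus libraries, read filtering, alignment.

Reads are aligned with a *local* aligner (``bwa bwasw``) so that one read may
produce several records — high-scoring pairs (HSPs) — on one or more consensus
sequences.  Everything downstream consumes plain SAM/BAM and relies only on
standard flags, MAPQ and CIGAR, so user-supplied alignments from any local
aligner are accepted.

Coordinate conventions: internal coordinates are 0-based half-open on both the
consensus and the read (read coordinates always refer to the read *as
sequenced*, i.e. in its original orientation); user-facing tables and plots are
1-based inclusive.
"""

from __future__ import annotations

import os
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TE_FAMILY = "te-family"
SINGLE_COPY_GENE = "single-copy-gene"

#: base -> integer code used in pileup accumulators
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASE = "ACGTN"


class TescopeError(RuntimeError):
    """Fatal, user-facing error."""


@dataclass
class ConsensusLibrary:
    """Named consensus sequences, each either a TE family or a single-copy gene."""

    entries: dict[str, tuple[str, str]]  # name -> (sequence, role)

    @property
    def families(self) -> list[str]:
        return [n for n, (_, r) in self.entries.items() if r == TE_FAMILY]

    @property
    def genes(self) -> list[str]:
        return [n for n, (_, r) in self.entries.items() if r == SINGLE_COPY_GENE]

    def sequence(self, name: str) -> str:
        return self.entries[name][0]

    def length(self, name: str) -> int:
        return len(self.entries[name][0])

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, (seq, _) in self.entries.items()
        ]
        SeqIO.write(records, str(path), "fasta")
        return path


def read_library(fasta_path: str | Path, gene_names: list[str] | None = None) -> ConsensusLibrary:
    """Load a consensus FASTA; entries named in ``gene_names`` become single-copy genes.

    Gene roles are always explicit — a name in ``gene_names`` that is absent
    from the FASTA is a fatal error, never silently ignored.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise TescopeError(f"consensus library not found: {fasta_path}")
    gene_names = list(gene_names or [])
    entries: dict[str, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in entries:
            raise TescopeError(f"duplicate sequence name in library: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise TescopeError(f"empty sequence in library: {rec.id!r}")
        entries[rec.id] = (seq, TE_FAMILY)
    for g in gene_names:
        if g not in entries:
            raise TescopeError(f"single-copy gene {g!r} not present in the library FASTA")
        entries[g] = (entries[g][0], SINGLE_COPY_GENE)
    return ConsensusLibrary(entries)


@dataclass
class AnnotationTrack:
    """GFF-style features (1-based inclusive) drawn under per-family panels."""

    features: list[tuple[str, int, int, str, str]]  # contig, start, end, type, label

    def for_contig(self, contig: str) -> list[tuple[int, int, str, str]]:
        return [(s, e, t, l) for c, s, e, t, l in self.features if c == contig]


def read_annotation(gff_path: str | Path) -> AnnotationTrack:
    """Read a GFF3 file keeping contig/start/end/type and a display label."""
    feats = []
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                continue
            contig, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            label = ftype
            if len(parts) > 8:
                for kv in parts[8].split(";"):
                    if kv.startswith(("Name=", "ID=")):
                        label = kv.split("=", 1)[1]
                        break
            feats.append((contig, int(start), int(end), ftype, label))
    return AnnotationTrack(feats)


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

def quality_filter(
    reads_path: str | Path,
    out_path: str | Path,
    min_mean_q: float = 15.0,
    min_len: int = 50,
    trim_q: int = 15,
) -> dict[str, int]:
    """Quality-filter a FASTQ file (Phred+33), writing survivors to ``out_path``.

    3' bases with quality below ``trim_q`` are trimmed first; reads shorter
    than ``min_len`` after trimming, or with mean quality below ``min_mean_q``,
    are dropped.  FASTA input carries no qualities and bypasses this step.
    Returns counters (input/trimmed/dropped/retained).
    """
    n_in = n_drop = n_trim = 0
    with open(out_path, "w") as out:
        for rec_no, rec in enumerate(_iter_fastq(reads_path), start=1):
            n_in += 1
            quals = rec.letter_annotations["phred_quality"]
            keep = len(quals)
            while keep > 0 and quals[keep - 1] < trim_q:
                keep -= 1
            if keep < len(quals):
                n_trim += 1
                rec = rec[:keep]
                quals = quals[:keep]
            if keep < min_len or (keep > 0 and sum(quals) / keep < min_mean_q) or keep == 0:
                n_drop += 1
                continue
            out.write(rec.format("fastq"))
    return {"input": n_in, "trimmed": n_trim, "dropped": n_drop, "retained": n_in - n_drop}


def _iter_fastq(path: str | Path) -> Iterator[SeqRecord]:
    it = SeqIO.parse(str(path), "fastq")
    rec_no = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise TescopeError(f"malformed FASTQ record #{rec_no + 1}: {exc}") from exc
        rec_no += 1
        yield rec


# ---------------------------------------------------------------------------
# external aligner
# ---------------------------------------------------------------------------

def align_reads(
    reads_path: str | Path,
    library: ConsensusLibrary,
    out_dir: str | Path,
    threads: int = 1,
    aligner: str = "bwa",
) -> Path:
    """Align reads to the consensus library with ``bwa bwasw``; return the SAM path.

    The aligner is invoked, never re-implemented; its multi-HSP output (one
    read appearing in several records) is exactly what the chainer consumes.
    """
    if shutil.which(aligner) is None:
        raise TescopeError(
            f"aligner {aligner!r} not found on PATH; install bwa "
            "(e.g. `conda install -c bioconda bwa`)"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = out_dir / "library.fasta"
    library.write_fasta(ref)
    _run([aligner, "index", str(ref)])
    sam = out_dir / (Path(reads_path).stem + ".sam")
    with open(sam, "w") as out:
        proc = subprocess.run(
            [aligner, "bwasw", "-t", str(threads), str(ref), str(reads_path)],
            stdout=out,
            stderr=subprocess.PIPE,
            text=True,
        )
    if proc.returncode != 0:
        raise TescopeError(f"aligner failed (exit {proc.returncode}):\n{proc.stderr}")
    return sam


def _run(cmd: list[str]) -> None:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise TescopeError(f"command {' '.join(cmd)} failed:\n{proc.stderr}")


# ---------------------------------------------------------------------------
# HSP loading
# ---------------------------------------------------------------------------

@dataclass
class HSP:
    """One local alignment of a read subsequence to a consensus interval.

    ``read_start``/``read_end`` are on the read as sequenced (original
    orientation), 0-based half-open.  ``match_ref_pos``/``match_base`` hold the
    per-base evidence (consensus position, read base code) for aligned bases;
    ``ins_pos``/``del_pos`` anchor short CIGAR indels on the consensus.
    """

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    mapq: int
    read_length: int
    ambiguous: bool
    match_ref_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    match_base: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint8))
    ins_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    del_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))

    def __post_init__(self) -> None:
        if not (self.ref_start < self.ref_end and self.read_start < self.read_end):
            raise ValueError("HSP intervals must be non-empty")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


@dataclass
class HSPLoadStats:
    mapped_records: int = 0
    skipped_records: int = 0
    hsps_emitted: int = 0
    reads: int = 0


def load_hsps(
    sam_path: str | Path,
    min_mapq_unambiguous: int = 1,
    min_internal_deletion: int = 30,
    stats: HSPLoadStats | None = None,
) -> Iterator[tuple[str, list[HSP]]]:
    """Stream (read_id, HSP list) groups from a SAM/BAM file.

    An HSP is *ambiguous* iff ``mapq < min_mapq_unambiguous`` (default: MAPQ 0,
    the aligner's multi-mapping signal).  Records whose CIGAR contains a
    deletion of at least ``min_internal_deletion`` bp are split into one HSP
    per retained segment, so a long-D encoding and a split-record encoding of
    the same junction are equivalent on ingest.  Records with inconsistent
    CIGAR/sequence length are counted and skipped, never silently dropped.
    """
    if stats is None:
        stats = HSPLoadStats()
    groups: dict[str, list[HSP]] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            stats.mapped_records += 1
            hsps = _record_to_hsps(rec, min_mapq_unambiguous, min_internal_deletion)
            if hsps is None:
                stats.skipped_records += 1
                continue
            stats.hsps_emitted += len(hsps)
            groups.setdefault(rec.query_name, []).extend(hsps)
    stats.reads = len(groups)
    yield from groups.items()


def _record_to_hsps(
    rec: pysam.AlignedSegment, min_mapq_unambiguous: int, min_internal_deletion: int
) -> list[HSP] | None:
    cigar = rec.cigartuples
    seq = rec.query_sequence
    if cigar is None or seq is None:
        return None
    # consumes-query ops: M=0, I=1, S=4, =7, X=8
    q_len = sum(l for op, l in cigar if op in (0, 1, 4, 7, 8))
    if q_len != len(seq):
        return None
    hard_left = cigar[0][1] if cigar[0][0] == 5 else 0
    hard_right = cigar[-1][1] if cigar[-1][0] == 5 else 0
    total_len = hard_left + len(seq) + hard_right
    strand = "-" if rec.is_reverse else "+"
    ambiguous = rec.mapping_quality < min_mapq_unambiguous

    # walk the CIGAR, splitting segments at long deletions
    segments: list[dict] = []
    cur = _new_segment()
    rpos = rec.reference_start
    qpos = 0  # position in SEQ
    for op, length in cigar:
        if op in (0, 7, 8):  # aligned
            if cur["ref_start"] is None:
                cur["ref_start"], cur["q_start"] = rpos, qpos
            cur["ref_pos"].append(np.arange(rpos, rpos + length, dtype=np.int32))
            cur["base"].append(
                np.frombuffer(seq[qpos : qpos + length].encode(), dtype=np.uint8)
            )
            rpos += length
            qpos += length
            cur["ref_end"], cur["q_end"] = rpos, qpos
        elif op == 1:  # insertion: anchor at preceding ref position
            if cur["ref_start"] is not None:
                cur["ins"].append(max(rpos - 1, 0))
            qpos += length
        elif op == 2:  # deletion
            if length >= min_internal_deletion:
                segments.append(cur)
                cur = _new_segment()
            else:
                cur["del"].extend(range(rpos, rpos + length))
            rpos += length
        elif op == 3:  # N: treat like a long deletion
            segments.append(cur)
            cur = _new_segment()
            rpos += length
        elif op in (4, 5):  # clips
            if op == 4:
                qpos += length
    segments.append(cur)

    out: list[HSP] = []
    for seg in segments:
        if seg["ref_start"] is None or seg["ref_end"] <= seg["ref_start"]:
            continue
        ref_pos = np.concatenate(seg["ref_pos"]) if seg["ref_pos"] else np.empty(0, np.int32)
        bases = np.concatenate(seg["base"]) if seg["base"] else np.empty(0, np.uint8)
        codes = _ascii_to_code(bases)
        # SEQ coordinates -> original read orientation
        q0, q1 = seg["q_start"], seg["q_end"]
        if strand == "+":
            read_start, read_end = hard_left + q0, hard_left + q1
        else:
            read_start = total_len - (hard_left + q1)
            read_end = total_len - (hard_left + q0)
        out.append(
            HSP(
                read_id=rec.query_name,
                contig=rec.reference_name,
                ref_start=seg["ref_start"],
                ref_end=seg["ref_end"],
                read_start=read_start,
                read_end=read_end,
                strand=strand,
                mapq=rec.mapping_quality,
                read_length=total_len,
                ambiguous=ambiguous,
                match_ref_pos=ref_pos,
                match_base=codes,
                ins_pos=np.asarray(seg["ins"], dtype=np.int32),
                del_pos=np.asarray(seg["del"], dtype=np.int32),
            )
        )
    return out


def _new_segment() -> dict:
    return {
        "ref_start": None,
        "ref_end": None,
        "q_start": None,
        "q_end": None,
        "ref_pos": [],
        "base": [],
        "ins": [],
        "del": [],
    }


_ASCII_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODE.items():
    _ASCII_LUT[ord(_b)] = _c
    _ASCII_LUT[ord(_b.lower())] = _c


def _ascii_to_code(ascii_bytes: np.ndarray) -> np.ndarray:
    return _ASCII_LUT[ascii_bytes]


def count_mapped_reads(sam_path: str | Path) -> int:
    """Number of distinct read names with at least one mapped record."""
    names = set()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if not rec.is_unmapped:
                names.add(rec.query_name)
    return len(names)
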