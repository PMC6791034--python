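"""Per-position composition tables: coverage, SNPs, indels, deletions.

For every consensus position the profile records base coverage (aligned read
bases, split into unambiguous and ambiguous layers), physical coverage (reads
whose split-alignment junction spans the position without aligning bases
there), per-base counts, short-indel counts, SNP calls, and the evidence for
internal deletions (junction reads, with a read-length-dependent detection
correction) and terminal truncations (soft-clipped reads anchored at internal
consensus positions).

Counting both base and physical coverage is what keeps abundance estimates
unbiased when internally deleted copies segregate: a junction read is evidence
for one whole (deleted) copy even though it aligns no bases inside the gap.
"""

from __future__ import annotations

import io
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import Chain, Junction
from .core_io import BASE_CODE, ConsensusLibrary, TescopeError

TABLE_COLUMNS = [
    "family", "sample_id", "pos", "refbase", "A", "C", "G", "T",
    "cov", "phys_cov", "hq_cov", "snp", "refsnp", "int_del",
    "trunc_left", "trunc_right", "ins", "del", "annotation",
]


@dataclass(frozen=True)
class ProfileParams:
    min_internal_deletion: int = 30
    min_segment: int = 30            # aligner's minimum sub-alignment length m
    breakpoint_tolerance: int = 5    # bp for clustering recurrent breakpoints
    min_clip: int = 30               # bp of soft clip required as truncation evidence
    min_dist: int = 10               # bp from consensus ends; closer anchors ignored
    snp_min_count: int = 2
    snp_min_freq: float = 0.1
    snp_fixed_threshold: float = 0.95


@dataclass
class InternalDeletionCall:
    """One internal deletion: a recurrent junction with corrected support.

    ``raw_frequency`` is the naive estimator (junction reads over mean base
    coverage across the gap) — biased low for short reads and high for long
    reads because only junctions central enough in a read are detectable.
    ``frequency`` uses the detection-corrected count and is a per-copy
    proportion: corrected / (corrected + mean gap base coverage).
    """

    family: str
    ref_start: int  # 0-based half-open
    ref_end: int
    raw_count: int
    corrected_count: float
    frequency: float
    raw_frequency: float
    corrected: bool = True

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class TruncationCall:
    """A terminal deletion: clipped reads anchored at one internal position."""

    family: str
    ref_pos: int   # 1-based first (left) / last (right) retained consensus base
    side: str      # 'left': the 5' part of the TE is missing; 'right': the 3' part
    count: int
    frequency: float


def detection_probability(read_length: float, min_segment: int = 30) -> float:
    """Probability that a junction-spanning read is reported as split.

    A local aligner refuses sub-alignments shorter than ``min_segment`` (m), so
    of the L possible placements of a junction inside a read of length L, only
    those leaving both flanks >= m — i.e. L - 2m + 1 of them — yield a visible
    split.  p = (L - 2m + 1)/L, clamped to (0, 1].
    """
    L, m = read_length, min_segment
    if L <= 2 * m:
        raise TescopeError(
            f"reads too short to detect internal deletions (L={L} <= 2m={2 * m})"
        )
    return min((L - 2 * m + 1) / L, 1.0)


@dataclass
class FamilyProfile:
    family: str
    sample_id: str
    ref_seq: str
    counts: np.ndarray       # (len, 5) total base counts A,C,G,T,N
    hq_counts: np.ndarray    # (len, 5) counts from unambiguous HSPs only
    phys_cov: np.ndarray     # (len,) junction-spanning reads (raw counts)
    ins: np.ndarray          # (len,) short-insertion observations
    dels: np.ndarray         # (len,) short-deletion observations
    phys_cov_corr: np.ndarray | None = None  # detection-corrected (1/p per junction read)
    snp: np.ndarray | None = None      # object array: '.', 'seg', 'fixed'
    refsnp: np.ndarray | None = None   # reference-allele frequency at SNP sites
    trunc_left: np.ndarray | None = None
    trunc_right: np.ndarray | None = None
    deletion_calls: list[InternalDeletionCall] = field(default_factory=list)
    truncation_calls: list[TruncationCall] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.ref_seq)

    @property
    def base_cov(self) -> np.ndarray:
        return self.counts[:, :4].sum(axis=1)

    @property
    def hq_cov(self) -> np.ndarray:
        return self.hq_counts[:, :4].sum(axis=1)

    @property
    def total_cov(self) -> np.ndarray:
        return self.base_cov + self.phys_cov

    @property
    def total_cov_corrected(self) -> np.ndarray:
        """Base + detection-corrected physical coverage (for abundance)."""
        phys = self.phys_cov_corr if self.phys_cov_corr is not None else self.phys_cov
        return self.base_cov + phys


@dataclass
class SampleProfile:
    sample_id: str
    families: dict[str, FamilyProfile]
    junctions: list[tuple[str, Junction, int]] = field(default_factory=list)
    # (contig, junction, read_length) per junction read
    clip_events: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (contig, side, ref_pos0, clip_len) per clipped chain end
    total_mapped_reads: int = 0

    def __getitem__(self, family: str) -> FamilyProfile:
        return self.families[family]


def build_pileup(
    chains: list[Chain],
    library: ConsensusLibrary,
    sample_id: str,
    params: ProfileParams | None = None,
) -> SampleProfile:
    """Accumulate per-position counts from every read's best chain.

    One row exists for every consensus position of every library entry, even
    at zero coverage.  Base counts come from aligned HSP bases; physical
    coverage is incremented across each junction's skipped interval; short
    CIGAR indels are tallied at their anchor positions.
    """
    params = params or ProfileParams()
    profiles: dict[str, FamilyProfile] = {}
    for name, (seq, _) in library.entries.items():
        n = len(seq)
        profiles[name] = FamilyProfile(
            family=name,
            sample_id=sample_id,
            ref_seq=seq,
            counts=np.zeros((n, 5), dtype=np.int64),
            hq_counts=np.zeros((n, 5), dtype=np.int64),
            phys_cov=np.zeros(n, dtype=np.int64),
            ins=np.zeros(n, dtype=np.int64),
            dels=np.zeros(n, dtype=np.int64),
            phys_cov_corr=np.zeros(n, dtype=np.float64),
        )
    junctions: list[tuple[str, Junction, int]] = []
    clip_events: list[tuple[str, str, int, int]] = []
    for chain in chains:
        if chain.contig not in profiles:
            raise TescopeError(
                f"alignment contig {chain.contig!r} absent from the consensus library"
            )
        prof = profiles[chain.contig]
        for h in chain.hsps:
            np.add.at(prof.counts, (h.match_ref_pos, h.match_base), 1)
            if not h.ambiguous:
                np.add.at(prof.hq_counts, (h.match_ref_pos, h.match_base), 1)
            if h.ins_pos.size:
                np.add.at(prof.ins, h.ins_pos, 1)
            if h.del_pos.size:
                np.add.at(prof.dels, h.del_pos, 1)
        for j in chain.junctions:
            prof.phys_cov[j.ref_start : j.ref_end] += 1
            if chain.read_length > 2 * params.min_segment:
                w = 1.0 / detection_probability(chain.read_length, params.min_segment)
            else:
                w = 1.0
            prof.phys_cov_corr[j.ref_start : j.ref_end] += w
            junctions.append((chain.contig, j, chain.read_length))
        _collect_clips(chain, clip_events, params)
    return SampleProfile(
        sample_id=sample_id,
        families=profiles,
        junctions=junctions,
        clip_events=clip_events,
        total_mapped_reads=len(chains),
    )


def _collect_clips(
    chain: Chain, out: list[tuple[str, str, int, int]], params: ProfileParams
) -> None:
    """Record reference-oriented end clips that no other HSP explains."""
    first, last = chain.hsps[0], chain.hsps[-1]
    if chain.strand == "+":
        ref_left_clip, left_ok = chain.left_clip, not chain.left_clip_explained
        ref_right_clip, right_ok = chain.right_clip, not chain.right_clip_explained
        ref_left_pos, ref_right_pos = first.ref_start, last.ref_end
    else:
        ref_left_clip, left_ok = chain.right_clip, not chain.right_clip_explained
        ref_right_clip, right_ok = chain.left_clip, not chain.left_clip_explained
        ref_left_pos, ref_right_pos = last.ref_start, first.ref_end
    if left_ok and ref_left_clip >= params.min_clip:
        out.append((chain.contig, "left", ref_left_pos, ref_left_clip))
    if right_ok and ref_right_clip >= params.min_clip:
        out.append((chain.contig, "right", ref_right_pos, ref_right_clip))


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

def call_snps(
    profile: SampleProfile,
    min_count: int | None = None,
    min_freq: float | None = None,
    fixed_threshold: float | None = None,
    params: ProfileParams | None = None,
    use_hq: bool = True,
) -> None:
    """Classify each covered position as '.', 'seg'(regating) or 'fixed'.

    A site is *fixed* when a single non-reference base reaches
    ``fixed_threshold`` frequency; *segregating* when some non-reference base
    has count >= min_count, frequency >= min_freq, and the reference allele is
    still present above 1 - fixed_threshold.  By default only unambiguous
    (MAPQ > 0) coverage enters the calls, so multi-mapping reads cannot create
    phantom SNPs; set ``use_hq=False`` to use all coverage.
    """
    params = params or ProfileParams()
    min_count = params.snp_min_count if min_count is None else min_count
    min_freq = params.snp_min_freq if min_freq is None else min_freq
    fixed_threshold = (
        params.snp_fixed_threshold if fixed_threshold is None else fixed_threshold
    )
    for prof in profile.families.values():
        counts = (prof.hq_counts if use_hq else prof.counts)[:, :4].astype(float)
        cov = counts.sum(axis=1)
        n = prof.length
        snp = np.full(n, ".", dtype=object)
        refsnp = np.full(n, np.nan)
        ref_idx = np.array([BASE_CODE.get(b, 4) for b in prof.ref_seq])
        covered = cov > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = counts / cov[:, None]
        idx = np.where(covered & (ref_idx < 4))[0]
        for i in idx:
            ref_f = freqs[i, ref_idx[i]]
            alt = [b for b in range(4) if b != ref_idx[i]]
            alt_counts = counts[i, alt]
            alt_freqs = freqs[i, alt]
            fixed = (alt_freqs >= fixed_threshold) & (alt_counts >= min_count)
            if fixed.any():
                snp[i] = "fixed"
                refsnp[i] = ref_f
                continue
            seg = (
                (alt_counts >= min_count)
                & (alt_freqs >= min_freq)
                & (ref_f > 1 - fixed_threshold)
            )
            if seg.any():
                snp[i] = "seg"
                refsnp[i] = ref_f
        prof.snp = snp
        prof.refsnp = refsnp


def allele_frequencies(prof: FamilyProfile, pos: int, use_hq: bool = True) -> dict[str, float]:
    """Non-reference allele frequencies at a 1-based position."""
    counts = (prof.hq_counts if use_hq else prof.counts)[pos - 1, :4]
    cov = counts.sum()
    if cov == 0:
        return {}
    ref = prof.ref_seq[pos - 1]
    return {
        "ACGT"[b]: counts[b] / cov
        for b in range(4)
        if "ACGT"[b] != ref and counts[b] > 0
    }


# ---------------------------------------------------------------------------
# internal deletions
# ---------------------------------------------------------------------------

def call_internal_deletions(
    profile: SampleProfile,
    params: ProfileParams | None = None,
) -> None:
    """Cluster junction reads into deletion calls with detection correction.

    Junctions whose breakpoints agree within ``breakpoint_tolerance`` on both
    ends merge into one call at the modal breakpoints.  Each junction read
    contributes 1/p to the corrected count, where p is that read's detection
    probability (its length and the aligner's minimum segment m); mixed read
    lengths therefore correct per read.  When reads are too short (L <= 2m)
    raw counts are reported and the call flagged uncorrected.
    """
    params = params or ProfileParams()
    by_family: dict[str, list[tuple[Junction, int]]] = defaultdict(list)
    for contig, j, read_len in profile.junctions:
        by_family[contig].append((j, read_len))
    for family, prof in profile.families.items():
        prof.deletion_calls = []
        items = sorted(by_family.get(family, []), key=lambda t: (t[0].ref_start, t[0].ref_end))
        clusters: list[list[tuple[Junction, int]]] = []
        for j, L in items:
            placed = False
            for cl in clusters:
                j0 = cl[0][0]
                if (
                    abs(j.ref_start - j0.ref_start) <= params.breakpoint_tolerance
                    and abs(j.ref_end - j0.ref_end) <= params.breakpoint_tolerance
                ):
                    cl.append((j, L))
                    placed = True
                    break
            if not placed:
                clusters.append([(j, L)])
        base_cov = prof.base_cov
        for cl in clusters:
            starts = Counter(j.ref_start for j, _ in cl)
            ends = Counter(j.ref_end for j, _ in cl)
            s = max(starts, key=lambda k: (starts[k], -k))
            e = max(ends, key=lambda k: (ends[k], -k))
            raw = len(cl)
            corrected = 0.0
            correctable = True
            for _, L in cl:
                if L <= 2 * params.min_segment:
                    correctable = False
                    break
                corrected += 1.0 / detection_probability(L, params.min_segment)
            if not correctable:
                corrected = float(raw)
            gap_cov = float(base_cov[s:e].mean()) if e > s else 0.0
            freq = corrected / (corrected + gap_cov) if corrected + gap_cov > 0 else 0.0
            raw_freq = raw / gap_cov if gap_cov > 0 else float("inf")
            prof.deletion_calls.append(
                InternalDeletionCall(
                    family=family,
                    ref_start=s,
                    ref_end=e,
                    raw_count=raw,
                    corrected_count=corrected,
                    frequency=freq,
                    raw_frequency=raw_freq,
                    corrected=correctable,
                )
            )
        prof.deletion_calls.sort(key=lambda c: (c.ref_start, c.ref_end))


# ---------------------------------------------------------------------------
# terminal deletions
# ---------------------------------------------------------------------------

def call_terminal_deletions(
    profile: SampleProfile,
    params: ProfileParams | None = None,
) -> None:
    """Turn clustered clip anchors into truncation calls.

    A 'left' call at reference position r (1-based) means copies missing the
    consensus 5' of r exist; evidence is chains whose reference-left end sits
    at r with an unexplained soft clip of at least ``min_clip`` bp.  Anchors
    within ``min_dist`` of the consensus ends are alignment edge effects, not
    truncations.  Anchors cluster with the same tolerance as deletions.
    """
    params = params or ProfileParams()
    by_family: dict[tuple[str, str], list[int]] = defaultdict(list)
    for contig, side, ref_pos, _clip in profile.clip_events:
        by_family[(contig, side)].append(ref_pos)
    for family, prof in profile.families.items():
        prof.truncation_calls = []
        prof.trunc_left = np.zeros(prof.length, dtype=np.int64)
        prof.trunc_right = np.zeros(prof.length, dtype=np.int64)
        n = prof.length
        for side in ("left", "right"):
            positions = sorted(by_family.get((family, side), []))
            clusters: list[list[int]] = []
            for p in positions:
                if clusters and p - clusters[-1][0] <= params.breakpoint_tolerance:
                    clusters[-1].append(p)
                else:
                    clusters.append([p])
            for cl in clusters:
                modal = Counter(cl).most_common(1)[0][0]
                if side == "left":
                    if modal < params.min_dist:
                        continue
                    pos1 = modal + 1  # first retained base
                else:
                    if modal > n - params.min_dist:
                        continue
                    pos1 = modal      # ref_pos is half-open end -> last retained base
                cov = prof.base_cov[pos1 - 1]
                count = len(cl)
                freq = count / (count + cov) if count + cov > 0 else 0.0
                prof.truncation_calls.append(
                    TruncationCall(family, pos1, side, count, freq)
                )
                if side == "left":
                    prof.trunc_left[pos1 - 1] += count
                else:
                    prof.trunc_right[pos1 - 1] += count
            prof.truncation_calls.sort(key=lambda c: (c.side, c.ref_pos))


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------

def estimate_divergence(prof: FamilyProfile) -> tuple[float | None, np.ndarray]:
    """Mean per-position mismatch fraction over covered positions.

    Returns (family divergence, per-position divergence with NaN where
    uncovered).  A family with zero coverage has undefined (None) divergence.
    """
    cov = prof.base_cov.astype(float)
    ref_idx = np.array([BASE_CODE.get(b, 4) for b in prof.ref_seq])
    valid = (cov > 0) & (ref_idx < 4)
    per_pos = np.full(prof.length, np.nan)
    if valid.any():
        ref_counts = prof.counts[np.arange(prof.length), ref_idx]
        per_pos[valid] = 1.0 - ref_counts[valid] / cov[valid]
        return float(per_pos[valid].mean()), per_pos
    return None, per_pos


# ---------------------------------------------------------------------------
# composition table I/O
# ---------------------------------------------------------------------------

def profile_to_table(
    profile: SampleProfile, annotation=None
) -> pd.DataFrame:
    """Flatten a sample profile to the per-position composition table."""
    frames = []
    for family, prof in profile.families.items():
        n = prof.length
        snp = prof.snp if prof.snp is not None else np.full(n, ".", dtype=object)
        refsnp = (
            prof.refsnp if prof.refsnp is not None else np.full(n, np.nan)
        )
        tl = prof.trunc_left if prof.trunc_left is not None else np.zeros(n, dtype=np.int64)
        tr = prof.trunc_right if prof.trunc_right is not None else np.zeros(n, dtype=np.int64)
        int_del = np.full(n, ".", dtype=object)
        for call in prof.deletion_calls:
            row = call.ref_start  # encode the call on its (1-based) start row
            cell = f"{call.ref_start + 1}:{call.ref_end}:{call.corrected_count!r}"
            int_del[row] = cell if int_del[row] == "." else int_del[row] + ";" + cell
        ann = np.full(n, ".", dtype=object)
        if annotation is not None:
            for s, e, _t, label in annotation.for_contig(family):
                ann[s - 1 : e] = label
        frames.append(
            pd.DataFrame(
                {
                    "family": family,
                    "sample_id": prof.sample_id,
                    "pos": np.arange(1, n + 1),
                    "refbase": list(prof.ref_seq),
                    "A": prof.counts[:, 0],
                    "C": prof.counts[:, 1],
                    "G": prof.counts[:, 2],
                    "T": prof.counts[:, 3],
                    "cov": prof.base_cov,
                    "phys_cov": prof.phys_cov,
                    "hq_cov": prof.hq_cov,
                    "snp": snp,
                    "refsnp": refsnp,
                    "int_del": int_del,
                    "trunc_left": tl,
                    "trunc_right": tr,
                    "ins": prof.ins,
                    "del": prof.dels,
                    "annotation": ann,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TABLE_COLUMNS]


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: dict[str, str] | None = None
) -> Path:
    """Write the composition table as TSV with a '#'-prefixed metadata header.

    Floats are serialized with ``repr`` so that reading the file back
    reproduces every value bit-exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# columns: " + "\t".join(TABLE_COLUMNS) + "\n")
        out = df.copy()
        for col in out.columns:
            if out[col].dtype == float:
                out[col] = out[col].map(lambda x: "." if pd.isna(x) else repr(float(x)))
        out.to_csv(fh, sep="\t", index=False, header=False)
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a composition table written by :func:`write_table`."""
    metadata: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body and not body.startswith("columns"):
                    k, v = body.split(":", 1)
                    metadata[k.strip()] = v.strip()
                continue
            rows.append(line)
    df = pd.read_csv(
        io.StringIO("".join(rows)),
        sep="\t",
        names=TABLE_COLUMNS,
        dtype={
            "family": str, "sample_id": str, "refbase": str, "snp": str,
            "int_del": str, "annotation": str, "refsnp": str,
        },
        na_filter=False,
    )
    # numeric columns keep pandas' inferred dtype: ints stay int64, repr'd
    # floats parse back to the identical float64
    df["refsnp"] = df["refsnp"].map(lambda s: np.nan if s == "." else float(s))
    df["pos"] = df["pos"].astype(np.int64)
    return df, metadata
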