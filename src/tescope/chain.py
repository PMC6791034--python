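"""Arrange each read's HSPs into its single best consistent chain.

A local aligner reports every high-scoring pair (HSP) of a read, which may be
on different contigs, overlap each other on the read, or skip large consensus
intervals.  For every read we enumerate all combinations of its HSPs, discard
inconsistent ones (mixed contigs/strands, overlapping read subsequences, large
unaligned internal read gaps, non-colinear reference order) and keep the single
combination that aligns the largest fraction of the read.  Consensus intervals
skipped between consecutive HSPs of the winning chain are internal-deletion
junctions; unaligned read ends are clip evidence for terminal truncations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .core_io import HSP


@dataclass(frozen=True)
class ChainParams:
    max_read_gap: int = 20        # bp of read allowed unaligned between HSPs
    max_read_overlap: int = 15    # bp of read overlap tolerated between HSPs
    min_internal_deletion: int = 30  # smaller reference gaps are aligner noise
    enumeration_cap: int = 10     # max HSPs for exhaustive subset enumeration


@dataclass
class Junction:
    """Consensus interval skipped between two consecutive HSPs of one chain."""

    contig: str
    ref_start: int  # 0-based half-open skipped interval
    ref_end: int
    read_gap: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class Chain:
    read_id: str
    contig: str
    strand: str
    hsps: list[HSP]  # ascending read_start
    read_length: int
    aligned_fraction: float
    junctions: list[Junction] = field(default_factory=list)
    left_clip: int = 0          # unaligned bp at read start (as sequenced)
    right_clip: int = 0
    left_clip_explained: bool = False   # clip overlapped by some other HSP
    right_clip_explained: bool = False
    enumeration_truncated: bool = False  # greedy fallback was used

    @property
    def ambiguous(self) -> bool:
        """A chain is ambiguous iff all of its HSPs are ambiguous (MAPQ 0)."""
        return all(h.ambiguous for h in self.hsps)


def enumerate_combinations(hsps: Sequence[HSP], cap: int = 10) -> tuple[list[tuple[HSP, ...]], bool]:
    """All non-empty HSP subsets, or a greedy longest-first path above ``cap``.

    Returns (subsets, truncated).  Subsets are emitted in deterministic order:
    by size descending, then lexicographically on their ref_start tuples.
    Above the cap, exhaustive enumeration (2^n subsets) is replaced by a
    single greedy chain grown longest-HSP-first plus all singletons; the
    ``truncated`` flag records the degradation.
    """
    hsps = list(hsps)
    if not hsps:
        return [], False
    if len(hsps) <= cap:
        subsets: list[tuple[HSP, ...]] = []
        for k in range(len(hsps), 0, -1):
            ksubs = [tuple(sorted(c, key=lambda h: (h.read_start, h.ref_start)))
                     for c in combinations(hsps, k)]
            ksubs.sort(key=lambda sub: tuple(h.ref_start for h in sub))
            subsets.extend(ksubs)
        return subsets, False
    # greedy fallback: seed with the longest HSP, extend while consistent
    order = sorted(hsps, key=lambda h: (-(h.read_span), h.read_start, h.ref_start))
    greedy: list[HSP] = []
    params = ChainParams()
    for h in order:
        trial = sorted(greedy + [h], key=lambda x: (x.read_start, x.ref_start))
        if is_consistent(trial, h.read_length, params.max_read_gap, params.max_read_overlap):
            greedy = trial
    subsets = [tuple(greedy)] if greedy else []
    subsets += [(h,) for h in sorted(hsps, key=lambda h: (h.read_start, h.ref_start))]
    return subsets, True


def is_consistent(
    subset: Sequence[HSP],
    read_length: int,
    max_read_gap: int = 20,
    max_read_overlap: int = 15,
) -> bool:
    """Whether a read-sorted HSP subset forms one colinear placement.

    Requires one contig and strand; read-coordinate overlaps bounded by
    ``max_read_overlap``; internal unaligned read gaps bounded by
    ``max_read_gap``; and reference order matching read order (ascending for
    '+' chains, descending for '-', no contained intervals).
    """
    if not subset:
        return False
    first = subset[0]
    if any(h.contig != first.contig or h.strand != first.strand for h in subset):
        return False
    if len(subset) == 1:
        return True
    strand = first.strand
    for a, b in zip(subset, subset[1:]):
        if b.read_start < a.read_start:
            return False  # not sorted
        overlap = a.read_end - b.read_start
        if overlap > max_read_overlap:
            return False
        gap = b.read_start - a.read_end
        if gap > max_read_gap:
            return False
        if strand == "+":
            if not (b.ref_start >= a.ref_end - max_read_overlap
                    and b.ref_start > a.ref_start and b.ref_end > a.ref_end):
                return False
        else:
            if not (a.ref_start >= b.ref_end - max_read_overlap
                    and b.ref_start < a.ref_start and b.ref_end < a.ref_end):
                return False
    return True


def _aligned_bases(subset: Sequence[HSP]) -> int:
    """Read bases covered by the union of the subset's read intervals."""
    total = 0
    prev_end = -1
    for h in sorted(subset, key=lambda x: x.read_start):
        start = max(h.read_start, prev_end)
        if h.read_end > start:
            total += h.read_end - start
            prev_end = h.read_end
        prev_end = max(prev_end, h.read_end)
    return total


def select_best_chain(
    consistent_subsets: Iterable[Sequence[HSP]],
    read_length: int,
    params: ChainParams | None = None,
    truncated: bool = False,
    all_hsps: Sequence[HSP] | None = None,
) -> Chain | None:
    """Pick the consistent subset aligning the largest read fraction.

    Ties break deterministically: fewest HSPs, then smallest leftmost
    reference start, then longest first HSP.  Returns ``None`` when no
    consistent subset exists (read unplaceable, excluded from all counts).
    ``all_hsps`` (the read's full HSP pool, any contig) marks end clips that
    are explained by another alignment and hence are not truncation evidence.
    """
    params = params or ChainParams()
    best: tuple | None = None
    best_subset: Sequence[HSP] | None = None
    for subset in consistent_subsets:
        frac = _aligned_bases(subset) / read_length
        key = (
            -frac,
            len(subset),
            min(h.ref_start for h in subset),
            -subset[0].read_span,
            tuple((h.ref_start, h.ref_end, h.read_start, h.read_end) for h in subset),
        )  # final coordinate tuple makes the order total, hence deterministic
        if best is None or key < best:
            best = key
            best_subset = subset
    if best_subset is None:
        return None
    hsps = sorted(best_subset, key=lambda h: (h.read_start, h.ref_start))
    first = hsps[0]
    junctions = []
    for a, b in zip(hsps, hsps[1:]):
        if first.strand == "+":
            g0, g1 = a.ref_end, b.ref_start
        else:
            g0, g1 = b.ref_end, a.ref_start
        if g1 - g0 >= params.min_internal_deletion:
            junctions.append(
                Junction(first.contig, g0, g1, read_gap=max(0, b.read_start - a.read_end))
            )
    left_clip = hsps[0].read_start
    right_clip = first.read_length - hsps[-1].read_end
    chain = Chain(
        read_id=first.read_id,
        contig=first.contig,
        strand=first.strand,
        hsps=hsps,
        read_length=first.read_length,
        aligned_fraction=_aligned_bases(hsps) / read_length,
        junctions=junctions,
        left_clip=left_clip,
        right_clip=right_clip,
        enumeration_truncated=truncated,
    )
    if all_hsps is not None:
        chosen = set(map(id, hsps))
        others = [h for h in all_hsps if id(h) not in chosen]
        chain.left_clip_explained = any(
            min(h.read_end, left_clip) - h.read_start > 0 for h in others
        )
        chain.right_clip_explained = any(
            h.read_end - max(h.read_start, first.read_length - right_clip) > 0
            for h in others
        )
    return chain


def chain_read(hsps: Sequence[HSP], params: ChainParams | None = None) -> Chain | None:
    """Full per-read pipeline: enumerate, filter for consistency, pick the best."""
    params = params or ChainParams()
    if not hsps:
        return None
    read_length = hsps[0].read_length
    subsets, truncated = enumerate_combinations(hsps, cap=params.enumeration_cap)
    consistent = [
        s for s in subsets
        if is_consistent(s, read_length, params.max_read_gap, params.max_read_overlap)
    ]
    return select_best_chain(
        consistent, read_length, params, truncated=truncated, all_hsps=hsps
    )


def chain_all(
    groups: Iterable[tuple[str, Sequence[HSP]]], params: ChainParams | None = None
) -> list[Chain]:
    """Chain every read group; unplaceable reads are dropped."""
    chains = []
    for _, hsps in groups:
        c = chain_read(hsps, params)
        if c is not None:
            chains.append(c)
    return chains


def dump_chain_debug(chains: Sequence[Chain], path) -> None:
    """Write per-read chain decisions as TSV (debugging aid)."""
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tstrand\tn_hsps\taligned_fraction\t"
                 "left_clip\tright_clip\tjunctions\ttruncated_enumeration\n")
        for c in chains:
            juncs = ";".join(f"{j.ref_start}-{j.ref_end}" for j in c.junctions) or "."
            fh.write(
                f"{c.read_id}\t{c.contig}\t{c.strand}\t{len(c.hsps)}\t"
                f"{c.aligned_fraction:.4f}\t{c.left_clip}\t{c.right_clip}\t"
                f"{juncs}\t{int(c.enumeration_truncated)}\n"
            )
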