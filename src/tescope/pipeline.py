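"""End-to-end orchestration: filter -> align -> chain -> profile -> abundance -> plot.

The pipeline is a plain function over a :class:`RunConfig`; the command-line
interface is a thin wrapper around it.  Each sample is processed
independently: FASTQ inputs are quality-filtered and aligned with the wrapped
local aligner, SAM/BAM inputs skip both steps.  All thresholds from the
analysis modules are carried in the config and logged into the table header.
"""

from __future__ import annotations

import logging
import sys
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import estimate_insertions, normalize_per_million, write_abundance
from .chain import ChainParams, chain_all
from .core_io import (
    ConsensusLibrary,
    HSPLoadStats,
    TescopeError,
    align_reads,
    load_hsps,
    quality_filter,
    read_annotation,
    read_library,
)
from .profile import (
    ProfileParams,
    SampleProfile,
    build_pileup,
    call_internal_deletions,
    call_snps,
    call_terminal_deletions,
    profile_to_table,
    write_table,
)
from .viz import PlotSpec, plot_grid

logger = logging.getLogger("tescope")

SAM_SUFFIXES = {".sam", ".bam", ".cram"}
FASTA_SUFFIXES = {".fa", ".fasta", ".fna"}


@dataclass
class RunConfig:
    inputs: list[str]                      # FASTQ/FASTA reads or SAM/BAM, one per sample
    library: str
    output_prefix: str = "tescope"
    sample_ids: list[str] | None = None
    families: list[str] | None = None      # None = all
    gene_names: list[str] = field(default_factory=list)
    annotation: str | None = None
    normalization: str = "none"            # none | per-million | gene
    min_mean_q: float = 15.0
    min_len: int = 50
    min_mapq_unambiguous: int = 1
    chain: ChainParams = field(default_factory=ChainParams)
    profile: ProfileParams = field(default_factory=ProfileParams)
    plot_format: str = "pdf"
    no_plot: bool = False
    threads: int = 1
    debug_chains: str | None = None  # TSV dump of per-read chain decisions

    def __post_init__(self) -> None:
        if self.normalization not in ("none", "per-million", "gene"):
            raise TescopeError(f"unknown normalization mode {self.normalization!r}")
        for p in [self.library, *self.inputs] + ([self.annotation] if self.annotation else []):
            if not Path(p).exists():
                raise TescopeError(f"input file not found: {p}")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.inputs):
            raise TescopeError("one sample id per input required")


@dataclass
class SampleResult:
    sample_id: str
    profile: SampleProfile
    table: pd.DataFrame
    table_path: Path | None = None
    stats: HSPLoadStats | None = None


def process_sample(
    input_path: str | Path,
    library: ConsensusLibrary,
    sample_id: str,
    config: RunConfig,
    workdir: Path,
) -> SampleResult:
    """Run one sample from reads or alignments to a finished profile."""
    input_path = Path(input_path)
    suffix = input_path.suffix.lower()
    if suffix in SAM_SUFFIXES:
        sam_path = input_path
        logger.info("%s: using supplied alignments %s", sample_id, input_path)
    else:
        reads = input_path
        if suffix not in FASTA_SUFFIXES:  # FASTA bypasses quality filtering
            filtered = workdir / f"{sample_id}.filtered.fastq"
            counters = quality_filter(
                reads, filtered, min_mean_q=config.min_mean_q, min_len=config.min_len
            )
            logger.info("%s: quality filter %s", sample_id, counters)
            reads = filtered
        sam_path = align_reads(reads, library, workdir, threads=config.threads)
        logger.info("%s: aligned to %s", sample_id, sam_path)
    stats = HSPLoadStats()
    groups = load_hsps(
        sam_path,
        min_mapq_unambiguous=config.min_mapq_unambiguous,
        min_internal_deletion=config.chain.min_internal_deletion,
        stats=stats,
    )
    chains = chain_all(groups, config.chain)
    if config.debug_chains:
        from .chain import dump_chain_debug

        dump_chain_debug(chains, f"{config.debug_chains}.{sample_id}.tsv")
    logger.info(
        "%s: %d mapped records, %d skipped, %d chains",
        sample_id, stats.mapped_records, stats.skipped_records, len(chains),
    )
    profile = build_pileup(chains, library, sample_id, config.profile)
    call_snps(profile, params=config.profile)
    call_internal_deletions(profile, config.profile)
    call_terminal_deletions(profile, config.profile)
    if config.normalization == "per-million":
        normalize_per_million(profile)
        call_snps(profile, params=config.profile)  # flags recomputed on scaled counts
    annotation = read_annotation(config.annotation) if config.annotation else None
    table = profile_to_table(profile, annotation)
    if config.families:
        keep = set(config.families) | set(config.gene_names)
        table = table[table["family"].isin(keep)].reset_index(drop=True)
    return SampleResult(sample_id, profile, table, stats=stats)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns paths and in-memory results."""
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    library = read_library(config.library, config.gene_names)
    annotation = read_annotation(config.annotation) if config.annotation else None
    sample_ids = config.sample_ids or [Path(p).stem for p in config.inputs]
    results: list[SampleResult] = []
    out_prefix = Path(config.output_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        with tempfile.TemporaryDirectory(prefix="tescope_") as tmp:
            for inp, sid in zip(config.inputs, sample_ids):
                try:
                    res = process_sample(inp, library, sid, config, Path(tmp))
                except TescopeError as exc:
                    raise TescopeError(f"sample {sid!r}: {exc}") from exc
                meta = {
                    "tool": f"tescope {__version__}",
                    "sample": sid,
                    "input": str(inp),
                    "normalization": config.normalization,
                    "min_internal_deletion": str(config.chain.min_internal_deletion),
                    "min_segment": str(config.profile.min_segment),
                }
                res.table_path = write_table(
                    res.table, f"{out_prefix}.{sid}.table.tsv", meta
                )
                written.append(res.table_path)
                results.append(res)

        outputs: dict = {"tables": [r.table_path for r in results]}
        if config.gene_names:
            estimates = []
            for r in results:
                estimates.extend(estimate_insertions(r.profile, config.gene_names))
            outputs["abundance"] = write_abundance(
                estimates, f"{out_prefix}.abundance.tsv"
            )
            written.append(outputs["abundance"])
            outputs["estimates"] = estimates
        if not config.no_plot:
            spec = PlotSpec(
                normalization=config.normalization, output_format=config.plot_format
            )
            plot_tables = [
                r.table[~r.table["family"].isin(set(config.gene_names))]
                for r in results
            ]
            outputs["plot"] = plot_grid(
                plot_tables, f"{out_prefix}.plot.{config.plot_format}", spec, annotation
            )
            written.append(outputs["plot"])
    except Exception:
        for p in written:  # never leave partial outputs behind
            Path(p).unlink(missing_ok=True)
        raise
    outputs["results"] = results
    return outputs


def calibrate_detection(
    read_lengths: list[int],
    seed: int = 1,
    n_reads: int = 2000,
    min_segment: int = 30,
    deletion: tuple[int, int] = (1200, 1800),
    consensus_length: int = 3000,
    use_aligner: bool = True,
) -> pd.DataFrame:
    """Empirically estimate the junction detection probability per read length.

    Simulates a landscape where every copy carries one internal deletion,
    aligns reads (with the wrapped aligner, or with truth alignments when
    ``use_aligner`` is false), and reports the fraction of junction-spanning
    reads that produced a visible junction, next to the analytic
    (L - 2m + 1)/L.  The resulting table can override the analytic correction
    for aligners with a different minimum sub-alignment length.
    """
    from .sim import SimulationConfig, emit_truth_alignments, random_dna, simulate_landscape, simulate_reads
    from .core_io import load_hsps as _load

    rng = np.random.default_rng(seed)
    cons = random_dna(consensus_length, rng)
    rows = []
    s, e = deletion
    for L in read_lengths:
        cov = n_reads * L / (consensus_length + 2 * (L + 50))
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31 - 1)),
            te_consensus=cons,
            background_length=max(4 * L + 200, 2000),
            n_haploid_genomes=1,
            copies_per_genome=1,
            internal_deletions=[(s, e, 1.0)],
            read_length=L,
            coverage=cov,
        )
        land = simulate_landscape(cfg)
        with tempfile.TemporaryDirectory(prefix="tescope_cal_") as tmp:
            tmp = Path(tmp)
            if use_aligner:
                fq = simulate_reads(land, tmp / "reads.fastq")
                sam = align_reads(fq, land.library, tmp)
            else:
                sam = emit_truth_alignments(land, tmp / "truth.sam").sam_path
            chains = chain_all(_load(sam))
        junction_reads = sum(
            1 for c in chains if any(
                abs(j.ref_start - s) <= 5 and abs(j.ref_end - e) <= 5 for j in c.junctions
            )
        )
        # spanning reads: junction reads plus reads from deleted copies whose
        # alignment stops at a breakpoint with clipped sequence beyond it (the
        # aligner could not place the short flank, but the read does span)
        tol = 3
        spanning = 0
        for c in chains:
            if c.contig != cfg.family_name:
                continue
            if any(abs(j.ref_start - s) <= tol for j in c.junctions):
                spanning += 1
                continue
            left_clip = c.left_clip if c.strand == "+" else c.right_clip
            right_clip = c.right_clip if c.strand == "+" else c.left_clip
            foot_start = min(h.ref_start for h in c.hsps)
            foot_end = max(h.ref_end for h in c.hsps)
            if (abs(foot_end - s) <= tol and right_clip >= 1) or (
                abs(foot_start - e) <= tol and left_clip >= 1
            ):
                spanning += 1
        p_hat = junction_reads / spanning if spanning else 0.0
        analytic = (L - 2 * min_segment + 1) / L if L > 2 * min_segment else 0.0
        if analytic <= 0:
            logger.warning("read length %d too short for junction detection (m=%d)",
                           L, min_segment)
        rows.append({"read_length": L, "p_hat": p_hat, "p_analytic": analytic,
                     "junction_reads": junction_reads, "spanning_reads": spanning})
    return pd.DataFrame(rows)
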