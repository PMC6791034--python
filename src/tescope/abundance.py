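"""Coverage normalization and copy-number (insertions per haploid genome) estimates.

Two normalization modes are supported, never combined: scaling to one million
mapped reads (comparable samples of similar genome size) and contrasting TE
coverage with the coverage of user-designated single-copy genes.  The gene
contrast yields I-hat, insertions per haploid genome: a gene present exactly
once per haploid genome is sequenced to the per-copy depth, so

    I_hat = mean total TE coverage / mean single-copy-gene coverage,

where total coverage = base + physical coverage.  Using total coverage is what
keeps the estimate unbiased when internally deleted copies segregate — their
junction reads carry the deleted interval's evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import TescopeError
from .profile import SampleProfile

NORM_MODES = ("none", "per-million", "gene")


@dataclass
class AbundanceEstimate:
    family: str
    sample_id: str
    mean_total_cov: float
    normalization: str
    gene_cov: float | None = None
    insertions_per_haploid: float | None = None
    per_gene_cov: dict[str, float] | None = None


def normalize_per_million(profile: SampleProfile, total_mapped_reads: int | None = None) -> None:
    """Scale every coverage-like field to one million mapped reads, in place.

    Counts A,C,G,T scale identically so allele frequencies are invariant.
    Mapped reads are reads with at least one retained chain over all contigs,
    genes included.
    """
    total = profile.total_mapped_reads if total_mapped_reads is None else total_mapped_reads
    if total <= 0:
        raise TescopeError("cannot normalize: zero mapped reads")
    f = 1e6 / total
    for prof in profile.families.values():
        prof.counts = prof.counts * f
        prof.hq_counts = prof.hq_counts * f
        prof.phys_cov = prof.phys_cov * f
        prof.ins = prof.ins * f
        prof.dels = prof.dels * f
        if prof.phys_cov_corr is not None:
            prof.phys_cov_corr = prof.phys_cov_corr * f


def gene_coverage(
    profile: SampleProfile, gene_names: list[str], robust: bool = False
) -> tuple[float, dict[str, float]]:
    """Pooled position-weighted mean base coverage over the listed genes.

    Pooling is position-weighted (a 2 kb gene counts twice a 1 kb gene): the
    pooled value equals the mean depth of the concatenated single-copy
    fraction.  Per-gene means are returned as diagnostics for outlier genes.
    """
    if not gene_names:
        raise TescopeError("no single-copy genes supplied")
    per_gene = {}
    pooled = []
    for g in gene_names:
        if g not in profile.families:
            raise TescopeError(f"gene {g!r} not present in the profile")
        cov = profile.families[g].base_cov.astype(float)
        per_gene[g] = float(_mean(cov, robust))
        pooled.append(cov)
    return float(_mean(np.concatenate(pooled), robust)), per_gene


def _mean(x: np.ndarray, robust: bool) -> float:
    if robust and x.size > 0:
        from scipy import stats

        return float(stats.trim_mean(x, 0.05))
    return float(x.mean()) if x.size else 0.0


def estimate_insertions(
    profile: SampleProfile,
    gene_names: list[str],
    families: list[str] | None = None,
    robust: bool = False,
    use_physical: bool = True,
) -> list[AbundanceEstimate]:
    """I-hat per family: mean total coverage over pooled gene coverage.

    ``use_physical=False`` switches to the naive base-coverage-only estimator,
    which underestimates copy number in the presence of internal deletions —
    exposed for comparison, not recommended.
    """
    gcov, per_gene = gene_coverage(profile, gene_names, robust)
    if gcov <= 0:
        raise TescopeError(
            "single-copy gene coverage is zero; insertions per haploid genome undefined"
        )
    out = []
    names = families if families is not None else [
        f for f in profile.families if f not in set(gene_names)
    ]
    for fam in names:
        prof = profile.families[fam]
        # detection-corrected physical coverage: junction reads whose flanks
        # were too short for the aligner are re-weighted in, so copies carrying
        # internal deletions contribute their full coverage share
        cov = prof.total_cov_corrected if use_physical else prof.base_cov
        mean_cov = _mean(cov.astype(float), robust)
        out.append(
            AbundanceEstimate(
                family=fam,
                sample_id=profile.sample_id,
                mean_total_cov=mean_cov,
                normalization="gene",
                gene_cov=gcov,
                insertions_per_haploid=mean_cov / gcov,
                per_gene_cov=per_gene,
            )
        )
    return out


def abundance_table(estimates: list[AbundanceEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": e.family,
                "sample_id": e.sample_id,
                "norm_mode": e.normalization,
                "mean_total_cov": e.mean_total_cov,
                "gene_cov": e.gene_cov if e.gene_cov is not None else np.nan,
                "insertions_per_haploid": (
                    e.insertions_per_haploid
                    if e.insertions_per_haploid is not None
                    else np.nan
                ),
            }
            for e in estimates
        ]
    )


def write_abundance(estimates: list[AbundanceEstimate], path: str | Path) -> Path:
    path = Path(path)
    abundance_table(estimates).to_csv(path, sep="\t", index=False)
    return path
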