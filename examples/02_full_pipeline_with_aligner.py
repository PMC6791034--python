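"""Full pipeline: simulate reads, align with bwa bwasw, profile, estimate copies.

Requires bwa on PATH.  A single-copy gene in the library anchors the
insertions-per-haploid-genome estimate (I-hat): a gene present once per
haploid genome is sequenced at the per-copy depth, so TE coverage divided by
gene coverage is the TE copy number per haploid genome.
"""

import tempfile
from pathlib import Path

import numpy as np

from tescope import (
    SimulationConfig,
    build_pileup,
    chain_all,
    estimate_insertions,
    align_reads,
    load_hsps,
    random_dna,
    simulate_landscape,
    simulate_reads,
)

config = SimulationConfig(
    seed=11,
    te_consensus=random_dna(3000, np.random.default_rng(3)),
    background_length=4000,
    n_haploid_genomes=10,
    copies_per_genome=2,            # true copy number: 2 per haploid genome
    divergence=0.03,
    read_length=100,
    coverage=8.0,
    genes=[("rpl32-like", 1500)],
)
landscape = simulate_landscape(config)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    fastq = simulate_reads(landscape, tmp / "reads.fastq")
    sam = align_reads(fastq, landscape.library, tmp)
    chains = chain_all(load_hsps(sam))
    profile = build_pileup(chains, landscape.library, "pool")

(estimate,) = estimate_insertions(profile, ["rpl32-like"])
print(f"mean TE coverage:   {estimate.mean_total_cov:.1f}")
print(f"gene coverage:      {estimate.gene_cov:.1f}")
print(f"I-hat (copies per haploid genome): "
      f"{estimate.insertions_per_haploid:.2f}  (simulated: 2)")
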