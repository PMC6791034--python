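"""Render the per-family composition plot from a composition table.

Generates a landscape with a planted SNP, an internal deletion, and a
left-truncated subpopulation, writes the composition table, re-reads it, and
plots — demonstrating that the figure is a pure function of the table file.
"""

import tempfile
from pathlib import Path

import numpy as np

from tescope import (
    PlotSpec,
    SimulationConfig,
    build_pileup,
    call_internal_deletions,
    call_snps,
    call_terminal_deletions,
    chain_all,
    emit_truth_alignments,
    load_hsps,
    plot_grid,
    profile_to_table,
    random_dna,
    read_table,
    simulate_landscape,
    write_table,
)

cons = random_dna(3000, np.random.default_rng(21))
alt = next(b for b in "ACGT" if b != cons[2040])
config = SimulationConfig(
    seed=5,
    te_consensus=cons,
    background_length=3000,
    n_haploid_genomes=20,
    snps=[(2040, alt, 0.6)],
    internal_deletions=[(900, 1500, 0.4)],
    truncations=[("left", 300, 0.2)],
    read_length=100,
    coverage=10.0,
)
landscape = simulate_landscape(config)

with tempfile.TemporaryDirectory() as tmp:
    truth = emit_truth_alignments(landscape, Path(tmp) / "truth.sam")
    chains = chain_all(load_hsps(truth.sam_path))
    profile = build_pileup(chains, landscape.library, "example")
    call_snps(profile)
    call_internal_deletions(profile)
    call_terminal_deletions(profile)

    table = profile_to_table(profile)
    table_path = write_table(table, Path(tmp) / "composition.tsv")
    reread, _ = read_table(table_path)
    out = plot_grid([reread], "composition_example.pdf", PlotSpec())

print(f"wrote {out}")
print("the panel shows: grey coverage (dark = unambiguous), a coloured SNP bar")
print(f"at position 2041 (frequency 0.6), a deletion arc over 901..1500, and a")
print("dashed left-truncation line ending at position 301")
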