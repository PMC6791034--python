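"""Sashimi-style composition plots: per-family panels and multi-sample grids.

Each panel stacks unambiguous (dark) over ambiguous (light) coverage, draws
non-reference allele bars coloured by base at height = allele frequency times
local coverage (the reference allele is never drawn), arcs over internal
deletions with stroke width scaling with corrected junction support, dashed
truncation lines whose opacity scales with frequency, and an optional feature
strip at the bottom.  Everything drawn is read straight off the composition
table — the plot performs no computation beyond scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Arc

from .core_io import AnnotationTrack, TescopeError

BASE_COLOURS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
MAX_ARC_WIDTH = 6.0
MIN_TRUNC_ALPHA = 0.15


@dataclass
class PlotSpec:
    normalization: str = "none"
    output_format: str = "pdf"  # 'pdf' | 'eps'
    base_colours: dict[str, str] = field(default_factory=lambda: dict(BASE_COLOURS))
    show_annotation: bool = True
    show_legend: bool = True

    @property
    def ylabel(self) -> str:
        return {
            "none": "coverage",
            "per-million": "coverage per million mapped reads",
            "gene": "coverage / single-copy gene",
        }.get(self.normalization, "coverage")


def _parse_int_del(cell: str) -> list[tuple[int, int, float]]:
    if cell in (".", "", None) or pd.isna(cell):
        return []
    out = []
    for part in str(cell).split(";"):
        s, e, c = part.split(":")
        out.append((int(s), int(e), float(c)))
    return out


def plot_family(
    ax: plt.Axes,
    rows: pd.DataFrame,
    spec: PlotSpec | None = None,
    annotation: AnnotationTrack | None = None,
    title: str | None = None,
) -> plt.Axes:
    """Draw one family/sample panel from its composition-table rows."""
    spec = spec or PlotSpec()
    fam = rows["family"].iloc[0] if len(rows) else "?"
    if len(rows) == 0 or (rows["cov"].to_numpy() + rows["phys_cov"].to_numpy()).sum() == 0:
        ax.text(0.5, 0.5, f"{fam}\nno coverage", ha="center", va="center",
                transform=ax.transAxes, fontsize=10, color="grey")
        ax.set_xticks([])
        ax.set_yticks([])
        return ax
    pos = rows["pos"].to_numpy()
    cov = rows["cov"].to_numpy(dtype=float)
    hq = rows["hq_cov"].to_numpy(dtype=float)
    ax.fill_between(pos, 0, cov, step="mid", color="#cccccc", label="ambiguous")
    ax.fill_between(pos, 0, hq, step="mid", color="#555555", label="unambiguous")

    # SNP bars: non-reference allele counts at segregating/fixed sites
    snp_rows = rows[rows["snp"].isin(["seg", "fixed"])]
    for _, r in snp_rows.iterrows():
        bottom = 0.0
        local = max(float(r["cov"]), 1e-9)
        counts = {b: float(r[b]) for b in "ACGT"}
        for b in "ACGT":
            if b == r["refbase"]:
                continue
            h = counts[b] / max(sum(counts.values()), 1e-9) * local
            if h <= 0:
                continue
            ax.bar(r["pos"], h, bottom=bottom, width=max(len(pos) / 400, 1.0),
                   color=spec.base_colours[b], zorder=3)
            bottom += h

    ymax = max(cov.max(), 1.0)
    # internal deletions: arcs with width ~ corrected support
    calls = []
    for cell in rows["int_del"]:
        calls.extend(_parse_int_del(cell))
    if calls:
        cmax = max(c for _, _, c in calls)
        for s, e, c in calls:
            width = 0.5 + (MAX_ARC_WIDTH - 0.5) * (c / cmax)
            centre = (s + e) / 2
            arc = Arc((centre, ymax), e - s, 0.6 * ymax, theta1=0, theta2=180,
                      lw=width, color="#7b3294", zorder=4)
            ax.add_patch(arc)
    # truncations: dashed lines from the consensus edge, opacity ~ frequency
    for side_col, side in (("trunc_left", "left"), ("trunc_right", "right")):
        tr = rows[rows[side_col] > 0]
        for _, r in tr.iterrows():
            count = float(r[side_col])
            local_cov = float(r["cov"])
            freq = count / (count + local_cov) if count + local_cov > 0 else 0
            alpha = min(1.0, MIN_TRUNC_ALPHA + (1 - MIN_TRUNC_ALPHA) * freq)
            x0 = pos.min() if side == "left" else pos.max()
            y = ymax * 1.05
            ax.plot([x0, r["pos"]], [y, y], ls="--", color="black", alpha=alpha, lw=1.5)
    ax.set_xlim(pos.min(), pos.max())
    ax.set_ylim(0, ymax * 1.25)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(spec.ylabel)
    ax.set_title(title or f"{fam} — {rows['sample_id'].iloc[0]}", fontsize=10)
    if annotation is not None and spec.show_annotation:
        for s, e, _t, label in annotation.for_contig(fam):
            ax.axvspan(s, e, ymin=0.0, ymax=0.03, color="#fdae61")
            ax.text((s + e) / 2, -0.06 * ymax, label, ha="center", va="top", fontsize=6)
    return ax


def plot_grid(
    tables: list[pd.DataFrame],
    out_path: str | Path,
    spec: PlotSpec | None = None,
    annotation: AnnotationTrack | None = None,
) -> Path:
    """Arrange samples as rows and families as columns; write PDF or EPS.

    Tables must share one normalization mode; columns share their x-axis and,
    when a normalization is set, their y-scale.
    """
    spec = spec or PlotSpec()
    if not tables:
        raise TescopeError("no tables to plot")
    if spec.output_format not in ("pdf", "eps"):
        raise TescopeError(f"unsupported output format {spec.output_format!r}")
    samples, families = [], []
    for t in tables:
        for s in t["sample_id"].unique():
            if s not in samples:
                samples.append(s)
        for f in t["family"].unique():
            if f not in families:
                families.append(f)
    big = pd.concat(tables, ignore_index=True)
    nrow, ncol = len(samples), len(families)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(max(6, 5 * ncol), 2.8 * nrow), squeeze=False,
        sharex="col",
    )
    for i, smp in enumerate(samples):
        for j, fam in enumerate(families):
            rows = big[(big["sample_id"] == smp) & (big["family"] == fam)]
            plot_family(axes[i][j], rows, spec, annotation, title=f"{fam} — {smp}")
    if spec.normalization != "none":
        for j in range(ncol):
            ymax = max(ax.get_ylim()[1] for ax in (axes[i][j] for i in range(nrow)))
            for i in range(nrow):
                axes[i][j].set_ylim(0, ymax)
    if spec.show_legend:
        handles = [
            plt.Rectangle((0, 0), 1, 1, color="#555555"),
            plt.Rectangle((0, 0), 1, 1, color="#cccccc"),
        ] + [plt.Rectangle((0, 0), 1, 1, color=c) for c in spec.base_colours.values()]
        labels = ["unambiguous", "ambiguous"] + [f"SNP {b}" for b in spec.base_colours]
        fig.legend(handles, labels, loc="upper center", ncol=6, fontsize=8, frameon=False)
    fig.tight_layout(rect=(0, 0, 1, 0.95))
    out_path = Path(out_path)
    if spec.output_format == "pdf":
        # suppress the timestamp so identical inputs give identical bytes
        fig.savefig(out_path, format="pdf", metadata={"CreationDate": None})
    else:
        fig.savefig(out_path, format=spec.output_format)
    plt.close(fig)
    return out_path
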