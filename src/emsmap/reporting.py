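"""Assemble mapping results into tracks, plots and a machine-readable report.

Two visual summaries are produced: a genome-wide SNP-index.DIV scatter with
the 1/3 threshold as a dashed horizontal line, and a close-up of
SNP-index.MP for the filtered markers on the candidate chromosome with the
smoothed curve and a dashed vertical line at its peak.  Whole-genome
depth/SNP-density rings are deliberately replaced by per-chromosome linear
panels, which carry the same information with a far simpler surface.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bsa import BSAResults
from .io import natural_chromosome_key, write_markers_tsv

logger = logging.getLogger(__name__)


@dataclass
class TrackBundle:
    """Plot-ready tracks extracted from fitted results."""

    genome_wide: pd.DataFrame  # chromosome, position, snp_index_div, passes_filter
    closeup: pd.DataFrame  # position, snp_index_mp, smoothed_mp (candidate chromosome)
    threshold: float
    candidate_chromosome: str | None
    peak_position: int | None


def build_tracks(results: BSAResults) -> TrackBundle:
    """Extract the genome-wide DIV track and the candidate-chromosome close-up.

    The close-up is restricted to filtered markers on the candidate
    chromosome; with zero filtered markers it is empty and a warning is
    issued.  The threshold line carries the model's DIV cutoff (1/3 by
    default) regardless of the data.
    """
    markers = results.markers
    genome_wide = (
        markers[["chromosome", "position", "snp_index_div", "passes_filter"]]
        .assign(_key=markers["chromosome"].map(natural_chromosome_key))
        .sort_values(["_key", "position"], kind="mergesort")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    if results.candidate_chromosome is None:
        warnings.warn("no filtered markers: close-up track is empty", stacklevel=2)
        closeup = pd.DataFrame(columns=["position", "snp_index_mp", "smoothed_mp"])
    else:
        closeup = results.closeup[["position", "snp_index_mp", "smoothed_mp"]].copy()
    return TrackBundle(
        genome_wide=genome_wide,
        closeup=closeup,
        threshold=results.theoretical.div_threshold,
        candidate_chromosome=results.candidate_chromosome,
        peak_position=results.peak_position,
    )


def plot_genome_wide(tracks: TrackBundle, ax=None):
    """Genome-wide SNP-index.DIV scatter with the dashed threshold line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for name, group in tracks.genome_wide.groupby("chromosome", sort=False):
        x = group["position"].to_numpy() + offset
        ax.scatter(x, group["snp_index_div"], s=3, alpha=0.5)
        ax.scatter(
            x[group["passes_filter"]],
            group.loc[group["passes_filter"], "snp_index_div"],
            s=6,
            color="crimson",
        )
        ticks.append(offset + group["position"].max() / 2)
        labels.append(str(name))
        offset += int(group["position"].max())
    ax.axhline(tracks.threshold, linestyle="--", color="black", linewidth=1)
    ax.set_xticks(ticks, labels, rotation=45, fontsize=7)
    ax.set_ylabel("SNP-index.DIV")
    return ax


def plot_closeup(tracks: TrackBundle, ax=None):
    """Close-up of SNP-index.MP with smoothed curve and dashed peak line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    if tracks.closeup.empty:
        ax.set_title("no filtered markers")
        return ax
    mb = tracks.closeup["position"] / 1e6
    ax.scatter(mb, tracks.closeup["snp_index_mp"], s=8, alpha=0.6, label="SNP-index.MP")
    ax.plot(mb, tracks.closeup["smoothed_mp"], color="black", label="smoothed")
    if tracks.peak_position is not None:
        ax.axvline(tracks.peak_position / 1e6, linestyle="--", color="black", linewidth=1)
    ax.set_xlabel(f"{tracks.candidate_chromosome} position (Mb)")
    ax.set_ylabel("SNP-index.MP")
    ax.legend(fontsize=7)
    return ax


def render_report(
    results: BSAResults, out_dir: str | Path, plots: bool = True
) -> dict[str, Path]:
    """Write markers TSV, track tables, a JSON run report and (optionally) plots.

    ``plots=False`` skips image generation for headless or speed-sensitive
    runs; all tabular outputs are always written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracks = build_tracks(results)

    paths: dict[str, Path] = {}
    paths["markers"] = write_markers_tsv(results.markers, out_dir / "markers.tsv")
    tracks.genome_wide.to_csv(out_dir / "track_genome_div.tsv", sep="\t", index=False)
    paths["track_genome"] = out_dir / "track_genome_div.tsv"
    tracks.closeup.to_csv(out_dir / "track_closeup_mp.tsv", sep="\t", index=False)
    paths["track_closeup"] = out_dir / "track_closeup_mp.tsv"

    report = results.to_dict()
    report["div_threshold_line"] = tracks.threshold
    paths["report"] = out_dir / "report.json"
    paths["report"].write_text(json.dumps(report, indent=2) + "\n")

    if plots:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        ax = plot_genome_wide(tracks)
        ax.figure.savefig(out_dir / "genome_wide_div.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        paths["plot_genome"] = out_dir / "genome_wide_div.png"

        ax = plot_closeup(tracks)
        ax.figure.savefig(out_dir / "closeup_mp.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        paths["plot_closeup"] = out_dir / "closeup_mp.png"

    logger.info("report written to %s", out_dir)
    return paths
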