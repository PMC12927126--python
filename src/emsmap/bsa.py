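"""MutMap-style bulked-segregant mapping from pooled allele depths.

The statistic is computed per marker from the two pools' allele depths:

* ``SNP-index = alt depth / total depth`` in each pool;
* ``SNP-index.DIV = |SNP-index.WP - theo_WP| + |SNP-index.MP - theo_MP|``,
  the summed absolute deviation from the theoretical causal-marker indices.

For a fully recessive single-gene trait scored in a selfed F2 ear the
theoretical indices are 1/3 in the wild-type pool and 1 in the mutant pool,
so the causal marker has DIV = 0 while an unlinked marker (index 1/2 in both
pools, or fixed at 1 in both) has expected DIV = 2/3.  Markers with
DIV < 1/3 are retained as trait-associated; the candidate chromosome is the
one most enriched in retained markers; the peak is the maximum of a
tricube-kernel smooth of SNP-index.MP along that chromosome; and candidate
causal mutations are the retained markers that are homozygous in the mutant
pool with a MODERATE/HIGH predicted impact, ordered by distance to the peak.

The module exposes both the individual operations and a statsmodels-style
pair: :class:`BulkedSegregantAnalysis` (the model, built from variant data)
whose :meth:`~BulkedSegregantAnalysis.fit` returns :class:`BSAResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, NoSignalError
from .io import (
    MP,
    WP,
    PoolObservation,
    VariantRecord,
    natural_chromosome_key,
    read_pooled_vcf,
    read_variants_table,
    variants_to_dataframe,
)

logger = logging.getLogger(__name__)

THIRD = 1.0 / 3.0


@dataclass(frozen=True)
class TheoreticalModel:
    """Expected causal-marker indices and the filtering rule.

    ``theo_wp``/``theo_mp`` are the theoretical SNP-indices of the causal
    marker in the wild-type and mutant pools (1/3 and 1 for a recessive
    single-gene trait).  Markers with DIV strictly below ``div_threshold``
    pass the filter.  ``min_depth`` is the minimum per-pool depth for a
    marker to be scored at all (0 disables all but the zero-depth rule).
    """

    theo_wp: float = THIRD
    theo_mp: float = 1.0
    div_threshold: float = THIRD
    min_depth: int = 5

    def __post_init__(self) -> None:
        for name, value in (("theo_wp", self.theo_wp), ("theo_mp", self.theo_mp)):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.div_threshold <= 0:
            raise ConfigurationError("div_threshold must be positive")
        if self.min_depth < 0:
            raise ConfigurationError("min_depth must be non-negative")


DEFAULT_MODEL = TheoreticalModel()


def snp_index(observation: PoolObservation | tuple[int, int]) -> float:
    """Fraction of reads carrying the alternative allele in one pool.

    Raises ``ValueError`` at zero total depth (the marker is undefined there;
    :func:`score_markers` excludes and counts such markers instead).
    """
    if isinstance(observation, PoolObservation):
        ad_ref, ad_alt = observation.ad_ref, observation.ad_alt
    else:
        ad_ref, ad_alt = observation
    total = ad_ref + ad_alt
    if total < 1:
        raise ValueError("SNP-index is undefined at zero depth")
    return ad_alt / total


def snp_index_div(
    idx_wp: float, idx_mp: float, model: TheoreticalModel = DEFAULT_MODEL
) -> float:
    """Summed absolute deviation of the two pool indices from theory."""
    for name, value in (("idx_wp", idx_wp), ("idx_mp", idx_mp)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    return abs(idx_wp - model.theo_wp) + abs(idx_mp - model.theo_mp)


_MARKER_COLUMNS = ["chromosome", "position", "ref", "alt",
                   "ad_ref_wp", "ad_alt_wp", "ad_ref_mp", "ad_alt_mp"]


def score_markers(
    variants: Sequence[VariantRecord] | pd.DataFrame,
    model: TheoreticalModel = DEFAULT_MODEL,
) -> pd.DataFrame:
    """Compute both SNP-indices, DIV and the filter flag for every marker.

    Markers below ``model.min_depth`` (or at zero depth) in either pool are
    excluded; the counts are kept in the result's ``attrs`` (``n_input``,
    ``n_excluded``).  ``passes_filter`` applies the strict ``DIV <
    div_threshold`` inequality.
    """
    if isinstance(variants, pd.DataFrame):
        df = variants.copy()
        missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"marker dataframe lacks columns {missing}")
    else:
        df = variants_to_dataframe(variants)
    n_input = len(df)

    depth_wp = df["ad_ref_wp"] + df["ad_alt_wp"]
    depth_mp = df["ad_ref_mp"] + df["ad_alt_mp"]
    floor = max(model.min_depth, 1)
    scorable = (depth_wp >= floor) & (depth_mp >= floor)
    df = df.loc[scorable].reset_index(drop=True)

    with np.errstate(invalid="ignore"):
        df["snp_index_wp"] = df["ad_alt_wp"] / (df["ad_ref_wp"] + df["ad_alt_wp"])
        df["snp_index_mp"] = df["ad_alt_mp"] / (df["ad_ref_mp"] + df["ad_alt_mp"])
    df["snp_index_div"] = np.abs(df["snp_index_wp"] - model.theo_wp) + np.abs(
        df["snp_index_mp"] - model.theo_mp
    )
    df["passes_filter"] = df["snp_index_div"] < model.div_threshold

    df.attrs["n_input"] = n_input
    df.attrs["n_excluded"] = n_input - len(df)
    if df.empty:
        warnings.warn("no scorable markers after the depth rule", stacklevel=2)
    return df


def select_candidate_chromosome(filtered_markers: pd.DataFrame | Sequence[str]) -> str:
    """Chromosome carrying the most filtered markers (natural order breaks ties)."""
    if isinstance(filtered_markers, pd.DataFrame):
        chromosomes = filtered_markers["chromosome"]
    else:
        chromosomes = pd.Series(list(filtered_markers), dtype=object)
    if len(chromosomes) == 0:
        raise NoSignalError("no filtered markers: cannot select a candidate chromosome")
    counts = chromosomes.value_counts()
    best = counts[counts == counts.max()].index
    return min(best, key=natural_chromosome_key)


def smooth_track(
    positions: Sequence[float], values: Sequence[float], bandwidth_bp: float = 2e6
) -> np.ndarray:
    """Tricube-kernel local average (Nadaraya-Watson) along the chromosome.

    Each smoothed value is a convex combination of the observed values, so
    the output is bounded by the observed range; a point with no neighbours
    inside the bandwidth returns its own value.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.size == 0:
        raise ValueError("smooth_track needs at least one point")
    if positions.size != values.size:
        raise ValueError("positions and values must have equal length")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    if bandwidth_bp <= 0:
        raise ValueError("bandwidth must be positive")
    u = np.abs(positions[:, None] - positions[None, :]) / bandwidth_bp
    weights = np.clip(1.0 - u**3, 0.0, None) ** 3
    return (weights @ values) / weights.sum(axis=1)


def locate_peak(positions: Sequence[float], smoothed_values: Sequence[float]) -> int:
    """Position of the maximum smoothed value (ties: smallest position)."""
    positions = np.asarray(positions)
    smoothed_values = np.asarray(smoothed_values, dtype=float)
    if positions.size == 0:
        raise ValueError("locate_peak needs at least one point")
    return int(positions[int(np.argmax(smoothed_values))])


_IMPACT_RANK = {"HIGH": 0, "MODERATE": 1}


def rank_candidates(
    filtered_markers: pd.DataFrame,
    peak_position: int,
    homozygosity_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Candidate causal mutations among the filtered markers.

    Retains markers homozygous in the mutant pool (``snp_index_mp >= 1 -
    tolerance``) whose predicted impact is MODERATE or HIGH (absent
    annotations count as MODIFIER), ordered by distance to the peak and then
    HIGH before MODERATE.  An empty result is reported, not an error.
    """
    if not 0.0 <= homozygosity_tolerance <= 1.0:
        raise ConfigurationError("homozygosity_tolerance must be in [0, 1]")
    df = filtered_markers.copy()
    impact = df["impact"].fillna("") if "impact" in df.columns else pd.Series("", index=df.index)
    keep = (df["snp_index_mp"] >= 1.0 - homozygosity_tolerance) & impact.isin(
        list(_IMPACT_RANK)
    )
    df = df.loc[keep].copy()
    if df.empty:
        logger.info("no candidate mutation satisfies the homozygosity/impact rule")
        df["distance_to_peak"] = pd.Series(dtype=int)
        return df
    df["distance_to_peak"] = (df["position"] - peak_position).abs()
    df["_impact_rank"] = df["impact"].map(_IMPACT_RANK)
    df = df.sort_values(
        ["distance_to_peak", "_impact_rank", "position"], kind="mergesort"
    ).drop(columns="_impact_rank")
    return df.reset_index(drop=True)


class BulkedSegregantAnalysis:
    """Bulked-segregant mapping model over two-pool allele-depth data.

    Parameters
    ----------
    variants
        A sequence of :class:`~emsmap.io.VariantRecord` with observations for
        both pools, or an equivalent wide dataframe (see
        :func:`~emsmap.io.variants_to_dataframe` for the columns).
    theoretical
        The :class:`TheoreticalModel` to score against; defaults to the
        recessive single-gene expectations (1/3, 1, threshold 1/3).

    Examples
    --------
    >>> model = BulkedSegregantAnalysis.from_vcf("pools.vcf")  # doctest: +SKIP
    >>> results = model.fit(bandwidth=2e6)                     # doctest: +SKIP
    >>> print(results.summary())                               # doctest: +SKIP
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord] | pd.DataFrame,
        theoretical: TheoreticalModel | None = None,
    ) -> None:
        self.theoretical = theoretical or DEFAULT_MODEL
        if isinstance(variants, pd.DataFrame):
            self.data = variants.copy()
        else:
            self.data = variants_to_dataframe(variants)
        if self.data.empty:
            warnings.warn("model built from zero variants", stacklevel=2)

    @classmethod
    def from_vcf(
        cls,
        path: str | Path,
        wp_sample: str = WP,
        mp_sample: str = MP,
        theoretical: TheoreticalModel | None = None,
    ) -> "BulkedSegregantAnalysis":
        return cls(read_pooled_vcf(path, wp_sample, mp_sample), theoretical)

    @classmethod
    def from_table(
        cls,
        path: str | Path,
        wp_sample: str = WP,
        mp_sample: str = MP,
        theoretical: TheoreticalModel | None = None,
    ) -> "BulkedSegregantAnalysis":
        return cls(read_variants_table(path, wp_sample, mp_sample), theoretical)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, theoretical: TheoreticalModel | None = None
    ) -> "BulkedSegregantAnalysis":
        return cls(df, theoretical)

    def fit(
        self,
        bandwidth: float = 2_000_000.0,
        homozygosity_tolerance: float = 0.0,
    ) -> "BSAResults":
        """Score all markers and localize the candidate mutation.

        ``bandwidth`` is the tricube smoothing bandwidth in bp (also the
        half-width used for the reported candidate interval);
        ``homozygosity_tolerance`` relaxes the mutant-pool homozygosity
        requirement for finite-depth data (0 demands SNP-index.MP == 1).
        """
        markers = score_markers(self.data, self.theoretical)
        filtered = markers.loc[markers["passes_filter"]]
        logger.info(
            "scored %d/%d markers, %d pass DIV < %.4g",
            len(markers),
            markers.attrs.get("n_input", len(markers)),
            len(filtered),
            self.theoretical.div_threshold,
        )

        if filtered.empty:
            warnings.warn("zero filtered markers: no mapping signal", stacklevel=2)
            return BSAResults(
                model=self,
                markers=markers,
                bandwidth=bandwidth,
                homozygosity_tolerance=homozygosity_tolerance,
            )

        chromosome = select_candidate_chromosome(filtered)
        closeup = (
            filtered.loc[filtered["chromosome"] == chromosome]
            .sort_values("position", kind="mergesort")
            .reset_index(drop=True)
        )
        smoothed = smooth_track(
            closeup["position"].to_numpy(), closeup["snp_index_mp"].to_numpy(), bandwidth
        )
        closeup = closeup.assign(smoothed_mp=smoothed)
        peak = locate_peak(closeup["position"].to_numpy(), smoothed)
        near_peak = closeup.loc[(closeup["position"] - peak).abs() <= bandwidth]
        interval = (int(near_peak["position"].min()), int(near_peak["position"].max()))
        ranked = rank_candidates(closeup, peak, homozygosity_tolerance)

        return BSAResults(
            model=self,
            markers=markers,
            bandwidth=bandwidth,
            homozygosity_tolerance=homozygosity_tolerance,
            candidate_chromosome=chromosome,
            peak_position=peak,
            candidate_interval=interval,
            ranked_candidates=ranked,
            closeup=closeup,
        )


@dataclass
class BSAResults:
    """Fitted mapping results: scored markers, localization and candidates."""

    model: BulkedSegregantAnalysis
    markers: pd.DataFrame
    bandwidth: float
    homozygosity_tolerance: float
    candidate_chromosome: str | None = None
    peak_position: int | None = None
    candidate_interval: tuple[int, int] | None = None
    ranked_candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    closeup: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def theoretical(self) -> TheoreticalModel:
        return self.model.theoretical

    @property
    def n_detected(self) -> int:
        return int(self.markers.attrs.get("n_input", len(self.markers)))

    @property
    def n_excluded(self) -> int:
        return int(self.markers.attrs.get("n_excluded", 0))

    @property
    def n_filtered(self) -> int:
        return int(self.markers["passes_filter"].sum()) if len(self.markers) else 0

    def summary(self) -> str:
        """Human-readable run summary, statsmodels style."""
        lines = [
            "        Bulked Segregant Analysis (MutMap SNP-index)",
            "=" * 60,
            f"SNPs detected                 {self.n_detected:>10d}",
            f"SNPs excluded (depth rule)    {self.n_excluded:>10d}",
            f"SNPs passing DIV filter       {self.n_filtered:>10d}",
            f"DIV threshold                 {self.theoretical.div_threshold:>10.4f}",
            f"Theoretical WP/MP index        {self.theoretical.theo_wp:.4f} / "
            f"{self.theoretical.theo_mp:.4f}",
        ]
        if self.candidate_chromosome is None:
            lines.append("Candidate chromosome            (no signal)")
        else:
            lines += [
                f"Candidate chromosome          {self.candidate_chromosome:>10s}",
                f"Peak position (bp)            {self.peak_position:>10d}",
                f"Candidate interval (bp)       [{self.candidate_interval[0]}, "
                f"{self.candidate_interval[1]}]",
                f"Candidate mutations           {len(self.ranked_candidates):>10d}",
            ]
            for row in self.ranked_candidates.head(5).itertuples(index=False):
                lines.append(
                    f"  {row.chromosome}:{row.position} {row.ref}>{row.alt}  "
                    f"{row.effect or 'unannotated'} {row.impact} {row.gene_id} "
                    f"{row.hgvs_c} {row.hgvs_p}  d={row.distance_to_peak / 1e6:.3f} Mb"
                )
        lines.append("=" * 60)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-safe run report (counts, localization, ranked candidates)."""
        return {
            "n_detected": self.n_detected,
            "n_excluded": self.n_excluded,
            "n_filtered": self.n_filtered,
            "theoretical": {
                "theo_wp": self.theoretical.theo_wp,
                "theo_mp": self.theoretical.theo_mp,
                "div_threshold": self.theoretical.div_threshold,
                "min_depth": self.theoretical.min_depth,
            },
            "bandwidth_bp": self.bandwidth,
            "homozygosity_tolerance": self.homozygosity_tolerance,
            "candidate_chromosome": self.candidate_chromosome,
            "peak_position": self.peak_position,
            "candidate_interval": list(self.candidate_interval)
            if self.candidate_interval
            else None,
            "ranked_candidates": self.ranked_candidates.to_dict(orient="records"),
        }

    def save(self, out_dir: str | Path, plots: bool = True) -> dict[str, Path]:
        """Write the marker table, JSON report, track tables and plots."""
        from .reporting import render_report

        return render_report(self, out_dir, plots=plots)


def run_pipeline(
    vcf: str | Path | None = None,
    table: str | Path | None = None,
    out_dir: str | Path | None = None,
    reference: str | Path | None = None,
    gff3: str | Path | None = None,
    wp_sample: str = WP,
    mp_sample: str = MP,
    theoretical: TheoreticalModel | None = None,
    bandwidth: float = 2_000_000.0,
    homozygosity_tolerance: float = 0.0,
    plots: bool = True,
) -> BSAResults:
    """End-to-end run: ingest, (re)annotate if resources given, fit, export.

    Exactly one of ``vcf``/``table`` must be provided.  If both a reference
    FASTA and a gene-model GFF3 are given, variants without annotations are
    annotated before scoring.
    """
    if (vcf is None) == (table is None):
        raise ConfigurationError("provide exactly one of vcf= or table=")
    if vcf is not None:
        logger.info("reading VCF %s", vcf)
        variants = read_pooled_vcf(vcf, wp_sample, mp_sample)
    else:
        logger.info("reading variant table %s", table)
        variants = read_variants_table(table, wp_sample, mp_sample)

    if reference is not None and gff3 is not None:
        import pyfaidx

        from .annotate import annotate_variants, read_gff3

        logger.info("annotating variants against %s / %s", gff3, reference)
        genes = read_gff3(gff3)
        fasta = pyfaidx.Fasta(str(reference))
        bare = [v for v in variants if v.annotation is None]
        annotate_variants(bare, genes, fasta)

    model = BulkedSegregantAnalysis(variants, theoretical)
    results = model.fit(bandwidth=bandwidth, homozygosity_tolerance=homozygosity_tolerance)
    if out_dir is not None:
        results.save(out_dir, plots=plots)
    return results
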