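"""Reading and writing the standard formats the pipeline touches.

Variants enter the pipeline either as a VCF with per-sample allele depths
(``AD`` in FORMAT) for the two phenotype pools, or as a GATK
VariantsToTable-style tab-separated table with ``CHROM POS REF ALT`` plus
per-sample ``<sample>.GT`` / ``<sample>.AD`` columns.  Both routes produce the
same list of :class:`VariantRecord` objects, so every downstream number is
independent of the container format.

SnpEff-style ``ANN`` INFO strings are parsed into :class:`EffectAnnotation`
(first entry only: SnpEff lists the most severe annotation first).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .exceptions import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: Canonical pool identifiers: wild-type pool and mutant pool.
WP = "WP"
MP = "MP"

_NUCLEOTIDES = frozenset("ACGT")


class EffectClass(str, Enum):
    """Variant consequence vocabulary used throughout the package."""

    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    START_LOST = "start_lost"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"


#: SnpEff-convention impact for each effect class.
IMPACT_FOR: dict[EffectClass, str] = {
    EffectClass.MISSENSE: "MODERATE",
    EffectClass.STOP_GAINED: "HIGH",
    EffectClass.START_LOST: "HIGH",
    EffectClass.SYNONYMOUS: "LOW",
    EffectClass.INTRONIC: "MODIFIER",
    EffectClass.INTERGENIC: "MODIFIER",
}

#: Sequence-ontology terms (as printed by SnpEff) mapped to EffectClass.
_SO_TERM_TO_CLASS: dict[str, EffectClass] = {
    "missense_variant": EffectClass.MISSENSE,
    "stop_gained": EffectClass.STOP_GAINED,
    "start_lost": EffectClass.START_LOST,
    "synonymous_variant": EffectClass.SYNONYMOUS,
    "intron_variant": EffectClass.INTRONIC,
    "intergenic_region": EffectClass.INTERGENIC,
    "intergenic_variant": EffectClass.INTERGENIC,
}

_CLASS_TO_SO_TERM: dict[EffectClass, str] = {
    EffectClass.MISSENSE: "missense_variant",
    EffectClass.STOP_GAINED: "stop_gained",
    EffectClass.START_LOST: "start_lost",
    EffectClass.SYNONYMOUS: "synonymous_variant",
    EffectClass.INTRONIC: "intron_variant",
    EffectClass.INTERGENIC: "intergenic_region",
}


@dataclass(frozen=True)
class EffectAnnotation:
    """One predicted consequence of a SNP on a gene model."""

    effect_class: EffectClass
    impact: str
    gene_id: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""

    def to_ann(self, alt_allele: str) -> str:
        """Render as a SnpEff-style 16-field ``ANN`` entry."""
        fields = [""] * 16
        fields[0] = alt_allele
        fields[1] = _CLASS_TO_SO_TERM[self.effect_class]
        fields[2] = self.impact
        fields[3] = self.gene_id
        fields[4] = self.gene_id
        fields[5] = "transcript"
        fields[6] = f"{self.gene_id}_T001" if self.gene_id else ""
        fields[7] = "protein_coding"
        fields[9] = self.hgvs_c
        fields[10] = self.hgvs_p
        return "|".join(fields)


@dataclass(frozen=True)
class PoolObservation:
    """Reference/alternative allele read depths for one pool at one variant."""

    ad_ref: int
    ad_alt: int

    def __post_init__(self) -> None:
        if self.ad_ref < 0 or self.ad_alt < 0:
            raise ValueError("allele depths must be non-negative")

    @property
    def depth(self) -> int:
        return self.ad_ref + self.ad_alt


@dataclass
class VariantRecord:
    """One biallelic SNP with 1-based coordinates and per-pool allele depths."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    annotation: EffectAnnotation | None = None
    pools: dict[str, PoolObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-nucleotide alleles are supported")
        if self.ref_allele == self.alt_allele:
            raise ValueError("REF and ALT must differ")


def parse_ann_field(ann_string: str) -> EffectAnnotation:
    """Parse the first entry of a SnpEff ``ANN`` INFO value.

    Unknown effect terms are mapped to intergenic/MODIFIER with a warning.
    Fewer than 11 pipe-delimited subfields raises :class:`FormatError`.
    """
    if not ann_string:
        raise FormatError("empty ANN string")
    first = ann_string.split(",")[0]
    parts = first.split("|")
    if len(parts) < 11:
        raise FormatError(
            f"ANN entry has {len(parts)} subfields, expected at least 11: {first!r}"
        )
    term = parts[1]
    effect = _SO_TERM_TO_CLASS.get(term)
    if effect is None:
        logger.warning("unknown ANN effect term %r; treating as intergenic/MODIFIER", term)
        effect = EffectClass.INTERGENIC
    return EffectAnnotation(
        effect_class=effect,
        impact=IMPACT_FOR[effect],
        gene_id=parts[3],
        hgvs_c=parts[9],
        hgvs_p=parts[10],
    )


def _is_biallelic_snp(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref in _NUCLEOTIDES
        and alts[0] in _NUCLEOTIDES
    )


def read_pooled_vcf(
    path: str | Path,
    wp_sample: str = WP,
    mp_sample: str = MP,
) -> list[VariantRecord]:
    """Read a two-pool VCF into :class:`VariantRecord` objects.

    Multi-allelic and indel lines are skipped (counted and logged).  A SNP line
    without AD raises :class:`FormatError`; a missing pool sample raises
    :class:`ConfigurationError`.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for sample in (wp_sample, mp_sample):
        if sample not in samples:
            raise ConfigurationError(
                f"sample {sample!r} not found in VCF (samples: {samples})"
            )
    wp_idx = samples.index(wp_sample)
    mp_idx = samples.index(mp_sample)

    records: list[VariantRecord] = []
    n_skipped = 0
    for v in vcf:
        if not _is_biallelic_snp(v.REF, v.ALT):
            n_skipped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise FormatError(f"no AD field at {v.CHROM}:{v.POS}")
        ann_raw = v.INFO.get("ANN")
        annotation = parse_ann_field(ann_raw) if ann_raw else None
        records.append(
            VariantRecord(
                chromosome=v.CHROM,
                position=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                annotation=annotation,
                pools={
                    WP: PoolObservation(int(ad[wp_idx, 0]), int(ad[wp_idx, 1])),
                    MP: PoolObservation(int(ad[mp_idx, 0]), int(ad[mp_idx, 1])),
                },
            )
        )
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel lines in %s", n_skipped, path)
    return records


_AD_RE = re.compile(r"^\d+,\d+$")


def _parse_ad(value: object, column: str) -> tuple[int, int]:
    text = str(value).strip()
    if not _AD_RE.match(text):
        raise FormatError(f"malformed AD value {text!r} in column {column!r}")
    ref_d, alt_d = text.split(",")
    return int(ref_d), int(alt_d)


def read_variants_table(
    path: str | Path,
    wp_sample: str = WP,
    mp_sample: str = MP,
) -> list[VariantRecord]:
    """Read a GATK VariantsToTable-style TSV into :class:`VariantRecord` objects.

    Required columns: ``CHROM POS REF ALT`` and ``<sample>.AD`` for both pools
    (``<sample>.GT`` is accepted but unused: the statistic is defined on allele
    depths only).  An optional ``ANN`` column is parsed like the VCF INFO
    field.  Gzip-compressed files are read transparently.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    wp_ad_col = f"{wp_sample}.AD"
    mp_ad_col = f"{mp_sample}.AD"
    for column in ("CHROM", "POS", "REF", "ALT", wp_ad_col, mp_ad_col):
        if column not in df.columns:
            raise FormatError(f"missing required column {column!r} in {path}")

    has_ann = "ANN" in df.columns
    records: list[VariantRecord] = []
    n_skipped = 0
    for i in range(len(df)):
        ref = str(df["REF"].iloc[i])
        alt = str(df["ALT"].iloc[i])
        if not _is_biallelic_snp(ref, alt.split(",")):
            n_skipped += 1
            continue
        wp_ref, wp_alt = _parse_ad(df[wp_ad_col].iloc[i], wp_ad_col)
        mp_ref, mp_alt = _parse_ad(df[mp_ad_col].iloc[i], mp_ad_col)
        annotation = None
        if has_ann:
            raw = df["ANN"].iloc[i]
            if isinstance(raw, str) and raw and raw != ".":
                annotation = parse_ann_field(raw)
        records.append(
            VariantRecord(
                chromosome=str(df["CHROM"].iloc[i]),
                position=int(df["POS"].iloc[i]),
                ref_allele=ref,
                alt_allele=alt,
                annotation=annotation,
                pools={
                    WP: PoolObservation(wp_ref, wp_alt),
                    MP: PoolObservation(mp_ref, mp_alt),
                },
            )
        )
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel rows in %s", n_skipped, path)
    return records


def _genotype_call(obs: PoolObservation) -> str:
    if obs.depth == 0:
        return "./."
    if obs.ad_alt == 0:
        return "0/0"
    if obs.ad_ref == 0:
        return "1/1"
    return "0/1"


def write_pooled_vcf(
    variants: Iterable[VariantRecord],
    path: str | Path,
    contigs: dict[str, int] | None = None,
    wp_sample: str = WP,
    mp_sample: str = MP,
) -> Path:
    """Write records as a minimal two-sample VCF v4.2 (GT and AD in FORMAT).

    The header carries no timestamp so output is byte-reproducible.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=emsmap"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | "
        "Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | cDNA.pos / cDNA.length | "
        "CDS.pos / CDS.length | AA.pos / AA.length | Distance | ERRORS / WARNINGS / INFO'\">",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + f"{wp_sample}\t{mp_sample}",
    ]
    for v in variants:
        info = v.annotation.to_ann(v.alt_allele) if v.annotation else None
        info_field = f"ANN={info}" if info else "."
        wp = v.pools[WP]
        mp = v.pools[MP]
        lines.append(
            "\t".join(
                [
                    v.chromosome,
                    str(v.position),
                    ".",
                    v.ref_allele,
                    v.alt_allele,
                    ".",
                    "PASS",
                    info_field,
                    "GT:AD",
                    f"{_genotype_call(wp)}:{wp.ad_ref},{wp.ad_alt}",
                    f"{_genotype_call(mp)}:{mp.ad_ref},{mp.ad_alt}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_variants_table(
    variants: Iterable[VariantRecord],
    path: str | Path,
    wp_sample: str = WP,
    mp_sample: str = MP,
) -> Path:
    """Write records as a GATK VariantsToTable-style TSV (CHROM POS REF ALT, GT/AD per pool)."""
    path = Path(path)
    rows = []
    for v in variants:
        wp = v.pools[WP]
        mp = v.pools[MP]
        rows.append(
            {
                "CHROM": v.chromosome,
                "POS": v.position,
                "REF": v.ref_allele,
                "ALT": v.alt_allele,
                f"{wp_sample}.GT": _genotype_call(wp),
                f"{wp_sample}.AD": f"{wp.ad_ref},{wp.ad_alt}",
                f"{mp_sample}.GT": _genotype_call(mp),
                f"{mp_sample}.AD": f"{mp.ad_ref},{mp.ad_alt}",
                "ANN": v.annotation.to_ann(v.alt_allele) if v.annotation else ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def natural_chromosome_key(name: str) -> tuple:
    """Sort key ordering chr2 before chr10 (digit runs compared numerically)."""
    return tuple(
        int(part) if part.isdigit() else part for part in re.split(r"(\d+)", str(name))
    )


def variants_to_dataframe(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    """Flatten records into the wide per-marker table used by the statistics."""
    rows = []
    for v in variants:
        ann = v.annotation
        wp = v.pools.get(WP)
        mp = v.pools.get(MP)
        if wp is None or mp is None:
            raise ConfigurationError(
                f"variant {v.chromosome}:{v.position} lacks an observation "
                "for one of the pools"
            )
        rows.append(
            (
                v.chromosome,
                v.position,
                v.ref_allele,
                v.alt_allele,
                wp.ad_ref,
                wp.ad_alt,
                mp.ad_ref,
                mp.ad_alt,
                ann.effect_class.value if ann else "",
                ann.impact if ann else "",
                ann.gene_id if ann else "",
                ann.hgvs_c if ann else "",
                ann.hgvs_p if ann else "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "position",
            "ref",
            "alt",
            "ad_ref_wp",
            "ad_alt_wp",
            "ad_ref_mp",
            "ad_alt_mp",
            "effect",
            "impact",
            "gene_id",
            "hgvs_c",
            "hgvs_p",
        ],
    )


def dataframe_to_variants(df: pd.DataFrame) -> list[VariantRecord]:
    """Inverse of :func:`variants_to_dataframe` (annotation fields optional)."""
    records = []
    for row in df.itertuples(index=False):
        effect = getattr(row, "effect", "")
        annotation = None
        if isinstance(effect, str) and effect:
            effect_class = EffectClass(effect)
            annotation = EffectAnnotation(
                effect_class=effect_class,
                impact=getattr(row, "impact", "") or IMPACT_FOR[effect_class],
                gene_id=getattr(row, "gene_id", "") or "",
                hgvs_c=getattr(row, "hgvs_c", "") or "",
                hgvs_p=getattr(row, "hgvs_p", "") or "",
            )
        records.append(
            VariantRecord(
                chromosome=str(row.chromosome),
                position=int(row.position),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                annotation=annotation,
                pools={
                    WP: PoolObservation(int(row.ad_ref_wp), int(row.ad_alt_wp)),
                    MP: PoolObservation(int(row.ad_ref_mp), int(row.ad_alt_mp)),
                },
            )
        )
    return records


def write_markers_tsv(markers: pd.DataFrame, path: str | Path) -> Path:
    """Write the scored-marker table, sorted by (chromosome, position).

    Chromosomes are ordered naturally (chr2 before chr10) so the layout is
    deterministic regardless of input order.
    """
    path = Path(path)
    df = markers.copy()
    df["_key"] = df["chromosome"].map(natural_chromosome_key)
    df = df.sort_values(["_key", "position"], kind="mergesort").drop(columns="_key")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_markers_tsv(path: str | Path) -> pd.DataFrame:
    """Read a marker table written by :func:`write_markers_tsv`."""
    df = pd.read_csv(path, sep="\t")
    for column in ("effect", "impact", "gene_id", "hgvs_c", "hgvs_p"):
        if column in df.columns:
            df[column] = df[column].fillna("")
    return df
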