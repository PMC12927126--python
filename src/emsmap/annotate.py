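"""A miniature strand-aware variant-effect annotator over toy gene models.

Gene models are ordered lists of 1-based closed CDS intervals on either
strand.  A SNP inside the CDS is projected to a coding-DNA position, the
affected codon is reconstructed from the reference and translated with the
standard nuclear genetic code, and the consequence is reported in HGVS
notation (``c.464C>T`` / ``p.P155L`` style, one-letter amino-acid codes).

Impact categories follow the SnpEff convention: start-lost and stop-gained
are HIGH, missense is MODERATE, synonymous is LOW, and non-coding positions
are MODIFIER.  Splice sites are not modelled: an intronic SNP is simply
intronic/MODIFIER.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
from Bio.Seq import Seq

from .exceptions import ConfigurationError, FormatError, ReferenceMismatchError
from .io import IMPACT_FOR, EffectAnnotation, EffectClass, VariantRecord

#: Byte codes used for in-memory reference arrays (0=A 1=C 2=G 3=T).
BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CodonAddress:
    """Position of a coding-DNA base inside its codon."""

    residue_index: int  # 1-based amino-acid position
    codon_offset: int  # 1, 2 or 3

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if self.codon_offset not in (1, 2, 3):
            raise ValueError("codon_offset must be in {1, 2, 3}")


def cds_position_to_codon(cds_position: int) -> CodonAddress:
    """Map a 1-based coding-DNA position to (residue index, offset in codon).

    c.464 lies at the second base of codon 155; c.1231 at the first base of
    codon 411.
    """
    if cds_position < 1:
        raise ValueError(f"cds_position must be >= 1, got {cds_position}")
    return CodonAddress(
        residue_index=(cds_position - 1) // 3 + 1,
        codon_offset=(cds_position - 1) % 3 + 1,
    )


@dataclass
class GeneModel:
    """Strand-aware CDS structure of one toy gene.

    ``cds_intervals`` are 1-based closed genomic intervals, sorted by genomic
    position and non-overlapping; the concatenated CDS length must be a
    multiple of 3.  On the minus strand the coding sequence runs from the
    3'-most genomic base backwards.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        intervals = tuple((int(a), int(b)) for a, b in self.cds_intervals)
        if not intervals:
            raise ValueError("gene model needs at least one CDS interval")
        prev_end = 0
        for start, end in intervals:
            if start < 1 or end < start:
                raise ValueError(f"bad CDS interval [{start}, {end}]")
            if start <= prev_end:
                raise ValueError("CDS intervals must be sorted and non-overlapping")
            prev_end = end
        self.cds_intervals = intervals
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.gene_id} not divisible by 3"
            )
        self._positions: np.ndarray | None = None

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint of the gene (first CDS base to last, introns included)."""
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def contains(self, position: int) -> bool:
        start, end = self.span
        return start <= position <= end

    def cds_genomic_positions(self) -> np.ndarray:
        """Genomic position of each CDS base, ordered by coding-DNA coordinate."""
        if self._positions is None:
            pieces = [np.arange(s, e + 1) for s, e in self.cds_intervals]
            order = np.concatenate(pieces)
            if self.strand == "-":
                order = order[::-1]
            self._positions = order
        return self._positions


def genomic_to_cds(gene: GeneModel, genomic_position: int) -> int | None:
    """Project a genomic position into 1-based coding-DNA space.

    Returns ``None`` for positions outside the CDS intervals (intronic,
    upstream or downstream).
    """
    offset = 0
    for start, end in gene.cds_intervals:
        if start <= genomic_position <= end:
            if gene.strand == "+":
                return offset + (genomic_position - start) + 1
            # minus strand: count from the 3'-most genomic CDS base backwards
            return gene.cds_length - (offset + (genomic_position - start))
        offset += end - start + 1
    return None


def cds_to_genomic(gene: GeneModel, cds_position: int) -> int:
    """Inverse projection: coding-DNA position to genomic position."""
    if not 1 <= cds_position <= gene.cds_length:
        raise ValueError(f"cds_position {cds_position} outside CDS of {gene.gene_id}")
    return int(gene.cds_genomic_positions()[cds_position - 1])


def fetch_sequence(reference, chromosome: str, start: int, end: int) -> str:
    """Fetch reference bases on the plus strand, 1-based closed coordinates.

    Accepts a mapping of chromosome name to a string, to a uint8 code array
    (0=A 1=C 2=G 3=T), or a ``pyfaidx.Fasta``-like object.
    """
    try:
        seq = reference[chromosome]
    except KeyError as exc:
        raise ConfigurationError(f"chromosome {chromosome!r} not in reference") from exc
    chunk = seq[start - 1 : end]
    if isinstance(chunk, str):
        return chunk
    if isinstance(chunk, np.ndarray):
        return _BASE_BYTES[chunk].tobytes().decode()
    return str(chunk)  # pyfaidx Sequence


def cds_sequence(gene: GeneModel, reference) -> str:
    """Spliced coding sequence of the gene, 5'->3' on the coding strand."""
    parts = [
        fetch_sequence(reference, gene.chromosome, start, end)
        for start, end in gene.cds_intervals
    ]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_effect(
    gene: GeneModel, reference, variant: VariantRecord
) -> EffectAnnotation:
    """Predict the consequence of a SNP on one gene model.

    Any substitution in the initiator ATG is start-lost (``p.M1?``); a codon
    mutated to a stop is stop-gained (``p.Q411*``); an unchanged amino acid is
    synonymous (``p.G100=``); any other coding change is missense
    (``p.P155L``).  A CDS position whose reference base disagrees with the
    reference sequence raises :class:`ReferenceMismatchError`.
    """
    ref_base = fetch_sequence(
        reference, variant.chromosome, variant.position, variant.position
    )
    if ref_base != variant.ref_allele:
        raise ReferenceMismatchError(
            f"REF {variant.ref_allele!r} at {variant.chromosome}:{variant.position} "
            f"disagrees with reference base {ref_base!r}"
        )

    cds_pos = genomic_to_cds(gene, variant.position)
    if cds_pos is None:
        effect = (
            EffectClass.INTRONIC if gene.contains(variant.position) else EffectClass.INTERGENIC
        )
        gene_id = gene.gene_id if effect is EffectClass.INTRONIC else ""
        return EffectAnnotation(effect, IMPACT_FOR[effect], gene_id=gene_id)

    # alleles on the coding strand
    if gene.strand == "+":
        c_ref, c_alt = variant.ref_allele, variant.alt_allele
    else:
        c_ref = variant.ref_allele.translate(_COMPLEMENT)
        c_alt = variant.alt_allele.translate(_COMPLEMENT)

    address = cds_position_to_codon(cds_pos)
    positions = gene.cds_genomic_positions()
    codon_slice = positions[3 * (address.residue_index - 1) : 3 * address.residue_index]
    codon = ""
    for pos in codon_slice:
        base = fetch_sequence(reference, gene.chromosome, int(pos), int(pos))
        codon += base.translate(_COMPLEMENT) if gene.strand == "-" else base
    assert codon[address.codon_offset - 1] == c_ref

    hgvs_c = f"c.{cds_pos}{c_ref}>{c_alt}"
    mutated = (
        codon[: address.codon_offset - 1] + c_alt + codon[address.codon_offset :]
    )
    aa_ref = _translate_codon(codon)
    aa_alt = _translate_codon(mutated)

    if address.residue_index == 1:
        # any substitution in the initiator ATG destroys the start codon
        effect, hgvs_p = EffectClass.START_LOST, "p.M1?"
    elif aa_alt == aa_ref:
        effect, hgvs_p = EffectClass.SYNONYMOUS, f"p.{aa_ref}{address.residue_index}="
    elif aa_alt == "*":
        effect, hgvs_p = EffectClass.STOP_GAINED, f"p.{aa_ref}{address.residue_index}*"
    else:
        # includes loss of the terminal stop codon, reported as a coding change
        effect, hgvs_p = EffectClass.MISSENSE, f"p.{aa_ref}{address.residue_index}{aa_alt}"

    return EffectAnnotation(
        effect_class=effect,
        impact=IMPACT_FOR[effect],
        gene_id=gene.gene_id,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
    )


def find_gene(
    genes: Sequence[GeneModel], chromosome: str, position: int
) -> GeneModel | None:
    """First gene whose genomic footprint contains the position, else None."""
    for gene in genes:
        if gene.chromosome == chromosome and gene.contains(position):
            return gene
    return None


def annotate_variants(
    variants: Iterable[VariantRecord],
    genes: Sequence[GeneModel],
    reference,
) -> None:
    """Attach an :class:`EffectAnnotation` to every variant inside a gene.

    Variants outside all gene footprints keep ``annotation=None`` (treated as
    intergenic/MODIFIER downstream).  Annotation happens in place.
    """
    by_chromosome: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chromosome.setdefault(gene.chromosome, []).append(gene)
    for v in variants:
        for gene in by_chromosome.get(v.chromosome, ()):
            if gene.contains(v.position):
                v.annotation = classify_effect(gene, reference, v)
                break


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> Path:
    """Write gene models as GFF3 with gene/mRNA/CDS features and CDS phase."""
    path = Path(path)
    lines = ["##gff-version 3"]
    for gene in genes:
        start, end = gene.span
        common = f"{gene.chromosome}\temsmap\t"
        lines.append(
            f"{common}gene\t{start}\t{end}\t.\t{gene.strand}\t.\tID={gene.gene_id}"
        )
        mrna_id = f"{gene.gene_id}_T001"
        lines.append(
            f"{common}mRNA\t{start}\t{end}\t.\t{gene.strand}\t.\t"
            f"ID={mrna_id};Parent={gene.gene_id}"
        )
        intervals = list(gene.cds_intervals)
        translation_order = intervals if gene.strand == "+" else intervals[::-1]
        phases = {}
        consumed = 0
        for s, e in translation_order:
            phases[(s, e)] = (3 - consumed % 3) % 3
            consumed += e - s + 1
        for s, e in intervals:
            lines.append(
                f"{common}CDS\t{s}\t{e}\t.\t{gene.strand}\t{phases[(s, e)]}\t"
                f"ID={mrna_id}_cds;Parent={mrna_id}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + CDS features) from a GFF3 file."""
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises plain ValueError subclasses
        raise FormatError(f"could not parse GFF3 {path}: {exc}") from exc
    genes = []
    for feature in db.features_of_type("gene"):
        cds = sorted(
            db.children(feature, featuretype="CDS"), key=lambda f: f.start
        )
        if not cds:
            continue
        genes.append(
            GeneModel(
                gene_id=feature.id,
                chromosome=feature.seqid,
                strand=feature.strand,
                cds_intervals=tuple((c.start, c.end) for c in cds),
            )
        )
    return genes
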