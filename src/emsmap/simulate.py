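"""Forward-genetics simulator for pooled-sequencing mutant mapping.

The generator reproduces the full statistical structure the mapping analysis
assumes, on a scaled-down toy genome:

* a random reference genome with a configurable GC content;
* EMS-spectrum point mutations: a strong excess of G:C->A:T transitions,
  the alkylation signature of ethyl methanesulfonate;
* one recessive causal SNP placed inside the coding sequence of a toy gene,
  with a requested consequence (missense, stop-gained, start-lost or
  synonymous);
* Mendelian 1:2:1 segregation of the causal allele in a selfed M2 ear, so a
  3:1 wild-type:mutant kernel ratio;
* phenotype-based pooling (wild-type pool WP, mutant pool MP) and linkage of
  every marker on the causal chromosome to the causal locus through a Haldane
  recombination map;
* pooled short-read sampling: Poisson total depth per site and per-read
  miscalls at a configurable error rate.

Everything is driven by a single :class:`numpy.random.Generator`, so a fixed
config and seed give byte-identical output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotate import GeneModel, annotate_variants, write_gff3
from .exceptions import ConfigurationError
from .io import (
    MP,
    WP,
    EffectClass,
    PoolObservation,
    VariantRecord,
    write_pooled_vcf,
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i

#: The 61 sense codons of the standard nuclear genetic code.
_SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]

#: Kernel genotypes at the causal locus: number of mutant alleles.
HOM_WT, HET, HOM_MUT = 0, 1, 2


def phenotype(genotype: int) -> str:
    """Phenotype of a kernel under full recessivity: mutant iff homozygous mutant."""
    return "mutant" if genotype == HOM_MUT else "wild-type"


@dataclass(frozen=True)
class CausalSpec:
    """Where the causal SNP goes and what it should do to its gene."""

    chromosome: str = "chr5"
    position: int = 10_000_000
    effect_class: EffectClass = EffectClass.MISSENSE


@dataclass
class SimulationConfig:
    """Study design of one simulated mapping experiment.

    Defaults mirror the real experimental scale, scaled down: ten 20-Mb
    chromosomes carrying 20,000 EMS SNPs with a 0.98 G:C->A:T fraction, two
    pools of 30 kernels sequenced to a 30x mean depth with a 0.1% per-read
    error rate.  ``bp_per_cm`` converts physical to genetic distance so each
    toy chromosome spans a realistic ~133 cM.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 20_000_000 for i in range(1, 11)}
    )
    gc_content: float = 0.47
    n_mutations: int = 20_000
    gc_to_at_bias: float = 0.98
    causal: CausalSpec = field(default_factory=CausalSpec)
    pool_size_wp: int = 30
    pool_size_mp: int = 30
    mean_depth: float = 30.0
    error_rate: float = 0.001
    fixed_fraction: float = 0.10
    bp_per_cm: float = 150_000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chromosome_lengths.values()):
            raise ConfigurationError("chromosome lengths must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigurationError("gc_content must be in (0, 1)")
        if self.n_mutations < 0:
            raise ConfigurationError("n_mutations must be non-negative")
        if self.n_mutations > sum(self.chromosome_lengths.values()):
            raise ConfigurationError("n_mutations exceeds genome size")
        for name, value in (
            ("gc_to_at_bias", self.gc_to_at_bias),
            ("error_rate", self.error_rate),
            ("fixed_fraction", self.fixed_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.pool_size_wp < 1 or self.pool_size_mp < 1:
            raise ConfigurationError("pool sizes must be >= 1")
        if self.mean_depth < 0:
            raise ConfigurationError("mean_depth must be non-negative")
        if self.bp_per_cm <= 0:
            raise ConfigurationError("bp_per_cm must be positive")
        if self.causal.chromosome not in self.chromosome_lengths:
            raise ConfigurationError(
                f"causal chromosome {self.causal.chromosome!r} not in genome"
            )

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "causal" in data and isinstance(data["causal"], Mapping):
            causal = dict(data["causal"])
            if "effect_class" in causal:
                causal["effect_class"] = EffectClass(causal["effect_class"])
            data["causal"] = CausalSpec(**causal)
        return cls(**data)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# reference genome


def generate_reference(
    chromosome_lengths: Mapping[str, int],
    gc_content: float = 0.47,
    rng=None,
) -> dict[str, np.ndarray]:
    """Random reference sequences as uint8 code arrays (0=A 1=C 2=G 3=T).

    Base composition: A and T each (1-gc)/2, C and G each gc/2.
    ``gc_content`` may be 0 or 1 here (handy for edge-case tests); the
    simulation config is stricter.
    """
    if any(length <= 0 for length in chromosome_lengths.values()):
        raise ConfigurationError("chromosome lengths must be positive")
    if not 0.0 <= gc_content <= 1.0:
        raise ConfigurationError("gc_content must be in [0, 1]")
    rng = _as_rng(rng)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    cuts = (at, at + gc, at + 2 * gc)  # A | C | G | T breakpoints on [0, 1)
    reference = {}
    for name, length in chromosome_lengths.items():
        u = rng.random(int(length))
        codes = (u >= cuts[0]).astype(np.uint8)
        codes += u >= cuts[1]
        codes += u >= cuts[2]
        reference[name] = codes
    return reference


def reference_to_string(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode()


def write_fasta(reference: Mapping[str, np.ndarray], path: str | Path) -> Path:
    """Write the reference as wrapped FASTA (60 columns)."""
    path = Path(path)
    with open(path, "w") as handle:
        for name, codes in reference.items():
            handle.write(f">{name}\n")
            seq = reference_to_string(codes)
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")
    return path


# ---------------------------------------------------------------------------
# EMS mutations


def _distinct_positions(
    rng: np.random.Generator, candidates: np.ndarray | int, k: int, taken: set[int]
) -> list[int]:
    """Sample k distinct entries of ``candidates`` not already in ``taken``.

    ``candidates`` may be an integer n, meaning the range [0, n).
    """
    if k == 0:
        return []
    n_candidates = candidates if isinstance(candidates, int) else len(candidates)
    if n_candidates - len(taken) < k:
        raise ConfigurationError("not enough available sites for requested mutations")
    chosen: list[int] = []
    while len(chosen) < k:
        size = (k - len(chosen)) * 2 + 8
        if isinstance(candidates, int):
            draw = rng.integers(0, candidates, size=size)
        else:
            draw = rng.choice(candidates, size=size, replace=True)
        for value in draw:
            value = int(value)
            if value not in taken:
                taken.add(value)
                chosen.append(value)
                if len(chosen) == k:
                    break
    return chosen


def draw_ems_mutations(
    reference: Mapping[str, np.ndarray],
    n_mutations: int,
    gc_to_at_bias: float,
    rng=None,
) -> list[VariantRecord]:
    """Draw EMS-spectrum point mutations on the reference.

    With probability ``gc_to_at_bias`` a mutation is a G->A or C->T transition
    at a G/C site (the canonical EMS alkylation product); otherwise it is a
    uniformly chosen other substitution at a random site.  Positions are
    distinct and sorted within each chromosome.
    """
    if n_mutations < 0:
        raise ConfigurationError("n_mutations must be non-negative")
    if not 0.0 <= gc_to_at_bias <= 1.0:
        raise ConfigurationError("gc_to_at_bias must be in [0, 1]")
    if n_mutations == 0:
        return []
    if not reference:
        raise ConfigurationError("reference is empty")
    rng = _as_rng(rng)

    names = list(reference)
    lengths = np.array([len(reference[n]) for n in names], dtype=float)
    if n_mutations > lengths.sum():
        raise ConfigurationError("n_mutations exceeds the number of available sites")
    allocation = rng.multinomial(n_mutations, lengths / lengths.sum())

    variants: list[VariantRecord] = []
    for name, n_chrom in zip(names, allocation):
        if n_chrom == 0:
            continue
        codes = reference[name]
        n_biased = int(rng.binomial(n_chrom, gc_to_at_bias))
        taken: set[int] = set()

        gc_sites = np.flatnonzero((codes == 1) | (codes == 2))
        if n_biased > 0 and len(gc_sites) < n_biased:
            raise ConfigurationError(
                f"chromosome {name} has too few G/C sites for the requested bias"
            )
        chrom_records: list[tuple[int, str, str]] = []
        for idx in _distinct_positions(rng, gc_sites, n_biased, taken):
            ref = "CG"[codes[idx] - 1]  # code 1 -> C, 2 -> G
            alt = "T" if ref == "C" else "A"
            chrom_records.append((idx, ref, alt))

        for idx in _distinct_positions(rng, len(codes), int(n_chrom) - n_biased, taken):
            ref = "ACGT"[codes[idx]]
            # exclude the EMS transition so "other substitution" means exactly that
            allowed = [
                b
                for b in "ACGT"
                if b != ref
                and not (ref == "G" and b == "A")
                and not (ref == "C" and b == "T")
            ]
            alt = allowed[int(rng.integers(len(allowed)))]
            chrom_records.append((idx, ref, alt))

        chrom_records.sort(key=lambda item: item[0])
        variants.extend(
            VariantRecord(chromosome=name, position=idx + 1, ref_allele=ref, alt_allele=alt)
            for idx, ref, alt in chrom_records
        )
    return variants


# ---------------------------------------------------------------------------
# Mendelian segregation and pooling


def simulate_m2_family(n_kernels: int, rng=None) -> np.ndarray:
    """Kernel genotypes at the causal locus in a selfed-heterozygote M2 ear.

    Draws from the Mendelian 1:2:1 distribution (hom-wt : het : hom-mut);
    the mutant phenotype appears only in homozygous-mutant kernels, so the
    expected wild-type:mutant ratio is 3:1.
    """
    if n_kernels < 1:
        raise ConfigurationError("n_kernels must be >= 1")
    rng = _as_rng(rng)
    return rng.choice(
        [HOM_WT, HET, HOM_MUT], size=n_kernels, p=[0.25, 0.5, 0.25]
    ).astype(np.int64)


def expected_pool_allele_frequency(pool_id: str, recombination_fraction: float) -> float:
    """Expected mutant-coupled allele frequency at a linked marker in a pool.

    The pool holds phenotype-selected kernels from a selfed F2 (infinite-pool
    expectation).  Enumerates the four gamete classes of the doubly
    heterozygous M1 in coupling phase, conditioned on kernel phenotype.  At
    r=0 this gives the theoretical causal-marker indices: 1/3 in the
    wild-type pool and 1 in the mutant pool.
    """
    r = float(recombination_fraction)
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    if pool_id not in (WP, MP):
        raise ConfigurationError(f"unknown pool {pool_id!r}")
    # (marker allele is alt?, causal allele is mutant?, probability)
    gametes = [
        (1, 1, (1 - r) / 2),
        (1, 0, r / 2),
        (0, 0, (1 - r) / 2),
        (0, 1, r / 2),
    ]
    numerator = 0.0
    denominator = 0.0
    for m1, c1, p1 in gametes:
        for m2, c2, p2 in gametes:
            is_mutant = c1 == 1 and c2 == 1
            if (pool_id == MP) != is_mutant:
                continue
            weight = p1 * p2
            denominator += weight
            numerator += weight * (m1 + m2) / 2.0
    return numerator / denominator


def simulate_pool_counts(
    allele_frequency,
    mean_depth: float,
    error_rate: float,
    rng=None,
) -> PoolObservation:
    """Sample pooled read counts at one marker.

    ``allele_frequency`` is either the pool's realized alternative-allele
    frequency or a sequence of kernel genotypes (0/1/2 mutant alleles), from
    which the frequency is computed.  Total depth is Poisson with the given
    mean; each read reports the wrong allele with probability ``error_rate``.
    """
    if mean_depth < 0:
        raise ConfigurationError("mean_depth must be non-negative")
    if not 0.0 <= error_rate <= 1.0:
        raise ConfigurationError("error_rate must be in [0, 1]")
    rng = _as_rng(rng)
    if np.ndim(allele_frequency) > 0:
        genotypes = np.asarray(allele_frequency)
        if genotypes.size == 0:
            raise ConfigurationError("empty pool")
        frequency = genotypes.sum() / (2.0 * genotypes.size)
    else:
        frequency = float(allele_frequency)
    if not 0.0 <= frequency <= 1.0:
        raise ConfigurationError("allele frequency must be in [0, 1]")
    depth = int(rng.poisson(mean_depth))
    p_alt = frequency * (1.0 - error_rate) + (1.0 - frequency) * error_rate
    ad_alt = int(rng.binomial(depth, p_alt)) if depth else 0
    return PoolObservation(ad_ref=depth - ad_alt, ad_alt=ad_alt)


def haldane_recombination_fraction(distance_bp, bp_per_cm: float) -> np.ndarray:
    """Haldane map function: r = (1 - exp(-2 d)) / 2 with d in Morgans."""
    d_morgan = np.asarray(distance_bp, dtype=float) / (bp_per_cm * 100.0)
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


# ---------------------------------------------------------------------------
# gene placement


_STOP = "TAA"


def _design_cds(
    rng: np.random.Generator,
    n_residues: int,
    forced_codons: Mapping[int, str],
) -> str:
    """Random open reading frame: ATG, sense codons, one stop; forced codons pinned."""
    codons = ["ATG"]
    body = rng.choice(_SENSE_CODONS, size=n_residues - 1)
    codons.extend(body.tolist())
    for index, codon in forced_codons.items():
        codons[index - 1] = codon
    codons.append(_STOP)
    return "".join(codons)


#: How each requested causal consequence is engineered into the gene: the
#: pinned codon, the coding-DNA position of the substitution, and the alleles
#: on the coding strand.  All four are EMS-type (C->T / G->A) changes.
_CAUSAL_DESIGNS: dict[EffectClass, dict] = {
    EffectClass.MISSENSE: dict(forced={155: "CCG"}, cds_pos=464, ref="C", alt="T"),  # p.P155L
    EffectClass.STOP_GAINED: dict(forced={411: "CAG"}, cds_pos=1231, ref="C", alt="T"),  # p.Q411*
    EffectClass.START_LOST: dict(forced={}, cds_pos=3, ref="G", alt="A"),  # p.M1?
    EffectClass.SYNONYMOUS: dict(forced={155: "GGC"}, cds_pos=465, ref="C", alt="T"),  # p.G155=
}

_CAUSAL_N_RESIDUES = 437  # protein length of the default causal gene


def _embed_gene(reference: dict[str, np.ndarray], gene: GeneModel, cds_seq: str) -> None:
    """Overwrite reference bases with the gene's CDS (plus-strand projection)."""
    positions = gene.cds_genomic_positions()
    codes = _CODE_OF[np.frombuffer(cds_seq.encode(), dtype=np.uint8)]
    if gene.strand == "-":
        codes = 3 - codes  # complement; position order already handles reversal
    reference[gene.chromosome][positions - 1] = codes


def _place_causal_gene(
    config: SimulationConfig, reference: dict[str, np.ndarray], rng: np.random.Generator
) -> tuple[GeneModel, VariantRecord]:
    causal = config.causal
    design = _CAUSAL_DESIGNS.get(causal.effect_class)
    if design is None:
        raise ConfigurationError(
            f"cannot engineer a causal mutation of class {causal.effect_class}"
        )
    cds = _design_cds(rng, _CAUSAL_N_RESIDUES, design["forced"])
    start = causal.position - design["cds_pos"] + 1
    end = start + len(cds) - 1
    if start < 1 or end > config.chromosome_lengths[causal.chromosome]:
        raise ConfigurationError(
            "causal position leaves no room for its gene model on "
            f"{causal.chromosome}: CDS would span [{start}, {end}]"
        )
    gene = GeneModel(
        gene_id=f"gene_causal",
        chromosome=causal.chromosome,
        strand="+",
        cds_intervals=((start, end),),
    )
    _embed_gene(reference, gene, cds)
    causal = VariantRecord(
        chromosome=causal.chromosome,
        position=causal.position,
        ref_allele=design["ref"],
        alt_allele=design["alt"],
    )
    return gene, causal


def _place_decoy_genes(
    config: SimulationConfig,
    reference: dict[str, np.ndarray],
    causal_gene: GeneModel,
    rng: np.random.Generator,
) -> list[GeneModel]:
    """Two small two-exon genes per chromosome, on alternating strands."""
    genes: list[GeneModel] = []
    n_residues = 300
    cds_len = (n_residues + 1) * 3
    exon1 = 450
    intron = 150
    for name, length in config.chromosome_lengths.items():
        for k, (fraction, strand) in enumerate(((0.3, "+"), (0.7, "-"))):
            start = int(length * fraction)
            end = start + exon1 - 1 + intron + (cds_len - exon1)
            if start < 1 or end > length:
                continue
            intervals = (
                (start, start + exon1 - 1),
                (start + exon1 + intron, end),
            )
            if (
                name == causal_gene.chromosome
                and intervals[0][0] <= causal_gene.span[1]
                and causal_gene.span[0] <= intervals[1][1]
            ):
                continue  # never shadow the causal gene
            gene = GeneModel(
                gene_id=f"gene_{name}_{k + 1}",
                chromosome=name,
                strand=strand,
                cds_intervals=intervals,
            )
            _embed_gene(reference, gene, _design_cds(rng, n_residues, {}))
            genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# full dataset


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulated experiment, for recovery tests."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene_id: str
    effect_class: EffectClass
    hgvs_c: str
    hgvs_p: str


@dataclass
class SimulatedDataset:
    """In-memory result of one simulation: variants with pooled depths + truth."""

    config: SimulationConfig
    variants: list[VariantRecord]
    genes: list[GeneModel]
    truth: TruthRecord
    reference: dict[str, np.ndarray] | None = None


def simulate_dataset(
    config: SimulationConfig, keep_reference: bool = False
) -> SimulatedDataset:
    """Run the full generative model described in the module docstring.

    Background EMS SNPs are heterozygous in the selfed M1 (expected pooled
    frequency 1/2 in both pools when unlinked) except for a configurable
    fraction fixed homozygous (frequency 1 in both pools).  Every marker on
    the causal chromosome is linked to the causal locus through the Haldane
    map; all EMS mutations arose in the single treated pollen grain, so they
    are in coupling phase with the causal allele.
    """
    rng = np.random.default_rng(config.rng_seed)

    reference = generate_reference(config.chromosome_lengths, config.gc_content, rng)
    causal_gene, causal_variant = _place_causal_gene(config, reference, rng)
    genes = [causal_gene] + _place_decoy_genes(config, reference, causal_gene, rng)

    variants = draw_ems_mutations(
        reference, config.n_mutations, config.gc_to_at_bias, rng
    )
    variants = [
        v
        for v in variants
        if not (
            v.chromosome == causal_variant.chromosome
            and v.position == causal_variant.position
        )
    ]
    variants.append(causal_variant)
    variants.sort(key=lambda v: (list(config.chromosome_lengths).index(v.chromosome), v.position))
    causal_index = variants.index(causal_variant)

    annotate_variants(variants, genes, reference)
    truth = TruthRecord(
        chromosome=causal_variant.chromosome,
        position=causal_variant.position,
        ref_allele=causal_variant.ref_allele,
        alt_allele=causal_variant.alt_allele,
        gene_id=causal_gene.gene_id,
        effect_class=causal_variant.annotation.effect_class,
        hgvs_c=causal_variant.annotation.hgvs_c,
        hgvs_p=causal_variant.annotation.hgvs_p,
    )

    n = len(variants)
    chromosomes = np.array([v.chromosome for v in variants])
    positions = np.array([v.position for v in variants], dtype=np.int64)

    is_fixed = rng.random(n) < config.fixed_fraction
    is_fixed[causal_index] = False  # the causal allele segregates by construction

    on_causal_chromosome = chromosomes == causal_variant.chromosome
    linked = on_causal_chromosome & ~is_fixed
    unlinked = ~on_causal_chromosome & ~is_fixed

    f_wp = np.ones(n)
    f_mp = np.ones(n)

    # gamete-level causal alleles of the pooled kernels (coupling phase)
    wp_kernel_alleles = rng.choice([0, 1], size=config.pool_size_wp, p=[1 / 3, 2 / 3])
    gametes_wp = np.concatenate(
        [np.stack([wp_kernel_alleles, np.zeros_like(wp_kernel_alleles)], axis=1).ravel()]
    )
    gametes_mp = np.ones(2 * config.pool_size_mp, dtype=np.int64)

    r = haldane_recombination_fraction(
        np.abs(positions[linked] - causal_variant.position), config.bp_per_cm
    )
    for gametes, pool_freqs in ((gametes_wp, f_wp), (gametes_mp, f_mp)):
        recombined = rng.random((linked.sum(), gametes.size)) < r[:, None]
        alt_alleles = gametes[None, :] ^ recombined
        pool_freqs[linked] = alt_alleles.mean(axis=1)

    for pool_size, pool_freqs in (
        (config.pool_size_wp, f_wp),
        (config.pool_size_mp, f_mp),
    ):
        n_alleles = 2 * pool_size
        pool_freqs[unlinked] = (
            rng.binomial(n_alleles, 0.5, size=unlinked.sum()) / n_alleles
        )

    for pool_id, pool_freqs in ((WP, f_wp), (MP, f_mp)):
        depth = rng.poisson(config.mean_depth, size=n)
        p_alt = pool_freqs * (1.0 - config.error_rate) + (1.0 - pool_freqs) * config.error_rate
        ad_alt = rng.binomial(depth, p_alt)
        for v, d, a in zip(variants, depth, ad_alt):
            v.pools[pool_id] = PoolObservation(int(d - a), int(a))

    return SimulatedDataset(
        config=config,
        variants=variants,
        genes=genes,
        truth=truth,
        reference=reference if keep_reference else None,
    )


def write_truth_tsv(truth: TruthRecord, path: str | Path) -> Path:
    path = Path(path)
    header = "chromosome\tposition\tref\talt\tgene_id\teffect\thgvs_c\thgvs_p\n"
    row = (
        f"{truth.chromosome}\t{truth.position}\t{truth.ref_allele}\t{truth.alt_allele}"
        f"\t{truth.gene_id}\t{truth.effect_class.value}\t{truth.hgvs_c}\t{truth.hgvs_p}\n"
    )
    path.write_text(header + row)
    return path


def build_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write reference FASTA, gene-model GFF3, pooled VCF and truth TSV.

    Returns the paths keyed by role.  Fully reproducible: identical config and
    seed give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = simulate_dataset(config, keep_reference=True)
    paths = {
        "reference": write_fasta(dataset.reference, out_dir / "reference.fasta"),
        "genes": write_gff3(dataset.genes, out_dir / "genes.gff3"),
        "vcf": write_pooled_vcf(
            dataset.variants, out_dir / "pools.vcf", contigs=config.chromosome_lengths
        ),
        "truth": write_truth_tsv(dataset.truth, out_dir / "truth.tsv"),
    }
    return paths
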