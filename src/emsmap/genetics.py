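"""Mendelian expectation calculators for recessive kernel mutants.

Covers the crosses used when characterizing and verifying a recessive
single-gene mutant: selfing a heterozygous carrier (3:1 wild-type:mutant
kernels on the ear), the allelism test (het x het for two mutations in the
same gene segregates ~1/4 mutant kernels; mutations in different genes give
none), and the mutagenesis-throughput estimator
``ears x seeds/ear x survival x pollination success x mutant ratio``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ConfigurationError


class CrossType(str, Enum):
    """Crosses between carriers of fully recessive mutations."""

    SELF_HETEROZYGOTE = "self_heterozygote"
    HET_X_HET_ALLELIC = "het_x_het_allelic"
    HET_X_HET_NONALLELIC = "het_x_het_nonallelic"


def expected_mutant_fraction(cross_type: CrossType | str) -> float:
    """Expected fraction of mutant-phenotype kernels for a cross.

    Selfing a heterozygote or crossing heterozygotes for allelic mutations
    both give 1/4 (the aa class of Aa x Aa).  Crossing heterozygotes for
    mutations in two different genes gives 0: every offspring inherits a
    functional allele at each locus.
    """
    cross_type = CrossType(cross_type)
    if cross_type in (CrossType.SELF_HETEROZYGOTE, CrossType.HET_X_HET_ALLELIC):
        return 0.25
    return 0.0


def simulate_cross_kernels(
    cross_type: CrossType | str, n_kernels: int, rng=None
) -> np.ndarray:
    """Simulate kernel phenotypes for a cross; True marks a mutant kernel."""
    if n_kernels < 1:
        raise ConfigurationError("n_kernels must be >= 1")
    cross_type = CrossType(cross_type)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if cross_type is CrossType.HET_X_HET_NONALLELIC:
        # each parent is wild-type homozygous at the other parent's locus, so
        # no kernel can be homozygous mutant at either gene
        return np.zeros(n_kernels, dtype=bool)
    maternal = rng.random(n_kernels) < 0.5
    paternal = rng.random(n_kernels) < 0.5
    return maternal & paternal


def segregation_ratio(is_mutant: np.ndarray) -> float:
    """Observed wild-type : mutant kernel ratio (wild-type count over mutant count)."""
    is_mutant = np.asarray(is_mutant, dtype=bool)
    n_mutant = int(is_mutant.sum())
    if n_mutant == 0:
        raise ConfigurationError("no mutant kernels: ratio undefined")
    return (is_mutant.size - n_mutant) / n_mutant


@dataclass(frozen=True)
class MutantYieldInputs:
    """Per-line inputs of the mutagenesis-throughput estimator."""

    seeds_per_ear: float
    survival_ratio: float
    mutant_ratio: float
    pollination_success: float = 0.5

    def __post_init__(self) -> None:
        if self.seeds_per_ear < 0:
            raise ConfigurationError("seeds_per_ear must be non-negative")
        for name in ("survival_ratio", "mutant_ratio", "pollination_success"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class YieldEstimate:
    """Raw product and its integer truncation."""

    raw: float
    count: int


def estimate_mutant_yield(inputs: MutantYieldInputs, n_ears: int = 100) -> YieldEstimate:
    """Expected number of independent mutants from ``n_ears`` mutagenized ears.

    ``n_ears x seeds_per_ear x survival_ratio x pollination_success x
    mutant_ratio``; reported both raw and truncated to a whole mutant (a tiny
    epsilon guards the floor against float round-off in the product).
    """
    if n_ears < 0:
        raise ConfigurationError("n_ears must be non-negative")
    raw = (
        n_ears
        * inputs.seeds_per_ear
        * inputs.survival_ratio
        * inputs.pollination_success
        * inputs.mutant_ratio
    )
    return YieldEstimate(raw=raw, count=int(math.floor(raw + 1e-9)))
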