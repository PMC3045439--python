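"""Genetic parameterization for parent-of-origin (imprinting) effects at one SNP.

A biallelic locus with alleles ``A`` (frequency ``p``) and ``a`` (frequency
``q = 1 - p``) has three observable genotypes but *four* ordered
configurations once the parental origin of each allele is resolved: writing
the maternally derived allele on the left,

====================  ======  ==================
configuration         code    genotypic value
====================  ======  ==================
``A|A``               2       ``mu + a``
``A|a``               1       ``mu + d + i``
``a|A``               1'      ``mu + d - i``
``a|a``               0       ``mu - a``
====================  ======  ==================

``a`` is the additive effect, ``d`` the dominance effect and ``i`` the
imprinting (parent-of-origin) effect: the two reciprocal heterozygotes share
an unordered genotype but differ in value by ``2i``.  A positive ``i`` means
the heterozygote carrying a maternally derived ``A`` has the larger value.

Each generation of a three-generation family design carries its own
parameter set; transgenerational change is the per-effect difference between
the parental and offspring generations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "GENOTYPES",
    "CONFIGS",
    "CONFIG_DESIGN",
    "OrderedConfiguration",
    "GenerationParams",
    "TransgenerationalDelta",
    "MatingType",
    "HWEFrequencies",
    "genotypic_value",
    "transgenerational_deltas",
    "hwe_frequencies",
    "offspring_configuration_distribution",
    "mating_type_table",
    "invert_configuration_means",
    "population_mean",
    "genetic_variance",
]

#: Unordered genotypes, major allele written first.
GENOTYPES = ("AA", "Aa", "aa")


class OrderedConfiguration(Enum):
    """A genotype with parental origin resolved: (maternal allele, paternal allele)."""

    AA = ("A", "A")  # code 2
    Aa = ("A", "a")  # code 1:  maternally derived A
    aA = ("a", "A")  # code 1': paternally derived A
    aa = ("a", "a")  # code 0

    @property
    def maternal(self) -> str:
        return self.value[0]

    @property
    def paternal(self) -> str:
        return self.value[1]

    @property
    def code(self) -> str:
        return {"AA": "2", "Aa": "1", "aA": "1'", "aa": "0"}[self.name]

    @property
    def unordered(self) -> str:
        """Collapse to the observable genotype (surjective onto AA/Aa/aa)."""
        return "".join(sorted(self.value))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.value[0]}|{self.value[1]}>"


#: Canonical configuration order used for all weight vectors and design rows.
CONFIGS = (
    OrderedConfiguration.AA,
    OrderedConfiguration.Aa,
    OrderedConfiguration.aA,
    OrderedConfiguration.aa,
)

CONFIG_INDEX = {c: k for k, c in enumerate(CONFIGS)}

_CONFIG_BY_ALLELES = {c.value: c for c in CONFIGS}

#: Design matrix mapping (mu, a, d, i) to the four configuration means.
#: Rows follow ``CONFIGS``; columns are the intercept and the three effects.
CONFIG_DESIGN = np.array(
    [
        [1.0, 1.0, 0.0, 0.0],   # A|A -> mu + a
        [1.0, 0.0, 1.0, 1.0],   # A|a -> mu + d + i
        [1.0, 0.0, 1.0, -1.0],  # a|A -> mu + d - i
        [1.0, -1.0, 0.0, 0.0],  # a|a -> mu - a
    ]
)


@dataclass(frozen=True)
class GenerationParams:
    """Genetic architecture of one generation.

    Parameters are in trait units; ``sigma2`` is the residual (environmental)
    variance and may be ``None`` until calibrated (e.g. from a heritability).
    """

    mu: float = 0.0
    a: float = 0.0
    d: float = 0.0
    i: float = 0.0
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.sigma2 is not None and self.sigma2 < 0:
            raise ValueError(f"sigma2 must be non-negative, got {self.sigma2}")

    def value(self, config: OrderedConfiguration) -> float:
        return genotypic_value(config, self)

    def values(self) -> np.ndarray:
        """Configuration means in ``CONFIGS`` order."""
        return CONFIG_DESIGN @ np.array([self.mu, self.a, self.d, self.i])

    def effects(self) -> np.ndarray:
        return np.array([self.mu, self.a, self.d, self.i])

    def with_sigma2(self, sigma2: float) -> "GenerationParams":
        return replace(self, sigma2=sigma2)


@dataclass(frozen=True)
class TransgenerationalDelta:
    """Per-effect change between the parental and offspring generations."""

    delta_a: float
    delta_d: float
    delta_i: float


@dataclass(frozen=True)
class MatingType:
    """One of the nine grandparental genotype-pair classes under random mating."""

    index: int
    grandmother_genotype: str
    grandfather_genotype: str
    population_frequency: float
    son_configuration_distribution: dict


@dataclass(frozen=True)
class HWEFrequencies:
    unordered: dict
    ordered: dict


def genotypic_value(config: OrderedConfiguration, params: GenerationParams) -> float:
    """Genotypic value of an ordered configuration under one generation's parameters."""
    if not isinstance(config, OrderedConfiguration):
        raise ValueError(f"invalid configuration: {config!r}")
    if config is OrderedConfiguration.AA:
        return params.mu + params.a
    if config is OrderedConfiguration.Aa:
        return params.mu + params.d + params.i
    if config is OrderedConfiguration.aA:
        return params.mu + params.d - params.i
    return params.mu - params.a


def transgenerational_deltas(
    p1: GenerationParams, p2: GenerationParams
) -> TransgenerationalDelta:
    """Differences (parental minus offspring) in additive, dominance and imprinting effects."""
    return TransgenerationalDelta(p1.a - p2.a, p1.d - p2.d, p1.i - p2.i)


def _check_freq(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")


def hwe_frequencies(p: float) -> HWEFrequencies:
    """Hardy-Weinberg genotype and ordered-configuration frequencies.

    Under random mating the maternal and paternal alleles are independent
    draws, so both reciprocal heterozygote configurations have frequency
    ``p*q`` and the unordered heterozygote has ``2*p*q``.
    """
    _check_freq(p)
    q = 1.0 - p
    unordered = {"AA": p * p, "Aa": 2 * p * q, "aa": q * q}
    ordered = {
        OrderedConfiguration.AA: p * p,
        OrderedConfiguration.Aa: p * q,
        OrderedConfiguration.aA: q * p,
        OrderedConfiguration.aa: q * q,
    }
    return HWEFrequencies(unordered=unordered, ordered=ordered)


def _validate_genotype(g: str) -> None:
    if g not in GENOTYPES:
        raise ValueError(f"unknown genotype {g!r}; expected one of {GENOTYPES}")


def offspring_configuration_distribution(
    mother_genotype: str, father_genotype: str
) -> dict:
    """Mendelian distribution of a child's ordered configuration.

    The maternal allele is a uniform draw from the mother's two alleles and
    the paternal allele a uniform draw from the father's.
    """
    _validate_genotype(mother_genotype)
    _validate_genotype(father_genotype)
    dist = {c: 0.0 for c in CONFIGS}
    for am in mother_genotype:
        for ap in father_genotype:
            dist[_CONFIG_BY_ALLELES[(am, ap)]] += 0.25
    return dist


def mating_type_table(p: float) -> list:
    """The nine grandparental mating types with HWE frequencies and son distributions.

    Ordered grandmother-major over (AA, Aa, aa) so that index 5 is the
    double-heterozygote cross, the only one whose sons can carry either
    reciprocal heterozygote configuration.
    """
    hwe = hwe_frequencies(p).unordered
    table = []
    for k, (gm, gf) in enumerate(itertools.product(GENOTYPES, repeat=2), start=1):
        table.append(
            MatingType(
                index=k,
                grandmother_genotype=gm,
                grandfather_genotype=gf,
                population_frequency=hwe[gm] * hwe[gf],
                son_configuration_distribution=offspring_configuration_distribution(gm, gf),
            )
        )
    return table


def invert_configuration_means(means) -> tuple:
    """Recover (mu, a, d, i) from the four configuration means (``CONFIGS`` order)."""
    means = np.asarray(means, dtype=float)
    theta = np.linalg.solve(CONFIG_DESIGN, means)
    return tuple(theta)


def population_mean(params: GenerationParams, p: float) -> float:
    """Trait mean under ordered HWE frequencies; ``i`` cancels by symmetry."""
    freqs = hwe_frequencies(p).ordered
    return float(sum(freqs[c] * genotypic_value(c, params) for c in CONFIGS))


def genetic_variance(params: GenerationParams, p: float) -> float:
    """Variance of the genotypic value under ordered HWE frequencies."""
    freqs = hwe_frequencies(p).ordered
    w = np.array([freqs[c] for c in CONFIGS])
    v = params.values()
    m = float(w @ v)
    return float(w @ (v - m) ** 2)
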