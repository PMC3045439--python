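"""Simulation of three-generation family samples.

Two sampling strategies of equal total size (1000 subjects) are built in:

* ``strategy1`` - many small families: 200 first-generation families, one
  son each, one grandchild per second-generation couple.
* ``strategy2`` - few large families: 50 first-generation families, three
  sons each (150 second-generation families), four grandchildren per couple.

Founders (grandparents and mothers) are drawn from Hardy-Weinberg
equilibrium at allele frequency ``p`` (default 0.6); transmission follows
Mendelian segregation with the parental origin of every allele tracked as
simulation truth.  Phenotypes are normal around the configuration's
genotypic value, with the residual variance calibrated per generation so
that the locus explains a chosen heritability ``h2`` of that generation's
phenotypic variance: ``sigma2 = Vg * (1 - h2) / h2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .family_model import (
    GENOTYPES,
    CONFIGS,
    GenerationParams,
    OrderedConfiguration,
    genetic_variance,
    genotypic_value,
)
from .pedigree import ThreeGenDataset

__all__ = [
    "DEFAULT_PARENTAL",
    "DEFAULT_OFFSPRING",
    "DesignSpec",
    "strategy_preset",
    "heritability_to_sigma2",
    "resolved_params",
    "simulate",
    "simulate_two_snp",
]

#: Default generating effects: parental (a, d, i) = (1.0, 0.5, 0.5),
#: offspring (a, d, i) = (0.5, 0.5, 0.0) so that the additive and imprinting
#: effects change across generations while dominance does not.
DEFAULT_PARENTAL = GenerationParams(mu=0.0, a=1.0, d=0.5, i=0.5)
DEFAULT_OFFSPRING = GenerationParams(mu=0.0, a=0.5, d=0.5, i=0.0)

_CONFIG_BY_ALLELES = {c.value: c for c in CONFIGS}


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design and generating parameters for one simulated study."""

    n_gen1_families: int
    sons_per_family: int
    children_per_couple: int
    allele_freq: float = 0.6
    h2_parental: float | None = 0.4
    h2_offspring: float | None = 0.4
    params_parental: GenerationParams = DEFAULT_PARENTAL
    params_offspring: GenerationParams = DEFAULT_OFFSPRING
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_gen1_families", "sons_per_family", "children_per_couple"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must be in (0, 1)")
        for h2, params in (
            (self.h2_parental, self.params_parental),
            (self.h2_offspring, self.params_offspring),
        ):
            if params.sigma2 is None:
                if h2 is None or not 0.0 < h2 < 1.0:
                    raise ValueError(
                        "h2 must be in (0, 1) when sigma2 is not given explicitly"
                    )

    @property
    def n_subjects(self) -> int:
        f, s, c = self.n_gen1_families, self.sons_per_family, self.children_per_couple
        return f * 2 + f * s * (2 + c)


def strategy_preset(name, **overrides) -> DesignSpec:
    """The two built-in sampling strategies (1000 subjects each)."""
    key = str(name).removeprefix("strategy")
    if key == "1":
        spec = DesignSpec(n_gen1_families=200, sons_per_family=1, children_per_couple=1)
    elif key == "2":
        spec = DesignSpec(n_gen1_families=50, sons_per_family=3, children_per_couple=4)
    else:
        raise ValueError(f"unknown strategy {name!r}; expected 'strategy1' or 'strategy2'")
    return replace(spec, **overrides) if overrides else spec


def heritability_to_sigma2(params: GenerationParams, p: float, h2: float) -> float:
    """Residual variance giving the locus heritability ``h2`` in one generation."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    vg = genetic_variance(params, p)
    if vg <= 0.0:
        raise ValueError(
            "genetic variance is zero (all effects zero); cannot calibrate sigma2 "
            "from a heritability - set sigma2 explicitly"
        )
    return vg * (1.0 - h2) / h2


def resolved_params(design: DesignSpec) -> tuple:
    """Generation parameters with sigma2 filled in from the heritabilities."""
    out = []
    for params, h2 in (
        (design.params_parental, design.h2_parental),
        (design.params_offspring, design.h2_offspring),
    ):
        if params.sigma2 is None:
            params = params.with_sigma2(
                heritability_to_sigma2(params, design.allele_freq, h2)
            )
        out.append(params)
    return tuple(out)


def _draw_founder_config(rng, p) -> OrderedConfiguration:
    alleles = tuple("A" if u < p else "a" for u in rng.random(2))
    return _CONFIG_BY_ALLELES[alleles]


def _transmit(rng, mother_geno: str, father_geno: str) -> OrderedConfiguration:
    am = mother_geno[rng.integers(2)]
    ap = father_geno[rng.integers(2)]
    return _CONFIG_BY_ALLELES[(am, ap)]


_MT_INDEX = {
    (gm, gf): 3 * i + j + 1
    for i, gm in enumerate(GENOTYPES)
    for j, gf in enumerate(GENOTYPES)
}


def simulate(design: DesignSpec, seed: int | None = None) -> ThreeGenDataset:
    """Draw one three-generation dataset under ``design``.

    The same seed reproduces the same dataset exactly.  Phenotypes exist only
    for second-generation fathers and third-generation children.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    par, off = resolved_params(design)
    sd1, sd2 = np.sqrt(par.sigma2), np.sqrt(off.sigma2)
    p = design.allele_freq

    rows = []

    def add(fam, sid, fid, mid, sex, gen, role, mt, config, pheno):
        rows.append(
            {
                "family_id": fam,
                "subject_id": sid,
                "father_id": fid,
                "mother_id": mid,
                "sex": sex,
                "generation": gen,
                "role": role,
                "mating_type": mt,
                "snp1": config.unordered,
                "phenotype": pheno,
                "config_true": config.name,
            }
        )

    for f in range(design.n_gen1_families):
        fam = f"F{f + 1:04d}"
        gf = _draw_founder_config(rng, p)
        gm = _draw_founder_config(rng, p)
        mt = _MT_INDEX[(gm.unordered, gf.unordered)]
        add(fam, f"{fam}-GF", "0", "0", "M", 1, "grandfather", mt, gf, np.nan)
        add(fam, f"{fam}-GM", "0", "0", "F", 1, "grandmother", mt, gm, np.nan)
        for s in range(design.sons_per_family):
            son_id = f"{fam}-S{s + 1}"
            son = _transmit(rng, gm.unordered, gf.unordered)
            y_son = genotypic_value(son, par) + rng.normal(0.0, sd1)
            add(fam, son_id, f"{fam}-GF", f"{fam}-GM", "M", 2, "father", mt, son, y_son)
            wife = _draw_founder_config(rng, p)
            wife_id = f"{son_id}-M"
            add(fam, wife_id, "0", "0", "F", 2, "mother", mt, wife, np.nan)
            for c in range(design.children_per_couple):
                child = _transmit(rng, wife.unordered, son.unordered)
                y = genotypic_value(child, off) + rng.normal(0.0, sd2)
                add(fam, f"{son_id}-C{c + 1}", son_id, wife_id, "U", 3, "child", mt, child, y)

    df = pd.DataFrame(rows)
    return ThreeGenDataset(df, n_snps=1, meta={"design": design})


# ---------------------------------------------------------------------------
# Two-SNP simulation (haplotype model)
# ---------------------------------------------------------------------------


def simulate_two_snp(design: DesignSpec, hap, seed: int | None = None) -> ThreeGenDataset:
    """Draw a two-SNP dataset under a haplotype system.

    Founder diplotypes are HWE draws from the haplotype frequencies; gametes
    recombine between the two SNPs with fraction ``r``; phenotypes follow the
    composite-diplotype value of the risk haplotype.  Only unordered two-SNP
    genotypes are observed; diplotypes are recorded as hidden truth.
    """
    from .haplotype import (
        HAPLOTYPES,
        genotype_strings,
        composite_class,
        transmission_matrix,
    )

    rng = np.random.default_rng(design.seed if seed is None else seed)
    freqs = np.asarray(hap.frequencies, dtype=float)
    if freqs.shape != (4,) or np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must be 4 non-negative values summing to 1")
    if not 0.0 <= hap.r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    risk = HAPLOTYPES.index(hap.risk_haplotype)
    p_risk = freqs[risk]

    par = hap.params_parental or design.params_parental
    off = hap.params_offspring or design.params_offspring
    if par.sigma2 is None:
        par = par.with_sigma2(heritability_to_sigma2(par, p_risk, design.h2_parental))
    if off.sigma2 is None:
        off = off.with_sigma2(heritability_to_sigma2(off, p_risk, design.h2_offspring))
    sd1, sd2 = np.sqrt(par.sigma2), np.sqrt(off.sigma2)

    T = transmission_matrix(hap.r)  # (16 diplotypes, 4 gametes)

    def founder():
        return int(rng.choice(4, p=freqs)), int(rng.choice(4, p=freqs))

    def gamete(diplo):
        return int(rng.choice(4, p=T[4 * diplo[0] + diplo[1]]))

    def value(diplo, params):
        return genotypic_value(CONFIGS[composite_class(diplo, risk)], params)

    rows = []

    def add(fam, sid, fid, mid, sex, gen, role, diplo, pheno):
        g1, g2 = genotype_strings(diplo)
        rows.append(
            {
                "family_id": fam,
                "subject_id": sid,
                "father_id": fid,
                "mother_id": mid,
                "sex": sex,
                "generation": gen,
                "role": role,
                "mating_type": 0,
                "snp1": g1,
                "snp2": g2,
                "phenotype": pheno,
                "diplotype_true": f"{HAPLOTYPES[diplo[0]]}|{HAPLOTYPES[diplo[1]]}",
            }
        )

    for f in range(design.n_gen1_families):
        fam = f"F{f + 1:04d}"
        gf, gm = founder(), founder()
        add(fam, f"{fam}-GF", "0", "0", "M", 1, "grandfather", gf, np.nan)
        add(fam, f"{fam}-GM", "0", "0", "F", 1, "grandmother", gm, np.nan)
        for s in range(design.sons_per_family):
            son_id = f"{fam}-S{s + 1}"
            son = (gamete(gm), gamete(gf))  # maternal haplotype first
            y_son = value(son, par) + rng.normal(0.0, sd1)
            add(fam, son_id, f"{fam}-GF", f"{fam}-GM", "M", 2, "father", son, y_son)
            wife = founder()
            wife_id = f"{son_id}-M"
            add(fam, wife_id, "0", "0", "F", 2, "mother", wife, np.nan)
            for c in range(design.children_per_couple):
                child = (gamete(wife), gamete(son))
                y = value(child, off) + rng.normal(0.0, sd2)
                add(fam, f"{son_id}-C{c + 1}", son_id, wife_id, "U", 3, "child", child, y)

    df = pd.DataFrame(rows)
    return ThreeGenDataset(df, n_snps=2, meta={"design": design, "haplotype_system": hap})
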