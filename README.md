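# imprintgen

Estimation and testing of **genomic imprinting (parent-of-origin) effects**
on a quantitative trait — and of their **transgenerational change** — from
three-generation human family samples.

## The problem

An imprinted locus expresses the maternally and paternally inherited allele
differently, so the two reciprocal heterozygotes `A|a` (maternal A) and
`a|A` (paternal A) have different expected phenotypes even though they are
indistinguishable as genotypes.  Epigenetic marks can also be cleared or
inherited between generations, so the strength of imprinting may itself
change from parents to offspring.  A sample of three-generation families
(grandfather, grandmother, father, mother, grandchildren) lets both
questions be asked from population data: grandparental genotypes reveal the
parental origin of the father's alleles, and parental genotypes reveal the
origin of each grandchild's alleles, except in doubly heterozygous matings
where the origin stays latent.

## The model

Writing the maternal allele left, the four ordered configurations of a
biallelic SNP have genotypic values per generation g ∈ {1 = parental,
2 = offspring}:

| configuration | value            |
|---------------|------------------|
| `A\|A`        | μ_g + a_g        |
| `A\|a`        | μ_g + d_g + i_g  |
| `a\|A`        | μ_g + d_g − i_g  |
| `a\|a`        | μ_g − a_g        |

with additive a, dominance d and imprinting i effects and residual
N(0, σ²_g) phenotypes; i_g is half the difference between reciprocal
heterozygotes.  Founders follow Hardy–Weinberg equilibrium at allele
frequency p (closed-form counting MLE).  Because offspring genotypes are
conditioned on parental genotypes, the likelihood splits into a paternal
and an offspring component that are maximized independently by an EM
algorithm over the latent configurations of ambiguous heterozygotes
(E-step: normal-density posterior on `A|a` vs `a|A`; M-step: weighted
least-squares update of (μ, a, d, i) and pooled σ²).  Hypotheses are
tested by likelihood-ratio statistics: χ²(1) for single effects, χ² with
one df per tied effect for transgenerational changes Δa = a₁−a₂,
Δd = d₁−d₂, Δi = i₁−i₂, and a permutation-calibrated LRT (phenotypes
shuffled within generation) for overall association.

A two-SNP extension designates one of the four haplotypes AB, Ab, aB, ab
as the risk haplotype H and applies the same (μ, a, d, i) parameterization
to the composite diplotypes (HH, H|non-risk, non-risk|H, non-risk pair).
Haplotype frequencies and the recombination fraction r are first estimated
from genotypes alone by an exact pedigree EM (founder phases weighted by
p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB) and by their offspring's segregation),
then plugged into the same mixture EM for the effects; the risk haplotype
is chosen by maximum likelihood over the four candidates.

## Worked example

```python
import imprintgen as ig

design = ig.strategy_preset("strategy1", h2_parental=0.4, h2_offspring=0.4)
data = ig.simulate(design, seed=42)          # 1000 subjects, 200 families
res = ig.TransgenImprintingModel(data).fit()
print(res.summary())
```

```
Transgenerational imprinting model (single SNP)
subjects: 1000, log-likelihood: -387.393, converged: True
allele frequency (founder MLE): 0.5858

generation   param  estimate  std err
-------------------------------------
  parental      mu   -0.0059   0.0969
  parental       a    0.9152   0.0969
  parental       d    0.5455   0.1359
  parental       i    0.7175   0.0958
  parental  sigma2    0.8561   0.0875
 offspring      mu   -0.0367   0.0437
 offspring       a    0.5547   0.0437
 offspring       d    0.4711   0.0625
 offspring       i    0.0180   0.0553
 offspring  sigma2    0.1860   0.0186

transgenerational deltas (parental - offspring): da = 0.3605, dd = 0.0744, di = 0.6995
```

The generating values were parental (a, d, i) = (1.0, 0.5, 0.5) and
offspring (0.5, 0.5, 0.0) at allele frequency 0.6: each estimate lands
within about two standard errors of its truth, and the fitted deltas show
the simulated loss of imprinting across generations.  The tests agree:

```python
print(res.test_effect("i", "parental"))      # i_parental: LR = 45.665, p = 1.4e-11 (reject)
print(res.test_transgenerational(("i",)))    # delta_i:    LR = 36.195, p = 1.8e-09 (reject)
print(res.test_overall(n_perm=199, seed=1))  # overall:    LR = 238.293, p = 0.005  (reject)
```

The same flows exist on the command line (`imprintgen simulate`, `fit`,
`test`, `power`, `haplotype`), reading and writing a documented pedigree
TSV with optional PLINK PED/MAP export, and
`ig.HaplotypeImprintingModel(two_snp_data).fit()` runs the two-SNP
haplotype analysis.

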