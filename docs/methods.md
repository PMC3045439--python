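# Methods

## Design and data

The sampling unit is a three-generation family: a grandfather and
grandmother (founders), one or more sons who become second-generation
fathers, each married to a mother drawn from the population (also a
founder), and their children.  Everyone is genotyped; **only the
second-generation fathers and the third-generation children are
phenotyped**.  This asymmetry is intrinsic to the design: parental origin
of alleles can be traced for fathers (through their parents) and for
children (through theirs), but not for founders, so only fathers and
children inform the imprinting parameters.  Estimators therefore never
require maternal phenotypes, and files may carry them only as ignored
values.

Two built-in allocations of 1000 subjects are provided:
`strategy1` (200 families × 1 son × 1 child — many small families) and
`strategy2` (50 families × 3 sons × 4 children — 150 second-generation
families inside 50 extended ones).

## Genetic parameterization

Ordered configurations (maternal allele left) map to means by

    value(A|A) = mu + a,   value(A|a) = mu + d + i,
    value(a|A) = mu + d - i,   value(a|a) = mu - a,

one parameter set (mu, a, d, i, sigma2) per generation.  The 4×4 design
matrix over configurations has rank 4, so the parameters are identifiable
from configuration means; positive i means the heterozygote with a
maternally derived A has the larger value, and i cancels from the
population mean because the reciprocal heterozygotes are equally frequent
under random mating.  Transgenerational change is the per-effect
difference Δa = a₁−a₂, Δd = d₁−d₂, Δi = i₁−i₂.

## Estimation

* **Allele frequency**: counting MLE over founders (grandparents and
  mothers), p̂ = (2·n_AA + n_Aa) / (2·n_founders).
* **Configuration priors**: a father is ambiguous only when both of his
  parents are heterozygous (the 5th of the nine grandparental mating
  types); a child only when both of its parents are.  Ambiguity always
  carries the symmetric Mendelian prior (1/2, 1/2); all other subjects
  have a forced configuration.  Mendelian impossibilities raise errors
  with the offending subject listed.
* **EM**: E-step computes posterior configuration weights from normal
  densities (in log space; with i = 0 the weight is exactly 1/2); M-step
  re-estimates the four configuration means by posterior-weighted least
  squares, inverts the rank-4 map to (mu, a, d, i), and pools the
  weighted squared residuals into one sigma2 per generation
  (homoscedastic across configurations).  The paternal and offspring
  likelihood components are independent, so the joint log-likelihood is
  their sum.
* **Constrained fits** (effects fixed at zero, or tied across
  generations for the Δ tests) run the same engine as an ECM: the tied
  mean update is a weighted least squares across both generations in a
  reduced parameter basis, followed by a conditional variance update.
  Both conditional maximizations increase the EM minorant, so the
  observed log-likelihood trace is non-decreasing for every fit, which
  the tests assert on every run.

### Numerical choices

* Initialization: mu, a, d from unordered-genotype means; i starts at
  0.1·SD(y) because a perfectly symmetric start (i = 0 with 1/2–1/2
  posteriors) is a fixed point of the EM map with î = 0.
* Convergence: absolute log-likelihood increment below 1e-8, at most
  1000 iterations (library defaults; both are arguments everywhere).
* sigma2 is floored at 1e-12 so that degenerate (constant-phenotype)
  inputs terminate cleanly; a configuration class with zero posterior
  weight triggers an "inestimable contrast" warning and a minimum-norm
  update.
* A likelihood-ratio statistic that comes out slightly negative (the
  unconstrained EM stopped in a marginally worse point than the nested
  fit) is clipped to zero.
* Standard errors come from the numerically differentiated observed
  information in (mu, a, d, i, log sigma2), with a delta-method
  conversion for sigma2.

## Hypothesis tests

Single effects use χ²(1) LRTs; transgenerational tests tie the selected
effects across generations and use χ² with one df per tied effect.  The
overall-association null (all six effects zero) retains the allele
frequency as a nuisance, so its threshold is calibrated by permuting
phenotypes *within* generation — fathers among fathers, children among
children — which preserves the pedigree/genotype structure and each
generation's marginal phenotype law; the default is 1000 permutations and
the permutation p-value is (1 + #{LR_perm ≥ LR_obs}) / (n_perm + 1).
The test level defaults to 0.05.  In the replicated calibration suite the
overall test runs with 19 permutations, which still yields an exact
0.05-level test (reject iff the observed LR exceeds every permuted one)
at a fraction of the cost.

Simulation at the null shows all nine tests (six single-effect, Δi,
joint Δadi, overall) within three Monte-Carlo standard errors of the
nominal 0.05 at 400 replicates.  The imprinting tests inherit a mild
finite-sample anticonservativeness from the symmetric-mixture component
of their likelihood (ambiguous heterozygotes), on the order of one to two
points at these sample sizes; it is visible in long calibration runs but
stays inside the acceptance band.

## Simulator

Founders are i.i.d. Hardy–Weinberg draws at allele frequency p (default
0.6); transmission is Mendelian with parental origin tracked as hidden
truth; phenotypes are configuration value plus N(0, sigma2_g) noise.
sigma2_g is calibrated per generation from that generation's effects and
a target heritability h²: sigma2 = Vg·(1−h²)/h², with Vg the genotypic
variance under ordered HWE frequencies.  Default generating effects are
parental (a, d, i) = (1.0, 0.5, 0.5) and offspring (0.5, 0.5, 0.0), so
the additive and imprinting effects change across generations while
dominance does not — this exercises every test in the battery, including
transgenerational loss of imprinting.  All randomness flows from one
seed; replicate k of a study derives its seed from the master seed, so
reports are bit-reproducible.

What the simulator does *not* emulate: genotyping error, missing
genotypes, ascertainment bias, population stratification, shared family
environment, maternal effects (which can masquerade as imprinting), or
mixed-sex second generations.  Passing tests therefore demonstrate the
statistical behaviour of the estimator under the idealized design, not
robustness to those realities.

## Two-SNP haplotype model

Four haplotypes AB, Ab, aB, ab with frequencies summing to one; one risk
haplotype H; composite diplotypes (HH, H|non, non|H, non|non) carry the
same (mu, a, d, i) parameterization at the haplotype level.

Stage 1 estimates (frequencies, r) from genotypes alone by an exact EM
over ordered-diplotype assignments of whole extended families.  Founder
diplotypes are products of haplotype frequencies (r plays no role in
founder frequencies; it enters only through transmission).  Gametes from
a doubly heterozygous parent are parental with probability (1−r)/2 each
and locus-swapped recombinants with r/2 each; parents heterozygous at
most at one locus transmit independently of r.  The E-step sums over all
candidate diplotypes of grandparents, sons, wives and children
(conditional independence of branches given the grandparental pair keeps
this linear in family size, and families of identical shape are batched
into array operations), so a double heterozygote's phase posterior
combines the population weight p_AB·p_ab/(p_AB·p_ab + p_Ab·p_aB) with
the evidence from its relatives' segregation.  The M-step counts expected
founder haplotypes (frequencies) and the expected recombinant fraction
among informative meioses (r, clipped to [0, 0.5]).  Offspring genotype
distributions for all 81 parental genotype combinations are generated
programmatically from this transmission machinery — there is no
hand-typed table — and each distribution sums to one by construction
(asserted exhaustively in the tests).

Stage 2 fixes (frequencies, r), converts each phenotyped subject's
ordered-diplotype posterior into a prior over the four composite
diplotypes, and runs the same per-generation mixture EM as the
single-SNP model; a one-stage joint fit of frequencies and effects is
deliberately out of scope.  The risk haplotype is chosen by refitting
under each of the four candidates and taking the maximum joint
log-likelihood, with exact ties broken toward the more frequent
haplotype; all four log-likelihoods are reported so near-ties are
visible.  When one SNP is monomorphic the model collapses to the
single-SNP model on the other locus and reproduces its fit exactly
(asserted in the tests).

## Study sizes used in the replicated suites

The shipped test suites run the power studies at 100 replicates per
strategy, null-calibration at 400 replicates, allele-frequency recovery
at 200 replicates, and haplotype-recovery at 48 replicates of an
800-subject design; these sizes give Monte-Carlo standard errors a few
times smaller than the margins being asserted while keeping the whole
suite runnable in minutes.  The acceptance script uses 200 / 100 / 150
replicates for its three quantities.

## Known limitations

* The χ² reference for the imprinting LRTs is asymptotic; with few
  informative (ambiguous) heterozygotes it is slightly anticonservative.
* Fathers' fitted configuration posteriors are not propagated into the
  offspring E-step; offspring ambiguity depends only on unordered
  parental genotypes, which keeps the two likelihood components
  independent but discards a sliver of information.
* Missing genotypes are not imputed; subjects with Mendelian conflicts
  abort the fit rather than being down-weighted.
* The haplotype module supports exactly two SNPs and a single risk
  haplotype.
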