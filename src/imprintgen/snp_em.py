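"""Maximum-likelihood estimation for a single SNP in the three-generation design.

Allele frequency has a closed-form counting MLE over founders.  The genetic
effects are estimated per generation by an EM algorithm over the latent
ordered configuration of ambiguous heterozygotes:

* a heterozygous *father* is ambiguous only when both of his parents are
  heterozygous (the double-heterozygote mating type); any homozygous
  grandparent forces the origin of one allele;
* a heterozygous *child* is ambiguous only when both its parents are
  heterozygous.

Ambiguous subjects enter with a symmetric Mendelian prior (1/2, 1/2) over
the reciprocal heterozygote configurations.  The E-step computes posterior
configuration weights from the normal phenotype densities; the M-step is a
posterior-weighted least-squares update of (mu, a, d, i) with a pooled
residual variance per generation.  Because offspring genotypes are
conditioned on parental genotypes, the joint likelihood decomposes into a
paternal and an offspring component that are maximized independently; the
joint log-likelihood is their sum.

The same engine also fits *constrained* models (effects fixed at zero or
tied across generations) for likelihood-ratio testing, via an ECM variant:
the tied mean update is a weighted least squares across both generations,
followed by a conditional variance update, which preserves the EM ascent
property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .family_model import (
    CONFIG_DESIGN,
    CONFIGS,
    GenerationParams,
    OrderedConfiguration,
)
from .pedigree import MendelianError, ThreeGenDataset

__all__ = [
    "FitResult",
    "estimate_allele_freq",
    "config_prior_weights",
    "resolve_father_configuration",
    "e_step_parental",
    "e_step_offspring",
    "m_step_parental",
    "em_parental",
    "em_offspring",
    "em_fit",
    "parental_block",
    "offspring_block",
    "observed_loglik",
    "param_standard_errors",
]

GEN_KEYS = ("parental", "offspring")

#: Parameter layout for joint fits: four effect parameters per generation.
PARAM_NAMES = ("mu1", "a1", "d1", "i1", "mu2", "a2", "d2", "i2")

_EFFECTS = ("a", "d", "i")

_MIN_SIGMA2 = 1e-12


@dataclass
class FitResult:
    """Converged EM estimates for one or both generations.

    ``loglik_trace`` is the observed-data log-likelihood at the start of each
    EM iteration and is non-decreasing; ``posteriors`` maps generation to an
    (n, 4) matrix of configuration weights in ``CONFIGS`` order.
    """

    params_by_generation: dict
    loglik: float
    posteriors: dict
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    constraints: tuple = ()
    inestimable: tuple = ()
    meta: dict = field(default_factory=dict)

    @property
    def params(self):
        """The single generation's params, or the dict for joint fits."""
        if len(self.params_by_generation) == 1:
            return next(iter(self.params_by_generation.values()))
        return self.params_by_generation


# ---------------------------------------------------------------------------
# Closed-form pieces
# ---------------------------------------------------------------------------


def estimate_allele_freq(data: ThreeGenDataset) -> float:
    """Allele-counting MLE of freq(A) over founders.

    Founders are the grandfathers, grandmothers and second-generation
    mothers - the individuals whose alleles enter the pedigree from the
    population.
    """
    founders = data.founders()
    if len(founders) == 0:
        raise ValueError("no genotyped founders in dataset")
    counts = founders["snp1"].value_counts()
    n_aa = int(counts.get("AA", 0))
    n_het = int(counts.get("Aa", 0))
    return (2 * n_aa + n_het) / (2 * len(founders))


def config_prior_weights(mother_geno: str, father_geno: str, child_geno: str) -> np.ndarray:
    """Mendelian prior over the child's four ordered configurations.

    Degenerate for unambiguous subjects; (0, 1/2, 1/2, 0) exactly when the
    child and both parents are heterozygous.  Raises
    :class:`~imprintgen.pedigree.MendelianError` on impossible trios.
    """
    w = np.zeros(4)
    for am in mother_geno:
        for ap in father_geno:
            if "".join(sorted((am, ap))) == child_geno:
                w[_CONFIG_POS[(am, ap)]] += 0.25
    total = w.sum()
    if total == 0.0:
        raise MendelianError(
            f"genotype {child_geno} impossible from parents {mother_geno} x {father_geno}"
        )
    return w / total


_CONFIG_POS = {c.value: k for k, c in enumerate(CONFIGS)}


def resolve_father_configuration(mating_type, father_genotype: str):
    """Configuration of a second-generation father, or ``"ambiguous"``.

    ``mating_type`` may be a :class:`~imprintgen.family_model.MatingType` or a
    ``(grandmother_genotype, grandfather_genotype)`` pair.  The grandmother is
    the maternal source.
    """
    if hasattr(mating_type, "grandmother_genotype"):
        gm, gf = mating_type.grandmother_genotype, mating_type.grandfather_genotype
    else:
        gm, gf = mating_type
    w = config_prior_weights(gm, gf, father_genotype)
    if np.count_nonzero(w) > 1:
        return "ambiguous"
    return CONFIGS[int(np.argmax(w))]


# ---------------------------------------------------------------------------
# E and M steps (single generation, exposed for direct use)
# ---------------------------------------------------------------------------


def _het_log_ratio(y, params: GenerationParams):
    s2 = params.sigma2
    m1 = params.mu + params.d + params.i
    m1p = params.mu + params.d - params.i
    return ((np.asarray(y, dtype=float) - m1p) ** 2 - (np.asarray(y) - m1) ** 2) / (2.0 * s2)


def e_step_parental(y, params: GenerationParams, prior=(0.5, 0.5)):
    """Posterior weight on configuration A|a (code 1) for ambiguous fathers.

    Computed in log space so that far-tail phenotypes are stable; with equal
    priors and ``i = 0`` the weight is exactly 1/2.
    """
    logit = _het_log_ratio(y, params) + np.log(prior[0] / prior[1])
    out = expit(logit)
    return float(out) if np.isscalar(y) else out


def e_step_offspring(y, params: GenerationParams, mother_genotype: str, father_genotype: str):
    """Posterior weight on A|a for an ambiguous child (both parents heterozygous)."""
    if mother_genotype != "Aa" or father_genotype != "Aa":
        raise ValueError(
            "child configuration is forced unless both parents are heterozygous; "
            f"got mother {mother_genotype}, father {father_genotype}"
        )
    return e_step_parental(y, params, prior=(0.5, 0.5))


def m_step_parental(y, weights) -> GenerationParams:
    """Weighted least-squares update of (mu, a, d, i) and pooled variance.

    ``weights`` is (n, 4) posterior configuration weight matrix.  A
    configuration with zero total weight leaves one contrast inestimable; the
    minimum-norm solution is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    sw = w.sum(axis=0)
    if np.any(sw <= 0):
        empty = [CONFIGS[k].name for k in np.flatnonzero(sw <= 0)]
        warnings.warn(f"configurations with zero weight: {empty}; contrast inestimable", stacklevel=2)
    A = CONFIG_DESIGN.T @ (sw[:, None] * CONFIG_DESIGN)
    b = CONFIG_DESIGN.T @ (w.T @ y)
    theta = np.linalg.lstsq(A, b, rcond=None)[0]
    m = CONFIG_DESIGN @ theta
    sigma2 = float((w * (y[:, None] - m) ** 2).sum() / len(y))
    return GenerationParams(*theta, sigma2=max(sigma2, 0.0))


# ---------------------------------------------------------------------------
# Blocks: phenotype vectors + Mendelian configuration priors per generation
# ---------------------------------------------------------------------------


def parental_block(data: ThreeGenDataset):
    """(y, prior, subject ids) for phenotyped second-generation fathers."""
    rows = data.with_parent_genotypes("father")
    rows = rows[rows["phenotype"].notna()]
    if len(rows) == 0:
        raise ValueError("no phenotyped fathers in dataset")
    prior = np.vstack(
        [
            config_prior_weights(r.mother_geno, r.father_geno, r.snp1)
            for r in rows.itertuples()
        ]
    )
    return rows["phenotype"].to_numpy(float), prior, rows["subject_id"].to_numpy()


def offspring_block(data: ThreeGenDataset):
    """(y, prior, subject ids) for phenotyped third-generation children."""
    rows = data.with_parent_genotypes("child")
    rows = rows[rows["phenotype"].notna()]
    if len(rows) == 0:
        raise ValueError("no phenotyped children in dataset")
    prior = np.vstack(
        [
            config_prior_weights(r.mother_geno, r.father_geno, r.snp1)
            for r in rows.itertuples()
        ]
    )
    return rows["phenotype"].to_numpy(float), prior, rows["subject_id"].to_numpy()


# ---------------------------------------------------------------------------
# Constraint handling
# ---------------------------------------------------------------------------


def _normalize_constraints(constraints, gens):
    out = []
    for c in constraints:
        c = str(c).replace(" ", "").replace("-", "_")
        if c in ("all_zero", "allzero"):
            for e in _EFFECTS:
                for g in gens:
                    out.append(f"{e}{g + 1}=0")
        elif c in ("a=0", "d=0", "i=0"):
            for g in gens:
                out.append(f"{c[0]}{g + 1}=0")
        else:
            out.append(c)
    return tuple(out)


def _constraint_basis(constraints, gens):
    """Matrix C mapping free parameters to the active (mu,a,d,i) layout."""
    active = [4 * g + k for g in gens for k in range(4)]
    pos = {PARAM_NAMES[j]: r for r, j in enumerate(active)}
    n = len(active)
    root = list(range(n))
    zero = set()

    def find(x):
        while root[x] != x:
            root[x] = root[root[x]]
            x = root[x]
        return x

    for c in constraints:
        lhs, rhs = c.split("=")
        if lhs not in pos:
            raise ValueError(f"constraint {c!r} refers to a generation not being fitted")
        if rhs == "0":
            zero.add(find(pos[lhs]))
        else:
            if rhs not in pos:
                raise ValueError(f"constraint {c!r} refers to a generation not being fitted")
            ra, rb = find(pos[lhs]), find(pos[rhs])
            if ra != rb:
                root[ra] = rb

    groups = {}
    for r in range(n):
        g = find(r)
        if g in {find(z) for z in zero}:
            continue
        groups.setdefault(g, []).append(r)
    C = np.zeros((n, len(groups)))
    for col, members in enumerate(groups.values()):
        C[members, col] = 1.0
    return C


# ---------------------------------------------------------------------------
# EM / ECM core
# ---------------------------------------------------------------------------


def _default_init(y, prior):
    """Moment start: genotype-class means for (mu, a, d); a small positive
    perturbation on i breaks the reciprocal-heterozygote symmetry (a
    symmetric start is a fixed point with i = 0)."""
    y = np.asarray(y, dtype=float)
    is_AA = prior[:, 0] > 0.999
    is_aa = prior[:, 3] > 0.999
    is_het = ~(is_AA | is_aa)
    mu = float(np.mean(y))
    m_AA = float(np.mean(y[is_AA])) if is_AA.any() else mu
    m_aa = float(np.mean(y[is_aa])) if is_aa.any() else mu
    m_het = float(np.mean(y[is_het])) if is_het.any() else mu
    a = (m_AA - m_aa) / 2.0
    d = m_het - (m_AA + m_aa) / 2.0
    i = 0.1 * float(np.std(y)) if np.std(y) > 0 else 0.1
    s2 = max(float(np.var(y)), 1e-6)
    return GenerationParams((m_AA + m_aa) / 2.0, a, d, i, sigma2=s2)


def _block_loglik_and_weights(y, prior, theta4, sigma2):
    m = CONFIG_DESIGN @ theta4
    with np.errstate(divide="ignore"):
        logp = np.where(prior > 0, np.log(np.clip(prior, 1e-300, None)), -np.inf)
    logphi = -0.5 * ((y[:, None] - m) ** 2 / sigma2 + np.log(2 * np.pi * sigma2))
    logw = logp + logphi
    lse = logsumexp(logw, axis=1)
    w = np.exp(logw - lse[:, None])
    return float(lse.sum()), w


def em_fit(
    blocks,
    constraints=(),
    init=None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FitResult:
    """Fit one or both generations by EM/ECM under optional constraints.

    ``blocks`` maps generation key ("parental"/"offspring") to ``(y, prior)``.
    Constraints: ``"a1=0"`` ... ``"i2=0"`` (or ``"a=0"`` for every fitted
    generation), ``"a1=a2"``, ``"d1=d2"``, ``"i1=i2"``, ``"all_zero"``.
    """
    gens = [GEN_KEYS.index(k) for k in blocks]
    keys = list(blocks)
    constraints = _normalize_constraints(constraints, gens)
    C = _constraint_basis(constraints, gens)

    ys = {k: np.asarray(blocks[k][0], dtype=float) for k in keys}
    priors = {k: np.asarray(blocks[k][1], dtype=float) for k in keys}

    init = dict(init or {})
    theta0, sigma2 = [], {}
    for k in keys:
        p0 = init.get(k) or _default_init(ys[k], priors[k])
        if p0.sigma2 is None:
            p0 = p0.with_sigma2(max(float(np.var(ys[k])), 1e-6))
        theta0.extend(p0.effects())
        sigma2[k] = p0.sigma2
    theta0 = np.asarray(theta0)
    # project the start into the constrained basis
    tf = np.linalg.lstsq(C, theta0, rcond=None)[0] if C.shape[1] else np.zeros(0)
    theta = C @ tf if C.shape[1] else np.zeros(len(theta0))

    trace = []
    weights = {}
    converged = False
    n_iter = 0
    inestimable = set()
    for it in range(max_iter + 1):
        ll = 0.0
        for j, k in enumerate(keys):
            bll, w = _block_loglik_and_weights(
                ys[k], priors[k], theta[4 * j : 4 * j + 4], sigma2[k]
            )
            ll += bll
            weights[k] = w
        trace.append(ll)
        if it > 0 and abs(ll - trace[-2]) < tol:
            converged = True
            break
        if it == max_iter:
            break
        # CM step 1: means by weighted least squares in the constrained basis
        if C.shape[1]:
            A = np.zeros((len(theta), len(theta)))
            b = np.zeros(len(theta))
            for j, k in enumerate(keys):
                sw = weights[k].sum(axis=0)
                sy = weights[k].T @ ys[k]
                sl = slice(4 * j, 4 * j + 4)
                A[sl, sl] = CONFIG_DESIGN.T @ (sw[:, None] * CONFIG_DESIGN) / sigma2[k]
                b[sl] = CONFIG_DESIGN.T @ sy / sigma2[k]
            Ar = C.T @ A @ C
            br = C.T @ b
            if np.linalg.matrix_rank(Ar) < Ar.shape[0]:
                inestimable.add("singular mean update (empty configuration class)")
            tf = np.linalg.lstsq(Ar, br, rcond=None)[0]
            theta = C @ tf
        # CM step 2: pooled variance per generation given the new means
        for j, k in enumerate(keys):
            m = CONFIG_DESIGN @ theta[4 * j : 4 * j + 4]
            s2 = float((weights[k] * (ys[k][:, None] - m) ** 2).sum() / len(ys[k]))
            sigma2[k] = max(s2, _MIN_SIGMA2)
        n_iter = it + 1

    params = {
        k: GenerationParams(*theta[4 * j : 4 * j + 4], sigma2=sigma2[k])
        for j, k in enumerate(keys)
    }
    return FitResult(
        params_by_generation=params,
        loglik=trace[-1],
        posteriors=dict(weights),
        n_iter=n_iter,
        converged=converged,
        loglik_trace=np.asarray(trace),
        constraints=constraints,
        inestimable=tuple(sorted(inestimable)),
    )


def em_parental(data: ThreeGenDataset, init=None, tol=1e-8, max_iter=1000) -> FitResult:
    """EM fit of the parental-generation parameters from fathers' phenotypes."""
    y, prior, _ = parental_block(data)
    init = {"parental": init} if isinstance(init, GenerationParams) else init
    return em_fit({"parental": (y, prior)}, init=init, tol=tol, max_iter=max_iter)


def em_offspring(data: ThreeGenDataset, init=None, tol=1e-8, max_iter=1000) -> FitResult:
    """EM fit of the offspring-generation parameters from children's phenotypes."""
    y, prior, _ = offspring_block(data)
    init = {"offspring": init} if isinstance(init, GenerationParams) else init
    return em_fit({"offspring": (y, prior)}, init=init, tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# Direct likelihood utilities (oracle / uncertainty)
# ---------------------------------------------------------------------------


def observed_loglik(blocks, params_by_generation) -> float:
    """Observed-data log-likelihood at given parameters (no latent update)."""
    ll = 0.0
    for k, (y, prior) in blocks.items():
        p = params_by_generation[k]
        bll, _ = _block_loglik_and_weights(
            np.asarray(y, float), np.asarray(prior, float), p.effects(), p.sigma2
        )
        ll += bll
    return ll


def param_standard_errors(blocks, params_by_generation) -> dict:
    """Asymptotic standard errors from the numerically observed information.

    Central-difference Hessian of the observed log-likelihood in
    (mu, a, d, i, log sigma2) per generation; the delta method converts the
    log-variance axis back to sigma2.
    """
    out = {}
    for k, (y, prior) in blocks.items():
        p = params_by_generation[k]
        x0 = np.array([p.mu, p.a, p.d, p.i, np.log(p.sigma2)])

        def nll(x):
            pp = GenerationParams(*x[:4], sigma2=float(np.exp(x[4])))
            return -observed_loglik({k: (y, prior)}, {k: pp})

        n = len(x0)
        h = 1e-4 * np.maximum(np.abs(x0), 1.0)
        H = np.zeros((n, n))
        for i_ in range(n):
            for j_ in range(i_, n):
                ei = np.zeros(n); ei[i_] = h[i_]
                ej = np.zeros(n); ej[j_] = h[j_]
                H[i_, j_] = H[j_, i_] = (
                    nll(x0 + ei + ej) - nll(x0 + ei - ej)
                    - nll(x0 - ei + ej) + nll(x0 - ei - ej)
                ) / (4 * h[i_] * h[j_])
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            se_sigma2 = se[4] * p.sigma2  # delta method for log sigma2
            out[k] = {"mu": se[0], "a": se[1], "d": se[2], "i": se[3], "sigma2": se_sigma2}
        except np.linalg.LinAlgError:
            out[k] = {n_: np.nan for n_ in ("mu", "a", "d", "i", "sigma2")}
    return out
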