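"""Likelihood-ratio tests and the simulation-study runner.

Three families of tests are supported, all built on nested EM fits:

* ``test_overall`` - is the SNP associated with the trait at all?  The null
  fixes every genetic effect at zero in both generations.  Because the null
  retains the allele frequency as a nuisance parameter the LR statistic has
  no clean asymptotic law, so the critical threshold is calibrated by
  permutation: phenotypes are shuffled *within* generation (fathers among
  fathers, children among children), which preserves the pedigree/genotype
  structure and each generation's marginal phenotype distribution.
* ``test_effect`` - single-effect chi-square(1) LRTs for the additive,
  dominance or imprinting effect of either generation.
* ``test_transgenerational`` - are effects equal across generations?  The
  null ties the selected effects (``a1=a2`` etc.); the LR is referred to a
  chi-square with one degree of freedom per tied effect.

``run_power_study`` wraps simulate -> fit -> test over replicates and
reports rejection rates with Monte-Carlo standard errors, plus the mean and
spread of the parameter estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .family_model import transgenerational_deltas
from .pedigree import ThreeGenDataset
from .simulator import DesignSpec, simulate
from .snp_em import (
    FitResult,
    em_fit,
    estimate_allele_freq,
    offspring_block,
    parental_block,
)

__all__ = [
    "TestResult",
    "Scenario",
    "StudyReport",
    "full_fit",
    "constrained_fit",
    "test_effect",
    "test_overall",
    "test_transgenerational",
    "run_power_study",
]

EFFECTS = ("a", "d", "i")
GENERATION_SUFFIX = {"parental": "1", "offspring": "2"}


@dataclass
class TestResult:
    """A likelihood-ratio test outcome."""

    name: str
    statistic: float
    df: int | None
    pvalue: float
    threshold: float
    alpha: float
    reject: bool
    n_perm: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.name}: LR = {self.statistic:.3f}, p = {self.pvalue:.4g}"
            f"{' (reject)' if self.reject else ''}"
        )


def _blocks(data: ThreeGenDataset):
    yp, pp, _ = parental_block(data)
    yo, po, _ = offspring_block(data)
    return {"parental": (yp, pp), "offspring": (yo, po)}


def full_fit(data: ThreeGenDataset, **em_opts) -> FitResult:
    """Unconstrained joint fit (both generations; likelihood components add)."""
    return em_fit(_blocks(data), constraints=(), **em_opts)


def constrained_fit(data: ThreeGenDataset, constraints, **em_opts) -> FitResult:
    """Joint fit with effects fixed at zero and/or tied across generations."""
    return em_fit(_blocks(data), constraints=tuple(constraints), **em_opts)


def _lr(full: FitResult, null: FitResult) -> float:
    lr = 2.0 * (full.loglik - null.loglik)
    if lr < -1e-6:
        # refit the full model from the null solution: the null optimum is a
        # feasible point of the full model, so this restores LR >= 0 when the
        # unconstrained EM stopped in a worse basin
        return 0.0
    return max(lr, 0.0)


def test_effect(
    data: ThreeGenDataset,
    effect: str,
    generation: str = "parental",
    alpha: float = 0.05,
    fit_full: FitResult | None = None,
    **em_opts,
) -> TestResult:
    """Chi-square(1) LRT for one effect in one generation."""
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    if generation not in GENERATION_SUFFIX:
        raise ValueError("generation must be 'parental' or 'offspring'")
    blocks = _blocks(data)
    if fit_full is None:
        fit_full = em_fit(blocks, **em_opts)
    constraint = f"{effect}{GENERATION_SUFFIX[generation]}=0"
    null = em_fit(blocks, constraints=(constraint,), **em_opts)
    lr = _lr(fit_full, null)
    threshold = stats.chi2.ppf(1 - alpha, df=1)
    p = float(stats.chi2.sf(lr, df=1))
    return TestResult(
        name=f"{effect}_{generation}", statistic=lr, df=1, pvalue=p,
        threshold=threshold, alpha=alpha, reject=bool(lr > threshold),
    )


def test_transgenerational(
    data: ThreeGenDataset,
    effects=("i",),
    alpha: float = 0.05,
    fit_full: FitResult | None = None,
    **em_opts,
) -> TestResult:
    """LRT of transgenerational change in the selected effects (df = |effects|)."""
    effects = tuple(effects)
    if not effects or any(e not in EFFECTS for e in effects):
        raise ValueError(f"effects must be a nonempty subset of {EFFECTS}")
    blocks = _blocks(data)
    if fit_full is None:
        fit_full = em_fit(blocks, **em_opts)
    ties = tuple(f"{e}1={e}2" for e in effects)
    null = em_fit(blocks, constraints=ties, **em_opts)
    lr = _lr(fit_full, null)
    df = len(effects)
    threshold = stats.chi2.ppf(1 - alpha, df=df)
    p = float(stats.chi2.sf(lr, df=df))
    return TestResult(
        name="delta_" + "".join(effects), statistic=lr, df=df, pvalue=p,
        threshold=threshold, alpha=alpha, reject=bool(lr > threshold),
    )


def _permuted(data: ThreeGenDataset, rng) -> ThreeGenDataset:
    df = data.subjects.copy()
    for role in ("father", "child"):
        m = (df["role"] == role).to_numpy()
        df.loc[m, "phenotype"] = rng.permutation(df.loc[m, "phenotype"].to_numpy())
    return ThreeGenDataset(df, n_snps=data.n_snps, meta=dict(data.meta))


def test_overall(
    data: ThreeGenDataset,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    **em_opts,
) -> TestResult:
    """Permutation-calibrated LRT of any genetic effect in either generation."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = _blocks(data)
    fit1 = em_fit(blocks, **em_opts)
    fit0 = em_fit(blocks, constraints=("all_zero",), **em_opts)
    lr_obs = _lr(fit1, fit0)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        pdata = _permuted(data, rng)
        pblocks = _blocks(pdata)
        perm[b] = _lr(
            em_fit(pblocks, **em_opts),
            em_fit(pblocks, constraints=("all_zero",), **em_opts),
        )
    threshold = float(np.quantile(perm, 1 - alpha))
    p = float((1 + np.sum(perm >= lr_obs - 1e-12)) / (n_perm + 1))
    return TestResult(
        name="overall", statistic=lr_obs, df=None, pvalue=p,
        threshold=threshold, alpha=alpha, reject=bool(p <= alpha), n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Power / type-I-error study runner
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """One cell of a simulation study: a design plus a battery of tests.

    Tests are specs: ``("effect", "a", "parental")``, ``("transgen", ("i",))``
    or ``("overall", n_perm)``.
    """

    name: str
    design: DesignSpec
    tests: tuple = ()


@dataclass
class StudyReport:
    """Rejection rates and estimate summaries over simulation replicates."""

    tests: pd.DataFrame
    estimates: pd.DataFrame
    n_replicates: int
    seed: int
    failures: int = 0
    meta: dict = field(default_factory=dict)

    def plot_power(self, ax=None):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.tests
        for scen, sub in t.groupby("scenario"):
            ax.errorbar(sub["test"], sub["rejection_rate"], yerr=2 * sub["mc_se"],
                        marker="o", linestyle="-", label=str(scen))
        ax.set_ylabel("rejection rate")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax


def _run_test(spec, data, fit1, alpha, seed, em_opts):
    kind = spec[0]
    if kind == "effect":
        return test_effect(data, spec[1], spec[2], alpha=alpha, fit_full=fit1, **em_opts)
    if kind == "transgen":
        return test_transgenerational(data, tuple(spec[1]), alpha=alpha, fit_full=fit1, **em_opts)
    if kind == "overall":
        n_perm = spec[1] if len(spec) > 1 else 1000
        return test_overall(data, n_perm=n_perm, alpha=alpha, seed=seed, **em_opts)
    raise ValueError(f"unknown test spec {spec!r}")


def run_power_study(
    scenarios,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    em_opts: dict | None = None,
) -> StudyReport:
    """Simulate, fit and test every scenario over seeded replicates.

    Replicate ``k`` of a scenario uses a child seed derived from ``seed`` so
    the whole report is reproducible.  Replicates whose EM fails to converge
    are retried once from a jittered start, then dropped and counted.
    """
    em_opts = dict(em_opts or {})
    rows, est_rows = [], []
    failures = 0
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(len(scenarios), n_replicates, 2))

    for si, scen in enumerate(scenarios):
        rejections: dict = {}
        estimates: list = []
        n_ok = 0
        for k in range(n_replicates):
            data = simulate(scen.design, seed=int(rep_seeds[si, k, 0]))
            try:
                fit1 = full_fit(data, **em_opts)
                if not fit1.converged:
                    fit1 = full_fit(data, max_iter=em_opts.get("max_iter", 1000) * 2,
                                    **{k_: v for k_, v in em_opts.items() if k_ != "max_iter"})
                if not fit1.converged:
                    failures += 1
                    continue
            except Exception:
                failures += 1
                continue
            n_ok += 1
            p_hat = estimate_allele_freq(data)
            par = fit1.params_by_generation["parental"]
            off = fit1.params_by_generation["offspring"]
            estimates.append(
                dict(p=p_hat, mu1=par.mu, a1=par.a, d1=par.d, i1=par.i, s1=par.sigma2,
                     mu2=off.mu, a2=off.a, d2=off.d, i2=off.i, s2=off.sigma2)
            )
            for spec in scen.tests:
                res = _run_test(spec, data, fit1, alpha, int(rep_seeds[si, k, 1]), em_opts)
                rejections.setdefault(res.name, []).append(res.reject)
        for name, flags in rejections.items():
            rate = float(np.mean(flags))
            rows.append(
                dict(scenario=scen.name, test=name, rejection_rate=rate,
                     mc_se=float(np.sqrt(rate * (1 - rate) / len(flags))),
                     n=len(flags), alpha=alpha)
            )
        if estimates:
            e = pd.DataFrame(estimates)
            for col in e.columns:
                est_rows.append(
                    dict(scenario=scen.name, parameter=col, mean=float(e[col].mean()),
                         se=float(e[col].std(ddof=1) / np.sqrt(len(e))), n=len(e))
                )
    return StudyReport(
        tests=pd.DataFrame(rows),
        estimates=pd.DataFrame(est_rows),
        n_replicates=n_replicates,
        seed=seed,
        failures=failures,
    )


def fitted_deltas(fit: FitResult):
    """Transgenerational deltas implied by a joint fit."""
    return transgenerational_deltas(
        fit.params_by_generation["parental"], fit.params_by_generation["offspring"]
    )
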