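"""Model/Results facade over the estimation machinery.

:class:`TransgenImprintingModel` is built from a three-generation dataset
(or a pedigree file / DataFrame); ``fit()`` runs the per-generation EM and
returns a :class:`TransgenImprintingResults` carrying the estimates, their
asymptotic standard errors, the transgenerational deltas and the fitted
posteriors, with ``summary()`` producing a readable table and the test
methods running the likelihood-ratio battery.  The two-SNP
:class:`HaplotypeImprintingModel` follows the same pattern with the
two-stage haplotype fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import haplotype as hap
from . import inference, io, snp_em
from .family_model import transgenerational_deltas
from .pedigree import ThreeGenDataset

__all__ = [
    "TransgenImprintingModel",
    "TransgenImprintingResults",
    "HaplotypeImprintingModel",
    "HaplotypeImprintingResults",
]


def _fmt_table(rows, header) -> str:
    widths = [max(len(str(r[c])) for r in ([header] + rows)) for c in range(len(header))]
    def line(r):
        return "  ".join(str(v).rjust(w) for v, w in zip(r, widths))
    sep = "-" * (sum(widths) + 2 * (len(widths) - 1))
    return "\n".join([line(header), sep] + [line(r) for r in rows])


class TransgenImprintingModel:
    """Single-SNP imprinting model for a three-generation family sample."""

    def __init__(self, data: ThreeGenDataset):
        data.validate()
        self.data = data

    @classmethod
    def from_pedigree(cls, path) -> "TransgenImprintingModel":
        return cls(io.read_pedigree(path, n_snps=1))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TransgenImprintingModel":
        return cls(ThreeGenDataset(df.copy(), n_snps=1))

    def fit(self, constraints=(), tol: float = 1e-8, max_iter: int = 1000
            ) -> "TransgenImprintingResults":
        fit = inference.constrained_fit(self.data, constraints, tol=tol, max_iter=max_iter)
        return TransgenImprintingResults(self, fit)


class TransgenImprintingResults:
    """Estimates, uncertainties and tests for a fitted single-SNP model."""

    def __init__(self, model: TransgenImprintingModel, fit: snp_em.FitResult):
        self.model = model
        self.fit = fit
        self.params_parental = fit.params_by_generation["parental"]
        self.params_offspring = fit.params_by_generation["offspring"]
        self.allele_freq = snp_em.estimate_allele_freq(model.data)
        self.deltas = transgenerational_deltas(self.params_parental, self.params_offspring)
        self.llf = fit.loglik
        self.converged = fit.converged
        self._bse = None

    @property
    def bse(self) -> dict:
        """Asymptotic standard errors (numerical observed information)."""
        if self._bse is None:
            blocks = inference._blocks(self.model.data)
            self._bse = snp_em.param_standard_errors(blocks, self.fit.params_by_generation)
        return self._bse

    # -- tests -------------------------------------------------------------
    def test_effect(self, effect, generation="parental", alpha=0.05, **em_opts):
        return inference.test_effect(self.model.data, effect, generation,
                                     alpha=alpha, fit_full=self.fit, **em_opts)

    def test_transgenerational(self, effects=("i",), alpha=0.05, **em_opts):
        return inference.test_transgenerational(self.model.data, effects,
                                                alpha=alpha, fit_full=self.fit, **em_opts)

    def test_overall(self, n_perm=1000, alpha=0.05, seed=None, **em_opts):
        return inference.test_overall(self.model.data, n_perm=n_perm,
                                      alpha=alpha, seed=seed, **em_opts)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        bse = self.bse
        rows = []
        for key, p in (("parental", self.params_parental),
                       ("offspring", self.params_offspring)):
            for name in ("mu", "a", "d", "i", "sigma2"):
                rows.append([
                    key, name, f"{getattr(p, name):.4f}", f"{bse[key][name]:.4f}",
                ])
        lines = [
            "Transgenerational imprinting model (single SNP)",
            f"subjects: {len(self.model.data.subjects)}, "
            f"log-likelihood: {self.llf:.3f}, converged: {self.converged}",
            f"allele frequency (founder MLE): {self.allele_freq:.4f}",
            "",
            _fmt_table(rows, ["generation", "param", "estimate", "std err"]),
            "",
            "transgenerational deltas (parental - offspring): "
            f"da = {self.deltas.delta_a:.4f}, dd = {self.deltas.delta_d:.4f}, "
            f"di = {self.deltas.delta_i:.4f}",
        ]
        return "\n".join(lines)

    def plot_loglik(self, ax=None):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.fit.loglik_trace)), self.fit.loglik_trace)
        ax.set_xlabel("EM iteration")
        ax.set_ylabel("observed log-likelihood")
        return ax


class HaplotypeImprintingModel:
    """Two-SNP haplotype imprinting model (risk vs non-risk composite diplotypes)."""

    def __init__(self, data: ThreeGenDataset):
        if data.n_snps < 2:
            raise ValueError("haplotype model requires two genotype columns")
        data.validate()
        self.data = data

    @classmethod
    def from_pedigree(cls, path) -> "HaplotypeImprintingModel":
        return cls(io.read_pedigree(path, n_snps=2))

    def fit(self, risk_haplotype=None, tol=1e-8, max_iter=1000
            ) -> "HaplotypeImprintingResults":
        stage1 = hap.em_haplotype_frequencies(self.data)
        if risk_haplotype is None:
            sel = hap.select_risk_haplotype(
                self.data, stage1.frequencies, stage1.r, tol=tol, max_iter=max_iter
            )
            risk, fit, logliks = sel.risk_haplotype, sel.fits[sel.risk_haplotype], sel.logliks
        else:
            fit = hap.fit_composite_diplotype_effects(
                self.data, stage1.frequencies, stage1.r, risk_haplotype,
                tol=tol, max_iter=max_iter,
            )
            risk, logliks = risk_haplotype, {risk_haplotype: fit.loglik}
        return HaplotypeImprintingResults(self, stage1, risk, fit, logliks)


class HaplotypeImprintingResults:
    def __init__(self, model, stage1: hap.HaplotypeFreqFit, risk: str,
                 fit: snp_em.FitResult, logliks: dict):
        self.model = model
        self.stage1 = stage1
        self.frequencies = stage1.frequencies
        self.r = stage1.r
        self.risk_haplotype = risk
        self.fit = fit
        self.logliks = logliks
        self.params_parental = fit.params_by_generation["parental"]
        self.params_offspring = fit.params_by_generation["offspring"]
        self.deltas = transgenerational_deltas(self.params_parental, self.params_offspring)
        self.llf = fit.loglik

    def test_transgenerational(self, effects=("i",), alpha=0.05, **em_opts):
        from scipy import stats

        full = self.fit
        ties = tuple(f"{e}1={e}2" for e in effects)
        null = hap.fit_composite_diplotype_effects(
            self.model.data, self.frequencies, self.r, self.risk_haplotype,
            constraints=ties, **em_opts)
        lr = max(2.0 * (full.loglik - null.loglik), 0.0)
        df = len(effects)
        thr = stats.chi2.ppf(1 - alpha, df=df)
        return inference.TestResult(
            name="hap_delta_" + "".join(effects), statistic=lr, df=df,
            pvalue=float(stats.chi2.sf(lr, df=df)), threshold=thr,
            alpha=alpha, reject=bool(lr > thr),
        )

    def summary(self) -> str:
        rows = [[h, f"{f:.4f}"] for h, f in zip(hap.HAPLOTYPES, self.frequencies)]
        prows = []
        for key, p in (("parental", self.params_parental),
                       ("offspring", self.params_offspring)):
            prows.append([key, f"{p.mu:.4f}", f"{p.a:.4f}", f"{p.d:.4f}",
                          f"{p.i:.4f}", f"{p.sigma2:.4f}"])
        lines = [
            "Haplotype imprinting model (two SNPs)",
            f"recombination fraction r = {self.r:.4f}; "
            f"risk haplotype = {self.risk_haplotype}; log-likelihood = {self.llf:.3f}",
            "",
            _fmt_table(rows, ["haplotype", "frequency"]),
            "",
            _fmt_table(prows, ["generation", "mu", "a", "d", "i", "sigma2"]),
        ]
        return "\n".join(lines)
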