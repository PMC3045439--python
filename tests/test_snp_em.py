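import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import imprintgen as ig
from imprintgen.family_model import CONFIGS, GenerationParams, OrderedConfiguration
from imprintgen.pedigree import MendelianError, ThreeGenDataset
from imprintgen.snp_em import (
    config_prior_weights,
    e_step_offspring,
    e_step_parental,
    em_fit,
    em_offspring,
    em_parental,
    estimate_allele_freq,
    m_step_parental,
    observed_loglik,
    offspring_block,
    parental_block,
    resolve_father_configuration,
)


def _founder_only_dataset(n_AA, n_Aa, n_aa):
    rows = []
    k = 0
    for geno, n in (("AA", n_AA), ("Aa", n_Aa), ("aa", n_aa)):
        for _ in range(n):
            k += 1
            rows.append(dict(family_id=f"F{k}", subject_id=f"S{k}", father_id="0",
                             mother_id="0", sex="F", generation=1,
                             role="grandmother", mating_type=0, snp1=geno,
                             phenotype=np.nan))
    return ThreeGenDataset(pd.DataFrame(rows))


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "counts, expected",
        [((36, 48, 16), 0.6), ((10, 0, 0), 1.0), ((1, 2, 1), 0.5)],
    )
    def test_counting(self, counts, expected):
        data = _founder_only_dataset(*counts)
        assert estimate_allele_freq(data) == pytest.approx(expected)

    def test_excludes_nonfounders(self, strategy1_data):
        # only grandparents and mothers count: 600 founders under strategy 1
        assert len(strategy1_data.founders()) == 600


class TestConfigurationResolution:
    def test_forced_origins(self):
        assert resolve_father_configuration(("AA", "aa"), "Aa") is OrderedConfiguration.Aa
        assert resolve_father_configuration(("aa", "AA"), "Aa") is OrderedConfiguration.aA
        assert resolve_father_configuration(("Aa", "Aa"), "AA") is OrderedConfiguration.AA

    def test_double_het_parents_ambiguous(self):
        assert resolve_father_configuration(("Aa", "Aa"), "Aa") == "ambiguous"
        w = config_prior_weights("Aa", "Aa", "Aa")
        assert np.allclose(w, [0, 0.5, 0.5, 0])

    def test_accepts_mating_type_object(self):
        mt = ig.mating_type_table(0.5)[4]  # the double-het cross
        assert resolve_father_configuration(mt, "Aa") == "ambiguous"

    def test_mendelian_violation(self):
        with pytest.raises(MendelianError):
            config_prior_weights("AA", "AA", "aa")


class TestESteps:
    def test_midpoint_and_null_imprinting_give_half(self):
        p = GenerationParams(0.0, 1.0, 0.3, 0.7, sigma2=2.0)
        assert e_step_parental(p.mu + p.d, p) == pytest.approx(0.5)
        p0 = GenerationParams(0.0, 1.0, 0.3, 0.0, sigma2=2.0)
        for y in (-3.0, 0.0, 5.0):
            assert e_step_parental(y, p0) == pytest.approx(0.5)

    def test_density_ratio_values(self):
        p = GenerationParams(0.0, 0.0, 0.0, 1.0, sigma2=1.0)
        assert e_step_parental(1.0, p) == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)
        assert e_step_offspring(-1.0, p, "Aa", "Aa") == pytest.approx(
            1 / (1 + np.exp(2)), abs=1e-12
        )

    def test_extreme_phenotype_stable(self):
        p = GenerationParams(0.0, 0.0, 0.0, 1.0, sigma2=1.0)
        assert e_step_parental(1e4, p) == pytest.approx(1.0)
        assert np.isfinite(e_step_parental(-1e4, p))

    def test_offspring_contract(self):
        p = GenerationParams(sigma2=1.0)
        with pytest.raises(ValueError):
            e_step_offspring(0.0, p, "AA", "Aa")


class TestMStep:
    def test_configuration_mean_inversion(self):
        means = {"AA": 2.0, "Aa": 1.2, "aA": 0.4, "aa": -1.0}
        y, w = [], []
        for k, c in enumerate(CONFIGS):
            for dy in (-0.5, 0.5):
                y.append(means[c.name] + dy)
                row = np.zeros(4)
                row[k] = 1.0
                w.append(row)
        p = m_step_parental(np.array(y), np.array(w))
        m2, m1, m1p, m0 = (means[c.name] for c in CONFIGS)
        assert p.mu == pytest.approx((m2 + m0) / 2)
        assert p.a == pytest.approx((m2 - m0) / 2)
        assert p.d == pytest.approx((m1 + m1p) / 2 - (m2 + m0) / 2)
        assert p.i == pytest.approx((m1 - m1p) / 2)

    def test_constant_phenotypes(self):
        y = np.full(8, 3.0)
        w = np.tile([0.25, 0.25, 0.25, 0.25], (8, 1))
        p = m_step_parental(y, w)
        assert p.mu == pytest.approx(3.0)
        assert (p.a, p.d, p.i) == pytest.approx((0.0, 0.0, 0.0))
        assert p.sigma2 == pytest.approx(0.0)

    def test_symmetric_weights_fix_imprinting_at_zero(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        w = np.zeros((20, 4))
        w[:10, 0] = 1.0
        w[10:, 1] = w[10:, 2] = 0.5  # all heterozygotes split half/half
        with pytest.warns(UserWarning, match="inestimable"):
            p = m_step_parental(y, w)
        assert p.i == pytest.approx(0.0, abs=1e-12)


def _direct_mle(y, prior, starts):
    """Brute-force observed-likelihood maximization (independent oracle)."""
    def nll(x):
        params = GenerationParams(*x[:4], sigma2=float(np.exp(x[4])))
        return -observed_loglik({"g": (y, prior)}, {"g": params})

    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="Nelder-Mead",
                       options=dict(maxiter=40000, xatol=1e-10, fatol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


class TestEMParental:
    def test_monotone_loglik(self, strategy1_data):
        fit = em_parental(strategy1_data)
        assert fit.converged
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_no_ambiguity_reaches_complete_data_mle(self):
        # forced-origin families only: EM equals one complete-data WLS step
        rng = np.random.default_rng(3)
        rows = []
        combos = [("AA", "aa"), ("aa", "AA"), ("AA", "AA"), ("aa", "aa")]
        k = 0
        for gm, gf in combos * 10:
            k += 1
            fam = f"F{k}"
            son_geno = "Aa" if gm != gf else gm
            rows.append(dict(family_id=fam, subject_id=f"{fam}-GM", father_id="0",
                             mother_id="0", sex="F", generation=1, role="grandmother",
                             mating_type=0, snp1=gm, phenotype=np.nan))
            rows.append(dict(family_id=fam, subject_id=f"{fam}-GF", father_id="0",
                             mother_id="0", sex="M", generation=1, role="grandfather",
                             mating_type=0, snp1=gf, phenotype=np.nan))
            rows.append(dict(family_id=fam, subject_id=f"{fam}-S1",
                             father_id=f"{fam}-GF", mother_id=f"{fam}-GM", sex="M",
                             generation=2, role="father", mating_type=0,
                             snp1=son_geno, phenotype=rng.normal()))
        data = ThreeGenDataset(pd.DataFrame(rows))
        fit = em_parental(data)
        y, prior, _ = parental_block(data)
        assert np.allclose(prior.max(axis=1), 1.0)  # all configurations forced
        direct = m_step_parental(y, prior)
        assert fit.params.effects() == pytest.approx(direct.effects(), abs=1e-6)
        assert fit.n_iter <= 3

    def test_matches_direct_maximization_on_small_data(self, tiny_data):
        rng = np.random.default_rng(7)
        for block_fn, fit_fn in ((parental_block, em_parental),
                                 (offspring_block, em_offspring)):
            y, prior, _ = block_fn(tiny_data)
            fit = fit_fn(tiny_data, tol=1e-12, max_iter=5000)
            base = np.array([np.mean(y), 0.5 * np.std(y), 0.0, 0.1 * np.std(y),
                             np.log(np.var(y))])
            starts = [base] + [base + rng.normal(scale=0.3, size=5) for _ in range(4)]
            oracle = _direct_mle(y, prior, starts)
            assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_parameter_recovery_strategy1(self):
        spec = ig.strategy_preset("strategy1", h2_parental=0.4, h2_offspring=0.4)
        from imprintgen.simulator import resolved_params

        truth, _ = resolved_params(spec)
        rng = np.random.default_rng(21)
        est = []
        for s in rng.integers(0, 2**31 - 1, size=40):
            fit = em_parental(ig.simulate(spec, seed=int(s)))
            est.append(fit.params.effects())
        est = np.array(est)
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        for j, name in enumerate(("mu", "a", "d", "i")):
            assert abs(mean[j] - getattr(truth, name)) < 3 * se[j] + 0.02, name


class TestEMOffspring:
    def test_forced_child_configurations(self):
        # mother AA transmits A: every heterozygous child is A|a
        w = config_prior_weights("AA", "Aa", "Aa")
        assert np.allclose(w, [0, 1, 0, 0])
        w = config_prior_weights("aa", "Aa", "Aa")
        assert np.allclose(w, [0, 0, 1, 0])

    def test_joint_loglik_decomposes(self, strategy1_data):
        full = ig.full_fit(strategy1_data)
        par = em_parental(strategy1_data)
        off = em_offspring(strategy1_data)
        assert full.loglik == pytest.approx(par.loglik + off.loglik, abs=1e-5)

    def test_parameter_recovery_strategy2(self):
        spec = ig.strategy_preset("strategy2", h2_parental=0.4, h2_offspring=0.4)
        from imprintgen.simulator import resolved_params

        _, truth = resolved_params(spec)
        rng = np.random.default_rng(22)
        est = []
        for s in rng.integers(0, 2**31 - 1, size=40):
            fit = em_offspring(ig.simulate(spec, seed=int(s)))
            est.append(fit.params.effects())
        est = np.array(est)
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        for j, name in enumerate(("mu", "a", "d", "i")):
            assert abs(mean[j] - getattr(truth, name)) < 3 * se[j] + 0.02, name

    def test_estimator_spread_shrinks_with_sample_size(self):
        rng = np.random.default_rng(23)
        sds = []
        for n_fam in (200, 800):
            spec = ig.DesignSpec(n_gen1_families=n_fam, sons_per_family=1,
                                 children_per_couple=1)
            iis = [
                em_parental(ig.simulate(spec, seed=int(s))).params.i
                for s in rng.integers(0, 2**31 - 1, size=15)
            ]
            sds.append(np.std(iis, ddof=1))
        assert sds[1] < sds[0]


class TestConstrainedReduction:
    def test_i_zero_equals_classical_additive_dominant_fit(self, strategy1_data):
        import statsmodels.api as sm

        fit = ig.constrained_fit(strategy1_data, ("i=0",))
        for key, rows in (("parental", strategy1_data.fathers()),
                          ("offspring", strategy1_data.children())):
            y = rows["phenotype"].to_numpy(float)
            xa = rows["snp1"].map({"AA": 1.0, "Aa": 0.0, "aa": -1.0}).to_numpy()
            xd = rows["snp1"].map({"AA": 0.0, "Aa": 1.0, "aa": 0.0}).to_numpy()
            ols = sm.OLS(y, sm.add_constant(np.column_stack([xa, xd]))).fit()
            p = fit.params_by_generation[key]
            assert p.mu == pytest.approx(ols.params[0], abs=1e-6)
            assert p.a == pytest.approx(ols.params[1], abs=1e-6)
            assert p.d == pytest.approx(ols.params[2], abs=1e-6)
            assert p.i == pytest.approx(0.0, abs=1e-12)
            assert p.sigma2 == pytest.approx(ols.ssr / len(y), abs=1e-6)

    def test_i_zero_makes_posteriors_symmetric(self, strategy1_data):
        fit = ig.constrained_fit(strategy1_data, ("i=0",))
        for w in fit.posteriors.values():
            het = (w[:, 1] > 0) & (w[:, 2] > 0)
            assert np.allclose(w[het, 1], w[het, 2])

    def test_empty_constraint_equals_full_fit(self, strategy1_data):
        a = ig.full_fit(strategy1_data)
        b = ig.constrained_fit(strategy1_data, ())
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)

    def test_tied_fit_on_tied_truth_small_deficit(self):
        params = GenerationParams(0.0, 0.8, 0.4, 0.3)
        spec = ig.DesignSpec(n_gen1_families=200, sons_per_family=1,
                             children_per_couple=1, params_parental=params,
                             params_offspring=params)
        rng = np.random.default_rng(9)
        lrs = []
        for s in rng.integers(0, 2**31 - 1, size=20):
            data = ig.simulate(spec, seed=int(s))
            full = ig.full_fit(data)
            tied = ig.constrained_fit(data, ("a1=a2", "d1=d2", "i1=i2"))
            lrs.append(2 * (full.loglik - tied.loglik))
        lrs = np.array(lrs)
        assert np.all(lrs >= -1e-6)
        # LR ~ chi2(3) under the tied truth: mean about 3, far from diverging
        assert np.mean(lrs) < 10.0
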