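"""NB-GLM fitting, dispersion estimation, LRTs, and FDR control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from digitexpr import (
    CountMatrix,
    DesignSpec,
    ValidationError,
    adjust_bh,
    design_from_metadata,
    estimate_dispersions,
    fit_nb_glm,
    lrt_any_digit,
    lrt_pairwise,
    nb_loglik,
    null_config,
    pc1_covariate,
    simulate_counts,
    storey_pi0,
    storey_q,
)
from digitexpr.diffexp import PHI_FLOOR, fit_nb_glm_batch


def brute_force_two_group_ll(y, groups, phi):
    """Independent likelihood oracle: grid + Nelder-Mead over group log-means."""
    r = 1.0 / phi

    def nll(theta):
        mu = np.exp(np.asarray(theta))[groups]
        return -nbinom.logpmf(y, r, r / (r + mu)).sum()

    best = np.inf
    for t1 in np.linspace(-1, 6, 4):
        for t2 in np.linspace(-1, 6, 4):
            res = minimize(
                nll, [t1, t2], method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-13, maxiter=3000),
            )
            best = min(best, res.fun)
    return -best


def brute_force_intercept_ll(y, phi):
    r = 1.0 / phi

    def nll(t):
        mu = np.full(len(y), np.exp(t[0]))
        return -nbinom.logpmf(y, r, r / (r + mu)).sum()

    best = np.inf
    for t0 in np.linspace(-1, 6, 8):
        res = minimize(nll, [t0], method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-13, maxiter=2000))
        best = min(best, res.fun)
    return -best


class TestFitNBGLM:
    def test_intercept_only_gives_arithmetic_mean(self):
        y = np.array([3.0, 9.0, 6.0, 2.0])
        X = np.ones((4, 1))
        _, _, mu = fit_nb_glm(y, X, np.zeros(4), 0.1)
        np.testing.assert_allclose(mu, y.mean(), rtol=1e-8)

    def test_matches_brute_force_oracle(self):
        y = np.array([3.0, 5.0, 10.0, 14.0])
        groups = np.array([0, 0, 1, 1])
        X = np.column_stack([np.ones(4), groups])
        beta, ll, mu = fit_nb_glm(y, X, np.zeros(4), 0.1)
        ll_oracle = brute_force_two_group_ll(y, groups, 0.1)
        assert ll == pytest.approx(ll_oracle, abs=1e-6)
        # group fitted means are the oracle's too (score equations)
        np.testing.assert_allclose(mu[:2], 4.0, rtol=1e-6)
        np.testing.assert_allclose(mu[2:], 12.0, rtol=1e-6)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(6):
            n = int(rng.integers(4, 9))
            groups = np.array([0] * (n // 2) + [1] * (n - n // 2))
            y = rng.integers(0, 201, size=n).astype(float)
            phi = float(rng.uniform(0.02, 0.5))
            X = np.column_stack([np.ones(n), groups])
            _, ll, _ = fit_nb_glm(y, X, np.zeros(n), phi)
            assert ll >= brute_force_two_group_ll(y, groups, phi) - 1e-6

    def test_all_zero_gene_degenerates_quietly(self):
        y = np.zeros(4)
        X = np.ones((4, 1))
        _, ll, mu = fit_nb_glm(y, X, np.zeros(4), 0.1)
        assert (mu < 1e-6).all()

    def test_offsets_shift_means(self):
        # doubling a sample's library doubles its fitted mean at fixed beta
        y = np.array([10.0, 20.0])
        X = np.ones((2, 1))
        off = np.log(np.array([1.0, 2.0]))
        beta, _, mu = fit_nb_glm(y, X, off, 0.0)
        assert mu[1] / mu[0] == pytest.approx(2.0, rel=1e-8)


class TestDispersionEstimation:
    def make_cm(self, Y, digits):
        genes = [f"g{i}" for i in range(Y.shape[0])]
        samples = [f"s{j}" for j in range(Y.shape[1])]
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "species": "m",
                "limb": "fore",
                "digit": digits,
                "stage": "st",
                "replicate": list(range(1, len(samples) + 1)),
            }
        ).set_index("sample_id")
        return CountMatrix(pd.DataFrame(Y, index=genes, columns=samples), meta)

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(4, 1, size=2000)
        Y = rng.poisson(mu[:, None], size=(2000, 6))
        cm = self.make_cm(Y, [1, 1, 1, 2, 2, 2])
        disp = estimate_dispersions(cm, design_from_metadata(cm.metadata, (1, 2)))
        assert disp.tagwise.mean() < 0.05

    def test_known_truth_recovered(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            mu = rng.lognormal(4.5, 1, size=1500)
            lam = rng.gamma(10.0, mu[:, None] / 10.0, size=(1500, 6))  # phi = 0.1
            Y = rng.poisson(lam)
            cm = self.make_cm(Y, [1, 1, 1, 2, 2, 2])
            disp = estimate_dispersions(cm, design_from_metadata(cm.metadata, (1, 2)))
            assert 0.05 <= disp.tagwise.mean() <= 0.2

    def test_constant_gene_at_lower_bound(self):
        rng = np.random.default_rng(1)
        Y = rng.poisson(50, size=(300, 6))
        Y[0] = 42  # identical counts in every sample
        cm = self.make_cm(Y, [1, 1, 1, 2, 2, 2])
        disp = estimate_dispersions(cm, design_from_metadata(cm.metadata, (1, 2)))
        assert disp.tagwise.iloc[0] == pytest.approx(PHI_FLOOR, rel=0.01)

    def test_all_zero_matrix_rejected(self):
        cm = self.make_cm(np.zeros((5, 4), dtype=int), [1, 1, 2, 2])
        with pytest.raises(ValidationError):
            estimate_dispersions(cm, design_from_metadata(cm.metadata, (1, 2)))


class TestLRT:
    def test_equal_groups_lr_zero(self):
        tab = pd.DataFrame(
            [[5, 8, 5, 8], [10, 3, 10, 3]],
            index=["gA", "gB"],
            columns=["a1", "a2", "b1", "b2"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": tab.columns,
                "species": "m",
                "limb": "fore",
                "digit": [1, 1, 2, 2],
                "stage": "s",
                "replicate": [1, 2, 1, 2],
            }
        ).set_index("sample_id")
        cm = CountMatrix(tab, meta)
        res = lrt_pairwise(cm, design_from_metadata(cm.metadata, (1, 2)), 0.1)
        assert res.table["lr"].max() == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.table["pvalue"], 1.0)

    def test_null_mean_lr_is_chisq_mean(self):
        """With phi fixed at truth, the LRT statistic has a chi-square(1)
        null mean of ~1 (pairwise) and chi-square(4) mean of ~4 (any-digit)."""
        lrs1, lrs4 = [], []
        for seed in range(3):
            res = simulate_counts(null_config(seed=300 + seed, n_genes=700, n_digits=5))
            cm = res.counts["mouse"]
            phi = res.truth.gene_truth["mouse"]["phi"].to_numpy()
            d_pair = design_from_metadata(cm.metadata, (1, 2))
            lrs1.append(lrt_pairwise(cm, d_pair, phi).table["lr"].mean())
            d_any = design_from_metadata(cm.metadata, "any-digit")
            lrs4.append(lrt_any_digit(cm, d_any, phi).table["lr"].mean())
        assert np.mean(lrs1) == pytest.approx(1.0, abs=0.15)
        assert np.mean(lrs4) == pytest.approx(4.0, abs=0.4)

    def test_planted_fold_change_detected_with_power(self):
        rng = np.random.default_rng(4)
        n = 2000
        mu_base = np.full(n, 100.0)
        # plant few genes so the library-size offset stays unconfounded
        planted = np.zeros(n, bool)
        planted[:40] = True
        mu2 = np.where(planted, mu_base * 4, mu_base)
        lam1 = rng.gamma(20.0, mu_base[:, None] / 20.0, (n, 3))
        lam2 = rng.gamma(20.0, mu2[:, None] / 20.0, (n, 3))
        Y = np.hstack([rng.poisson(lam1), rng.poisson(lam2)])  # phi = 0.05
        tab = pd.DataFrame(Y, index=[f"g{i}" for i in range(n)],
                           columns=[f"s{j}" for j in range(6)])
        meta = pd.DataFrame(
            {
                "sample_id": tab.columns,
                "species": "m", "limb": "fore",
                "digit": [1, 1, 1, 2, 2, 2], "stage": "s",
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        ).set_index("sample_id")
        cm = CountMatrix(tab, meta)
        res = lrt_pairwise(cm, design_from_metadata(cm.metadata, (1, 2)), 0.05)
        frac = (res.table["pvalue"][planted] < 1e-3).mean()
        assert frac >= 0.95
        # orientation: planted genes are up in digit 2
        assert res.table["log2fc"][planted].median() == pytest.approx(2.0, abs=0.3)
        # unplanted genes stay quiet
        assert (res.table["pvalue"][~planted] < 1e-3).mean() < 0.01

    def test_any_digit_needs_three_levels(self, tiny_counts):
        with pytest.raises(ValidationError):
            lrt_any_digit(
                tiny_counts, design_from_metadata(tiny_counts.metadata, "any-digit"), 0.1
            )

    def test_absent_contrast_level_rejected(self, tiny_counts):
        with pytest.raises(ValidationError, match="absent"):
            design_from_metadata(tiny_counts.metadata, (1, 4)).design_matrices()

    def test_all_zero_gene_reported_na_and_excluded_from_m(self):
        tab = pd.DataFrame(
            [[5, 8, 25, 28], [0, 0, 0, 0]],
            index=["gA", "gZero"],
            columns=["a1", "a2", "b1", "b2"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": tab.columns,
                "species": "m", "limb": "fore",
                "digit": [1, 1, 2, 2], "stage": "s", "replicate": [1, 2, 1, 2],
            }
        ).set_index("sample_id")
        cm = CountMatrix(tab, meta)
        res = lrt_pairwise(cm, design_from_metadata(cm.metadata, (1, 2)), 0.05)
        assert np.isnan(res.table.loc["gZero", "pvalue"])
        # with a single tested gene, BH-adjusted equals raw
        assert res.table.loc["gA", "padj_bh"] == pytest.approx(
            res.table.loc["gA", "pvalue"]
        )

    def test_noise_covariate_preserves_null_uniformity(self):
        res = simulate_counts(null_config(seed=77, n_genes=1500))
        cm = res.counts["mouse"]
        rng = np.random.default_rng(0)
        noise = pd.DataFrame(
            {"junk": rng.normal(size=cm.n_samples)}, index=cm.sample_ids
        )
        from digitexpr.diagnostics import pvalue_uniformity

        ks = {}
        for cov in (None, noise):
            design = design_from_metadata(cm.metadata, (1, 2), covariates=cov)
            disp = estimate_dispersions(cm, design)
            de = lrt_pairwise(cm, design, disp)
            ks[cov is None] = pvalue_uniformity(de.table["pvalue"].dropna()).ks_distance
        assert abs(ks[True] - ks[False]) < 0.02


class TestFDR:
    def test_bh_hand_examples(self):
        assert adjust_bh([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert (adjust_bh([1.0, 1.0, 1.0]) == 1.0).all()

    def test_bh_nan_propagates_and_m_excludes(self):
        out = adjust_bh([0.05, np.nan])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.05)  # m = 1

    @settings(max_examples=40, deadline=None)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50),
    )
    def test_bh_matches_statsmodels(self, p):
        ours = adjust_bh(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_storey_reduces_to_bh_when_pi0_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=800)
        q, pi0 = storey_q(p)
        assert pi0 > 0.8
        np.testing.assert_allclose(q, pi0 * adjust_bh(p), atol=1e-12)

    def test_pi0_recovered_in_mixture(self):
        rng = np.random.default_rng(5)
        m = 5000
        null_p = rng.uniform(size=int(0.8 * m))
        alt_p = rng.beta(0.1, 8.0, size=m - len(null_p))
        p = np.concatenate([null_p, alt_p])
        pi0 = storey_pi0(p)
        assert pi0 == pytest.approx(0.8, abs=0.05)

    def test_storey_calls_at_least_bh(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(size=400), rng.beta(0.1, 10, size=100)])
        q, pi0 = storey_q(p)
        assert pi0 < 1
        assert (q < 0.05).sum() >= (adjust_bh(p) < 0.05).sum()

    def test_small_m_falls_back_to_pi0_one(self, caplog):
        with caplog.at_level("WARNING"):
            pi0 = storey_pi0(np.linspace(0.01, 0.99, 50))
        assert pi0 == 1.0


class TestPC1Covariate:
    def test_sign_and_separation(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(3, 1, size=(100, 1))
        vals = base * np.ones((100, 6)) + rng.normal(0, 0.1, (100, 6))
        vals[:50, 3:] += 5.0  # non-biological split on half the genes
        df = pd.DataFrame(vals, columns=[f"s{j}" for j in range(6)])
        pc1 = pc1_covariate(df)
        assert len(set(np.sign(pc1[:3]))) == 1
        assert set(np.sign(pc1[:3])) != set(np.sign(pc1[3:]))
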