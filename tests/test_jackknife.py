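import numpy as np
import pytest

from metabopca import (
    FitOptions,
    align_loadings,
    cutoff_frequency,
    fit_ppca,
    generate_ppca,
    group_bin_tests,
    jackknife_model,
    jackknife_se,
    ppca_closed_form,
    preprocess,
    significant_loadings,
)
from metabopca.datasets import SpectralDataset
from metabopca.jackknife import JackknifeResult

from conftest import dataset_from


class TestJackknifeSE:
    def test_two_values_closed_form(self):
        # the formula reduces to |a - b| / 2 at n = 2
        assert jackknife_se([3.0, 8.0]) == pytest.approx(2.5)
        assert jackknife_se([-1.0, 1.0]) == pytest.approx(1.0)

    def test_equal_values_give_zero(self):
        assert jackknife_se([4.0] * 6) == 0.0

    def test_one_to_five_matches_direct_summation(self):
        # sqrt(4/5 * sum((v - 3)^2)) = sqrt(4/5 * 10) = sqrt(8)
        assert jackknife_se([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(np.sqrt(8.0))

    def test_brute_force_oracle_on_random_vectors(self, rng):
        v = rng.standard_normal(12)
        n = len(v)
        vbar = v.mean()
        expected = np.sqrt((n - 1) / n * np.sum((v - vbar) ** 2))
        assert jackknife_se(v) == pytest.approx(expected)

    def test_order_invariance(self, rng):
        v = rng.standard_normal(9)
        assert jackknife_se(v) == pytest.approx(jackknife_se(v[::-1]))

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            jackknife_se([1.0])


class TestJackknifeModel:
    def test_near_identical_samples_give_near_zero_se(self, rng):
        base = rng.standard_normal(8)
        X = np.tile(base, (12, 1)) + 1e-9 * rng.standard_normal((12, 8))
        X += np.outer(np.linspace(-1, 1, 12), rng.standard_normal(8))  # rank-1 signal
        data = preprocess(dataset_from(X))
        fit = fit_ppca(data, 1)
        jk = jackknife_model(data, 1, fit)
        assert jk.se.max() < 1e-6

    def test_matches_cold_started_brute_force(self):
        # oracle: refit each leave-one-out from the closed-form eigendecomposition
        data, _ = generate_ppca(30, 15, 2, sigma2=0.8, seed=17)
        dc = preprocess(data)
        opts = FitOptions(tol=1e-12, max_iter=10000)
        fit = fit_ppca(dc, 2, opts)
        jk = jackknife_model(dc, 2, fit, opts=opts)
        n = dc.n
        stack = np.empty((n, dc.p, 2))
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            cold = ppca_closed_form(dc.subset(mask), 2)
            stack[i] = align_loadings(cold.W, fit.model.W, sign_only=True)
        expected_se = jackknife_se(stack, axis=0)
        assert np.abs(jk.se - expected_se).max() < 1e-5

    def test_se_shrinks_with_sample_size(self):
        # averaged over replicates, quadrupling n should roughly halve the SEs
        ses = {}
        for n in (15, 60):
            vals = []
            for s in range(5):
                data, _ = generate_ppca(n, 10, 2, sigma2=1.0, eigengap=8.0, seed=40 + s)
                dc = preprocess(data)
                fit = fit_ppca(dc, 2)
                vals.append(jackknife_model(dc, 2, fit).se.mean())
            ses[n] = np.mean(vals)
        ratio = ses[15] / ses[60]
        assert 2.0 * 0.7 < ratio < 2.0 * 1.3  # ~1/sqrt(n) scaling

    def test_jackknife_needs_converged_fit(self):
        data, _ = generate_ppca(20, 8, 2, seed=1)
        dc = preprocess(data)
        fit = fit_ppca(dc, 2, FitOptions(init="random", seed=0, max_iter=1))
        with pytest.raises(ValueError, match="non-converged"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                jackknife_model(dc, 2, fit)


def _fake_jk(estimates, ci_low, ci_high, labels):
    est = np.asarray(estimates, dtype=float)
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    return JackknifeResult(
        estimate=est,
        se=(hi - lo) / (2 * 1.96),
        ci_low=lo,
        ci_high=hi,
        significant=(lo > 0) | (hi < 0),
        bin_labels=labels,
        level=0.95,
        n_refits=10,
    )


class TestSignificantLoadings:
    def setup_method(self):
        self.jk = _fake_jk(
            estimates=[[1.2], [-0.9], [0.5], [0.05], [-2.0]],
            ci_low=[[0.8], [-1.3], [-0.1], [-0.2], [-2.5]],
            ci_high=[[1.6], [-0.5], [1.1], [0.3], [-1.5]],
            labels=["a", "b", "c", "d", "e"],
        )

    def test_membership_matches_hand_enumeration(self):
        # significant: a, b, e (CIs exclude 0); c, d do not
        sel = significant_loadings(self.jk, pc=1, cutoff=0.0)
        assert [s[0] for s in sel] == ["e", "a", "b"]  # sorted by |loading|

    def test_cutoff_filters_by_magnitude(self):
        sel = significant_loadings(self.jk, pc=1, cutoff=1.0)
        assert [s[0] for s in sel] == ["e", "a"]

    def test_infinite_cutoff_empty(self):
        assert significant_loadings(self.jk, pc=1, cutoff=np.inf) == []

    def test_monotone_nesting_in_cutoff(self):
        for c1, c2 in [(0.0, 0.5), (0.5, 1.0), (0.0, 2.0)]:
            s1 = {s[0] for s in significant_loadings(self.jk, pc=1, cutoff=c1)}
            s2 = {s[0] for s in significant_loadings(self.jk, pc=1, cutoff=c2)}
            assert s2 <= s1

    def test_pc_out_of_range(self):
        with pytest.raises(ValueError):
            significant_loadings(self.jk, pc=2)


class TestCutoffFrequency:
    def test_all_equal_loadings_occupy_single_bin(self):
        table = cutoff_frequency(np.full(10, 0.7), np.ones(10, dtype=bool), n_bins=5)
        assert (table["count"] > 0).sum() == 1

    def test_bimodal_loadings_drop_steeply_between_modes(self, rng):
        low = 0.2 + 0.02 * rng.standard_normal(60)
        high = 0.9 + 0.02 * rng.standard_normal(20)
        est = np.concatenate([low, high])
        table = cutoff_frequency(est, np.ones(80, dtype=bool), n_bins=20)
        retained = table["retained"].to_numpy()
        thr = table["threshold"].to_numpy()
        mid = (thr > 0.4) & (thr < 0.8)
        assert retained[mid].std() < 1.0  # flat plateau between the modes
        assert retained[0] >= 79 and retained[mid][0] == 20  # '>' drops the minimum itself

    def test_uniform_loadings_retention_curve(self, rng):
        p = 189
        est = rng.uniform(0, 1, size=p)
        table = cutoff_frequency(est, np.ones(p, dtype=bool), n_bins=10)
        retained = table["retained"].to_numpy()
        thr = table["threshold"].to_numpy()
        assert np.all(np.diff(retained) <= 0)
        np.testing.assert_allclose(retained, p * (1 - thr), atol=3 * np.sqrt(p))

    def test_no_significant_bins_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no significant"):
            table = cutoff_frequency(np.ones(5), np.zeros(5, dtype=bool))
        assert table.empty


class TestGroupBinTests:
    def test_identical_groups_give_t_zero_p_one(self, rng):
        half = rng.standard_normal((6, 4))
        X = np.vstack([half, half])  # same values copied into both groups
        data = dataset_from(X)
        groups = np.repeat([0, 1], 6)
        table = group_bin_tests(data, groups)
        np.testing.assert_allclose(table["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p"], 1.0, atol=1e-12)

    def test_large_shift_detected(self, rng):
        X = rng.standard_normal((18, 5))
        groups = np.repeat([0, 1], 9)
        X[groups == 1, 2] += 10.0  # ten pooled-sd units on one bin
        table = group_bin_tests(dataset_from(X), groups)
        row = table[table["bin_label"] == "b2"].iloc[0]
        assert row["p_adjusted"] < 1e-3
        assert row["direction"] == 1

    def test_single_bin_bh_is_identity(self, rng):
        X = rng.standard_normal((10, 4))
        groups = np.repeat([0, 1], 5)
        table = group_bin_tests(dataset_from(X), groups, bins=["b1"])
        assert len(table) == 1
        assert table["p_adjusted"].iloc[0] == pytest.approx(table["p"].iloc[0])

    def test_small_group_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="at least 2"):
            group_bin_tests(dataset_from(X), np.array([0, 0, 0, 0, 1]))
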