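"""Marker QC, kinships, GBLUP fitting and the two validation schemes."""

import numpy as np
import pandas as pd
import pytest

from diallelkit import DiallelDesign, simdata
from diallelkit.gp import (KinshipMatrix, cv_kfold, filter_markers, fit_gblup,
                           hybrid_H, impute_allele_freq, loo_gca_prediction,
                           vanraden_G)
from diallelkit.simdata import GenotypeMatrix

from conftest import cross_series


def _panel(calls, parents=None):
    calls = np.asarray(calls, dtype=float)
    parents = parents or [f"P{i}" for i in range(calls.shape[0])]
    markers = [f"M{i}" for i in range(calls.shape[1])]
    return GenotypeMatrix(parents=parents, markers=markers, calls=calls)


class TestFilterMarkers:
    def test_missingness_threshold_strict(self):
        nan = np.nan
        calls = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [nan, nan, 0],
                          [0, nan, 1]])  # col0: 20% miss, col1: 40%, col2: 0%
        filt, ledger = filter_markers(_panel(calls), max_missing=0.2,
                                      maf_min=0.0)
        assert ledger["after_missing_filter"] == 2
        assert "M1" not in filt.markers and "M0" in filt.markers

    def test_maf_exactly_at_threshold_retained(self):
        # 10 parents, one het: frequency 0.05 exactly
        col = np.zeros((10, 1))
        col[0, 0] = 1.0
        filt, _ = filter_markers(_panel(col), maf_min=0.05)
        assert filt.n_markers == 1
        below = np.zeros((20, 1))
        below[0, 0] = 1.0  # MAF 0.025 < 0.05
        with pytest.raises(ValueError):
            filter_markers(_panel(below), maf_min=0.05)

    def test_ledger_matches_brute_force_census(self):
        rng = np.random.default_rng(17)
        geno = simdata.simulate_founders(20, 3000, maf_range=(0.01, 0.5),
                                         missing_rate=0.1, seed=23)
        filt, ledger = filter_markers(geno, max_missing=0.15, maf_min=0.05)
        # brute-force census, marker by marker
        survivors = []
        n_after_miss = n_after_mono = 0
        for j, m in enumerate(geno.markers):
            col = geno.calls[:, j]
            if np.isnan(col).mean() > 0.15:
                continue
            n_after_miss += 1
            obs = col[~np.isnan(col)]
            f = obs.mean() / 2.0
            if f == 0.0 or f == 1.0:
                continue
            n_after_mono += 1
            if min(f, 1 - f) < 0.05:
                continue
            survivors.append(m)
        assert ledger["after_missing_filter"] == n_after_miss
        assert ledger["after_monomorphic_filter"] == n_after_mono
        assert ledger["after_maf_filter"] == len(survivors)
        assert filt.markers == survivors


class TestImpute:
    def test_no_missing_is_identity(self, small_geno):
        filt, _ = filter_markers(small_geno)
        done = impute_allele_freq(filt)
        done2 = impute_allele_freq(done)
        np.testing.assert_array_equal(done.calls, done2.calls)

    def test_mean_dosage_imputation(self):
        calls = np.array([[0.0], [2.0], [np.nan]])
        out = impute_allele_freq(_panel(calls))
        assert out.calls[2, 0] == pytest.approx(1.0)
        assert out.calls[0, 0] == 0.0 and out.calls[1, 0] == 2.0

    def test_mean_preserved(self, small_geno):
        before = np.nanmean(small_geno.calls, axis=0)
        after = impute_allele_freq(small_geno).calls.mean(axis=0)
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_all_missing_marker_rejected(self):
        calls = np.array([[np.nan], [np.nan]])
        with pytest.raises(ValueError):
            impute_allele_freq(_panel(calls))


class TestVanRaden:
    def test_hand_computed_three_by_two(self):
        # dosages ((0,2),(2,0),(1,1)): p = (0.5, 0.5), denom = 1,
        # W = ((-1,1),(1,-1),(0,0)), G = WW'
        g = _panel([[0, 2], [2, 0], [1, 1]])
        G = vanraden_G(g)
        expect = np.array([[2.0, -2.0, 0.0], [-2.0, 2.0, 0.0],
                           [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(G.values, expect, atol=1e-12)

    def test_identical_rows_share_relationship(self):
        rng = np.random.default_rng(2)
        row = rng.integers(0, 3, 50).astype(float)
        other = rng.integers(0, 3, (3, 50)).astype(float)
        G = vanraden_G(_panel(np.vstack([row, row, other])))
        assert G.values[0, 1] == pytest.approx(G.values[0, 0])
        assert G.values[0, 1] == pytest.approx(G.values[1, 1])

    def test_average_diagonal_near_one_under_hwe(self):
        geno = simdata.simulate_founders(30, 10_000, missing_rate=0.0, seed=3)
        G = vanraden_G(geno)
        assert G.values.diagonal().mean() == pytest.approx(1.0, rel=0.05)
        assert G.is_psd()

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError):
            vanraden_G(_panel(np.zeros((4, 5))))


class TestHybridH:
    def test_identity_G_closed_form(self):
        parents = ["A", "B", "C", "D"]
        G = KinshipMatrix(parents, np.eye(4))
        crosses = [("A", "B"), ("C", "D"), ("A", "C")]
        H = hybrid_H(G, crosses)
        # diagonal (G_ii G_jj + G_ij^2)/2 = 0.5; disjoint crosses 0
        np.testing.assert_allclose(H.values.diagonal(), 0.5)
        assert H.values[0, 1] == pytest.approx(0.0)
        # shared parent A between (A,B) and (A,C): (1*0 + 0*0)/2 = 0
        assert H.values[0, 2] == pytest.approx(0.0)

    def test_monte_carlo_covariance_oracle(self):
        rng = np.random.default_rng(8)
        M = rng.standard_normal((4, 30))
        G = KinshipMatrix(["A", "B", "C", "D"], M @ M.T / 30)
        design = DiallelDesign(("A", "B", "C", "D"))
        H = hybrid_H(G, design.crosses)
        L = np.linalg.cholesky(G.values + 1e-10 * np.eye(4))
        n = 200_000
        x = (L @ rng.standard_normal((4, n)))
        y = (L @ rng.standard_normal((4, n)))
        idx = {p: i for i, p in enumerate(design.parents)}
        h = np.stack([(x[idx[a]] * y[idx[b]] + x[idx[b]] * y[idx[a]]) / 2.0
                      for a, b in design.crosses])
        emp = np.cov(h)
        np.testing.assert_allclose(emp, H.values, atol=0.02)

    def test_ungenotyped_parent_dropped_with_warning(self):
        G = KinshipMatrix(["A", "B", "C"], np.eye(3))
        with pytest.warns(UserWarning, match="ungenotyped"):
            H = hybrid_H(G, [("A", "B"), ("A", "Z")])
        assert H.labels == [("A", "B")]

    def test_psd_on_random_panels(self):
        for seed in range(20):
            geno = simdata.simulate_founders(10, 300, missing_rate=0.05,
                                             seed=seed)
            filt, _ = filter_markers(geno, maf_min=0.0)
            G = vanraden_G(impute_allele_freq(filt))
            design = DiallelDesign(tuple(geno.parents))
            H = hybrid_H(G, design.crosses)
            assert G.is_psd() and H.is_psd()


class TestFitGBLUP:
    @staticmethod
    def _setup(seed=5, var_sca=0.3, var_error=0.25, n_parents=15):
        geno = simdata.simulate_founders(n_parents, 600, missing_rate=0.0,
                                         seed=seed)
        design = DiallelDesign(tuple(geno.parents))
        G = vanraden_G(geno)
        truth = simdata.simulate_diallel_truth(geno, 0.5, var_sca,
                                               use_markers=True,
                                               seed=seed + 1)
        rng = np.random.default_rng(seed + 2)
        y = np.array([truth.hybrid_value(c) for c in design.crosses])
        y = y + rng.normal(0, np.sqrt(var_error), len(y))
        return design, G, cross_series(y, design), truth

    def test_constant_response_gives_zero_genetic_variance(self):
        design, G, y, _ = self._setup()
        m = fit_gblup(y * 0.0 + 3.0, design.crosses, G)
        assert m.var_g <= 1e-6 and m.var_h <= 1e-6

    def test_fixed_variances_match_gls_oracle(self):
        design, G, y, _ = self._setup()
        var_e, var_g, var_h = 0.3, 0.5, 0.2
        m = fit_gblup(y, design.crosses, G,
                      fix_vars=(var_e, var_g, var_h))
        # dense GLS/BLUP oracle from the full covariance matrix
        n = len(y)
        pidx = design.parent_index()
        Z = np.zeros((n, design.n_parents))
        for r, (a, b) in enumerate(design.crosses):
            Z[r, pidx[a]] += 1
            Z[r, pidx[b]] += 1
        H = hybrid_H(G, design.crosses).values
        V = var_e * np.eye(n) + var_g * Z @ G.values @ Z.T + var_h * H
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y.to_numpy())
        resid = y.to_numpy() - X @ beta
        g = var_g * G.values @ Z.T @ Vi @ resid
        h = var_h * H @ Vi @ resid
        assert m.mu == pytest.approx(float(beta[0]), abs=1e-8)
        np.testing.assert_allclose(m.gca.to_numpy(), g, atol=1e-8)
        np.testing.assert_allclose(m.sca.to_numpy(), h, atol=1e-8)

    def test_reml_recovers_gca_variance(self):
        # marker-determined GCA, high heritability, 105 hybrids
        hits = []
        for rep in range(100):
            design, G, y, truth = self._setup(seed=100 + 3 * rep,
                                              var_sca=0.0, var_error=0.25)
            m = fit_gblup(y, design.crosses, G)
            hits.append(m.var_g)
        assert abs(np.mean(hits) - 0.5) < 0.3 * 0.5

    def test_gibbs_and_reml_agree_when_well_conditioned(self):
        design, G, y, _ = self._setup(seed=41, var_sca=0.3, var_error=0.25)
        reml = fit_gblup(y, design.crosses, G, method="reml")
        gibbs = fit_gblup(y, design.crosses, G, method="gibbs", seed=7)
        assert gibbs.var_g == pytest.approx(reml.var_g, rel=0.15)
        # with one observation per hybrid the saturated SCA term and the
        # residual are only identified through H's off-diagonals; compare the
        # identified per-hybrid non-GCA variance var_e + var_h * mean(diag H)
        d = float(np.diagonal(hybrid_H(G, design.crosses).values).mean())
        tot_reml = reml.var_e + reml.var_h * d
        tot_gibbs = gibbs.var_e + gibbs.var_h * d
        assert tot_gibbs == pytest.approx(tot_reml, rel=0.15)

    def test_input_validation(self):
        design, G, y, _ = self._setup()
        with pytest.raises(ValueError, match="at least 10"):
            fit_gblup(y.iloc[:5], list(design.crosses)[:5], G)
        bad = KinshipMatrix(list(G.labels),
                            G.values - 0.5 * np.eye(len(G.labels)))
        with pytest.raises(ValueError, match="positive semi-definite"):
            fit_gblup(y, design.crosses, bad)


class TestLooGCA:
    def test_noiseless_additive_means_give_r_one(self, design8, rng):
        g = rng.normal(0, 1, 8)
        g -= g.mean()
        y = np.array([g[i] + g[j] + 5.0
                      for i in range(8) for j in range(i + 1, 8)])
        res = loo_gca_prediction(cross_series(y, design8), design8)
        assert res.correlations["value"] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(res.predictions["value"], y, atol=1e-8)

    def test_hand_recomputed_leave_one_out(self, design5, rng):
        y = rng.normal(0, 1, design5.n_crosses)
        res = loo_gca_prediction(cross_series(y, design5), design5)
        # oracle: ordinary lstsq on the reduced table with explicit centering
        crosses = list(design5.crosses)
        pidx = design5.parent_index()
        for k in (0, 3, 7):
            keep = [i for i in range(len(crosses)) if i != k]
            A = np.zeros((len(keep), 1 + 5))
            for r, i in enumerate(keep):
                a, b = crosses[i]
                A[r, 0] = 1.0
                A[r, 1 + pidx[a]] = A[r, 1 + pidx[b]] = 1.0
            # append the constraint row with a huge weight
            w = 1e8
            A_aug = np.vstack([A, w * np.r_[0.0, np.ones(5)]])
            y_aug = np.r_[y[keep], 0.0]
            sol = np.linalg.lstsq(A_aug, y_aug, rcond=None)[0]
            a, b = crosses[k]
            expect = sol[0] + sol[1 + pidx[a]] + sol[1 + pidx[b]]
            assert res.predictions["value"].iloc[k] == pytest.approx(
                expect, abs=1e-5)

    def test_permuted_phenotypes_within_null_band(self, design15, rng):
        g = rng.normal(0, 1, 15)
        y = np.array([g[i] + g[j] for i in range(15)
                      for j in range(i + 1, 15)])
        null_rs = []
        for _ in range(60):
            perm = rng.permutation(y)
            res = loo_gca_prediction(cross_series(perm, design15), design15)
            null_rs.append(abs(res.correlations["value"]))
        bound = np.quantile(null_rs, 0.95)
        res = loo_gca_prediction(
            cross_series(rng.permutation(y), design15), design15)
        assert abs(res.correlations["value"]) < max(bound, 0.35) + 0.15

    def test_needs_five_parents(self):
        d = DiallelDesign.from_n_parents(4)
        y = cross_series(np.arange(6, dtype=float), d)
        with pytest.raises(ValueError, match="5 parents"):
            loo_gca_prediction(y, d)


class TestCVKfold:
    @staticmethod
    def _setup(h2, seed=42, n_parents=10):
        geno = simdata.simulate_founders(n_parents, 500, missing_rate=0.0,
                                         seed=seed)
        design = DiallelDesign(tuple(geno.parents))
        G = vanraden_G(geno)
        truth = simdata.simulate_diallel_truth(geno, 0.5, 0.0,
                                               use_markers=True, seed=seed)
        gvals = np.array([truth.hybrid_value(c) for c in design.crosses])
        rng = np.random.default_rng(seed + 1)
        if h2 == 0:
            y = rng.normal(0, 1, len(gvals))
        else:
            ve = gvals.var(ddof=1) * (1 - h2) / h2
            y = gvals + rng.normal(0, np.sqrt(ve), len(gvals))
        return design, G, cross_series(y, design)

    def test_seed_reproducibility_and_sensitivity(self):
        design, G, y = self._setup(0.6)
        a = cv_kfold(y, design.crosses, G, k=5, seed=3)
        b = cv_kfold(y, design.crosses, G, k=5, seed=3)
        c = cv_kfold(y, design.crosses, G, k=5, seed=4)
        assert a.correlations == b.correlations
        pd.testing.assert_series_equal(a.folds, b.folds)
        assert not a.folds.equals(c.folds)

    def test_fold_sizes_differ_by_at_most_one(self):
        design, G, y = self._setup(0.6)
        res = cv_kfold(y, design.crosses, G, k=7, seed=1)
        sizes = res.folds.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_zero_heritability_r_within_null_band(self):
        design, G, y = self._setup(0.0, seed=9)
        res = cv_kfold(y, design.crosses, G, k=5, seed=2)
        # null band ~ 2/sqrt(n) for n = 45 hybrids, plus shrinkage slack
        assert abs(res.correlations["value"]) < 0.45

    def test_k_equal_to_n_hybrids_is_leave_one_out(self):
        design, G, y = self._setup(0.9, seed=15)
        res = cv_kfold(y, design.crosses, G, k=len(y), seed=5)
        assert (res.folds.value_counts() == 1).all()
        assert res.predictions["value"].notna().all()

    def test_k_validation(self):
        design, G, y = self._setup(0.6)
        with pytest.raises(ValueError):
            cv_kfold(y, design.crosses, G, k=1)
        with pytest.raises(ValueError):
            cv_kfold(y, design.crosses, G, k=len(y) + 1)
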