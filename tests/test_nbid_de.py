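import math

import numpy as np
import pytest

import nbid
from nbid.nbid_de import DesignInfo, fit_full, fit_null, nbid_gene_test

from conftest import nb_counts


def _two_group_design(rng, n_per_group, depth=1000.0, depth_sd=0.3):
    groups = np.r_[np.zeros(n_per_group, int), np.ones(n_per_group, int)]
    depths = depth * rng.lognormal(0, depth_sd, 2 * n_per_group)
    return groups, depths


def _simulate_gene(rng, groups, depths, prop, beta1, phi0, phi1):
    mu = depths * prop * np.exp(beta1 * groups)
    phi = np.where(groups == 1, phi1, phi0)
    return rng.poisson(rng.gamma(1 / phi, mu * phi))


class TestFitFull:
    def test_effect_recovery(self, rng):
        groups, depths = _two_group_design(rng, 500)
        est = []
        for _ in range(40):
            y = _simulate_gene(rng, groups, depths, 0.005, math.log(2), 0.5, 0.5)
            est.append(fit_full(y, DesignInfo(groups, np.log(depths))).beta1)
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - math.log(2)) < 3 * se

    def test_independent_dispersion_recovery(self, rng):
        groups, depths = _two_group_design(rng, 1000)
        p0, p1 = [], []
        for _ in range(30):
            y = _simulate_gene(rng, groups, depths, 0.01, 0.0, 0.2, 1.0)
            fit = fit_full(y, DesignInfo(groups, np.log(depths)))
            p0.append(fit.phi0)
            p1.append(fit.phi1)
        assert np.mean(p0) == pytest.approx(0.2, rel=0.2)
        assert np.mean(p1) == pytest.approx(1.0, rel=0.2)

    def test_group_relabeling_symmetry(self, rng):
        groups, depths = _two_group_design(rng, 200)
        y = _simulate_gene(rng, groups, depths, 0.01, 0.5, 0.3, 0.8)
        d1 = DesignInfo(groups, np.log(depths))
        d2 = DesignInfo(1 - groups, np.log(depths))
        f1, f2 = fit_full(y, d1), fit_full(y, d2)
        assert f2.beta1 == pytest.approx(-f1.beta1, abs=1e-5)
        assert f2.phi0 == pytest.approx(f1.phi1, rel=1e-3, abs=1e-8)
        assert f2.phi1 == pytest.approx(f1.phi0, rel=1e-3, abs=1e-8)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)

    def test_one_group_all_zero_flagged_separation(self, rng):
        groups, depths = _two_group_design(rng, 50)
        y = _simulate_gene(rng, groups, depths, 0.01, 0.0, 0.3, 0.3)
        y[groups == 1] = 0
        res = nbid_gene_test(y, DesignInfo(groups, np.log(depths)))
        assert res["flag"] == "separation"
        assert np.isfinite(res["p"])
        assert res["p"] < 0.01


class TestFitNull:
    def test_matches_one_parameter_grid(self, rng):
        """Null intercept vs an independent 1-d likelihood grid oracle."""
        from scipy.stats import nbinom

        groups, depths = _two_group_design(rng, 100)
        y = _simulate_gene(rng, groups, depths, 0.005, 0.0, 0.5, 0.5)
        design = DesignInfo(groups, np.log(depths))
        null = fit_null(y, design, 0.5, 0.5)
        theta = 2.0
        b_grid = null.beta0 + np.linspace(-0.05, 0.05, 2001)
        lls = np.array(
            [
                nbinom.logpmf(y, theta, theta / (theta + depths * np.exp(b))).sum()
                for b in b_grid
            ]
        )
        assert null.loglik >= lls.max() - 1e-4
        assert abs(null.loglik - lls.max()) < 1e-4

    def test_nesting_and_offset_invariance(self, rng):
        groups, depths = _two_group_design(rng, 150)
        y = _simulate_gene(rng, groups, depths, 0.01, 0.4, 0.3, 0.6)
        design = DesignInfo(groups, np.log(depths))
        full = fit_full(y, design)
        null = fit_null(y, design, full.phi0, full.phi1)
        assert null.loglik <= full.loglik + 1e-8
        shifted = DesignInfo(groups, np.log(depths) + 2.0)
        null2 = fit_null(y, shifted, full.phi0, full.phi1)
        assert null2.beta0 == pytest.approx(null.beta0 - 2.0, abs=1e-6)
        assert null2.loglik == pytest.approx(null.loglik, abs=1e-8)


class TestGeneTest:
    def test_permutation_within_groups_invariant(self, rng):
        groups, depths = _two_group_design(rng, 80, depth_sd=0.0)
        y = _simulate_gene(rng, groups, depths, 0.01, 0.3, 0.4, 0.4)
        design = DesignInfo(groups, np.log(depths))
        r1 = nbid_gene_test(y, design)
        perm = np.concatenate(
            [rng.permutation(np.flatnonzero(groups == g)) for g in (0, 1)]
        )
        r2 = nbid_gene_test(y[perm], DesignInfo(groups[perm], np.log(depths[perm])))
        assert r2["p"] == pytest.approx(r1["p"], rel=1e-6)

    def test_strong_effect_detected(self, rng):
        groups, depths = _two_group_design(rng, 500)
        y = _simulate_gene(rng, groups, depths, 0.005, math.log(4), 0.5, 0.5)
        res = nbid_gene_test(y, DesignInfo(groups, np.log(depths)))
        assert res["p"] < 1e-10

    def test_unequal_dispersion_null_calibrated(self, rng):
        # the unequal-variance analogy: phi0 = 0.2 vs phi1 = 2.0, no effect
        groups, depths = _two_group_design(rng, 500)
        design = DesignInfo(groups, np.log(depths))
        ps = []
        for _ in range(400):
            y = _simulate_gene(rng, groups, depths, 0.005, 0.0, 0.2, 2.0)
            ps.append(nbid_gene_test(y, design)["p"])
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_equal_dispersion_matches_statsmodels_oracle(self, rng):
        """Cross-check against an equal-dispersion NB GLM LRT built from
        statsmodels (full model: discrete NB MLE; null: GLM with the
        full-model dispersion fixed)."""
        sm = pytest.importorskip("statsmodels.api")
        groups, depths = _two_group_design(rng, 150)
        X = np.column_stack([np.ones_like(depths), groups.astype(float)])
        n_checked = 0
        for _ in range(50):
            y = _simulate_gene(
                rng, groups, depths, 10 ** rng.uniform(-3, -2), rng.normal(0, 0.5),
                0.4, 0.4,
            )
            if (y > 0).sum() < 5:
                continue
            res = nbid_gene_test(
                y, DesignInfo(groups, np.log(depths)), equal_dispersions=True
            )
            try:
                m_full = sm.NegativeBinomial(y, X, offset=np.log(depths)).fit(disp=0)
            except Exception:
                continue
            if not m_full.mle_retvals.get("converged", True):
                continue
            m_null = sm.GLM(
                y,
                np.ones((len(y), 1)),
                family=sm.families.NegativeBinomial(alpha=max(m_full.params[-1], 1e-8)),
                offset=np.log(depths),
            ).fit()
            lrt_sm = 2 * (m_full.llf - m_null.llf)
            assert res["lrt_stat"] == pytest.approx(lrt_sm, abs=0.02)
            n_checked += 1
        assert n_checked >= 30


class TestRunNbid:
    def _matrix(self, rng, n_genes=40, n_cells=200):
        mat, _ = nbid.generate_nb_matrix(
            n_genes=n_genes, n_cells=n_cells, seed=int(rng.integers(2**31))
        )
        return mat

    def test_size_factor_scale_invariance(self, rng):
        mat = self._matrix(rng)
        groups = rng.integers(0, 2, mat.n_cells)
        sf = nbid.cell_totals(mat).totals.astype(float)
        t1 = nbid.run_nbid(mat, groups, size_factors=sf)
        t2 = nbid.run_nbid(mat, groups, size_factors=sf * 10)
        # invariance is exact analytically; numerically to optimizer tolerance
        np.testing.assert_allclose(t1["p"], t2["p"], atol=1e-5)

    def test_zero_total_cells_dropped_with_warning(self, rng):
        mat = self._matrix(rng, n_genes=30, n_cells=60)
        counts = mat.counts.copy()
        counts[:, 0] = 0
        mat2 = nbid.CountMatrix(counts, mat.gene_ids, mat.cell_ids)
        groups = np.r_[np.zeros(30, int), np.ones(30, int)]
        with pytest.warns(UserWarning):
            nbid.run_nbid(mat2, groups)

    def test_lowly_detected_genes_not_tested(self, rng):
        mat = self._matrix(rng, n_genes=30, n_cells=60)
        counts = mat.counts.copy()
        counts[0] = 0
        counts[0, 0] = 3  # one nonzero cell only
        mat2 = nbid.CountMatrix(counts, mat.gene_ids, mat.cell_ids)
        groups = np.r_[np.zeros(30, int), np.ones(30, int)]
        table = nbid.run_nbid(mat2, groups)
        assert mat.gene_ids[0] not in set(table["gene_id"])

    def test_requires_two_groups(self, rng):
        mat = self._matrix(rng, n_genes=10, n_cells=20)
        with pytest.raises(ValueError):
            nbid.run_nbid(mat, np.zeros(20, int))
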