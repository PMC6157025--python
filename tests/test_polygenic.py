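"""Variance-component heritability: likelihood oracle, recovery, LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import kinherit as kh
from kinherit.kinship import KinshipMatrix
from kinherit.polygenic import (UnidentifiableKinshipError, _profile_loglik,
                                KinshipEigen)

from conftest import make_pedigree


def _dense_loglik(h2, y, k_values):
    """Direct dense-matrix oracle: ML profile log-likelihood at h²."""
    n = len(y)
    sigma = h2 * k_values + (1 - h2) * np.eye(n)
    x = np.ones((n, 1))
    si = np.linalg.inv(sigma)
    beta = np.linalg.solve(x.T @ si @ x, x.T @ si @ y)
    r = y - x @ beta
    s2 = float(r.T @ si @ r) / n
    sign, logdet = np.linalg.slogdet(sigma)
    return -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)


class TestLikelihoodOracle:
    def test_eigen_path_matches_dense_inversion(self):
        """Rotated profile likelihood equals the brute-force dense form."""
        rows = []
        for f in range(1, 6):
            fam = str(f)
            rows += [(fam, f"{fam}a", None, None, "M"),
                     (fam, f"{fam}b", None, None, "F"),
                     (fam, f"{fam}c", f"{fam}a", f"{fam}b", "M"),
                     (fam, f"{fam}d", f"{fam}a", f"{fam}b", "F")]
        ped = make_pedigree(rows)
        k = kh.pedigree_kinship(ped)
        rng = np.random.default_rng(43)
        y = rng.standard_normal(ped.n)
        eig = KinshipEigen.from_kinship(k)
        yt = eig.rotate(y)
        xt = eig.rotate(np.ones((ped.n, 1)))
        for h2 in (0.0, 0.2, 0.5, 0.8, 0.99):
            fast = _profile_loglik(h2, eig.eigenvalues, yt, xt)[0]
            dense = _dense_loglik(h2, y, k.values)
            assert fast == pytest.approx(dense, abs=1e-6)

    def test_fitted_h2_matches_dense_grid(self, small_study, small_kinship):
        _, ped, _, pheno = small_study
        y = kh.inverse_normal(
            kh.residualize(kh.average_visits(pheno, "trait", "pre"), pheno))
        fit = kh.fit_polygenic(y, small_kinship)
        grid = np.linspace(0, 1, 401)
        yv = y.values
        dense = [_dense_loglik(h, yv, small_kinship.values) for h in grid]
        h2_grid = grid[int(np.argmax(dense))]
        assert fit.h2 == pytest.approx(h2_grid, abs=0.005)
        assert fit.loglik_full >= max(dense) - 1e-6


class TestFitProperties:
    def test_component_ratio_identity(self, small_study, small_kinship):
        _, _, _, pheno = small_study
        y = kh.inverse_normal(
            kh.residualize(kh.average_visits(pheno, "trait", "pre"), pheno))
        fit = kh.fit_polygenic(y, small_kinship)
        # template pedigree is non-inbred: mean diag is exactly 1
        assert fit.h2 == pytest.approx(
            fit.sigma2_g / (fit.sigma2_g + fit.sigma2_e), abs=1e-10)
        assert fit.loglik_full >= fit.loglik_null - 1e-6

    def test_scale_invariance_phi_vs_two_phi(self, small_study,
                                             small_kinship):
        """Doubling K leaves ĥ², Λ, p unchanged; σ̂²g halves."""
        _, _, _, pheno = small_study
        y = kh.inverse_normal(
            kh.residualize(kh.average_visits(pheno, "trait", "pre"), pheno))
        f1 = kh.fit_polygenic(y, small_kinship)
        doubled = KinshipMatrix(small_kinship.sample_ids,
                                2.0 * small_kinship.values)
        f2 = kh.fit_polygenic(y, doubled)
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-6)
        assert f2.lrt_statistic == pytest.approx(f1.lrt_statistic, abs=1e-6)
        assert f2.p_value == pytest.approx(f1.p_value, rel=1e-6)
        assert f2.sigma2_g == pytest.approx(f1.sigma2_g / 2, rel=1e-4)

    def test_identity_kinship_unidentifiable(self):
        k = KinshipMatrix([str(i) for i in range(50)], np.eye(50))
        rng = np.random.default_rng(0)
        with pytest.raises(UnidentifiableKinshipError):
            kh.fit_polygenic(rng.standard_normal(50), k)

    def test_pure_breeding_value_hits_upper_boundary(self, small_study,
                                                     small_kinship):
        _, ped, _, _ = small_study
        rng = np.random.default_rng(44)
        vals, vecs = np.linalg.eigh(small_kinship.values)
        g = vecs @ (np.sqrt(np.clip(vals, 0, None))
                    * rng.standard_normal(ped.n))
        fit = kh.fit_polygenic(pd.Series(g, index=small_kinship.sample_ids),
                               small_kinship)
        assert fit.h2 >= 0.95
        if fit.boundary:
            assert np.isnan(fit.h2_se)

    def test_indefinite_postprocessed_matrix_tolerated(self):
        # unit-diagonal, non-negative, but indefinite — the shape zeroing
        # negatives can produce; the likelihood must still evaluate
        block = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        n_blocks = 30
        v = np.kron(np.eye(n_blocks), block)
        k = KinshipMatrix([f"s{i}" for i in range(3 * n_blocks)], v,
                          source="empirical", postprocessed=True)
        assert k.min_eigenvalue() < -1e-3
        rng = np.random.default_rng(46)
        fit = kh.fit_polygenic(
            pd.Series(rng.standard_normal(k.n), index=k.sample_ids), k)
        assert np.isfinite(fit.loglik_full)
        assert fit.n_eigen_clipped > 0

    def test_null_trait_estimates_near_zero(self, small_study,
                                            small_kinship):
        _, ped, _, _ = small_study
        cfg = kh.SimulationConfig(n_families=10, true_h2=0.0, seed=45)
        eig = KinshipEigen.from_kinship(small_kinship)
        ests, rejects = [], 0
        for rep in range(100):
            ph = kh.simulate_trait(ped, small_kinship, cfg, seed=1000 + rep)
            y = kh.inverse_normal(
                kh.residualize(kh.average_visits(ph, "trait", "pre"), ph))
            fit = kh.fit_polygenic(y, k=small_kinship, eig=eig)
            ests.append(fit.h2)
            rejects += fit.p_value <= 0.05
        assert np.median(ests) < 0.05
        assert rejects / 100 <= 0.12  # ~5% nominal, binomial slack


class TestLRT:
    def test_zero_statistic_gives_p_one(self, small_study, small_kinship):
        fit = kh.PolygenicFit(h2=0, h2_se=np.nan, sigma2_g=0, sigma2_e=1,
                              loglik_full=-10.0, loglik_null=-10.0,
                              p_value=1.0, n=100, kinship_source="pedigree",
                              boundary=True)
        assert kh.lrt_h2(fit) == 1.0

    def test_half_chi_square_tail(self):
        fit = kh.PolygenicFit(h2=0.3, h2_se=0.1, sigma2_g=0.3, sigma2_e=0.7,
                              loglik_full=-8.0, loglik_null=-8.0 - 3.841 / 2,
                              p_value=0.0, n=100, kinship_source="pedigree",
                              boundary=False)
        assert kh.lrt_h2(fit) == pytest.approx(
            0.5 * stats.chi2.sf(3.841, 1), rel=1e-6)
        assert kh.lrt_h2(fit) == pytest.approx(0.025, abs=5e-4)
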