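"""Vectorisation, free energy, variational Laplace and model comparison."""

import numpy as np
import pytest

import fielddcm as fd
from fielddcm.inversion import devectorise, free_energy, vectorise

from conftest import reduced_priors


def _random_hermitian_psd(rng, nc=2, nf=3, s=4):
    z = rng.standard_normal((nc, nf, s, 6)) + 1j * rng.standard_normal((nc, nf, s, 6))
    return np.einsum("cfij,cfkj->cfik", z, np.conj(z)) / 6


class TestVectorise:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        v = _random_hermitian_psd(rng)
        back = devectorise(vectorise(v), 2, 3, 4)
        assert np.allclose(back, v)

    def test_length_counts(self):
        rng = np.random.default_rng(1)
        v = _random_hermitian_psd(rng)
        assert len(vectorise(v)) == 2 * 3 * 4 * 4  # s(s+1)/2 + s(s-1)/2 = s^2

    def test_real_input_gives_zero_imaginary_slots(self):
        rng = np.random.default_rng(2)
        v = _random_hermitian_psd(rng).real.astype(complex)
        vec = vectorise(v).reshape(2, 3, 16)
        assert np.allclose(vec[..., 10:], 0.0)

    def test_non_hermitian_rejected(self):
        v = np.zeros((1, 1, 2, 2), complex)
        v[0, 0, 0, 1] = 1.0
        with pytest.raises(ValueError):
            vectorise(v)


class TestFreeEnergy:
    def _conjugate_setup(self, rng, d=4, lam=1.3):
        prior_cov = np.diag(rng.uniform(0.2, 2.0, d))
        y = rng.standard_normal(d)
        prec = np.exp(lam)
        cov = np.linalg.inv(prec * np.eye(d) + np.linalg.inv(prior_cov))
        mu = cov @ (prec * y)
        return y, mu, cov, prior_cov, lam

    def test_matches_conjugate_log_evidence(self):
        # identity predictor: F at the analytic posterior equals the exact
        # log marginal likelihood of the linear-Gaussian model
        rng = np.random.default_rng(3)
        y, mu, cov, prior_cov, lam = self._conjugate_setup(rng)
        F = free_energy(mu, cov, lam, y, prediction=mu,
                        jacobian=np.eye(len(y)), prior_cov=prior_cov)
        from scipy.stats import multivariate_normal

        marg = multivariate_normal.logpdf(
            y, mean=np.zeros(len(y)),
            cov=prior_cov + np.exp(-lam) * np.eye(len(y)))
        assert F == pytest.approx(marg, abs=1e-6)

    def test_complexity_penalty_for_informed_null_parameter(self):
        # enlarging a linear model with a parameter whose generating effect
        # is zero (but which the data inform) lowers the evidence bound
        rng = np.random.default_rng(4)
        n = 40
        J1 = rng.standard_normal((n, 2))
        theta = np.array([0.7, -0.3])
        y = J1 @ theta
        lam = 2.0

        def conj_F(J, prior_cov):
            prec = np.exp(lam)
            cov = np.linalg.inv(prec * J.T @ J + np.linalg.inv(prior_cov))
            mu = cov @ (prec * J.T @ y)
            return free_energy(mu, cov, lam, y, prediction=J @ mu, jacobian=J,
                               prior_cov=prior_cov)

        F_small = conj_F(J1, np.eye(2))
        J2 = np.column_stack([J1, rng.standard_normal(n)])
        F_big = conj_F(J2, np.eye(3))
        assert F_big < F_small

    def test_invariant_to_data_ordering(self):
        rng = np.random.default_rng(5)
        y, mu, cov, prior_cov, lam = self._conjugate_setup(rng)
        perm = rng.permutation(len(y))
        F1 = free_energy(mu, cov, lam, y, prediction=mu,
                         jacobian=np.eye(len(y)), prior_cov=prior_cov)
        F2 = free_energy(mu[..., :], cov, lam, y[perm], prediction=mu[perm],
                         jacobian=np.eye(len(y))[perm], prior_cov=prior_cov)
        assert F1 == pytest.approx(F2)

    def test_grows_with_fit_quality(self):
        rng = np.random.default_rng(6)
        y, mu, cov, prior_cov, lam = self._conjugate_setup(rng)
        F_good = free_energy(mu, cov, lam, y, prediction=y, jacobian=None,
                             prior_cov=prior_cov)
        F_bad = free_energy(mu, cov, lam, y, prediction=y + 1.0, jacobian=None,
                            prior_cov=prior_cov)
        assert F_good > F_bad


@pytest.fixture(scope="module")
def tiny_setup(design):
    """A deliberately small inversion problem: few frequencies, few modes."""
    spec = fd.build_model_space()[0]  # G-only
    grid = fd.SpectralGrid.default(freqs=np.linspace(10, 80, 12), n_modes=8)
    priors = reduced_priors(spec)
    return spec, grid, priors


class TestVariationalLaplace:
    def test_self_consistency_at_noiseless_prior_means(self, design, tiny_setup):
        spec, grid, priors = tiny_setup
        clean = fd.predict_conditions({}, spec, design, priors, grid)
        data = fd.CrossSpectra(values=clean, grid=grid,
                               conditions=list(design.labels),
                               sites=[f"site{i}" for i in range(4)])
        res = fd.variational_laplace(data, spec, design, priors=priors,
                                     grid=grid, max_iter=8)
        assert np.abs(res.mean).max() < 1e-3

    def test_no_information_limit_returns_prior(self, design, tiny_setup):
        spec, grid, priors = tiny_setup
        ds = fd.generate_dataset(None, spec, design, n_epochs=32, seed=6,
                                 grid=grid, priors=priors)
        res = fd.variational_laplace(
            ds.data, spec, design, priors=priors, grid=grid, max_iter=8,
            lam_prior=(-40.0, 1e-10),
        )
        assert np.abs(res.mean).max() < 1e-2
        assert np.allclose(res.cov, priors.prior_covariance(), rtol=0.01)

    def test_free_energy_trace_monotone(self, design, tiny_setup):
        spec, grid, priors = tiny_setup
        ds = fd.generate_dataset(None, spec, design, n_epochs=64, seed=7,
                                 grid=grid, priors=priors)
        res = fd.variational_laplace(ds.data, spec, design, priors=priors,
                                     grid=grid, max_iter=16)
        assert np.all(np.diff(res.f_trace) >= -1e-9)

    def test_deterministic(self, design, tiny_setup):
        spec, grid, priors = tiny_setup
        ds = fd.generate_dataset(None, spec, design, n_epochs=64, seed=8,
                                 grid=grid, priors=priors)
        r1 = fd.variational_laplace(ds.data, spec, design, priors=priors,
                                    grid=grid, max_iter=6)
        r2 = fd.variational_laplace(ds.data, spec, design, priors=priors,
                                    grid=grid, max_iter=6)
        assert r1.free_energy == r2.free_energy
        assert np.array_equal(r1.mean, r2.mean)

    def test_posterior_covariance_symmetric_psd(self, design, tiny_setup):
        spec, grid, priors = tiny_setup
        ds = fd.generate_dataset(None, spec, design, n_epochs=64, seed=9,
                                 grid=grid, priors=priors)
        res = fd.variational_laplace(ds.data, spec, design, priors=priors,
                                     grid=grid, max_iter=6)
        assert np.allclose(res.cov, res.cov.T)
        assert np.linalg.eigvalsh(res.cov).min() > 0


class TestCompareModels:
    def _result(self, F, n=10, name="m"):
        from fielddcm.inversion import PosteriorResult

        return PosteriorResult(names=[], mean=np.zeros(1), cov=np.eye(1),
                               lam=0.0, free_energy=F, f_trace=np.array([F]),
                               converged=True, n_data=n)

    def test_equal_evidence_splits_half(self):
        bmc = fd.compare_models([self._result(10.0), self._result(10.0)])
        assert np.allclose(bmc.probabilities, [0.5, 0.5])

    def test_three_nats_is_twenty_to_one(self):
        bmc = fd.compare_models([self._result(3.0), self._result(0.0)])
        ratio = bmc.probabilities[0] / bmc.probabilities[1]
        assert round(ratio) == 20

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(10)
        results = [self._result(f) for f in rng.uniform(-50, 50, 7)]
        bmc = fd.compare_models(results)
        assert bmc.probabilities.sum() == pytest.approx(1.0)
        assert np.all(bmc.probabilities >= 0)
        assert bmc.relative_log_evidence.max() == 0.0

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError):
            fd.compare_models([self._result(1.0, n=10), self._result(2.0, n=12)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fd.compare_models([])
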