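"""Gaussian composite likelihood, fitting, and bootstrap uncertainty."""

import numpy as np
import pytest

from ldmoments.basis import build_basis, evaluate_state
from ldmoments.demography import DemographicModel, Epoch, expected_curves
from ldmoments.genotype_stats import BinnedStatistics
from ldmoments.inference import (
    InferenceError,
    ParameterSpec,
    bootstrap_ci,
    composite_loglik,
    fit,
    gaussian_loglik,
)


class TestGaussianLoglik:
    def test_maximum_at_mean(self, rng):
        Sigma = np.diag([2.0, 0.5, 1.0])
        M = np.array([1.0, -1.0, 0.0])
        at_mode = gaussian_loglik(M, M, Sigma)
        expected = -0.5 * np.log((2 * np.pi) ** 3 * np.linalg.det(Sigma))
        assert at_mode == pytest.approx(expected, rel=1e-12)
        assert gaussian_loglik(M + 0.1, M, Sigma) < at_mode

    def test_univariate_closed_form(self):
        assert gaussian_loglik(
            np.array([1.0]), np.array([0.0]), np.array([[1.0]])
        ) == pytest.approx(-0.5 * (np.log(2 * np.pi) + 1.0), rel=1e-12)

    def test_matches_dense_linear_algebra(self, rng):
        A = rng.normal(size=(5, 5))
        Sigma = A @ A.T + 0.5 * np.eye(5)
        v, M = rng.normal(size=5), rng.normal(size=5)
        direct = -0.5 * (
            5 * np.log(2 * np.pi)
            + np.log(np.linalg.det(Sigma))
            + (v - M) @ np.linalg.inv(Sigma) @ (v - M)
        )
        assert gaussian_loglik(v, M, Sigma) == pytest.approx(direct, abs=1e-10)

    def test_rank_deficient_covariance_is_floored(self):
        Sigma = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank one
        out = gaussian_loglik(np.array([0.1, 0.1]), np.zeros(2), Sigma)
        assert np.isfinite(out)

    def test_dimension_mismatch(self):
        with pytest.raises(InferenceError):
            gaussian_loglik(np.zeros(2), np.zeros(3), np.eye(3))


def one_pop_spec(theta=1e-3):
    def builder(p):
        return DemographicModel(
            N_ref=p["N"],
            theta=theta,
            events=[
                Epoch(duration=0.4, sizes={"anc": 1.0}),
                Epoch(duration=p["T"], sizes={"anc": p["nu"]}, dt=2e-3),
            ],
        )

    return ParameterSpec(
        names=["N", "nu", "T"],
        bounds=[(1e3, 1e5), (0.02, 5.0), (0.005, 0.5)],
        builder=builder,
    )


def synthetic_data(spec, truth, bin_edges, noise_sd=0.0, seed=0):
    """Model-exact binned data with optional iid noise and diagonal cov."""
    curve = expected_curves(spec.model(truth), bin_edges, normalization="anc")
    rngl = np.random.default_rng(seed)
    means = curve.values + rngl.normal(0, noise_sd, curve.values.shape)
    k = len(curve.labels)
    cov = np.tile((max(noise_sd, 1e-6) ** 2) * np.eye(k), (len(bin_edges) - 1, 1, 1))
    reps = means[None] + rngl.normal(0, max(noise_sd, 1e-12), (60,) + means.shape)
    return BinnedStatistics(
        bin_edges=np.asarray(bin_edges),
        labels=curve.labels,
        means=means,
        cov=cov,
        n_pairs=np.full(len(bin_edges) - 1, 1000.0),
        normalization="anc",
        replicates=reps,
        meta={"norm_index_1based": 1},
    )


BINS = np.logspace(-4.5, -3.0, 6)
TRUTH = np.array([10000.0, 0.25, 0.08])


class TestCompositeLoglik:
    def test_additivity_over_bins(self):
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=1e-4)
        full = composite_loglik(TRUTH, spec, data)
        perturbed = data.means.copy()
        perturbed[2] += 0.05
        data2 = BinnedStatistics(
            bin_edges=data.bin_edges, labels=data.labels, means=perturbed,
            cov=data.cov, n_pairs=data.n_pairs, normalization=data.normalization,
            meta=data.meta,
        )
        delta_full = composite_loglik(TRUTH, spec, data2) - full
        # recompute only bin 2 by hand
        keep_single = [
            composite_loglik(TRUTH, spec, d)
            for d in (data, data2)
        ]
        assert delta_full == pytest.approx(keep_single[1] - keep_single[0])
        assert delta_full < 0

    def test_exact_data_attains_per_bin_maxima(self):
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=0.0)
        at_truth = composite_loglik(TRUTH, spec, data)
        k = len(data.labels) - len(data.constant_labels())
        per_bin_max = -0.5 * k * np.log(2 * np.pi * 1e-12)  # det of 1e-6^2 I
        assert at_truth == pytest.approx(per_bin_max * data.n_bins, rel=1e-6)

    def test_unevaluable_model_gives_minus_inf(self):
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=1e-4)
        bad = np.array([10000.0, 0.25, np.nan])
        assert composite_loglik(bad, spec, data) == -np.inf


class TestFit:
    def test_recovers_generating_parameters_from_exact_data(self):
        """Fitting exact expectations with tiny covariance recovers the truth
        to better than 0.1% in every parameter."""
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=0.0)
        res = fit(spec, data, start=[8000, 0.4, 0.05], seed=1, xatol=1e-6)
        np.testing.assert_allclose(res.values, TRUTH, rtol=1e-3)
        assert res.converged

    def test_deterministic_under_seed(self):
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=2e-4, seed=3)
        r1 = fit(spec, data, start=[8000, 0.4, 0.05], n_starts=3, seed=7)
        r2 = fit(spec, data, start=[8000, 0.4, 0.05], n_starts=3, seed=7)
        np.testing.assert_array_equal(r1.values, r2.values)
        assert len(r1.starts) == 3

    def test_statistic_mask_changes_objective(self):
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=2e-4, seed=5)
        dz_labels = [l for l in data.labels if l.startswith("Dz_")]
        full = composite_loglik(TRUTH, spec, data)
        masked = composite_loglik(TRUTH, spec, data, mask_statistics=dz_labels)
        assert masked != full
        res = fit(spec, data, start=[8000, 0.4, 0.05], seed=1,
                  mask_statistics=dz_labels)
        assert all(l not in res.residual_labels for l in dz_labels)

    def test_start_outside_bounds_rejected(self):
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=1e-4)
        with pytest.raises(InferenceError):
            fit(spec, data, start=[10.0, 0.25, 0.08])


class TestBootstrapCI:
    def test_zero_variance_replicates_give_zero_width(self):
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=0.0)
        data.replicates = np.repeat(data.means[None], 20, axis=0)
        res = fit(spec, data, start=[8000, 0.4, 0.05], seed=1, xatol=1e-6)
        ci = bootstrap_ci(spec, data, res, n_refits=8, seed=2, method="normal")
        for p in ci["parameters"].values():
            assert p["upper"] - p["lower"] == pytest.approx(0.0, abs=1e-6 * p["upper"] + 1e-9)

    def test_deterministic_under_seed(self):
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=2e-4, seed=3)
        res = fit(spec, data, start=[8000, 0.4, 0.05], seed=1)
        c1 = bootstrap_ci(spec, data, res, n_refits=6, seed=11)
        c2 = bootstrap_ci(spec, data, res, n_refits=6, seed=11)
        assert c1["parameters"] == c2["parameters"]

    def test_missing_replicates_rejected(self):
        spec = one_pop_spec()
        data = synthetic_data(spec, TRUTH, BINS, noise_sd=1e-4)
        data.replicates = None
        res = fit(spec, data, start=[8000, 0.4, 0.05], seed=1)
        with pytest.raises(InferenceError):
            bootstrap_ci(spec, data, res)
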