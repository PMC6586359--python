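"""Equilibrium, Crank-Nicolson integration, events, and LD-decay curves."""

import math

import numpy as np
import pytest

from ldmoments.basis import build_basis, evaluate_state
from ldmoments.demography import (
    Admixture,
    DemographicModel,
    DemographyError,
    Epoch,
    Marginalize,
    Split,
    equilibrium,
    expected_curves,
    integrate,
    model_from_dict,
    signed_d_decay,
)
from ldmoments.operators import RateParameters, assemble_dense


class TestEquilibrium:
    def test_heterozygosity_fixed_point(self, basis_p1):
        """At nu = 1 the stationary heterozygosity equals theta (E[H] = 4Nu)."""
        eq = equilibrium(RateParameters(nu=[1.0], rho=0.5, theta=2e-3), basis_p1)
        assert eq["H_1_1"] == pytest.approx(2e-3, rel=1e-10)

    def test_residual_is_zero(self, basis_p1):
        params = RateParameters(nu=[0.7], rho=1.3, theta=1e-3)
        eq = equilibrium(params, basis_p1)
        resid = assemble_dense(params) @ eq.values
        assert np.max(np.abs(resid)) <= 1e-12 * np.max(np.abs(eq.values))

    def test_sigma_d2_closed_form(self, basis_p1):
        """One-population equilibrium sigma_d^2 = (10+rho)/(22+13rho+rho^2)."""
        for rho in (0.0, 1.0, 5.0, 20.0):
            eq = equilibrium(RateParameters(nu=[1.0], rho=rho, theta=1e-3), basis_p1)
            sd2 = eq["DD_1_1"] / eq["pi2_1_1_1_1"]
            assert sd2 == pytest.approx((10 + rho) / (22 + 13 * rho + rho**2), rel=1e-9)

    def test_theta_zero_rejected(self, basis_p1):
        with pytest.raises(DemographyError):
            equilibrium(RateParameters(nu=[1.0], rho=1.0, theta=0.0), basis_p1)


class TestIntegrate:
    def test_equilibrium_is_stationary(self, basis_p1):
        params = RateParameters(nu=[1.0], rho=1.0, theta=1e-3)
        eq = equilibrium(params, basis_p1)
        out = integrate(eq, params, T=0.5, dt=1e-3)
        np.testing.assert_allclose(out.values, eq.values, atol=1e-8 * eq.values.max())

    def test_one_entry_preserved_exactly(self, basis_p2, rng):
        y0 = evaluate_state(basis_p2, rng.dirichlet([1, 1, 1, 1], size=2))
        params = RateParameters(nu=[1.0, 0.2], rho=2.0, theta=1e-3)
        out = integrate(y0, params, T=0.3, dt=5e-3)
        assert out["ONE"] == 1.0

    def test_second_order_convergence(self, basis_p1, rng):
        """Halving dt shrinks the error by about four (Crank-Nicolson)."""
        y0 = evaluate_state(basis_p1, rng.dirichlet([1, 1, 1, 1])[None])
        params = RateParameters(nu=[0.5], rho=4.0, theta=1e-3)
        ref = integrate(y0, params, T=0.2, dt=1e-5).values
        err = []
        for dt in (4e-3, 2e-3):
            err.append(np.max(np.abs(integrate(y0, params, T=0.2, dt=dt).values - ref)))
        assert err[0] / err[1] == pytest.approx(4.0, rel=0.25)

    def test_time_varying_sizes(self, basis_p1):
        """Exponential-size epochs integrate against a midpoint-evaluated A."""
        params_fn = lambda t: RateParameters(nu=[math.exp(-t)], rho=0.0, theta=1e-3)
        eq = equilibrium(RateParameters(nu=[1.0], rho=0.0, theta=1e-3), basis_p1)
        out = integrate(eq, params_fn, T=0.2, dt=1e-3)
        assert out["H_1_1"] < eq["H_1_1"]  # shrinking population loses diversity

    def test_negative_duration_rejected(self, basis_p1, rng):
        y0 = evaluate_state(basis_p1, rng.dirichlet([1, 1, 1, 1])[None])
        with pytest.raises(DemographyError):
            integrate(y0, RateParameters(nu=[1.0]), T=-1.0)


def test_signed_d_closed_form_decay():
    """E[D](T) = exp(-(1 + rho/2) T) D0 for one population."""
    rho, T, d0 = 1.0, 0.3, 0.2
    value = signed_d_decay(d0, nu=1.0, rho=rho, T=T, dt=1e-3)
    assert value == pytest.approx(d0 * math.exp(-(1 + rho / 2) * T), rel=1e-6)


class TestModelEvaluation:
    def bottleneck_model(self, theta=1e-3):
        return DemographicModel(
            N_ref=1e4,
            theta=theta,
            events=[
                Epoch(duration=0.05, sizes={"anc": 1.0}),
                Epoch(duration=0.05, sizes={"anc": 0.1}),
                Epoch(duration=0.02, sizes={"anc": 1.0}),
            ],
        )

    def test_without_mutation_everything_decays(self, basis_p1, rng):
        y0 = evaluate_state(basis_p1, rng.dirichlet([1, 1, 1, 1])[None])
        params = RateParameters(nu=[1.0], rho=0.5, theta=0.0)
        out = integrate(y0, params, T=30.0, dt=5e-3)
        assert np.max(np.abs(out.values[:-1])) < 1e-9

    def test_theta_scaling_invariance_of_normalized_curves(self):
        bins = np.logspace(-5, np.log10(2e-3), 6)
        c1 = expected_curves(self.bottleneck_model(1e-3), bins, normalization="anc")
        c2 = expected_curves(self.bottleneck_model(1e-2), bins, normalization="anc")
        assert np.max(np.abs(c1.values - c2.values)) < 1e-10

    def test_raw_h_scales_linearly_with_theta(self):
        bins = np.array([1e-4, 2e-4])
        c1 = expected_curves(self.bottleneck_model(1e-3), bins, normalization="raw")
        c2 = expected_curves(self.bottleneck_model(5e-4), bins, normalization="raw")
        assert c1.column("H_1_1")[0] == pytest.approx(2 * c2.column("H_1_1")[0], rel=1e-8)

    def test_sigma_d2_decreases_with_r(self):
        bins = np.logspace(-5, np.log10(2e-3), 8)
        model = DemographicModel(N_ref=1e4, theta=1e-3, events=[Epoch(0.02, {"anc": 1.0})])
        curve = expected_curves(model, bins, normalization="anc")
        assert np.all(np.diff(curve.column("DD_1_1")) < 0)

    def test_multi_population_pipeline(self):
        model = DemographicModel(
            N_ref=1e4,
            theta=1e-3,
            events=[
                Epoch(0.01, {"anc": 1.0}),
                Split("anc", ("A", "B")),
                Epoch(0.05, {"A": 1.0, "B": 0.3}, migration={("A", "B"): 0.5}),
                Admixture("A", "B", 0.2, "C"),
                Epoch(0.01, {"A": 1.0, "B": 0.3, "C": 0.5}),
                Marginalize("B"),
            ],
        )
        out = model.evaluate(rho=1.0)
        assert out.basis.pops.labels == ("A", "C")
        assert np.all(np.isfinite(out.values))
        assert out["H_1_1"] > 0 and out["DD_1_1"] > 0

    def test_bins_outside_validity_rejected(self):
        model = self.bottleneck_model()
        with pytest.raises(DemographyError):
            expected_curves(model, [0.01, 0.2], normalization="raw")


class TestYamlModels:
    def test_time_and_rate_conversion(self):
        spec = {
            "N_ref": 10000,
            "theta": 1e-3,
            "time_units": "years",
            "generation_time": 29,
            "events": [
                {
                    "epoch": {
                        "duration": 2.0 * 10000 * 29,  # exactly one 2N unit
                        "sizes": {"anc": 1.0},
                        "rate_units": "per_generation",
                        "migration": [],
                    }
                }
            ],
        }
        model = model_from_dict(spec)
        assert model.events[0].duration == pytest.approx(1.0)

    def test_curve_tsv_roundtrip(self, tmp_path):
        model = model_from_dict(
            {"N_ref": 5000, "theta": 1e-3,
             "events": [{"epoch": {"duration": 0.02, "sizes": {"anc": 1.0}}}]}
        )
        curve = expected_curves(model, np.logspace(-4, -3, 4), normalization="anc")
        path = tmp_path / "curve.tsv"
        curve.to_tsv(path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert list(df.columns[:2]) == ["bin_left", "bin_right"]
        np.testing.assert_allclose(df["DD_1_1"].to_numpy(), curve.column("DD_1_1"))
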