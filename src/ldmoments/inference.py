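"""Composite-likelihood fitting of demographic models to binned LD statistics.

For each recombination bin ``i`` the observed normalized statistic vector
``v_i`` is modeled as multivariate normal around the model expectation
``M_i(Theta)`` with covariance ``Sigma_i`` estimated by the genomic block
bootstrap; the composite log-likelihood is the sum over bins (between-bin
dependence is ignored, which is why uncertainties come from refitting
bootstrap replicates rather than from the curvature of the composite
likelihood).  ``N_ref`` is a model parameter: it scales the recombination
bins as ``rho_i = 4 N_ref r_i``, which is what makes it identifiable from
r-binned curves.

Optimization is a bounded derivative-free simplex (Nelder-Mead) on
log-transformed positive parameters, with optional seeded multi-start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.optimize
import scipy.stats

from .demography import DemographicModel, expected_curves
from .genotype_stats import BinnedStatistics

logger = logging.getLogger(__name__)


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gaussian building block
# ---------------------------------------------------------------------------

EIGENVALUE_FLOOR = 1e-6  # times trace(Sigma)/k; bootstrap Sigma can be singular


def gaussian_loglik(
    v: np.ndarray, M: np.ndarray, Sigma: np.ndarray, shrinkage: float = 0.0
) -> float:
    """Multivariate normal log-density log N(v; M, Sigma).

    Rank-deficient covariance (a hazard of block bootstraps with few blocks)
    is regularized by flooring eigenvalues at ``1e-6 * trace(Sigma)/k``.
    ``shrinkage`` blends Sigma toward its diagonal,
    ``(1-a) Sigma + a diag(Sigma)``: with many correlated statistics and a
    finite number of bootstrap replicates the smallest sample eigenvalues are
    strongly downward-biased, and inverting them over-weights directions whose
    variance is poorly known; diagonal shrinkage keeps parameter uncertainty
    calibrated.
    """
    v = np.asarray(v, dtype=float)
    M = np.asarray(M, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    k = v.shape[0]
    if M.shape != (k,) or Sigma.shape != (k, k):
        raise InferenceError("dimension mismatch in gaussian_loglik")
    if shrinkage:
        Sigma = (1.0 - shrinkage) * Sigma + shrinkage * np.diag(np.diag(Sigma))
    w, U = np.linalg.eigh((Sigma + Sigma.T) / 2.0)
    floor = EIGENVALUE_FLOOR * max(np.trace(Sigma) / k, 1e-300)
    w = np.maximum(w, floor)
    resid = U.T @ (v - M)
    return float(
        -0.5 * (k * np.log(2 * np.pi) + np.sum(np.log(w)) + np.sum(resid**2 / w))
    )


# ---------------------------------------------------------------------------
# parameter specification
# ---------------------------------------------------------------------------


@dataclass
class ParameterSpec:
    """Names, bounds, transforms and the mapping to a demographic model.

    ``builder(values_dict)`` returns the :class:`DemographicModel`; the model
    must expose ``N_ref`` (fit jointly, since it scales the recombination
    bins).  ``transforms`` are ``"log"`` (positive parameters, optimized on a
    log scale) or ``"identity"``.
    """

    names: list[str]
    bounds: list[tuple[float, float]]
    builder: Callable[[dict], DemographicModel]
    transforms: list[str] | None = None

    def __post_init__(self):
        if self.transforms is None:
            self.transforms = ["log" if lo > 0 else "identity" for lo, _ in self.bounds]
        if not (len(self.names) == len(self.bounds) == len(self.transforms)):
            raise InferenceError("parameter spec fields have inconsistent lengths")

    def to_internal(self, values: np.ndarray) -> np.ndarray:
        out = np.array(values, dtype=float)
        for i, t in enumerate(self.transforms):
            if t == "log":
                out[i] = np.log(out[i])
        return out

    def from_internal(self, values: np.ndarray) -> np.ndarray:
        out = np.array(values, dtype=float)
        for i, t in enumerate(self.transforms):
            if t == "log":
                out[i] = np.exp(out[i])
        return out

    def internal_bounds(self) -> list[tuple[float, float]]:
        out = []
        for (lo, hi), t in zip(self.bounds, self.transforms):
            out.append((np.log(lo), np.log(hi)) if t == "log" else (lo, hi))
        return out

    def model(self, values: np.ndarray) -> DemographicModel:
        return self.builder(dict(zip(self.names, values)))


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------


def _data_matrices(
    data: BinnedStatistics, mask_statistics: Sequence[str] | None
):
    """Column subset used in the objective (drops identically-one rows)."""
    drop = set(data.constant_labels())
    if mask_statistics:
        drop |= set(mask_statistics)
    keep = [i for i, l in enumerate(data.labels) if l not in drop]
    labels = [data.labels[i] for i in keep]
    return keep, labels


def composite_loglik(
    values: np.ndarray,
    spec: ParameterSpec,
    data: BinnedStatistics,
    mask_statistics: Sequence[str] | None = None,
    means_override: np.ndarray | None = None,
    cov_shrinkage: float = 0.0,
) -> float:
    """Sum over bins of the Gaussian log-likelihood at the model expectation.

    Model curves are evaluated at the data's bins (geometric-mean rho) under
    the same normalization; ``mask_statistics`` removes labels from the
    objective (e.g. the Dz rows, mirroring model-misspecification
    diagnostics).  Returns -inf if the model cannot be evaluated.
    """
    if data.cov is None:
        raise InferenceError("data has no covariance; run the block bootstrap first")
    keep, _ = _data_matrices(data, mask_statistics)
    try:
        model = spec.model(np.asarray(values, dtype=float))
        curve = expected_curves(model, data.bin_edges, normalization=data.normalization)
    except Exception as exc:
        logger.debug("model evaluation failed at %s: %s", values, exc)
        return -np.inf
    order = [curve.labels.index(l) for l in data.labels]
    M = curve.values[:, order]
    means = data.means if means_override is None else means_override
    total = 0.0
    for b in range(data.n_bins):
        if not np.all(np.isfinite(means[b])):
            continue
        total += gaussian_loglik(
            means[b][keep], M[b][keep], data.cov[b][np.ix_(keep, keep)],
            shrinkage=cov_shrinkage,
        )
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    names: list[str]
    values: np.ndarray
    loglik: float
    converged: bool
    n_evaluations: int
    residual_z: np.ndarray | None = None  # (n_bins, k) per-statistic z-scores
    residual_labels: list[str] | None = None
    starts: list[dict] = field(default_factory=list)
    ci: dict | None = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def _residual_report(values, spec, data, mask_statistics):
    keep, labels = _data_matrices(data, mask_statistics)
    model = spec.model(values)
    curve = expected_curves(model, data.bin_edges, normalization=data.normalization)
    order = [curve.labels.index(l) for l in data.labels]
    M = curve.values[:, order]
    z = np.full((data.n_bins, len(keep)), np.nan)
    for b in range(data.n_bins):
        sd = np.sqrt(np.diag(data.cov[b])[keep])
        z[b] = (data.means[b][keep] - M[b][keep]) / np.where(sd > 0, sd, np.nan)
    return labels, z


def fit(
    spec: ParameterSpec,
    data: BinnedStatistics,
    start: Sequence[float] | dict,
    mask_statistics: Sequence[str] | None = None,
    n_starts: int = 1,
    seed: int = 0,
    perturb: float = 0.3,
    maxiter: int = 2000,
    xatol: float = 1e-4,
    means_override: np.ndarray | None = None,
    cov_shrinkage: float = 0.0,
) -> FitResult:
    """Maximize the composite log-likelihood with a bounded simplex search.

    Multi-start: ``n_starts - 1`` additional seeded starts perturb the initial
    point by ``perturb`` on the internal (log) scale; the best optimum is
    returned.  Deterministic for a fixed seed.
    """
    if isinstance(start, dict):
        start = [start[n] for n in spec.names]
    start = np.asarray(start, dtype=float)
    for s, (lo, hi), n in zip(start, spec.bounds, spec.names):
        if not (lo <= s <= hi):
            raise InferenceError(f"start for {n} outside bounds")
    rng = np.random.default_rng(seed)
    internal0 = spec.to_internal(start)
    bounds = spec.internal_bounds()

    def objective(internal):
        return -composite_loglik(
            spec.from_internal(internal), spec, data, mask_statistics,
            means_override=means_override, cov_shrinkage=cov_shrinkage,
        )

    best = None
    starts_log = []
    n_eval = 0
    for k in range(n_starts):
        x0 = internal0.copy()
        if k > 0:
            x0 = x0 + rng.normal(0, perturb, size=x0.shape)
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = scipy.optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": maxiter, "xatol": xatol, "fatol": 1e-6, "adaptive": True},
        )
        n_eval += res.nfev
        starts_log.append(
            {"start": spec.from_internal(x0).tolist(), "loglik": -float(res.fun),
             "success": bool(res.success)}
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise InferenceError(f"all optimization starts failed: {starts_log}")
    values = spec.from_internal(best.x)
    labels, z = _residual_report(values, spec, data, mask_statistics)
    return FitResult(
        names=list(spec.names),
        values=values,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_evaluations=n_eval,
        residual_z=z,
        residual_labels=labels,
        starts=starts_log,
    )


def bootstrap_ci(
    spec: ParameterSpec,
    data: BinnedStatistics,
    fit_result: FitResult,
    n_refits: int = 50,
    seed: int = 0,
    mask_statistics: Sequence[str] | None = None,
    level: float = 0.95,
    max_failure_rate: float = 0.2,
    maxiter: int = 500,
    xatol: float = 2e-3,
    cov_shrinkage: float = 0.0,
    method: str = "percentile",
) -> dict:
    """Confidence intervals from refits on bootstrap replicates.

    Each refit replaces the observed per-bin mean vectors with one bootstrap
    replicate (covariances kept fixed) and restarts the simplex from the
    original optimum.  Requires the replicate vectors stored by the block
    bootstrap.  ``method="percentile"`` takes refit quantiles;
    ``method="normal"`` uses the estimate +/- z * sd(refits), whose width is
    unbiased when only a few dozen refits are affordable (the extreme order
    statistics of a small sample sit systematically inside the true
    quantiles).
    """
    if data.replicates is None:
        raise InferenceError("data has no stored bootstrap replicate vectors")
    rng = np.random.default_rng(seed)
    n_avail = data.replicates.shape[0]
    picks = rng.choice(n_avail, size=min(n_refits, n_avail), replace=False)
    estimates, failures = [], 0
    for b in picks:
        try:
            res = fit(
                spec,
                data,
                start=fit_result.values,
                mask_statistics=mask_statistics,
                n_starts=1,
                seed=seed,
                maxiter=maxiter,
                xatol=xatol,
                means_override=data.replicates[b],
                cov_shrinkage=cov_shrinkage,
            )
            estimates.append(res.values)
        except InferenceError:
            failures += 1
    if failures > max_failure_rate * len(picks):
        raise InferenceError(
            f"{failures}/{len(picks)} bootstrap refits failed"
        )
    estimates = np.array(estimates)
    alpha = (1 - level) / 2
    if method == "normal":
        z = scipy.stats.norm.ppf(1 - alpha)
        sd = estimates.std(axis=0, ddof=1)
        lo = fit_result.values - z * sd
        hi = fit_result.values + z * sd
    elif method == "percentile":
        lo = np.quantile(estimates, alpha, axis=0)
        hi = np.quantile(estimates, 1 - alpha, axis=0)
    else:
        raise InferenceError(f"unknown CI method {method!r}")
    return {
        "level": level,
        "method": method,
        "n_refits": int(len(estimates)),
        "n_failures": int(failures),
        "parameters": {
            n: {"lower": float(l), "upper": float(h), "estimates": estimates[:, i].tolist()}
            for i, (n, l, h) in enumerate(zip(spec.names, lo, hi))
        },
    }
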