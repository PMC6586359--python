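"""Reproducible synthetic validation studies.

These are the package's own end-to-end checks, kept in the library so that
the test suite and reproduction scripts share one implementation:

* random trajectory configurations comparing moment-system predictions with
  the Wright-Fisher oracle;
* an isolation-then-admixture design (two populations drifting apart for 2N
  generations, then a 1% pulse) probing the admixture transform, including
  the strong post-pulse elevation of E[Dz];
* a two-population split-with-migration parameter-recovery study run end to
  end: Wright-Fisher panel -> genotype estimators -> binned statistics with
  block bootstrap -> composite-likelihood fit -> bootstrap-refit confidence
  intervals.

Problem sizes are chosen so the whole suite runs on a single CPU in minutes,
while staying inside the validity regime of the leading-order moment system:
the per-generation neglected terms are of relative order (lambda/2N)^2 for a
statistic decaying at scaled rate lambda (up to 3 + rho), so their
accumulation over a run of G generations, G*(lambda/2N)^2, must stay well
below the sampling noise of the study.  Panels use 1e5 SNP pairs; the
recovery study runs at N = 500 diploids for 160 generations with rho up to 6
and 20 sampled diploids per population, placing the residual approximation
error well below the sampling standard error of the fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import build_basis, evaluate_state
from .demography import DemographicModel, Epoch, Split
from .genotype_stats import compute_binned_statistics
from .inference import ParameterSpec, bootstrap_ci, fit
from .operators import exact_generation_matrices
from .wright_fisher import TwoLocusWF, WFConfig, sample_panel_from_freqs, statistics_array


# ---------------------------------------------------------------------------
# oracle-vs-moment-system trajectory configurations
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryConfig:
    pop_sizes: list[int]
    r: float
    mig: np.ndarray
    init: np.ndarray
    generations: int


def random_trajectory_config(rng: np.random.Generator, max_pops: int = 3) -> TrajectoryConfig:
    """A random small configuration within the moment system's regime.

    Sizes 200-500 diploids, r <= 0.003, per-generation migration <= 7e-4
    (scaled rates mtilde up to ~0.7) and random (possibly linked) initial
    haplotype frequencies, over 20-80 generations.  The caps keep the
    neglected second-order terms -- (lambda/2N)^2 drift corrections and,
    most importantly, m^2 migration products, which accumulate over the run
    and can be amplified by near-cancelling cross-population statistics --
    below the Monte-Carlo standard error of 1e5 replicates.
    """
    P = int(rng.integers(1, max_pops + 1))
    N = rng.integers(200, 501, size=P).tolist()
    r = float(rng.uniform(0, 0.003))
    mig = np.zeros((P, P))
    if P > 1:
        for i in range(P):
            for j in range(P):
                if i != j and rng.random() < 0.7:
                    mig[i, j] = float(rng.uniform(0, 7e-4))
    init = rng.dirichlet([2.0, 2.0, 2.0, 2.0], size=P)
    generations = int(rng.integers(20, 81))
    return TrajectoryConfig(pop_sizes=N, r=r, mig=mig, init=init, generations=generations)


def generation_matrix(config: TrajectoryConfig) -> np.ndarray:
    """One-generation recursion matrix I + sum(D_i/2N_i) + R r + sum(M m)."""
    P = len(config.pop_sizes)
    labels, drift, recomb, mig, _ = exact_generation_matrices(P)
    n = len(labels)
    A = np.zeros((n, n))
    for i, N in enumerate(config.pop_sizes):
        for (r_, c), v in drift[i].items():
            A[r_, c] += float(v) / (2 * N)
    for (r_, c), v in recomb.items():
        A[r_, c] += float(v) * config.r
    for (i, j), comp in mig.items():
        for (r_, c), v in comp.items():
            A[r_, c] += float(v) * config.mig[i, j]
    return np.eye(n) + A


def predict_trajectory(config: TrajectoryConfig) -> np.ndarray:
    """Moment-system prediction of all basis statistics after `generations`."""
    P = len(config.pop_sizes)
    basis = build_basis([f"p{i}" for i in range(P)])
    y = evaluate_state(basis, config.init).values
    step = generation_matrix(config)
    return np.linalg.matrix_power(step, config.generations) @ y


def run_trajectory_config(config: TrajectoryConfig, replicates: int, seed: int):
    """(labels, prediction, oracle mean, oracle SE) at the final generation."""
    wf = WFConfig(
        pop_sizes=config.pop_sizes,
        r=config.r,
        mig=config.mig,
        init=config.init,
        generations=config.generations,
        replicates=replicates,
        seed=seed,
    )
    sim = TwoLocusWF(wf)
    sim.run(config.generations)
    est = sim.statistics()
    return est.labels, predict_trajectory(config), est.mean, est.se


# ---------------------------------------------------------------------------
# isolation + admixture pulse (elevated E[Dz] after a 1% pulse)
# ---------------------------------------------------------------------------


def admixture_pulse_study(
    N: int = 150,
    isolation_generations: int | None = None,
    fraction: float = 0.01,
    r: float = 0.002,
    replicates: int = 100_000,
    seed: int = 0,
):
    """Two identical populations drift in isolation for 2N generations, then
    the first receives a pulse of lineages from the second.

    Returns (labels, moment prediction, oracle mean, oracle SE) for the full
    two-population basis immediately after the pulse, where the prediction
    chains the per-generation recursion with the admixture transform.
    """
    from .basis import StatisticVector, map_label
    from .events import pulse_migration

    gens = isolation_generations if isolation_generations is not None else 2 * N
    init = np.array([[0.25, 0.25, 0.25, 0.25]] * 2)
    config = TrajectoryConfig(
        pop_sizes=[N, N], r=r, mig=np.zeros((2, 2)), init=init, generations=gens
    )
    basis = build_basis(["focal", "diverged"])
    y = StatisticVector(basis, predict_trajectory(config))
    y = pulse_migration(y, "diverged", "focal", fraction)
    # the pulse moves "focal" to the end of the population ordering; map the
    # original labels by population name to read the vector back out
    idx_map = {
        i: y.basis.pops.index(name) for i, name in enumerate(basis.pops.labels)
    }
    prediction = np.array(
        [y.values[y.basis.index_of(map_label(lbl, idx_map))] if lbl.family != "ONE" else 1.0
         for lbl in basis.labels]
    )

    wf = WFConfig(
        pop_sizes=[N, N], r=r, init=init, generations=gens, replicates=replicates, seed=seed
    )
    sim = TwoLocusWF(wf)
    sim.run(gens)
    sim.admix_pulse(source=1, dest=0, fraction=fraction)
    values = statistics_array(sim.freqs, basis.labels)
    mean = values.mean(axis=0)
    se = values.std(axis=0, ddof=1) / np.sqrt(replicates)
    return basis.names(), prediction, mean, se


# ---------------------------------------------------------------------------
# end-to-end split-with-migration recovery
# ---------------------------------------------------------------------------


@dataclass
class SplitMigrationStudy:
    """Study conditions for the two-population recovery experiment."""

    N: float = 500.0  # diploid size of both daughter populations (= N_ref)
    T: float = 160.0  # split age in generations
    m: float = 1.0e-3  # symmetric per-generation migration (mtilde = 1)
    n_pairs: int = 100_000
    n_diploids: int = 20
    r_min: float = 2.0e-4
    r_max: float = 3.0e-3  # rho in [0.4, 6] at N = 500
    n_bins: int = 6
    n_boot: int = 150
    cov_shrinkage: float = 1.0
    bounds: dict = field(
        default_factory=lambda: {"N": (100, 2500), "T": (30, 800), "m": (5e-5, 0.01)}
    )
    start: dict = field(default_factory=lambda: {"N": 800.0, "T": 110.0, "m": 5e-4})

    @property
    def bin_edges(self) -> np.ndarray:
        return np.logspace(np.log10(self.r_min), np.log10(self.r_max), self.n_bins + 1)

    def parameter_spec(self) -> ParameterSpec:
        initial = evaluate_state(build_basis(["anc"]), np.array([[0.25] * 4]))

        def builder(p: dict) -> DemographicModel:
            N = p["N"]
            return DemographicModel(
                N_ref=N,
                theta=0.0,
                initial=initial,
                root="anc",
                events=[
                    Split("anc", ("pop1", "pop2")),
                    Epoch(
                        duration=p["T"] / (2 * N),
                        sizes={"pop1": 1.0, "pop2": 1.0},
                        migration={
                            ("pop1", "pop2"): 2 * N * p["m"],
                            ("pop2", "pop1"): 2 * N * p["m"],
                        },
                        dt=1e-2,
                    ),
                ],
            )

        names = ["N", "T", "m"]
        return ParameterSpec(
            names=names, bounds=[self.bounds[n] for n in names], builder=builder
        )

    def truth(self) -> dict:
        return {"N": self.N, "T": self.T, "m": self.m}

    def simulate_panel(self, seed: int):
        rng = np.random.default_rng(seed)
        r = np.exp(
            rng.uniform(
                np.log(self.r_min * 1.05), np.log(self.r_max * 0.95), self.n_pairs
            )
        )
        cfg = WFConfig(
            pop_sizes=[int(self.N)] * 2,
            r=r,
            mig=np.array([[0, self.m], [self.m, 0]]),
            init=np.array([[0.25] * 4] * 2),
            generations=int(self.T),
            replicates=self.n_pairs,
            seed=seed,
        )
        sim = TwoLocusWF(cfg)
        sim.run(cfg.generations)
        return sample_panel_from_freqs(
            sim.freqs,
            sim.r,
            [self.n_diploids] * 2,
            ["pop1", "pop2"],
            sim.rng,
            pairs_per_chrom=500,
            map_rate_cm_per_mb=10.0,
        )

    def binned_data(self, panel, seed: int):
        return compute_binned_statistics(
            panel.to_genotype_matrix(),
            panel.recombination_map(),
            ["pop1", "pop2"],
            bin_edges=self.bin_edges,
            r_min=self.r_min,
            r_max=self.r_max,
            normalization="pop1",
            n_boot=self.n_boot,
            seed=seed,
            block_by_chromosome=True,
            min_diploids=20,
        )

    def run(self, seed: int, n_refits: int = 28) -> dict:
        """One full recovery run; returns estimates, CIs and coverage flags."""
        panel = self.simulate_panel(seed)
        data = self.binned_data(panel, seed)
        spec = self.parameter_spec()
        res = fit(
            spec,
            data,
            start=self.start,
            n_starts=1,
            seed=seed,
            xatol=1e-3,
            cov_shrinkage=self.cov_shrinkage,
        )
        ci = bootstrap_ci(
            spec,
            data,
            res,
            n_refits=n_refits,
            seed=seed,
            maxiter=400,
            xatol=2e-3,
            cov_shrinkage=self.cov_shrinkage,
            method="normal",
        )
        truth = self.truth()
        covered = {
            n: ci["parameters"][n]["lower"] <= truth[n] <= ci["parameters"][n]["upper"]
            for n in spec.names
        }
        return {
            "seed": seed,
            "estimates": res.as_dict(),
            "loglik": res.loglik,
            "ci": {
                n: (ci["parameters"][n]["lower"], ci["parameters"][n]["upper"])
                for n in spec.names
            },
            "covered": covered,
        }
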