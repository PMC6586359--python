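"""Discrete two-locus, multi-deme Wright-Fisher simulator.

This is the brute-force oracle for the moment system: it simulates many
independent replicates of a two-locus system (haplotypes AB, Ab, aB, ab) in
``P`` demes and reports Monte-Carlo means and standard errors of every basis
statistic.  It also doubles as the synthetic-data generator: panels of
unlinked SNP pairs with diploid genotypes are written as plain-text VCF with
a matching population map and recombination map.

Within-generation update order: deterministic recombination, mutation
(symmetric two-allele, used only to reach stationarity) and migration applied
to expected haplotype frequencies, followed by multinomial resampling of
``2 N_i`` haplotypes per deme.  Differences between orderings are above
leading order.  Migration is the deterministic contribution of population
``i``'s gamete pool to population ``j`` with weight ``m_ij`` (the probability
that a lineage in ``j`` has its parent in ``i``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .basis import MomentBasis, MomentLabel, build_basis


class WFError(ValueError):
    pass


# ---------------------------------------------------------------------------
# vectorized statistics
# ---------------------------------------------------------------------------


def statistics_array(freqs: np.ndarray, labels: Sequence[MomentLabel]) -> np.ndarray:
    """Evaluate basis statistics on frequency states.

    ``freqs`` has shape (..., P, 4) in haplotype order AB, Ab, aB, ab; the
    result has shape (..., len(labels)).  Definitions mirror the
    locus-exchange-symmetrized basis polynomials.
    """
    p = freqs[..., 0] + freqs[..., 1]
    q = freqs[..., 0] + freqs[..., 2]
    D = freqs[..., 0] * freqs[..., 3] - freqs[..., 1] * freqs[..., 2]
    cols = []
    for lbl in labels:
        if lbl.family == "ONE":
            cols.append(np.ones(freqs.shape[:-2]))
        elif lbl.family == "DD":
            i, j = lbl.indices
            cols.append(D[..., i] * D[..., j])
        elif lbl.family == "Dz":
            i, (j, k) = lbl.indices
            zjk = (1 - 2 * p[..., j]) * (1 - 2 * q[..., k])
            zkj = (1 - 2 * p[..., k]) * (1 - 2 * q[..., j])
            cols.append(0.5 * D[..., i] * (zjk + zkj))
        elif lbl.family == "pi2":
            (i, j), (k, l) = lbl.indices
            left_p = p[..., i] * (1 - p[..., j]) + p[..., j] * (1 - p[..., i])
            right_q = q[..., k] * (1 - q[..., l]) + q[..., l] * (1 - q[..., k])
            left_q = q[..., i] * (1 - q[..., j]) + q[..., j] * (1 - q[..., i])
            right_p = p[..., k] * (1 - p[..., l]) + p[..., l] * (1 - p[..., k])
            cols.append(0.125 * (left_p * right_q + left_q * right_p))
        elif lbl.family == "H":
            i, j = lbl.indices
            hp = p[..., i] * (1 - p[..., j]) + p[..., j] * (1 - p[..., i])
            hq = q[..., i] * (1 - q[..., j]) + q[..., j] * (1 - q[..., i])
            cols.append(0.5 * (hp + hq))
        else:  # pragma: no cover
            raise WFError(f"unknown family {lbl.family}")
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# configuration and estimates
# ---------------------------------------------------------------------------


@dataclass
class WFConfig:
    """Simulation settings; probabilities are per generation."""

    pop_sizes: Sequence[int]  # diploid N per deme (2N haplotypes resampled)
    r: float | np.ndarray = 0.0  # may vary per replicate
    u: float = 0.0  # symmetric two-allele mutation per locus (finite sites)
    mig: np.ndarray | None = None  # m[i, j]: parent in i for a lineage in j
    init: np.ndarray | None = None  # (P, 4) or (replicates, P, 4)
    generations: int = 0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        self.pop_sizes = list(int(n) for n in self.pop_sizes)
        if any(n <= 0 for n in self.pop_sizes):
            raise WFError("population sizes must be positive")
        P = len(self.pop_sizes)
        if self.mig is None:
            self.mig = np.zeros((P, P))
        self.mig = np.asarray(self.mig, dtype=float)
        if self.mig.shape != (P, P):
            raise WFError("migration matrix shape mismatch")
        if self.init is not None:
            self.init = np.asarray(self.init, dtype=float)
            if not np.allclose(self.init.sum(axis=-1), 1.0, atol=1e-9):
                raise WFError("initial haplotype frequencies must sum to 1")

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)


@dataclass
class OracleEstimate:
    """Monte-Carlo means and standard errors of basis statistics."""

    labels: list[str]
    mean: np.ndarray
    se: np.ndarray
    replicates: int

    def __getitem__(self, label: str) -> tuple[float, float]:
        i = self.labels.index(label)
        return float(self.mean[i]), float(self.se[i])

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {l: (float(m), float(s)) for l, m, s in zip(self.labels, self.mean, self.se)}


def _estimate(values: np.ndarray, labels: list[str]) -> OracleEstimate:
    R = values.shape[0]
    mean = values.mean(axis=0)
    se = values.std(axis=0, ddof=1) / np.sqrt(R) if R > 1 else np.zeros(mean.shape)
    return OracleEstimate(labels=labels, mean=mean, se=se, replicates=R)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


class TwoLocusWF:
    """Vectorized two-locus Wright-Fisher dynamics over replicates."""

    def __init__(self, config: WFConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        P, R = config.n_pops, config.replicates
        if config.init is None:
            raise WFError("an initial haplotype frequency state is required")
        init = config.init
        if init.ndim == 2:
            init = np.broadcast_to(init, (R, P, 4))
        self.freqs = np.array(init, dtype=float)
        if self.freqs.shape != (R, P, 4):
            raise WFError(f"initial state shape {self.freqs.shape} != {(R, P, 4)}")
        self.r = np.broadcast_to(np.asarray(config.r, dtype=float), (R,)).copy()
        self.generation = 0

    # deterministic expectation updates -----------------------------------
    def _recombine(self):
        f = self.freqs
        D = f[..., 0] * f[..., 3] - f[..., 1] * f[..., 2]
        shift = self.r[:, None] * D
        f[..., 0] -= shift
        f[..., 1] += shift
        f[..., 2] += shift
        f[..., 3] -= shift

    def _mutate(self):
        u = self.config.u
        if u == 0:
            return
        K = np.array([[1 - u, u], [u, 1 - u]])
        R, P = self.freqs.shape[:2]
        t = self.freqs.reshape(R, P, 2, 2)
        t = np.einsum("la,rpab,mb->rplm", K, t, K)
        self.freqs = t.reshape(R, P, 4)

    def _migrate(self):
        m = self.config.mig
        if not m.any():
            return
        P = self.config.n_pops
        W = m.T.copy()  # W[j, i] = weight of source i in dest j
        np.fill_diagonal(W, 1.0 - m.sum(axis=0))
        if np.any(np.diag(W) < 0):
            raise WFError("total immigration probability exceeds 1")
        self.freqs = np.einsum("ji,rih->rjh", W, self.freqs)

    def _drift(self):
        for i, N in enumerate(self.config.pop_sizes):
            n = 2 * N
            p = np.clip(self.freqs[:, i, :], 0.0, None)
            p /= p.sum(axis=1, keepdims=True)
            counts = self.rng.multinomial(n, p)
            self.freqs[:, i, :] = counts / n
        self.generation += 1

    def step(self):
        self._recombine()
        self._mutate()
        self._migrate()
        self._drift()

    def run(self, generations: int):
        for _ in range(generations):
            self.step()
        return self

    # discrete events ------------------------------------------------------
    def admix_pulse(self, source: int, dest: int, fraction: float):
        """dest receives a fraction of lineages from source (deterministic mix)."""
        if not 0.0 <= fraction <= 1.0:
            raise WFError("fraction outside [0, 1]")
        self.freqs[:, dest, :] = (
            fraction * self.freqs[:, source, :] + (1 - fraction) * self.freqs[:, dest, :]
        )
        return self

    # observables ----------------------------------------------------------
    def statistics(self, basis: MomentBasis | None = None) -> OracleEstimate:
        basis = basis or build_basis([f"p{i}" for i in range(self.config.n_pops)])
        values = statistics_array(self.freqs, basis.labels)
        return _estimate(values, basis.names())


def simulate_replicates(
    config: WFConfig, record: Sequence[int] | None = None
) -> dict[int, OracleEstimate]:
    """Run the oracle and report statistics at the requested generations.

    ``record`` is a list of generation indices (0 = initial state); the
    default records only the final generation.
    """
    record = sorted(set(record if record is not None else [config.generations]))
    if record and record[-1] > config.generations:
        raise WFError("recording time beyond the simulated horizon")
    sim = TwoLocusWF(config)
    basis = build_basis([f"p{i}" for i in range(config.n_pops)])
    out: dict[int, OracleEstimate] = {}
    if record and record[0] == 0:
        out[0] = sim.statistics(basis)
        record = record[1:]
    for target in record:
        sim.run(target - sim.generation)
        out[target] = sim.statistics(basis)
    return out


def stationary_estimate(
    config: WFConfig,
    burn_in: int | None = None,
    sample_every: int | None = None,
    n_samples: int = 20,
) -> OracleEstimate:
    """Time-averaged statistics at mutation-drift-recombination stationarity.

    Requires ``u > 0``.  After a burn-in (default ``20 N`` generations, with a
    warning below ``10 * 2N``) the chain is sampled every ``sample_every``
    generations (default ``2 N``); per-replicate time averages are treated as
    independent draws, so the standard error is taken across replicates and is
    robust to residual autocorrelation within a replicate.
    """
    import warnings

    if config.u <= 0:
        raise WFError("stationary estimates require u > 0")
    N = max(config.pop_sizes)
    if burn_in is None:
        burn_in = 20 * N
    if burn_in < 10 * 2 * N:
        warnings.warn("burn-in below 10*2N generations; estimates may be biased")
    if sample_every is None:
        sample_every = 2 * N
    sim = TwoLocusWF(config)
    basis = build_basis([f"p{i}" for i in range(config.n_pops)])
    sim.run(burn_in)
    acc = []
    for _ in range(n_samples):
        acc.append(statistics_array(sim.freqs, basis.labels))
        sim.run(sample_every)
    rep_means = np.mean(np.stack(acc, axis=0), axis=0)  # (R, L)
    return _estimate(rep_means, basis.names())


# ---------------------------------------------------------------------------
# synthetic diploid panels (VCF + population map + recombination map)
# ---------------------------------------------------------------------------


@dataclass
class DiploidPanel:
    """A panel of independent SNP pairs with diploid genotype codes.

    ``genotypes`` has shape (n_sites, n_individuals) with values in
    {0, 1, 2} counting the derived allele; sites come in consecutive pairs.
    """

    chrom: np.ndarray  # per site, chromosome name index
    chrom_names: list[str]
    positions: np.ndarray  # per site, 1-based bp
    genotypes: np.ndarray
    samples: list[str]
    sample_pops: list[str]
    pair_r: np.ndarray  # true per-generation r per pair
    map_rate_cm_per_mb: float

    def write_vcf(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for name in self.chrom_names:
                length = int(self.positions[self.chrom == self.chrom_names.index(name)].max()) + 10**6
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            gt_strings = np.array(["0/0", "0/1", "1/1", "./."])
            codes = np.where(self.genotypes < 0, 3, self.genotypes)
            for s in range(self.genotypes.shape[0]):
                row = "\t".join(gt_strings[codes[s]])
                fh.write(
                    f"{self.chrom_names[self.chrom[s]]}\t{self.positions[s]}\t.\tA\tT\t.\tPASS\t.\tGT\t{row}\n"
                )

    def to_genotype_matrix(self):
        """In-memory GenotypeMatrix view (identical to the VCF round-trip)."""
        from .genotype_stats import GenotypeMatrix

        return GenotypeMatrix(
            chrom=self.chrom.copy(),
            chrom_names=list(self.chrom_names),
            positions=self.positions.copy(),
            genotypes=self.genotypes.astype(np.int8),
            samples=list(self.samples),
            pop_of=dict(zip(self.samples, self.sample_pops)),
        )

    def recombination_map(self):
        """Matching uniform-rate RecombinationMap object."""
        from .genotype_stats import RecombinationMap

        length = int(self.positions.max()) + 10**6
        return RecombinationMap.uniform(
            self.chrom_names, self.map_rate_cm_per_mb, length_bp=length
        )

    def write_popmap(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tpopulation\n")
            for s, p in zip(self.samples, self.sample_pops):
                fh.write(f"{s}\t{p}\n")

    def write_recmap(self, path) -> None:
        """HapMap-format text map: chrom, pos, rate (cM/Mb), cumulative cM."""
        with open(path, "w") as fh:
            fh.write("Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)\n")
            rate = self.map_rate_cm_per_mb
            for c, name in enumerate(self.chrom_names):
                sel = self.chrom == c
                last = int(self.positions[sel].max()) + 10**6
                for pos in (1, last):
                    cum = (pos - 1) * rate * 1e-6
                    fh.write(f"{name}\t{pos}\t{rate:.6f}\t{cum:.10f}\n")


def simulate_diploid_panel(
    config: WFConfig,
    n_pairs: int,
    sample_sizes: dict | Sequence[int],
    pop_names: Sequence[str] | None = None,
    pairs_per_chrom: int = 500,
    map_rate_cm_per_mb: float = 1.0,
    pair_spacing_bp: int = 2_000_000,
) -> DiploidPanel:
    """Simulate independent SNP-pair systems and sample diploid genotypes.

    Each pair is one replicate of the two-locus system (``config.r`` may be an
    array of length ``n_pairs`` for per-pair recombination distances).
    Diploid individuals are formed by random union of gametes; genotype codes
    count the derived allele.  Sites are laid out so that the within-pair bp
    distance reproduces the true ``r`` under a uniform map of
    ``map_rate_cm_per_mb``, while distinct pairs are separated by
    ``pair_spacing_bp`` (far beyond any sensible ``r_max``); chromosomes of
    ``pairs_per_chrom`` pairs provide natural bootstrap blocks.
    """
    P = config.n_pops
    pop_names = list(pop_names) if pop_names is not None else [f"pop{i}" for i in range(P)]
    if isinstance(sample_sizes, dict):
        n_d = [int(sample_sizes[p]) for p in pop_names]
    else:
        n_d = [int(x) for x in sample_sizes]
    for i, nd in enumerate(n_d):
        if nd > config.pop_sizes[i]:
            raise WFError("cannot sample more diploids than the population contains")
    cfg = WFConfig(
        pop_sizes=config.pop_sizes,
        r=np.broadcast_to(np.asarray(config.r, dtype=float), (n_pairs,)).copy(),
        u=config.u,
        mig=config.mig,
        init=config.init,
        generations=config.generations,
        replicates=n_pairs,
        seed=config.seed,
    )
    sim = TwoLocusWF(cfg)
    sim.run(config.generations)
    return sample_panel_from_freqs(
        sim.freqs,
        sim.r,
        n_d,
        pop_names,
        rng=sim.rng,
        pairs_per_chrom=pairs_per_chrom,
        map_rate_cm_per_mb=map_rate_cm_per_mb,
        pair_spacing_bp=pair_spacing_bp,
    )


def sample_panel_from_freqs(
    freqs: np.ndarray,
    pair_r: np.ndarray,
    n_d: Sequence[int],
    pop_names: Sequence[str],
    rng: np.random.Generator,
    pairs_per_chrom: int = 500,
    map_rate_cm_per_mb: float = 1.0,
    pair_spacing_bp: int = 2_000_000,
) -> DiploidPanel:
    """Draw diploid genotypes (random union of gametes) from frequency states."""
    n_pairs, P, _ = freqs.shape
    samples, sample_pops = [], []
    geno_cols = []
    for i, pop in enumerate(pop_names):
        nd = n_d[i]
        samples += [f"{pop}_{k}" for k in range(nd)]
        sample_pops += [pop] * nd
        cum = np.cumsum(freqs[:, i, :], axis=1)
        cum[:, -1] = 1.0
        draws = rng.random((n_pairs, nd, 2))
        hap = (draws[..., :, :, None] < cum[:, None, None, :]).argmax(axis=-1)
        # haplotype index order AB, Ab, aB, ab: derived-A at left for 0,1; derived-B at right for 0,2
        left = (hap <= 1).sum(axis=-1)  # per pair, per individual: 0..2
        right = ((hap == 0) | (hap == 2)).sum(axis=-1)
        geno_cols.append(np.stack([left, right], axis=-1))  # (n_pairs, nd, 2)
    geno = np.concatenate(geno_cols, axis=1)  # (n_pairs, total_nd, 2)
    n_ind = geno.shape[1]
    genotypes = np.empty((2 * n_pairs, n_ind), dtype=np.int8)
    genotypes[0::2] = geno[:, :, 0]
    genotypes[1::2] = geno[:, :, 1]
    # genomic layout
    r_per_bp = map_rate_cm_per_mb * 1e-8
    pair_idx = np.arange(n_pairs)
    chrom_of_pair = pair_idx // pairs_per_chrom
    within = pair_idx % pairs_per_chrom
    left_pos = 1 + within * pair_spacing_bp
    dist_bp = np.maximum(1, np.round(np.asarray(pair_r) / r_per_bp).astype(np.int64))
    right_pos = left_pos + dist_bp
    positions = np.empty(2 * n_pairs, dtype=np.int64)
    positions[0::2] = left_pos
    positions[1::2] = right_pos
    chrom = np.repeat(chrom_of_pair, 2).astype(np.int64)
    chrom_names = [f"chr{c + 1}" for c in range(int(chrom_of_pair.max()) + 1)]
    return DiploidPanel(
        chrom=chrom,
        chrom_names=chrom_names,
        positions=positions,
        genotypes=genotypes,
        samples=samples,
        sample_pops=sample_pops,
        pair_r=np.asarray(pair_r, dtype=float),
        map_rate_cm_per_mb=map_rate_cm_per_mb,
    )
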