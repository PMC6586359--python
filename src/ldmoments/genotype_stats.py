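"""Genome-wide binned two-locus statistics from unphased diploid genotypes.

Haplotype-based statistics (D^2, Dz, pi2, H and their cross-population
analogues) cannot be computed directly from unphased genotypes.  Instead,
every basis statistic gets an *unbiased estimator* built from per-population
genotype counts at a SNP pair: assuming random union of gametes within each
population, the expectation of any product of falling factorials of the nine
two-locus genotype counts is an exact polynomial in that population's
haplotype frequencies; inverting this linear map (exact rational arithmetic,
derived symbolically once per number of populations) yields, for each basis
statistic, a polynomial in genotype counts whose sampling expectation equals
the population statistic for every haplotype-frequency state.  The classical
genotype-count estimator D-hat of Weir is provided as well; it is biased for
D, which is precisely why the derived bias-corrected combinations are used
for the genome-wide averages.

The rest of the module handles the practical pipeline: reading VCF genotypes
and a HapMap-format recombination map, assigning SNP pairs to
recombination-distance bins (r from linearly interpolated cumulative map
distance), averaging raw pair statistics per bin, sigma_d^2-style
normalization by one population's pi2, and a genomic block bootstrap for the
covariance of the binned statistic vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._polynomial import LinearBasisSolver, Monomial, Poly, falling
from .basis import (
    BasisError,
    MomentBasis,
    build_basis,
    hap_symbol,
    label_polynomial,
)
from .operators import reduce_simplex


class DataStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotype categories
# ---------------------------------------------------------------------------

# category index c = 3*gL + gR, where gL, gR in {0,1,2} count the focal
# (ALT/derived) allele at the left and right locus
N_CATEGORIES = 9


def _category_probabilities(pop: int) -> list[Poly]:
    """P(genotype category) as polynomials in haplotype frequencies (random
    union of gametes)."""
    x = [Poly.sym(hap_symbol(pop, h)) for h in ("AB", "Ab", "aB", "ab")]
    # haplotype h carries focal-left if h in {AB, Ab}, focal-right if {AB, aB}
    left = [1, 1, 0, 0]
    right = [1, 0, 1, 0]
    probs = [Poly() for _ in range(N_CATEGORIES)]
    for h1 in range(4):
        for h2 in range(4):
            gl = left[h1] + left[h2]
            gr = right[h1] + right[h2]
            probs[3 * gl + gr] = probs[3 * gl + gr] + x[h1] * x[h2]
    return probs


def weir_D_hat(counts, n_d):
    """The genotype-count estimator of D (biased; used as a raw statistic).

    ``counts`` indexes the nine genotype categories ``c = 3*gL + gR`` (counts
    of the focal allele at left/right locus); supports vectorized arrays with
    the category axis last.  ``n_d`` is the number of diploids.
    """
    counts = np.asarray(counts, dtype=float)
    n_d = np.asarray(n_d, dtype=float)
    if np.any(n_d <= 0):
        raise DataStatsError("n_d must be positive")
    c = counts
    joint = 2 * c[..., 8] + c[..., 7] + c[..., 5] + 0.5 * c[..., 4]
    gl = np.array([i // 3 for i in range(9)], dtype=float)
    gr = np.array([i % 3 for i in range(9)], dtype=float)
    nA = (c * gl).sum(axis=-1)
    nB = (c * gr).sum(axis=-1)
    return joint / (2 * n_d) - (nA / (2 * n_d)) * (nB / (2 * n_d))


# ---------------------------------------------------------------------------
# symbolic derivation of unbiased estimators
# ---------------------------------------------------------------------------

# a candidate is a per-population multiset of genotype categories b_g; its
# runtime value is prod_g falling(n_g, b_g) / falling(n_d, sum b_g), whose
# expectation under multinomial sampling is exactly prod_g P_g^{b_g}
Candidate = tuple[tuple[int, int], ...]  # ((category, order), ...)


def _candidates(max_order: int) -> list[Candidate]:
    out: list[Candidate] = [()]
    if max_order >= 1:
        out += [((g, 1),) for g in range(N_CATEGORIES)]
    if max_order >= 2:
        for g in range(N_CATEGORIES):
            for h in range(g, N_CATEGORIES):
                out.append(((g, 2),) if g == h else ((g, 1), (h, 1)))
    return out


@lru_cache(maxsize=None)
def _pop_solver(pop: int, max_order: int):
    """Solver projecting pop-``pop`` polynomials onto candidate expectations."""
    probs = [reduce_simplex(p, pop + 1) for p in _category_probabilities(pop)]
    cands = _candidates(max_order)
    expectations = []
    for cand in cands:
        e = Poly.const(1)
        for g, order in cand:
            e = e * probs[g] ** order
        expectations.append(e)
    return cands, LinearBasisSolver(expectations, cands, allow_dependent=True)


def _pop_part(mono: Monomial, pop_syms: set[str]) -> tuple[Monomial, Monomial]:
    mine = tuple((s, e) for s, e in mono if s in pop_syms)
    rest = tuple((s, e) for s, e in mono if s not in pop_syms)
    return mine, rest


def _tensor_resolve(target: Poly, pops: list[int], max_orders: dict[int, int]):
    """Express ``target`` as sum of products of per-population candidate
    expectations; returns {(cand_pop0, cand_pop1, ...): Fraction}."""
    if not pops:
        const = target.constant_part()
        if Poly.const(const) != target:
            raise DataStatsError("estimator derivation: residual cross terms")
        return {(): const} if const else {}
    pop, rest_pops = pops[0], pops[1:]
    syms = {hap_symbol(pop, h) for h in ("AB", "Ab", "aB")}
    groups: dict[Monomial, Poly] = {}
    for mono, coeff in target.terms.items():
        mine, rest = _pop_part(mono, syms)
        groups.setdefault(mine, Poly())._iadd_term(rest, coeff)
    cands, solver = _pop_solver(pop, max_orders[pop])
    gammas = solver.project_vector(groups)
    # verify: reconstruct and compare exactly
    recon = Poly()
    for cand, gamma in gammas.items():
        idx = cands.index(cand)
        recon = recon + solver.basis_polys[idx] * gamma
    if recon != target:
        raise DataStatsError("estimator derivation: target outside estimable span")
    out = {}
    for cand, gamma in gammas.items():
        gamma = gamma if isinstance(gamma, Poly) else Poly.const(gamma)
        for combo, coeff in _tensor_resolve(gamma, rest_pops, max_orders).items():
            key = (cand,) + combo
            out[key] = out.get(key, Fraction(0)) + coeff
    return {k: v for k, v in out.items() if v}


def _flip_category(c: int, flip_left: bool, flip_right: bool) -> int:
    gl, gr = c // 3, c % 3
    if flip_left:
        gl = 2 - gl
    if flip_right:
        gr = 2 - gr
    return 3 * gl + gr


def _symmetrize_alleles(combos: dict) -> dict:
    """Average an estimator over the allele-relabeling group.

    Every basis statistic is invariant under relabeling the counted allele at
    either locus, but a particular solution of the (non-unique) estimator
    system need not be; averaging the four relabeled copies keeps
    unbiasedness and makes the invariance exact, table by table.
    """
    out: dict = {}
    for combo, coeff in combos.items():
        for flip_left in (False, True):
            for flip_right in (False, True):
                key = tuple(
                    tuple(
                        sorted(
                            (_flip_category(g, flip_left, flip_right), o)
                            for g, o in cand
                        )
                    )
                    for cand in combo
                )
                out[key] = out.get(key, Fraction(0)) + coeff / 4
    return {k: v for k, v in out.items() if v}


@lru_cache(maxsize=None)
def pair_estimator_formulas(n_pops: int):
    """Unbiased genotype-count estimator for every basis statistic.

    Returns ``(labels, formulas)`` where each formula is a list of
    ``(coefficient, ((pop, candidate), ...))`` terms; candidate values are the
    normalized falling-factorial products described in the module docstring.
    Derived symbolically once and cached.
    """
    basis = build_basis([f"p{i}" for i in range(n_pops)])
    pops = list(range(n_pops))
    labels, formulas = [], []
    for lbl in basis.labels:
        if lbl.family == "ONE":
            continue
        target = reduce_simplex(label_polynomial(lbl, n_pops), n_pops)
        base_orders = {}
        for pop in pops:
            syms = {hap_symbol(pop, h) for h in ("AB", "Ab", "aB")}
            deg = target.degree(syms)
            base_orders[pop] = (deg + 1) // 2
        # phase-ambiguous parts (e.g. a bare D, or p*q within one population)
        # need products of two count factors even at frequency-degree two, so
        # allow one extra factorial order where the minimal choice fails
        combos = None
        for bump in (0, 1, 2):
            try:
                combos = _tensor_resolve(
                    target, pops, {p: o + bump for p, o in base_orders.items()}
                )
                break
            except DataStatsError:
                continue
        if combos is None:
            raise DataStatsError(
                f"no unbiased genotype estimator found for {lbl.to_string()}"
            )
        combos = _symmetrize_alleles(combos)
        terms = []
        for combo, coeff in combos.items():
            factors = tuple(
                (pop, cand) for pop, cand in zip(pops, combo) if cand
            )
            terms.append((coeff, factors))
        labels.append(lbl.to_string())
        formulas.append(terms)
    return labels, formulas


def evaluate_pair_statistics(
    counts: np.ndarray, n_d: np.ndarray, n_pops: int
) -> tuple[list[str], np.ndarray]:
    """Evaluate the unbiased estimators on genotype-count tables.

    ``counts``: (n_pairs, P, 9) genotype-category counts per population;
    ``n_d``: (n_pairs, P) diploids with complete data.  Returns labels and an
    (n_pairs, n_stats) array; pairs where any involved population has fewer
    than two diploids yield NaN for the affected statistics.
    """
    counts = np.asarray(counts, dtype=float)
    n_d = np.asarray(n_d, dtype=float)
    labels, formulas = pair_estimator_formulas(n_pops)
    # precompute candidate values per population
    cache: dict[tuple[int, Candidate], np.ndarray] = {}

    def cand_value(pop: int, cand: Candidate) -> np.ndarray:
        key = (pop, cand)
        if key not in cache:
            order = sum(o for _, o in cand)
            num = np.ones(counts.shape[0])
            for g, o in cand:
                num = num * falling(counts[:, pop, g], o)
            denom = falling(n_d[:, pop], order)
            with np.errstate(divide="ignore", invalid="ignore"):
                cache[key] = np.where(denom > 0, num / np.where(denom == 0, 1, denom), np.nan)
        return cache[key]

    out = np.empty((counts.shape[0], len(labels)))
    for s, terms in enumerate(formulas):
        acc = np.zeros(counts.shape[0])
        for coeff, factors in terms:
            val = np.full(counts.shape[0], float(coeff))
            for pop, cand in factors:
                val = val * cand_value(pop, cand)
            acc = acc + val
        out[:, s] = acc
    return labels, out


def pair_statistics(counts, n_d, n_pops: int | None = None):
    """Unbiased basis-statistic estimates for a single SNP pair.

    ``counts``: (P, 9) genotype-category counts; ``n_d``: per-population
    diploid counts.  Returns {label: value}.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    P = n_pops or counts.shape[0]
    n_d = np.atleast_1d(np.asarray(n_d, dtype=float))
    labels, values = evaluate_pair_statistics(counts[None], n_d[None], P)
    return dict(zip(labels, values[0]))


# ---------------------------------------------------------------------------
# genotype data and recombination maps
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes {0,1,2,-1(missing)} with site coordinates."""

    chrom: np.ndarray  # per site: index into chrom_names
    chrom_names: list[str]
    positions: np.ndarray  # 1-based bp, sorted within chromosome
    genotypes: np.ndarray  # (n_sites, n_individuals), int8
    samples: list[str]
    pop_of: dict[str, str]

    def __post_init__(self):
        for c in range(len(self.chrom_names)):
            sel = self.chrom == c
            if np.any(np.diff(self.positions[sel]) < 0):
                raise DataStatsError("positions must be sorted within chromosomes")

    def population_columns(self, populations: Sequence[str]) -> dict[str, np.ndarray]:
        cols = {p: [] for p in populations}
        for idx, s in enumerate(self.samples):
            p = self.pop_of.get(s)
            if p in cols:
                cols[p].append(idx)
        return {p: np.array(v, dtype=int) for p, v in cols.items()}


def read_vcf(vcf_path, popmap_path) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF plus a sample->population TSV."""
    from cyvcf2 import VCF

    popmap = pd.read_csv(popmap_path, sep="\t")
    pop_of = dict(zip(popmap.iloc[:, 0].astype(str), popmap.iloc[:, 1].astype(str)))
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    chrom_names: list[str] = []
    chrom_idx: dict[str, int] = {}
    chroms, positions, rows = [], [], []
    for variant in vcf:
        name = variant.CHROM
        if name not in chrom_idx:
            chrom_idx[name] = len(chrom_names)
            chrom_names.append(name)
        chroms.append(chrom_idx[name])
        positions.append(variant.POS)
        gt = variant.gt_types.astype(np.int8)  # 0,1,2 and 3=unknown with gts012
        gt[gt == 3] = -1
        rows.append(gt)
    vcf.close()
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=np.int64),
        chrom_names=chrom_names,
        positions=np.array(positions, dtype=np.int64),
        genotypes=np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8),
        samples=samples,
        pop_of=pop_of,
    )


@dataclass
class RecombinationMap:
    """Cumulative genetic map per chromosome, linearly interpolated in bp."""

    chrom_positions: dict[str, np.ndarray]
    chrom_morgans: dict[str, np.ndarray]

    @staticmethod
    def read(path) -> "RecombinationMap":
        """HapMap-style text: chrom, pos(bp), rate(cM/Mb), cumulative cM."""
        df = pd.read_csv(path, sep=r"\s+")
        cpos, cmor = {}, {}
        for name, grp in df.groupby(df.columns[0], sort=False):
            pos = grp.iloc[:, 1].to_numpy(dtype=float)
            cm = grp.iloc[:, 3].to_numpy(dtype=float)
            if np.any(np.diff(pos) <= 0) or np.any(np.diff(cm) < 0):
                raise DataStatsError(f"map for {name} is not monotone")
            cpos[str(name)] = pos
            cmor[str(name)] = cm / 100.0  # Morgans
        return RecombinationMap(cpos, cmor)

    @staticmethod
    def uniform(chrom_names, rate_cm_per_mb: float, length_bp: int = 2**40) -> "RecombinationMap":
        cpos = {c: np.array([1.0, float(length_bp)]) for c in chrom_names}
        cmor = {
            c: np.array([0.0, (length_bp - 1) * rate_cm_per_mb * 1e-8])
            for c in chrom_names
        }
        return RecombinationMap(cpos, cmor)

    def interpolate(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Cumulative position in Morgans; NaN outside the map span."""
        if chrom not in self.chrom_positions:
            return np.full(len(positions), np.nan)
        xp, fp = self.chrom_positions[chrom], self.chrom_morgans[chrom]
        pos = np.asarray(positions, dtype=float)
        out = np.interp(pos, xp, fp)
        out[(pos < xp[0]) | (pos > xp[-1])] = np.nan
        return out


# ---------------------------------------------------------------------------
# pair enumeration and binning
# ---------------------------------------------------------------------------


def assign_bins(r: np.ndarray, bin_edges: Sequence[float]) -> np.ndarray:
    """Bin index per pair for half-open bins [r_k, r_{k+1}); -1 = outside."""
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.searchsorted(edges, r, side="right") - 1
    idx[(r < edges[0]) | (r >= edges[-1])] = -1
    return idx


def enumerate_pairs(
    gm: GenotypeMatrix,
    recmap: RecombinationMap,
    r_min: float,
    r_max: float,
):
    """All within-chromosome SNP pairs with r_min <= r <= r_max.

    Returns (left_site, right_site, r) index arrays; sites outside the map
    span are excluded (counted in a warning).
    """
    lefts, rights, rs = [], [], []
    n_excluded = 0
    for c, name in enumerate(gm.chrom_names):
        sel = np.flatnonzero(gm.chrom == c)
        if sel.size < 2:
            continue
        g = recmap.interpolate(name, gm.positions[sel])
        ok = np.isfinite(g)
        n_excluded += int((~ok).sum())
        sel, g = sel[ok], g[ok]
        # two-pointer window on the (sorted) cumulative map positions
        j0 = np.searchsorted(g, g + r_min, side="left")
        j1 = np.searchsorted(g, g + r_max, side="right")
        for a in range(len(sel)):
            lo, hi = max(j0[a], a + 1), j1[a]
            if hi > lo:
                lefts.append(np.full(hi - lo, sel[a]))
                rights.append(sel[lo:hi])
                rs.append(g[lo:hi] - g[a])
    if n_excluded:
        warnings.warn(f"{n_excluded} SNPs outside the recombination map span were excluded")
    if not lefts:
        return (np.empty(0, dtype=int),) * 2 + (np.empty(0),)
    return np.concatenate(lefts), np.concatenate(rights), np.concatenate(rs)


def genotype_pair_counts(
    gm: GenotypeMatrix,
    lefts: np.ndarray,
    rights: np.ndarray,
    populations: Sequence[str],
):
    """Per-population 9-category genotype counts for SNP pairs.

    Missing data is handled pairwise-complete: an individual contributes to a
    pair only if both sites are called.  Returns (counts (n_pairs, P, 9),
    n_d (n_pairs, P)).
    """
    cols = gm.population_columns(populations)
    n_pairs = len(lefts)
    P = len(populations)
    counts = np.zeros((n_pairs, P, N_CATEGORIES), dtype=np.int32)
    n_d = np.zeros((n_pairs, P), dtype=np.int32)
    for pi, pop in enumerate(populations):
        idx = cols[pop]
        if idx.size == 0:
            raise DataStatsError(f"no samples assigned to population {pop!r}")
        gl = gm.genotypes[np.ix_(lefts, idx)].astype(np.int16)
        gr = gm.genotypes[np.ix_(rights, idx)].astype(np.int16)
        valid = (gl >= 0) & (gr >= 0)
        combo = np.where(valid, 3 * gl + gr, N_CATEGORIES)
        for cat in range(N_CATEGORIES):
            counts[:, pi, cat] = (combo == cat).sum(axis=1)
        n_d[:, pi] = valid.sum(axis=1)
    return counts, n_d


# ---------------------------------------------------------------------------
# aggregation, normalization, bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BinnedStatistics:
    """Binned, optionally normalized statistic vectors with covariance."""

    bin_edges: np.ndarray
    labels: list[str]
    means: np.ndarray  # (n_bins, k)
    cov: np.ndarray | None  # (n_bins, k, k)
    n_pairs: np.ndarray  # per bin
    normalization: str = "raw"
    replicates: np.ndarray | None = None  # (n_boot, n_bins, k)
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def column(self, label: str) -> np.ndarray:
        return self.means[:, self.labels.index(label)]

    def constant_labels(self) -> list[str]:
        """Rows that are identically one under the chosen normalization."""
        if self.normalization == "raw":
            return []
        i = self.meta.get("norm_index_1based")
        if i is None:
            return []
        return [f"pi2_{i}_{i}_{i}_{i}", f"H_{i}_{i}"]

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        df = pd.DataFrame(self.means, columns=self.labels)
        df.insert(0, "bin_left", self.bin_edges[:-1])
        df.insert(1, "bin_right", self.bin_edges[1:])
        df.insert(2, "n_pairs", self.n_pairs)
        df.to_csv(prefix.with_suffix(".means.tsv"), sep="\t", index=False)
        if self.cov is not None:
            rows = []
            for b in range(self.n_bins):
                for i, li in enumerate(self.labels):
                    for j, lj in enumerate(self.labels):
                        rows.append((b, li, lj, self.cov[b, i, j]))
            pd.DataFrame(rows, columns=["bin", "row", "col", "cov"]).to_csv(
                prefix.with_suffix(".cov.tsv"), sep="\t", index=False
            )
        with open(prefix.with_suffix(".meta.json"), "w") as fh:
            json.dump(
                {
                    "bin_edges": list(map(float, self.bin_edges)),
                    "labels": self.labels,
                    "n_pairs": [int(x) for x in self.n_pairs],
                    "normalization": self.normalization,
                    **{k: v for k, v in self.meta.items()},
                },
                fh,
                indent=1,
            )


def _normalize_rows(
    sums: np.ndarray, npairs: np.ndarray, labels: list[str], norm_pop_idx: int | None
) -> np.ndarray:
    """Bin means from block sums; optional sigma_d^2-style normalization."""
    with np.errstate(divide="ignore", invalid="ignore"):
        means = sums / npairs[:, None]
    if norm_pop_idx is None:
        return means
    i = norm_pop_idx + 1
    pi2_col = labels.index(f"pi2_{i}_{i}_{i}_{i}")
    h_col = labels.index(f"H_{i}_{i}")
    is_h = np.array([l.startswith("H_") for l in labels])
    denom = np.where(is_h[None, :], means[:, [h_col]], means[:, [pi2_col]])
    return means / denom


def aggregate_and_normalize(
    stats: np.ndarray,
    bin_idx: np.ndarray,
    n_bins: int,
    labels: list[str],
    norm_pop_idx: int | None,
    bin_edges: np.ndarray,
    normalization_name: str,
) -> BinnedStatistics:
    """Per-bin means of raw pair statistics, optionally normalized."""
    k = stats.shape[1]
    sums = np.zeros((n_bins, k))
    npairs = np.zeros(n_bins)
    valid = bin_idx >= 0
    finite = np.all(np.isfinite(stats), axis=1)
    use = valid & finite
    np.add.at(sums, bin_idx[use], stats[use])
    np.add.at(npairs, bin_idx[use], 1)
    if np.any(npairs == 0):
        warnings.warn("empty recombination bins flagged as missing (NaN)")
    means = _normalize_rows(sums, npairs, labels, norm_pop_idx)
    return BinnedStatistics(
        bin_edges=np.asarray(bin_edges, dtype=float),
        labels=labels,
        means=means,
        cov=None,
        n_pairs=npairs,
        normalization=normalization_name,
        meta={"norm_index_1based": None if norm_pop_idx is None else norm_pop_idx + 1},
    )


def bootstrap_covariance(
    stats: np.ndarray,
    bin_idx: np.ndarray,
    block_idx: np.ndarray,
    n_bins: int,
    labels: list[str],
    norm_pop_idx: int | None,
    n_boot: int,
    seed: int,
    bin_edges: np.ndarray,
    normalization_name: str,
) -> BinnedStatistics:
    """Block bootstrap over contiguous genomic blocks.

    Pairs stay attached to their block (left-SNP rule chosen upstream), which
    preserves the local dependence between neighboring/overlapping pairs;
    blocks are resampled with replacement and the full per-bin normalized
    vector is recomputed per replicate.
    """
    if n_boot < 2:
        raise DataStatsError("n_boot must be >= 2")
    k = stats.shape[1]
    valid = (bin_idx >= 0) & np.all(np.isfinite(stats), axis=1)
    blocks = np.unique(block_idx[valid])
    if blocks.size < 2:
        raise DataStatsError("need at least two genomic blocks for the bootstrap")
    B = blocks.size
    remap = {b: i for i, b in enumerate(blocks)}
    cell = np.array([remap[b] for b in block_idx[valid]]) * n_bins + bin_idx[valid]
    sums = np.zeros((B * n_bins, k))
    npairs = np.zeros(B * n_bins)
    np.add.at(sums, cell, stats[valid])
    np.add.at(npairs, cell, 1)
    sums = sums.reshape(B, n_bins, k)
    npairs = npairs.reshape(B, n_bins)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, n_bins, k))
    for b in range(n_boot):
        pick = rng.integers(0, B, size=B)
        s = sums[pick].sum(axis=0)
        n = npairs[pick].sum(axis=0)
        reps[b] = _normalize_rows(s, n, labels, norm_pop_idx)
    point = aggregate_and_normalize(
        stats, bin_idx, n_bins, labels, norm_pop_idx, bin_edges, normalization_name
    )
    cov = np.empty((n_bins, k, k))
    for i in range(n_bins):
        x = reps[:, i, :]
        ok = np.all(np.isfinite(x), axis=1)
        if ok.sum() >= 2:
            cov[i] = np.cov(x[ok].T, ddof=1)
        else:
            cov[i] = np.nan
    point.cov = cov
    point.replicates = reps
    point.meta["n_boot"] = n_boot
    point.meta["seed"] = seed
    point.meta["n_blocks"] = int(B)
    return point


# ---------------------------------------------------------------------------
# high-level pipeline
# ---------------------------------------------------------------------------


def compute_binned_statistics(
    gm: GenotypeMatrix,
    recmap: RecombinationMap,
    populations: Sequence[str],
    bin_edges: Sequence[float] | None = None,
    r_min: float = 1e-5,
    r_max: float = 2e-3,
    normalization: str | None = None,
    n_boot: int = 200,
    seed: int = 0,
    block_span_bp: int = 5_000_000,
    block_by_chromosome: bool = False,
    min_diploids: int = 20,
) -> BinnedStatistics:
    """End-to-end: pairs -> estimators -> bins -> normalization -> bootstrap.

    Default bin edges are 12 log-spaced bins over the default r bounds
    [1e-5, 2e-3]; pairs with any involved population below ``min_diploids``
    complete diploids are skipped.  ``normalization`` is a population label
    (sigma_d^2-style) or None for raw statistics.
    """
    populations = list(populations)
    if bin_edges is None:
        bin_edges = np.logspace(np.log10(r_min), np.log10(r_max), 13)
    bin_edges = np.asarray(bin_edges, dtype=float)
    lefts, rights, r = enumerate_pairs(gm, recmap, r_min, r_max)
    if lefts.size == 0:
        raise DataStatsError("no SNP pairs within the requested r range")
    bin_idx = assign_bins(r, bin_edges)
    counts, n_d = genotype_pair_counts(gm, lefts, rights, populations)
    enough = np.all(n_d >= max(2, min_diploids), axis=1)
    n_skipped = int((~enough).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} pairs skipped (below the diploid minimum)")
    labels, stats = evaluate_pair_statistics(counts, n_d, len(populations))
    bin_idx = np.where(enough, bin_idx, -1)
    if block_by_chromosome:
        block_idx = gm.chrom[lefts]
    else:
        block_idx = gm.chrom[lefts] * 10**6 + (gm.positions[lefts] - 1) // block_span_bp
    norm_pop_idx = populations.index(normalization) if normalization else None
    out = bootstrap_covariance(
        stats,
        bin_idx,
        block_idx,
        len(bin_edges) - 1,
        labels,
        norm_pop_idx,
        n_boot,
        seed,
        bin_edges,
        normalization or "raw",
    )
    out.meta.update(
        {
            "populations": populations,
            "r_min": r_min,
            "r_max": r_max,
            "min_diploids": min_diploids,
            "n_pairs_total": int(lefts.size),
            "n_pairs_skipped": n_skipped,
        }
    )
    return out
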