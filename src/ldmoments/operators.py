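"""Sparse drift, migration, recombination and mutation operators.

Operator matrices on a :class:`~ldmoments.basis.MomentBasis` are not
hand-transcribed.  They are generated by *enumeration*: each basis statistic
is a polynomial in per-population haplotype frequencies, and its expectation
after one Wright-Fisher generation is computed symbolically, keeping terms to
leading order in the small quantities ``1/2N_i`` (drift), ``r``
(recombination), ``m_ij`` (migration) and ``u`` (mutation) and discarding all
of their cross products.  The resulting image polynomial is re-expressed
exactly (rational arithmetic) as a linear combination of basis statistics,
which yields one matrix row per statistic.  The machinery works for any
number of populations; for a single population it reproduces the classical
printed drift matrix ``[[-3,1,1],[4,-5,0],[0,1,-2]]/(2N)`` and recombination
matrix ``r*diag(-2,-1,0)`` of the (D^2, Dz, pi2) system exactly.

Per-generation update order: recombination, then migration (both deterministic
frequency updates), then multinomial drift; mutation under the infinite-sites
model is a separate additive source term (a new mutation arises on a random
background haplotype in one population and is paired with standing variation
at the other locus).  Differences between update orderings are above leading
order.

Internally the continuous-time scaling of the model measures time in units of
``2 N_ref`` generations, so that the assembled generator is
``A = sum_i D_i / nu_i + sum_ij Mtilde_ij M_ij + (rho/2) R + (theta/2) U``
with ``nu_i = N_i/N_ref``, ``mtilde_ij = 2 N_ref m_ij``, ``rho = 4 N_ref r``
and ``theta = 4 N_ref u``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from ._polynomial import LinearBasisSolver, Poly
from .basis import (
    HAPLOTYPES,
    BasisError,
    MomentBasis,
    MomentLabel,
    PopulationSet,
    build_basis,
    freq_p,
    freq_q,
    hap_symbol,
    label_polynomial,
    locus_swap_map,
    signed_d,
)


class OperatorError(ValueError):
    pass


class UnsupportedOrderError(OperatorError):
    pass


# ---------------------------------------------------------------------------
# small-parameter bookkeeping
# ---------------------------------------------------------------------------


def _eps(pop: int) -> str:
    return f"eps{pop}"  # 1/(2 N_pop), per generation


def _mig_sym(src: int, dst: int) -> str:
    return f"m_{src}_{dst}"  # P(lineage in dst has parent in src), per generation


def _small_weights(n_pops: int) -> dict[str, int]:
    weights = {"r": 1, "u": 1}
    for i in range(n_pops):
        weights[_eps(i)] = 1
        for j in range(n_pops):
            if i != j:
                weights[_mig_sym(i, j)] = 1
    return weights


def _subs_truncated(poly: Poly, mapping: dict[str, Poly], weights, max_order=1) -> Poly:
    """Substitute and expand, pruning beyond-leading-order terms eagerly."""
    out = Poly()
    for mono, coeff in poly.terms.items():
        term = Poly.const(coeff)
        for sym, exp in mono:
            repl = mapping.get(sym)
            base = repl if repl is not None else Poly.sym(sym)
            for _ in range(exp):
                term = (term * base).truncate(weights, max_order)
        out = out + term
    return out


# ---------------------------------------------------------------------------
# one-generation expectation
# ---------------------------------------------------------------------------


def _deterministic_mapping(n_pops: int) -> dict[str, Poly]:
    """Recombination followed by migration, composed, to leading order."""
    rec: dict[str, Poly] = {}
    for i in range(n_pops):
        d = signed_d(i) * Poly.sym("r")
        rec[hap_symbol(i, "AB")] = Poly.sym(hap_symbol(i, "AB")) - d
        rec[hap_symbol(i, "Ab")] = Poly.sym(hap_symbol(i, "Ab")) + d
        rec[hap_symbol(i, "aB")] = Poly.sym(hap_symbol(i, "aB")) + d
        rec[hap_symbol(i, "ab")] = Poly.sym(hap_symbol(i, "ab")) - d
    weights = _small_weights(n_pops)
    mapping: dict[str, Poly] = {}
    for j in range(n_pops):
        for hap in HAPLOTYPES:
            expr = Poly.sym(hap_symbol(j, hap))
            for i in range(n_pops):
                if i == j:
                    continue
                m = Poly.sym(_mig_sym(i, j))
                expr = expr + m * (
                    Poly.sym(hap_symbol(i, hap)) - Poly.sym(hap_symbol(j, hap))
                )
            # compose with recombination (cross terms r*m are dropped)
            mapping[hap_symbol(j, hap)] = _subs_truncated(expr, rec, weights)
    return mapping


def _drift_expectation(poly: Poly, n_pops: int) -> Poly:
    """Multinomial-resampling expectation, first order in each 1/(2N_i).

    For one population with sampled frequencies ``x_h = n_h / 2N`` and
    pre-drift frequencies ``y_h``,
    ``E[prod x_h^a_h] = prod y^a (1 - A(A-1)/2 * eps) +
    eps * sum_h C(a_h,2) y_h^{a_h-1} prod_{g!=h} y_g^{a_g}`` with
    ``A = sum a_h`` and ``eps = 1/(2N)``; populations are independent given
    the deterministic state, and corrections of order eps_i*eps_j are dropped.
    """
    weights = _small_weights(n_pops)
    pop_syms = [
        {hap_symbol(i, hap) for hap in HAPLOTYPES} for i in range(n_pops)
    ]
    out = Poly()
    for mono, coeff in poly.terms.items():
        base = Poly({mono: coeff})
        out = out + base
        if any(weights.get(s, 0) for s, _ in mono):
            continue  # already first order; drift corrections would be second
        exps = dict(mono)
        for i in range(n_pops):
            a = {s: e for s, e in exps.items() if s in pop_syms[i]}
            total = sum(a.values())
            if total < 2:
                continue
            eps = Poly.sym(_eps(i))
            corr = Poly.const(Fraction(-total * (total - 1), 2)) * base
            for s, e in a.items():
                if e >= 2:
                    reduced = dict(exps)
                    reduced[s] = e - 1
                    mono_red = tuple(sorted((k, v) for k, v in reduced.items() if v))
                    corr = corr + Poly(
                        {mono_red: coeff * Fraction(e * (e - 1), 2)}
                    )
            out = out + eps * corr
    return out.truncate(weights, 1)


def _mutation_source(poly: Poly, n_pops: int) -> Poly:
    """Infinite-sites mutation injection for a genome-wide pair statistic.

    A new mutation arising in population ``a`` (rate ``2 N_a u`` per
    generation) creates a site at frequency ``1/(2 N_a)`` on a random
    background haplotype; paired with standing variation at the other locus it
    injects new pairs into the statistic.  The coefficient of the first order
    in the new-site frequency, with the Bernoulli background averaged over the
    standing frequency, gives the source; it is proportional to ``u`` and
    independent of ``N``.
    """
    eps, xi = "mut_eps", "mut_xi"
    source = Poly()
    for locus in ("right", "left"):
        for a in range(n_pops):
            mapping: dict[str, Poly] = {}
            for i in range(n_pops):
                if locus == "right":
                    anc = freq_p(i)  # left-locus standing frequency
                    carrier, other = ("aB", "ab"), ("AB", "Ab")
                else:
                    anc = freq_q(i)
                    carrier, other = ("Ab", "ab"), ("AB", "aB")
                if i != a:
                    mapping[hap_symbol(i, other[0])] = Poly()
                    mapping[hap_symbol(i, carrier[0])] = Poly()
                    mapping[hap_symbol(i, other[1])] = anc
                    mapping[hap_symbol(i, carrier[1])] = 1 - anc
                else:
                    e, x = Poly.sym(eps), Poly.sym(xi)
                    mapping[hap_symbol(i, other[0])] = e * x
                    mapping[hap_symbol(i, carrier[0])] = e * (1 - x)
                    mapping[hap_symbol(i, other[1])] = anc - e * x
                    mapping[hap_symbol(i, carrier[1])] = (1 - anc) - e * (1 - x)
            image = poly.subs(mapping).coefficient(eps, 1)
            image = image.reduce_idempotent(xi).subs({xi: freq_p(a) if locus == "right" else freq_q(a)})
            source = source + image
    return source * Poly.sym("u")


def one_generation_expectation(poly: Poly, n_pops: int, include_mutation: bool = True) -> Poly:
    """E[statistic at t+1 | state at t] to leading order, with symbolic rates.

    The result is a polynomial in time-``t`` haplotype frequencies and the
    per-generation small symbols ``eps{i} = 1/(2N_i)``, ``r``, ``m_{i}_{j}``
    and ``u``.  Total degree above four is unsupported (the moment family used
    here closes at fourth order).
    """
    if poly.degree() > 4:
        raise UnsupportedOrderError("monomials of total degree > 4 are not supported")
    mapping = _deterministic_mapping(n_pops)
    weights = _small_weights(n_pops)
    image = _subs_truncated(poly, mapping, weights)
    image = _drift_expectation(image, n_pops)
    if include_mutation:
        image = image + _mutation_source(poly, n_pops)
    return image


# ---------------------------------------------------------------------------
# per-generation coefficient matrices (exact, cached per population count)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenerationStructure:
    """Exact per-generation operator coefficients for a P-population basis.

    ``drift[i]`` is the matrix multiplying ``1/(2N_i)``; ``recomb`` multiplies
    ``r``; ``migration[(i,j)]`` multiplies ``m_ij``; ``mutation`` multiplies
    ``u``.  Entries are ``{(row, col): Fraction}`` over basis positions.
    """

    n_pops: int
    labels: tuple[MomentLabel, ...]
    drift: tuple[dict, ...]
    recomb: dict
    migration: dict
    mutation: dict

    def matrix(self, component: dict) -> sp.csr_matrix:
        n = len(self.labels)
        if not component:
            return sp.csr_matrix((n, n))
        rows, cols, vals = zip(*[(r, c, float(v)) for (r, c), v in component.items()])
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def reduce_simplex(poly: Poly, n_pops: int) -> Poly:
    """Eliminate x_ab = 1 - x_AB - x_Ab - x_aB in every population.

    Haplotype frequencies live on a simplex, so statistic polynomials are
    only defined modulo the constraint; projection onto the basis requires a
    canonical coordinate system.
    """
    mapping = {
        hap_symbol(i, "ab"): 1
        - Poly.sym(hap_symbol(i, "AB"))
        - Poly.sym(hap_symbol(i, "Ab"))
        - Poly.sym(hap_symbol(i, "aB"))
        for i in range(n_pops)
    }
    return poly.subs(mapping)


def _basis_solver(n_pops: int) -> tuple[tuple[MomentLabel, ...], LinearBasisSolver]:
    dummy = build_basis([f"p{i}" for i in range(n_pops)])
    polys = [reduce_simplex(p, n_pops) for p in dummy.polynomials()]
    return dummy.labels, LinearBasisSolver(polys, list(range(len(polys))))


@lru_cache(maxsize=None)
def generation_structure(n_pops: int) -> GenerationStructure:
    labels, solver = _basis_solver(n_pops)
    polys = [label_polynomial(lbl, n_pops) for lbl in labels]
    weights = _small_weights(n_pops)
    swap = locus_swap_map(n_pops)
    drift = [dict() for _ in range(n_pops)]
    recomb: dict = {}
    migration: dict = {(i, j): {} for i in range(n_pops) for j in range(n_pops) if i != j}
    mutation: dict = {}
    for row, poly in enumerate(polys):
        image = one_generation_expectation(poly, n_pops) - poly
        image = reduce_simplex(image.symmetrized([{}, swap]), n_pops)
        parts = image.split_by(weights)
        zero_order = parts.pop(None, Poly())
        if zero_order:
            raise OperatorError(
                f"one-generation image of {labels[row]} has a zeroth-order mismatch"
            )
        for sym, part in parts.items():
            coeffs = solver.project(part)
            for col, value in coeffs.items():
                if sym == "r":
                    recomb[(row, col)] = value
                elif sym == "u":
                    mutation[(row, col)] = value
                elif sym.startswith("eps"):
                    drift[int(sym[3:])][(row, col)] = value
                else:
                    _, i, j = sym.split("_")
                    migration[(int(i), int(j))][(row, col)] = value
    return GenerationStructure(
        n_pops=n_pops,
        labels=labels,
        drift=tuple(drift),
        recomb=recomb,
        migration=migration,
        mutation=mutation,
    )


# ---------------------------------------------------------------------------
# scaled operators (time in units of 2 N_ref generations)
# ---------------------------------------------------------------------------


@dataclass
class RateParameters:
    """Scaled rates: nu_i = N_i/N_ref, mtilde_ij = 2*N_ref*m_ij (source i,
    destination j; zero diagonal), rho = 4*N_ref*r, theta = 4*N_ref*u."""

    nu: np.ndarray
    mig: np.ndarray | None = None
    rho: float = 0.0
    theta: float = 0.0

    def __post_init__(self):
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        P = self.nu.shape[0]
        if self.mig is None:
            self.mig = np.zeros((P, P))
        self.mig = np.asarray(self.mig, dtype=float)
        if self.mig.shape != (P, P):
            raise OperatorError(f"migration matrix shape {self.mig.shape} != ({P},{P})")
        if np.any(self.nu <= 0) or not np.all(np.isfinite(self.nu)):
            raise OperatorError("population sizes nu must be positive and finite")
        if np.any(self.mig < 0) or np.any(np.diag(self.mig) != 0):
            raise OperatorError("migration rates must be >= 0 with zero diagonal")
        if self.rho < 0:
            raise OperatorError("rho must be >= 0")
        if self.theta < 0:
            raise OperatorError("theta must be >= 0")

    @property
    def n_pops(self) -> int:
        return self.nu.shape[0]


@dataclass
class EvolutionOperator:
    basis: MomentBasis
    matrix: sp.csr_matrix

    def __post_init__(self):
        n = self.basis.size
        if self.matrix.shape != (n, n):
            raise OperatorError("operator dimension does not match basis size")
        self.matrix.eliminate_zeros()

    def __add__(self, other: "EvolutionOperator") -> "EvolutionOperator":
        if other.basis.size != self.basis.size:
            raise OperatorError("operator dimension mismatch")
        return EvolutionOperator(self.basis, (self.matrix + other.matrix).tocsr())

    def to_triplets(self) -> list[tuple[str, str, float]]:
        """Render as (row label, column label, coefficient) triplets."""
        names = self.basis.names()
        coo = self.matrix.tocoo()
        return [
            (names[i], names[j], float(v))
            for i, j, v in zip(coo.row, coo.col, coo.data)
        ]


def _check_basis(basis: MomentBasis, n: int):
    if len(basis.pops) != n:
        raise OperatorError(
            f"parameter dimension {n} does not match basis with {len(basis.pops)} populations"
        )


def build_drift(basis: MomentBasis, nu) -> EvolutionOperator:
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    if np.any(nu <= 0):
        raise OperatorError("population sizes nu must be positive")
    _check_basis(basis, nu.shape[0])
    struct = generation_structure(len(basis.pops))
    total = sp.csr_matrix((basis.size, basis.size))
    for i, nui in enumerate(nu):
        total = total + struct.matrix(struct.drift[i]) / nui
    return EvolutionOperator(basis, total.tocsr())


def build_recombination(basis: MomentBasis, rho: float) -> EvolutionOperator:
    if rho < 0:
        raise OperatorError("rho must be >= 0")
    struct = generation_structure(len(basis.pops))
    return EvolutionOperator(basis, (struct.matrix(struct.recomb) * (rho / 2.0)).tocsr())


def build_migration(basis: MomentBasis, mig) -> EvolutionOperator:
    mig = np.asarray(mig, dtype=float)
    P = len(basis.pops)
    if mig.shape != (P, P):
        raise OperatorError(f"migration matrix shape {mig.shape} != ({P},{P})")
    if np.any(mig < 0):
        raise OperatorError("migration rates must be >= 0")
    struct = generation_structure(P)
    total = sp.csr_matrix((basis.size, basis.size))
    for (i, j), comp in struct.migration.items():
        if mig[i, j]:
            total = total + struct.matrix(comp) * mig[i, j]
    return EvolutionOperator(basis, total.tocsr())


def build_mutation(basis: MomentBasis, theta: float) -> EvolutionOperator:
    if theta < 0:
        raise OperatorError("theta must be >= 0")
    struct = generation_structure(len(basis.pops))
    return EvolutionOperator(basis, (struct.matrix(struct.mutation) * (theta / 2.0)).tocsr())


def assemble(params: RateParameters, basis: MomentBasis) -> EvolutionOperator:
    """Scaled generator A of dy/dT = A y, T in units of 2*N_ref generations."""
    _check_basis(basis, params.n_pops)
    return EvolutionOperator(basis, sp.csr_matrix(assemble_dense(params)))


@lru_cache(maxsize=None)
def _dense_components(n_pops: int):
    """Dense float copies of the per-generation coefficient matrices."""
    struct = generation_structure(n_pops)
    n = len(struct.labels)

    def dense(component: dict) -> np.ndarray:
        A = np.zeros((n, n))
        for (r, c), v in component.items():
            A[r, c] = float(v)
        return A

    drift = np.stack([dense(d) for d in struct.drift])
    mig = np.zeros((n_pops, n_pops, n, n))
    for (i, j), comp in struct.migration.items():
        mig[i, j] = dense(comp)
    return drift, mig, dense(struct.recomb), dense(struct.mutation)


def assemble_dense(params: RateParameters) -> np.ndarray:
    """Dense scaled generator (fast path used by the integrator)."""
    drift, mig, recomb, mut = _dense_components(params.n_pops)
    A = np.tensordot(1.0 / params.nu, drift, axes=(0, 0))
    if params.mig.any():
        A += np.tensordot(params.mig.ravel(), mig.reshape(params.n_pops**2, *A.shape), axes=(0, 0))
    A += (params.rho / 2.0) * recomb
    A += (params.theta / 2.0) * mut
    return A


# ---------------------------------------------------------------------------
# the signed-D system (drift + recombination only; no closed form with
# migration at this order, so migration is rejected)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def signed_d_structure(n_pops: int):
    polys = [signed_d(i) for i in range(n_pops)]
    solver = LinearBasisSolver(
        [reduce_simplex(p, n_pops) for p in polys], list(range(n_pops))
    )
    weights = _small_weights(n_pops)
    swap = locus_swap_map(n_pops)
    drift = [dict() for _ in range(n_pops)]
    recomb: dict = {}
    for row, poly in enumerate(polys):
        image = (one_generation_expectation(poly, n_pops, include_mutation=False) - poly)
        image = reduce_simplex(image.symmetrized([{}, swap]), n_pops)
        for sym, part in image.split_by(weights).items():
            if sym is None:
                if part:
                    raise OperatorError("signed-D image zeroth order mismatch")
                continue
            if sym.startswith("m_"):
                raise OperatorError(
                    "the signed-D system does not close under migration"
                )
            coeffs = solver.project(part)
            target = recomb if sym == "r" else drift[int(sym[3:])]
            for col, value in coeffs.items():
                target[(row, col)] = value
    return drift, recomb


def signed_d_generator(nu, rho: float) -> np.ndarray:
    """Scaled generator of dE[D_i]/dT for isolated populations."""
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    P = nu.shape[0]
    drift, recomb = signed_d_structure(P)
    A = np.zeros((P, P))
    for i in range(P):
        for (r, c), v in drift[i].items():
            A[r, c] += float(v) / nu[i]
    for (r, c), v in recomb.items():
        A[r, c] += float(v) * (rho / 2.0)
    return A


def exact_generation_matrices(n_pops: int):
    """Per-generation coefficient matrices as exact Fraction dictionaries.

    Returns (labels, drift_list, recomb, migration, mutation): the matrices
    multiplying 1/(2N_i), r, m_ij and u in the one-generation recursion
    ``y_{t+1} - y_t = (sum_i D_i/(2N_i) + R r + sum M_ij m_ij + U u) y_t``.
    """
    s = generation_structure(n_pops)
    return s.labels, list(s.drift), dict(s.recomb), {k: dict(v) for k, v in s.migration.items()}, dict(s.mutation)
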