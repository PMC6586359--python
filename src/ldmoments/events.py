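"""Discrete demographic events: population splits and admixture pulses.

Both events are linear maps from the pre-event moment basis to the enlarged
post-event basis.

*Split*: immediately after a split, every statistic obtained by replacing any
subset of the parental indices with either child index equals the
corresponding parental statistic (two lineages drawn from different children
are exchangeable with two lineages drawn from the parent at the instant of
the split).

*Admixture*: a pulse in which each lineage of the new population derives from
``source1`` with probability ``f`` and from ``source2`` with probability
``1 - f``.  Haplotype frequencies in the admixed population are the exact
mixture ``x_adm = f x_1 + (1-f) x_2``; every moment involving the admixed
population is obtained by substituting this sampling law into the statistic's
polynomial, expanding, and re-expressing the result exactly in pre-event
basis moments.  For E[D_adm] and E[D_adm^2] this reproduces the classical
expansions in terms of D_1, D_2, D_1 D_2, the allele-frequency divergence
``delta = (p_1 - p_2)(q_1 - q_2)``, and their products, with coefficients
(f, 1-f, f(1-f)) and (f^2, (1-f)^2, 2f(1-f), 2f^2(1-f), 2f(1-f)^2,
f^2(1-f)^2) respectively.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache

import numpy as np

from ._polynomial import Poly
from .basis import (
    HAPLOTYPES,
    BasisError,
    MomentBasis,
    PopulationSet,
    StatisticVector,
    build_basis,
    hap_symbol,
    label_polynomial,
    map_label,
    marginalize,
)
from .operators import _basis_solver, reduce_simplex


def split_basis(old: MomentBasis, parent: str, children: tuple[str, str]) -> MomentBasis:
    """Post-split population set: child1 takes the parent's slot, child2 is appended."""
    c1, c2 = children
    if c2 in old.pops.labels or (c1 in old.pops.labels and c1 != parent):
        raise BasisError(f"split label collision: {children}")
    labels = [c1 if lbl == parent else lbl for lbl in old.pops.labels] + [c2]
    return build_basis(labels)


def split_matrix(old: MomentBasis, parent: str, children: tuple[str, str]):
    new = split_basis(old, parent, children)
    parent_idx = old.pops.index(parent)
    c2_idx = len(new.pops) - 1
    c1_idx = parent_idx
    index_map = {i: i for i in range(len(old.pops))}
    index_map[c1_idx] = parent_idx
    index_map[c2_idx] = parent_idx
    T = np.zeros((new.size, old.size))
    for row, lbl in enumerate(new.labels):
        T[row, old.index_of(map_label(lbl, index_map))] = 1.0
    return new, T


def apply_split(vec: StatisticVector, parent: str, children: tuple[str, str]) -> StatisticVector:
    new, T = split_matrix(vec.basis, parent, children)
    return StatisticVector(new, T @ vec.values)


@lru_cache(maxsize=None)
def _admixture_structure(n_pops: int, i1: int, i2: int):
    """Symbolic transform (entries: Poly in 'f') from P pops to P+1 with the
    admixed population appended; cached per population count and source slots."""
    old_labels, solver = _basis_solver(n_pops)
    adm = n_pops
    new_basis = build_basis([f"p{i}" for i in range(n_pops + 1)])
    f = Poly.sym("f")
    mix = {
        hap_symbol(adm, hap): f * Poly.sym(hap_symbol(i1, hap))
        + (1 - f) * Poly.sym(hap_symbol(i2, hap))
        for hap in HAPLOTYPES
    }
    rows = []
    for lbl in new_basis.labels:
        if adm not in lbl.populations():
            rows.append({old_labels.index(lbl): Poly.const(1)})
            continue
        target = reduce_simplex(
            label_polynomial(lbl, n_pops + 1).subs(mix), n_pops
        )
        # split the target by powers of f and project each part exactly
        combined: dict[int, Poly] = {}
        max_pow = target.degree({"f"})
        for k in range(max_pow + 1):
            part = target.coefficient("f", k)
            if not part:
                continue
            for col, coeff in solver.project(part).items():
                acc = combined.setdefault(col, Poly())
                combined[col] = acc + Poly.sym("f", k) * coeff if k else acc + coeff
        rows.append(combined)
    return tuple(new_basis.labels), rows


def admixture_matrix(
    old: MomentBasis, source1: str, source2: str, child: str, f: float
):
    """Transform matrix from the old basis to the basis with ``child`` appended."""
    if not (0.0 <= f <= 1.0):
        raise BasisError(f"admixture fraction f={f} outside [0, 1]")
    if source1 == source2:
        raise BasisError("admixture sources must differ")
    if child in old.pops.labels:
        raise BasisError(f"admixture label collision: {child}")
    i1, i2 = old.pops.index(source1), old.pops.index(source2)
    _, rows = _admixture_structure(len(old.pops), i1, i2)
    new = build_basis(list(old.pops.labels) + [child])
    T = np.zeros((new.size, old.size))
    env = {"f": Fraction(f).limit_denominator(10**12)}
    for row, entries in enumerate(rows):
        for col, poly in entries.items():
            T[row, col] = float(poly.evaluate(env))
    return new, T


def admixture_matrix_symbolic(old: MomentBasis, source1: str, source2: str):
    """Exact transform with entries as polynomials in the admixture fraction."""
    i1, i2 = old.pops.index(source1), old.pops.index(source2)
    labels, rows = _admixture_structure(len(old.pops), i1, i2)
    return labels, rows


def apply_admixture(
    vec: StatisticVector,
    source1: str,
    source2: str,
    f: float,
    child: str,
    replace: bool = False,
) -> StatisticVector:
    """Expand the moment vector to include an admixed population.

    With ``replace=True`` the second source is marginalized out afterwards
    (pulse into an existing population is modeled as admixture followed by
    dropping the stand-in source).
    """
    new, T = admixture_matrix(vec.basis, source1, source2, child, f)
    out = StatisticVector(new, T @ vec.values)
    if replace:
        out = marginalize(out, source2)
    return out


def pulse_migration(vec: StatisticVector, source: str, dest: str, f: float) -> StatisticVector:
    """One-generation admixture pulse: ``dest`` receives a fraction ``f`` of
    lineages from ``source``; the population set is unchanged."""
    from .basis import relabel

    tmp = dest + "__pulse"
    out = apply_admixture(vec, source, dest, f, child=tmp, replace=True)
    return relabel(out, {tmp: dest})


__all__ = [
    "apply_split",
    "apply_admixture",
    "pulse_migration",
    "split_matrix",
    "split_basis",
    "admixture_matrix",
    "admixture_matrix_symbolic",
]
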