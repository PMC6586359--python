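"""Canonical multi-population basis of two-locus moment statistics.

The moment system evolves a vector of expectations over a family of one- and
two-locus statistics.  For ``P`` populations, with ``p_i``/``q_i`` the
derived-allele frequencies at the left/right locus in population ``i`` and
``D_i`` the haplotype-frequency covariance, the families are

* ``DD(i,j)``   -- E[D_i D_j]
* ``Dz(i,(j,k))`` -- E[D_i (1 - 2 p_j)(1 - 2 q_k)]
* ``pi2((i,j),(k,l))`` -- E[(1/4)(p_i(1-p_j) + p_j(1-p_i))(q_k(1-q_l) + q_l(1-q_k))]
* ``H(i,j)``    -- cross-population heterozygosity E[p_i(1-p_j) + p_j(1-p_i)]
* ``ONE``       -- the constant 1, appended so the infinite-sites mutation
  source is a matrix column and the whole system is linear.

Because the statistics are genome-wide averages over pairs of loci, they are
invariant under exchanging the two loci and under permuting symmetric index
slots; labels are stored only in the canonical form produced by
:func:`canonicalize` (``DD``/``H`` pairs sorted; the ``Dz`` inner pair sorted;
``pi2`` inner pairs and the outer pair-of-pairs sorted).  The single-population
diagonal of ``pi2`` reduces exactly to ``p(1-p)q(1-q)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._polynomial import Poly

FAMILIES = ("DD", "Dz", "pi2", "H", "ONE")

HAPLOTYPES = ("AB", "Ab", "aB", "ab")


class BasisError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationSet:
    """Ordered, unique population labels; order is fixed for a basis' lifetime."""

    labels: tuple[str, ...]

    def __init__(self, labels):
        labels = tuple(labels)
        if len(labels) == 0:
            raise BasisError("PopulationSet requires at least one population")
        if len(set(labels)) != len(labels):
            raise BasisError(f"duplicate population labels: {labels}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True, order=True)
class MomentLabel:
    family: str
    indices: tuple

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise BasisError(f"unknown moment family {self.family!r}")

    def populations(self) -> set[int]:
        if self.family == "ONE":
            return set()
        if self.family in ("DD", "H"):
            return set(self.indices)
        if self.family == "Dz":
            i, (j, k) = self.indices
            return {i, j, k}
        (i, j), (k, l) = self.indices
        return {i, j, k, l}

    def to_string(self) -> str:
        """Serialize with 1-based population indices, e.g. ``pi2_1_1_2_2``."""
        if self.family == "ONE":
            return "ONE"
        if self.family in ("DD", "H"):
            i, j = self.indices
            return f"{self.family}_{i + 1}_{j + 1}"
        if self.family == "Dz":
            i, (j, k) = self.indices
            return f"Dz_{i + 1}_{j + 1}_{k + 1}"
        (i, j), (k, l) = self.indices
        return f"pi2_{i + 1}_{j + 1}_{k + 1}_{l + 1}"

    @staticmethod
    def from_string(text: str) -> "MomentLabel":
        if text == "ONE":
            return MomentLabel("ONE", ())
        parts = text.split("_")
        family, idx = parts[0], [int(x) - 1 for x in parts[1:]]
        if family in ("DD", "H") and len(idx) == 2:
            return canonicalize(MomentLabel(family, (idx[0], idx[1])))
        if family == "Dz" and len(idx) == 3:
            return canonicalize(MomentLabel("Dz", (idx[0], (idx[1], idx[2]))))
        if family == "pi2" and len(idx) == 4:
            return canonicalize(
                MomentLabel("pi2", ((idx[0], idx[1]), (idx[2], idx[3])))
            )
        raise BasisError(f"cannot parse moment label {text!r}")


def canonicalize(label: MomentLabel) -> MomentLabel:
    """Map a label to its canonical representative under the statistic's symmetries.

    Idempotent; equivalent labels (under unordered ``DD``/``H`` pairs, the
    locus-exchange symmetry of the ``Dz`` inner pair, and the inner/outer pair
    symmetries of ``pi2``) map to the same representative.
    """
    fam = label.family
    if fam == "ONE":
        return MomentLabel("ONE", ())
    if fam in ("DD", "H"):
        i, j = label.indices
        return MomentLabel(fam, tuple(sorted((i, j))))
    if fam == "Dz":
        i, (j, k) = label.indices
        return MomentLabel("Dz", (i, tuple(sorted((j, k)))))
    if fam == "pi2":
        (i, j), (k, l) = label.indices
        left, right = tuple(sorted((i, j))), tuple(sorted((k, l)))
        return MomentLabel("pi2", tuple(sorted((left, right))))
    raise BasisError(f"unknown moment family {fam!r}")


# ---------------------------------------------------------------------------
# statistic polynomials in per-population haplotype frequencies
# ---------------------------------------------------------------------------


def hap_symbol(pop: int, hap: str) -> str:
    return f"x{pop}_{hap}"


def freq_p(pop: int) -> Poly:
    return Poly.sym(hap_symbol(pop, "AB")) + Poly.sym(hap_symbol(pop, "Ab"))


def freq_q(pop: int) -> Poly:
    return Poly.sym(hap_symbol(pop, "AB")) + Poly.sym(hap_symbol(pop, "aB"))


def signed_d(pop: int) -> Poly:
    return Poly.sym(hap_symbol(pop, "AB")) * Poly.sym(hap_symbol(pop, "ab")) - Poly.sym(
        hap_symbol(pop, "Ab")
    ) * Poly.sym(hap_symbol(pop, "aB"))


def locus_swap_map(n_pops: int) -> dict[str, str]:
    """Symbol permutation implementing the exchange of the two loci (Ab <-> aB)."""
    mp = {}
    for i in range(n_pops):
        mp[hap_symbol(i, "Ab")] = hap_symbol(i, "aB")
        mp[hap_symbol(i, "aB")] = hap_symbol(i, "Ab")
    return mp


def label_polynomial(label: MomentLabel, n_pops: int) -> Poly:
    """Locus-exchange-symmetrized polynomial realizing a canonical label."""
    fam = label.family
    if fam == "ONE":
        return Poly.const(1)
    swap = locus_swap_map(n_pops)
    if fam == "DD":
        i, j = label.indices
        return signed_d(i) * signed_d(j)  # already locus symmetric
    if fam == "Dz":
        i, (j, k) = label.indices
        raw = signed_d(i) * (1 - 2 * freq_p(j)) * (1 - 2 * freq_q(k))
        return raw.symmetrized([{}, swap])
    if fam == "pi2":
        (i, j), (k, l) = label.indices
        left = freq_p(i) * (1 - freq_p(j)) + freq_p(j) * (1 - freq_p(i))
        right = freq_q(k) * (1 - freq_q(l)) + freq_q(l) * (1 - freq_q(k))
        raw = left * right / 4
        return raw.symmetrized([{}, swap])
    if fam == "H":
        i, j = label.indices
        raw = freq_p(i) * (1 - freq_p(j)) + freq_p(j) * (1 - freq_p(i))
        return raw.symmetrized([{}, swap])
    raise BasisError(f"unknown moment family {fam!r}")


# ---------------------------------------------------------------------------
# the basis itself
# ---------------------------------------------------------------------------


def _all_canonical_labels(n_pops: int) -> list[MomentLabel]:
    pops = range(n_pops)
    labels: list[MomentLabel] = []
    seen: set[MomentLabel] = set()

    def push(lbl: MomentLabel):
        c = canonicalize(lbl)
        if c not in seen:
            seen.add(c)
            labels.append(c)

    block: list[MomentLabel] = []

    def flush():
        nonlocal block
        labels.sort()
        block.extend(labels)
        labels.clear()

    for i in pops:
        for j in pops:
            push(MomentLabel("DD", (i, j)))
    flush()
    for i in pops:
        for j in pops:
            for k in pops:
                push(MomentLabel("Dz", (i, (j, k))))
    flush()
    for i in pops:
        for j in pops:
            for k in pops:
                for l in pops:
                    push(MomentLabel("pi2", ((i, j), (k, l))))
    flush()
    for i in pops:
        for j in pops:
            push(MomentLabel("H", (i, j)))
    flush()
    block.append(MomentLabel("ONE", ()))
    return block


@dataclass(frozen=True)
class MomentBasis:
    pops: PopulationSet
    labels: tuple[MomentLabel, ...] = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(_all_canonical_labels(len(self.pops))))

    @property
    def size(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: MomentLabel | str) -> int:
        if isinstance(label, str):
            label = MomentLabel.from_string(label)
        label = canonicalize(label)
        try:
            return self.labels.index(label)
        except ValueError as exc:
            raise BasisError(f"{label} not in basis") from exc

    def names(self) -> list[str]:
        return [lbl.to_string() for lbl in self.labels]

    def polynomials(self) -> list[Poly]:
        n = len(self.pops)
        return [label_polynomial(lbl, n) for lbl in self.labels]

    def family_slice(self, family: str) -> list[int]:
        return [i for i, lbl in enumerate(self.labels) if lbl.family == family]


def build_basis(pops: PopulationSet | list[str]) -> MomentBasis:
    if not isinstance(pops, PopulationSet):
        pops = PopulationSet(pops)
    return MomentBasis(pops)


@dataclass
class StatisticVector:
    basis: MomentBasis
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.basis.size,):
            raise BasisError(
                f"value vector of length {self.values.shape} does not match basis size "
                f"{self.basis.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise BasisError("statistic vector contains non-finite entries")

    def __getitem__(self, label):
        return self.values[self.basis.index_of(label)]

    def __setitem__(self, label, value):
        self.values[self.basis.index_of(label)] = value

    def copy(self) -> "StatisticVector":
        return StatisticVector(self.basis, self.values.copy())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.basis.names(), self.values))


def evaluate_state(basis: MomentBasis, freqs) -> StatisticVector:
    """Evaluate every basis statistic on a deterministic frequency state.

    ``freqs`` has shape (P, 4) giving per-population haplotype frequencies in
    the order ``AB, Ab, aB, ab``.
    """
    freqs = np.asarray(freqs, dtype=float)
    env = {
        hap_symbol(i, hap): float(freqs[i, h])
        for i in range(len(basis.pops))
        for h, hap in enumerate(HAPLOTYPES)
    }
    values = [float(poly.evaluate(env)) for poly in basis.polynomials()]
    return StatisticVector(basis, np.array(values))


def marginalize(vec: StatisticVector, drop: str) -> StatisticVector:
    """Project a statistic vector onto the basis without population ``drop``."""
    old = vec.basis
    if len(old.pops) < 2:
        raise BasisError("cannot marginalize the last population")
    drop_idx = old.pops.index(drop)
    keep = [lbl for lbl in old.pops.labels if lbl != drop]
    new_basis = build_basis(keep)
    remap = {}
    for new_pos, lbl in enumerate(keep):
        remap[old.pops.index(lbl)] = new_pos
    values = np.empty(new_basis.size)
    for i, new_lbl in enumerate(new_basis.labels):
        old_lbl = _map_label(new_lbl, {v: k for k, v in remap.items()})
        values[i] = vec.values[old.index_of(old_lbl)]
    _ = drop_idx
    return StatisticVector(new_basis, values)


def _map_label(label: MomentLabel, index_map: dict[int, int]) -> MomentLabel:
    fam = label.family
    if fam == "ONE":
        return label
    if fam in ("DD", "H"):
        i, j = label.indices
        return canonicalize(MomentLabel(fam, (index_map[i], index_map[j])))
    if fam == "Dz":
        i, (j, k) = label.indices
        return canonicalize(
            MomentLabel("Dz", (index_map[i], (index_map[j], index_map[k])))
        )
    (i, j), (k, l) = label.indices
    return canonicalize(
        MomentLabel(
            "pi2",
            ((index_map[i], index_map[j]), (index_map[k], index_map[l])),
        )
    )


def map_label(label: MomentLabel, index_map: dict[int, int]) -> MomentLabel:
    """Relabel the population indices of a canonical label (and re-canonicalize)."""
    return _map_label(label, index_map)


def relabel(vec: StatisticVector, mapping: dict[str, str]) -> StatisticVector:
    """Rename populations (values are re-ordered to the new canonical basis)."""
    new_names = [mapping.get(lbl, lbl) for lbl in vec.basis.pops.labels]
    new_basis = build_basis(new_names)
    # position of old population in the new ordered set
    index_map = {i: new_basis.pops.index(new_names[i]) for i in range(len(new_names))}
    values = np.empty(new_basis.size)
    for i, lbl in enumerate(vec.basis.labels):
        values[new_basis.index_of(_map_label(lbl, index_map))] = vec.values[i]
    return StatisticVector(new_basis, values)
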