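"""Exact multivariate polynomial algebra over rational coefficients.

This is the small symbolic engine behind the one-generation enumeration of
moment operators, the admixture/split transforms, and the derivation of
unbiased genotype-based estimators.  Everything is exact: coefficients are
:class:`fractions.Fraction`, monomials are sorted tuples of
``(symbol, exponent)`` pairs.  A light-weight "order" mechanism supports the
leading-order truncation used throughout the moment system: designated
symbols (drift ``1/2N``, recombination ``r``, mutation ``u``, migration
``m_ij``) carry weight one and every product of two or more of them is
discarded.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Callable, Iterable, Mapping

Monomial = tuple[tuple[str, int], ...]

_ZERO = Fraction(0)


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(10**12)
    raise TypeError(f"cannot coerce {value!r} to an exact rational")


def _mul_monomials(a: Monomial, b: Monomial) -> Monomial:
    if not a:
        return b
    if not b:
        return a
    merged: dict[str, int] = dict(a)
    for sym, exp in b:
        merged[sym] = merged.get(sym, 0) + exp
    return tuple(sorted(merged.items()))


class Poly:
    """Sparse exact polynomial: ``{monomial: Fraction}``."""

    __slots__ = ("terms",)

    def __init__(self, terms: Mapping[Monomial, Fraction] | None = None):
        self.terms: dict[Monomial, Fraction] = {}
        if terms:
            for mono, coeff in terms.items():
                if coeff:
                    self.terms[mono] = coeff

    # -- constructors -----------------------------------------------------
    @staticmethod
    def sym(name: str, power: int = 1) -> "Poly":
        if power == 0:
            return Poly.const(1)
        return Poly({((name, power),): Fraction(1)})

    @staticmethod
    def const(value) -> "Poly":
        value = _as_fraction(value)
        return Poly({(): value}) if value else Poly()

    @staticmethod
    def from_terms(terms: Iterable[tuple[Fraction, Monomial]]) -> "Poly":
        out = Poly()
        for coeff, mono in terms:
            out._iadd_term(mono, _as_fraction(coeff))
        return out

    def copy(self) -> "Poly":
        return Poly(dict(self.terms))

    # -- arithmetic -------------------------------------------------------
    def _iadd_term(self, mono: Monomial, coeff: Fraction) -> None:
        new = self.terms.get(mono, _ZERO) + coeff
        if new:
            self.terms[mono] = new
        else:
            self.terms.pop(mono, None)

    def __add__(self, other) -> "Poly":
        other = other if isinstance(other, Poly) else Poly.const(other)
        out = self.copy()
        for mono, coeff in other.terms.items():
            out._iadd_term(mono, coeff)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Poly":
        return Poly({m: -c for m, c in self.terms.items()})

    def __sub__(self, other) -> "Poly":
        return self + (-(other if isinstance(other, Poly) else Poly.const(other)))

    def __rsub__(self, other) -> "Poly":
        return Poly.const(other) - self

    def __mul__(self, other) -> "Poly":
        if not isinstance(other, Poly):
            coeff = _as_fraction(other)
            return Poly({m: c * coeff for m, c in self.terms.items()})
        out = Poly()
        for m1, c1 in self.terms.items():
            for m2, c2 in other.terms.items():
                out._iadd_term(_mul_monomials(m1, m2), c1 * c2)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Poly":
        return self * (Fraction(1) / _as_fraction(other))

    def __pow__(self, exponent: int) -> "Poly":
        if exponent < 0:
            raise ValueError("negative powers are not supported")
        result = Poly.const(1)
        base = self
        n = exponent
        while n:
            if n & 1:
                result = result * base
            base = base * base
            n >>= 1
        return result

    def __eq__(self, other) -> bool:
        other = other if isinstance(other, Poly) else Poly.const(other)
        return self.terms == other.terms

    def __hash__(self):
        return hash(frozenset(self.terms.items()))

    def __bool__(self) -> bool:
        return bool(self.terms)

    def __repr__(self) -> str:
        if not self.terms:
            return "Poly(0)"
        bits = []
        for mono, coeff in sorted(self.terms.items()):
            factors = "*".join(
                s if e == 1 else f"{s}^{e}" for s, e in mono
            )
            bits.append(f"{coeff}{'*' + factors if factors else ''}")
        return "Poly(" + " + ".join(bits) + ")"

    # -- structure --------------------------------------------------------
    def symbols(self) -> set[str]:
        return {s for mono in self.terms for s, _ in mono}

    def degree(self, symbols: set[str] | None = None) -> int:
        best = 0
        for mono in self.terms:
            d = sum(e for s, e in mono if symbols is None or s in symbols)
            best = max(best, d)
        return best

    def constant_part(self) -> Fraction:
        return self.terms.get((), _ZERO)

    def subs(self, mapping: Mapping[str, "Poly"]) -> "Poly":
        """Simultaneous substitution of symbols by polynomials."""
        out = Poly()
        for mono, coeff in self.terms.items():
            term = Poly.const(coeff)
            for sym, exp in mono:
                repl = mapping.get(sym)
                term = term * (repl**exp if repl is not None else Poly.sym(sym, exp))
            out = out + term
        return out

    def map_symbols(self, mapping: Mapping[str, str]) -> "Poly":
        out = Poly()
        for mono, coeff in self.terms.items():
            new = tuple(sorted((mapping.get(s, s), e) for s, e in mono))
            # merge duplicates created by non-injective maps
            merged: dict[str, int] = {}
            for s, e in new:
                merged[s] = merged.get(s, 0) + e
            out._iadd_term(tuple(sorted(merged.items())), coeff)
        return out

    def truncate(self, weights: Mapping[str, int], max_order: int = 1) -> "Poly":
        """Drop terms whose total weight over the given symbols exceeds max_order."""
        out = Poly()
        for mono, coeff in self.terms.items():
            w = sum(weights.get(s, 0) * e for s, e in mono)
            if w <= max_order:
                out.terms[mono] = coeff
        return out

    def coefficient(self, sym: str, power: int) -> "Poly":
        """Polynomial coefficient of sym**power (sym removed from the result)."""
        out = Poly()
        for mono, coeff in self.terms.items():
            exps = dict(mono)
            if exps.pop(sym, 0) == power:
                out.terms[tuple(sorted(exps.items()))] = coeff
        return out

    def split_by(self, symbols: Iterable[str]) -> dict[str | None, "Poly"]:
        """Group first-order terms by which small symbol they carry.

        Assumes the polynomial is at most first order in the given symbols
        (i.e. already truncated); the key ``None`` collects the symbol-free
        part.
        """
        symset = set(symbols)
        out: dict[str | None, Poly] = {}
        for mono, coeff in self.terms.items():
            present = [(s, e) for s, e in mono if s in symset]
            if not present:
                out.setdefault(None, Poly())._iadd_term(mono, coeff)
            else:
                if len(present) > 1 or present[0][1] > 1:
                    raise ValueError("polynomial is not first order in the small symbols")
            if len(present) == 1:
                sym = present[0][0]
                rest = tuple((s, e) for s, e in mono if s != sym)
                out.setdefault(sym, Poly())._iadd_term(rest, coeff)
        return out

    def reduce_idempotent(self, sym: str) -> "Poly":
        """Apply sym**k -> sym (Bernoulli indicator reduction)."""
        out = Poly()
        for mono, coeff in self.terms.items():
            new = tuple(sorted((s, 1 if s == sym else e) for s, e in mono))
            out._iadd_term(new, coeff)
        return out

    def symmetrized(self, maps: list[Mapping[str, str]]) -> "Poly":
        """Average of the polynomial over a list of symbol permutations."""
        total = Poly()
        for mp in maps:
            total = total + self.map_symbols(mp)
        return total / len(maps)

    def evaluate(self, env: Mapping[str, object]):
        """Numeric (or ring-element) evaluation; missing symbols are an error."""
        total = None
        for mono, coeff in self.terms.items():
            term = coeff if not isinstance(coeff, float) else coeff
            value = term
            for sym, exp in mono:
                value = value * (env[sym] ** exp)
            total = value if total is None else total + value
        if total is None:
            return Fraction(0)
        return total


def falling(x, k: int):
    """Falling factorial x*(x-1)*...*(x-k+1); works for numbers and arrays."""
    result = 1
    for i in range(k):
        result = result * (x - i)
    return result


class LinearBasisSolver:
    """Exact projection of polynomials onto the span of a fixed polynomial basis.

    Given basis polynomials ``B_j`` the solver finds, for a target ``t``,
    rational coefficients ``c_j`` with ``sum_j c_j B_j == t`` exactly, raising
    if no representation exists.  Pivot monomials are chosen once; the
    right-hand side may have coefficients in any commutative ring containing
    the rationals (e.g. :class:`Poly` in an admixture-fraction symbol), since
    divisions only involve rational pivots.
    """

    def __init__(
        self,
        basis_polys: list[Poly],
        labels: list | None = None,
        allow_dependent: bool = False,
    ):
        self.labels = labels if labels is not None else list(range(len(basis_polys)))
        self.basis_polys = basis_polys
        k = len(basis_polys)
        monomials: dict[Monomial, int] = {}
        for poly in basis_polys:
            for mono in poly.terms:
                monomials.setdefault(mono, len(monomials))
        # rows: list over monomial index of {col: Fraction}
        rows: list[dict[int, Fraction]] = [dict() for _ in range(len(monomials))]
        for j, poly in enumerate(basis_polys):
            for mono, coeff in poly.terms.items():
                rows[monomials[mono]][j] = coeff
        self._monomial_index = monomials
        # Gauss-Jordan over the rows to find k pivot monomials and the
        # transform T with c = T @ b (b restricted to pivot monomials).
        # Work on augmented rows [A_row | I-selector] implicitly: track for each
        # pivot the elimination coefficients applied to raw rhs entries.
        pivot_rows: list[int] = []
        # M: current matrix rows as dicts col->Fraction; E: row ops as dict
        # raw_row_index -> Fraction (expressing current row as combo of raw rows)
        M = [dict(r) for r in rows]
        E: list[dict[int, Fraction]] = [{i: Fraction(1)} for i in range(len(rows))]
        used = [False] * len(rows)
        active_cols: list[int] = []
        for col in range(k):
            pivot = None
            for i in range(len(M)):
                if not used[i] and M[i].get(col):
                    pivot = i
                    break
            if pivot is None:
                if allow_dependent:
                    continue
                raise ValueError("basis polynomials are linearly dependent")
            active_cols.append(col)
            used[pivot] = True
            pivot_rows.append(pivot)
            inv = Fraction(1) / M[pivot][col]
            M[pivot] = {c: v * inv for c, v in M[pivot].items()}
            E[pivot] = {r: v * inv for r, v in E[pivot].items()}
            for i in range(len(M)):
                if i != pivot and M[i].get(col):
                    factor = M[i][col]
                    for c, v in M[pivot].items():
                        newv = M[i].get(c, _ZERO) - factor * v
                        if newv:
                            M[i][c] = newv
                        else:
                            M[i].pop(c, None)
                    for r, v in E[pivot].items():
                        newv = E[i].get(r, _ZERO) - factor * v
                        if newv:
                            E[i][r] = newv
                        else:
                            E[i].pop(r, None)
        # after full Gauss-Jordan, row `pivot_rows[j]` has a 1 in active column
        # j and zeros in all other active columns, so c_col = E[pivot] . b_raw
        self._active_cols = active_cols
        self._solution_rows = [E[pr] for pr in pivot_rows]
        self._label_pos = {id(lbl): i for i, lbl in enumerate(self.labels)}

    def project_vector(self, b: Mapping[Monomial, object], verify_target: Poly | None = None):
        """Solve for coefficients given a raw monomial -> value mapping."""
        bb: dict[int, object] = {}
        for mono, value in b.items():
            idx = self._monomial_index.get(mono)
            if idx is None:
                raise ValueError(f"target monomial {mono} outside basis span")
            bb[idx] = value
        coeffs = {}
        for col, row in zip(self._active_cols, self._solution_rows):
            total = None
            for raw_idx, weight in row.items():
                if raw_idx in bb:
                    term = bb[raw_idx] * weight
                    total = term if total is None else total + term
            if total is not None and (not isinstance(total, Fraction) or total):
                coeffs[self.labels[col]] = (total, col)
        out = {label: value for label, (value, _) in coeffs.items()}
        if verify_target is not None:
            recon = Poly()
            for label, (value, col) in coeffs.items():
                poly = self.basis_polys[col]
                recon = recon + poly * value
            if recon != verify_target:
                raise ValueError("projection inconsistent: target not in basis span")
        return out

    def project(self, target: Poly, rhs_coeff=lambda c: c):
        """Return {label: coefficient} with sum(coeff * basis) == target.

        ``rhs_coeff`` maps the target's Fraction coefficients into the
        coefficient ring of the result (identity for rational targets).
        """
        b = {mono: rhs_coeff(coeff) for mono, coeff in target.terms.items()}
        return self.project_vector(b, verify_target=target)
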