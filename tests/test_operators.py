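"""Operator construction: printed single-population matrices, migration and
mutation rows, scaling conventions, and structural invariants."""

from fractions import Fraction

import numpy as np
import pytest

from ldmoments.basis import build_basis, hap_symbol, signed_d
from ldmoments._polynomial import Poly
from ldmoments.operators import (
    OperatorError,
    RateParameters,
    UnsupportedOrderError,
    assemble,
    assemble_dense,
    build_drift,
    build_migration,
    build_mutation,
    build_recombination,
    exact_generation_matrices,
    one_generation_expectation,
    signed_d_generator,
)

F = Fraction


class TestPrintedMatrices:
    """The classical one-population (D^2, Dz, pi2) recursion, exactly."""

    def test_drift_block(self):
        labels, drift, _, _, _ = exact_generation_matrices(1)
        names = [l.to_string() for l in labels]
        idx = [names.index(s) for s in ("DD_1_1", "Dz_1_1_1", "pi2_1_1_1_1")]
        expected = [[-3, 1, 1], [4, -5, 0], [0, 1, -2]]
        for a, row in zip(idx, expected):
            for b, value in zip(idx, row):
                assert drift[0].get((a, b), F(0)) == F(value)

    def test_recombination_block(self):
        labels, _, recomb, _, _ = exact_generation_matrices(1)
        names = [l.to_string() for l in labels]
        idx = [names.index(s) for s in ("DD_1_1", "Dz_1_1_1", "pi2_1_1_1_1")]
        expected = [-2, -1, 0]
        for a, diag in zip(idx, expected):
            assert recomb.get((a, a), F(0)) == F(diag)
            for b in idx:
                if b != a:
                    assert recomb.get((a, b), F(0)) == 0

    def test_h_row_and_mutation_source(self):
        labels, drift, _, _, mut = exact_generation_matrices(1)
        names = [l.to_string() for l in labels]
        h, one = names.index("H_1_1"), names.index("ONE")
        assert drift[0][(h, h)] == F(-1)
        assert mut[(h, one)] == F(2)  # the +2u source of the H recursion

    def test_pi2_mutation_source_from_heterozygosity(self):
        labels, _, _, _, mut = exact_generation_matrices(1)
        names = [l.to_string() for l in labels]
        assert mut[(names.index("pi2_1_1_1_1"), names.index("H_1_1"))] == F(1)

    def test_one_row_identically_zero(self):
        labels, drift, recomb, mig, mut = exact_generation_matrices(2)
        one = len(labels) - 1
        for comp in [*drift, recomb, mut, *mig.values()]:
            assert not any(r == one for (r, c) in comp)


class TestCrossPopulationRows:
    def test_dd12_decay_rate(self):
        """E[D1 D2] decays at 1/2N1 + 1/2N2 + 2r with no other sources."""
        labels, drift, recomb, _, mut = exact_generation_matrices(2)
        names = [l.to_string() for l in labels]
        row = names.index("DD_1_2")
        for i in (0, 1):
            entries = {c: v for (r_, c), v in drift[i].items() if r_ == row}
            assert entries == {row: F(-1)}
        rec_entries = {c: v for (r_, c), v in recomb.items() if r_ == row}
        assert rec_entries == {row: F(-2)}
        assert not any(r_ == row for (r_, c) in mut)

    def test_h12_migration_recursion(self):
        """H12 row: +m12 toward H11, +m21 toward H22, -(m12+m21) diagonal."""
        labels, _, _, mig, _ = exact_generation_matrices(2)
        names = [l.to_string() for l in labels]
        h12, h11, h22 = (names.index(s) for s in ("H_1_2", "H_1_1", "H_2_2"))
        m12 = {c: v for (r, c), v in mig[(0, 1)].items() if r == h12}
        m21 = {c: v for (r, c), v in mig[(1, 0)].items() if r == h12}
        assert m12 == {h11: F(1), h12: F(-1)}
        assert m21 == {h22: F(1), h12: F(-1)}

    def test_migration_locality(self):
        """Rows for single-population moments of pop 3 ignore m between 1 and 2."""
        labels, _, _, mig, _ = exact_generation_matrices(3)
        names = [l.to_string() for l in labels]
        row = names.index("DD_3_3")
        assert not any(r == row for (r, c) in mig[(0, 1)])
        assert not any(r == row for (r, c) in mig[(1, 0)])


class TestScaledOperators:
    def test_zero_rates_give_zero_operators(self, basis_p2):
        assert build_recombination(basis_p2, 0.0).matrix.nnz == 0
        assert build_migration(basis_p2, np.zeros((2, 2))).matrix.nnz == 0
        assert build_mutation(basis_p2, 0.0).matrix.nnz == 0

    def test_infinite_sizes_remove_drift(self, basis_p2):
        op = build_drift(basis_p2, [1e30, 1e30])
        assert np.abs(op.matrix.toarray()).max() < 1e-25

    def test_invalid_parameters_rejected(self, basis_p2):
        with pytest.raises(OperatorError):
            build_drift(basis_p2, [1.0, -1.0])
        with pytest.raises(OperatorError):
            build_recombination(basis_p2, -0.5)
        with pytest.raises(OperatorError):
            build_migration(basis_p2, -np.ones((2, 2)))
        with pytest.raises(OperatorError):
            build_mutation(basis_p2, -1e-3)
        with pytest.raises(OperatorError):
            RateParameters(nu=[1.0], mig=np.array([[0.5]]))

    def test_assemble_is_sum_of_components(self, basis_p2):
        params = RateParameters(
            nu=[0.5, 2.0], mig=np.array([[0, 1.0], [0.3, 0]]), rho=1.5, theta=1e-3
        )
        total = assemble(params, basis_p2).matrix.toarray()
        parts = (
            build_drift(basis_p2, params.nu).matrix
            + build_migration(basis_p2, params.mig).matrix
            + build_recombination(basis_p2, params.rho).matrix
            + build_mutation(basis_p2, params.theta).matrix
        ).toarray()
        np.testing.assert_allclose(total, parts, atol=1e-14)
        np.testing.assert_allclose(total, assemble_dense(params), atol=1e-14)

    def test_ld_block_eigenvalues_negative(self, basis_p1):
        """Pure drift (D^2, Dz, pi2) decays: the printed matrix is stable."""
        params = RateParameters(nu=[1.0], rho=0.0, theta=0.0)
        A = assemble(params, basis_p1).matrix.toarray()[:3, :3]
        assert np.max(np.linalg.eigvals(A).real) < 0

    def test_population_swap_symmetry(self, basis_p2):
        """A symmetric two-population model commutes with the pop swap."""
        from ldmoments.basis import map_label

        params = RateParameters(
            nu=[0.7, 0.7], mig=np.array([[0, 0.8], [0.8, 0]]), rho=1.0, theta=1e-3
        )
        A = assemble(params, basis_p2).matrix.toarray()
        swap = {0: 1, 1: 0}
        perm = [basis_p2.index_of(map_label(l, swap)) for l in basis_p2.labels]
        P = np.eye(len(perm))[perm]
        np.testing.assert_allclose(A, P @ A @ P.T, atol=1e-12)


class TestOneGenerationExpectation:
    def test_signed_d_decay(self):
        image = one_generation_expectation(signed_d(0), 1, include_mutation=False)
        d = signed_d(0)
        expected = d - Poly.sym("eps0") * d - Poly.sym("r") * d
        # compare modulo the simplex constraint
        from ldmoments.operators import reduce_simplex

        assert reduce_simplex(image, 1) == reduce_simplex(expected, 1)

    def test_heterozygosity_recursion_with_mutation(self):
        p = Poly.sym(hap_symbol(0, "AB")) + Poly.sym(hap_symbol(0, "Ab"))
        target = p * (1 - p)
        image = one_generation_expectation(target, 1)
        from ldmoments.operators import reduce_simplex

        expected = target - Poly.sym("eps0") * target + Poly.sym("u")
        assert reduce_simplex(image, 1) == reduce_simplex(expected, 1)

    def test_degree_limit(self):
        with pytest.raises(UnsupportedOrderError):
            one_generation_expectation(signed_d(0) ** 3, 1)


def test_signed_d_generator_rate():
    A = signed_d_generator([1.0], rho=2.0)
    assert A.shape == (1, 1)
    assert A[0, 0] == pytest.approx(-(1.0 + 1.0))  # 1/nu + rho/2


def test_operator_triplet_rendering(basis_p1):
    op = build_recombination(basis_p1, 2.0)
    triplets = op.to_triplets()
    assert ("DD_1_1", "DD_1_1", -2.0) in triplets
    assert ("Dz_1_1_1", "Dz_1_1_1", -1.0) in triplets
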