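"""Reduced eigenproblem: oracle equivalence, closed forms, asymptotics."""

import numpy as np
import pytest

from stratpca import (
    CovParams,
    ModelError,
    PopulationLayout,
    asymptotic_error_ratio,
    asymptotic_solve,
    build_full_cov,
    build_reduced,
    critical_size,
    freq_to_cov,
    mean_adjust,
    reduce_and_solve,
    representative_distances,
    small_eigenvalues,
    solve_reduced,
    two_pop_closed_form,
)
from stratpca.simulate import subtle_structure_freq_model

from conftest import random_layout, random_params


def dense_spectrum(params, layout):
    adj, _ = mean_adjust(params, layout)
    return np.sort(np.linalg.eigvalsh(build_full_cov(adj, layout)))[::-1]


class TestBuildReduced:
    def test_one_population_reduces_to_zero(self):
        lay = PopulationLayout(("P1",), (10,))
        adj, _ = mean_adjust(CovParams([1.0], [0.8], [[0.8]]), lay)
        system = build_reduced(adj, lay)
        assert np.allclose(system.R, 0.0, atol=1e-12)

    def test_row_sums_vanish_and_similarity(self, rng, table1):
        layout, params = table1
        adj, _ = mean_adjust(params, layout)
        system = build_reduced(adj, layout)
        assert np.max(np.abs(system.R.sum(axis=1))) < 1e-10
        # B = S R S^-1 shares the spectrum of R
        assert np.allclose(
            np.sort(np.linalg.eigvals(system.R).real),
            np.sort(np.linalg.eigvalsh(system.B)),
            atol=1e-9,
        )

    def test_unadjusted_input_rejected(self, table1):
        layout, params = table1
        with pytest.raises(ModelError, match="mean_adjust"):
            build_reduced(params, layout)


class TestSolveReduced:
    def test_oracle_equivalence_random_parameters(self, rng):
        """Reduced + small eigenvalues reproduce the dense adjusted spectrum,
        and the dense top eigenvectors are constant within populations."""
        for _ in range(40):
            K = int(rng.integers(1, 7))
            params = random_params(rng, K)
            layout = random_layout(rng, K, max_per_pop=50)
            sol = reduce_and_solve(params, layout)
            expected = list(sol.eigenvalues)
            for val, mult in small_eigenvalues(params, layout):
                expected.extend([val] * mult)
            dense = dense_spectrum(params, layout)
            scale = max(np.max(np.abs(dense)), 1.0)
            assert np.allclose(np.sort(expected)[::-1], dense,
                               atol=1e-8 * scale)

    def test_piecewise_constant_eigenvectors(self, rng):
        params = random_params(rng, 3)
        layout = PopulationLayout(("P1", "P2", "P3"), (7, 12, 20))
        adj, _ = mean_adjust(params, layout)
        sol = solve_reduced(build_reduced(adj, layout))
        full = build_full_cov(adj, layout)
        # each nontrivial axis, expanded to individuals, is a dense eigenvector
        for j in sol.nontrivial_axes():
            v = layout.expand(sol.coefficients[j])
            assert np.allclose(full @ v, sol.eigenvalues[j] * v, atol=1e-8)

    def test_trivial_solution_constant_with_zero_eigenvalue(self, rng, table1):
        layout, params = table1
        sol = reduce_and_solve(params, layout)
        triv = sol.coefficients[sol.trivial_index]
        assert np.allclose(triv, triv[0])
        assert abs(sol.eigenvalues[sol.trivial_index]) < 1e-9 * np.max(
            np.abs(sol.eigenvalues)
        )

    def test_constraints_and_weighted_orthogonality(self, rng):
        params = random_params(rng, 5)
        layout = random_layout(rng, 5, max_per_pop=40)
        sol = reduce_and_solve(params, layout)
        ns = layout.sizes_array
        a = sol.coefficients
        for j in sol.nontrivial_axes():
            assert abs(np.sum(ns * a[j])) < 1e-8
            assert np.sum(ns * a[j] ** 2) == pytest.approx(1.0)
            for k in sol.nontrivial_axes():
                if k != j:
                    assert abs(np.sum(ns * a[j] * a[k])) < 1e-8

    def test_small_populations_far_from_center(self, table1):
        # equal parameters: the pattern reflects sample sizes alone, and the
        # smallest population lies farthest from the origin
        layout, params = table1
        sol = reduce_and_solve(params, layout)
        radius = np.sqrt(
            np.sum(sol.coefficients[sol.nontrivial_axes()] ** 2, axis=0)
        )
        assert radius[0] > radius[1] > radius[2]

    def test_close_triple_collapses_on_leading_axes(self, table2):
        # P1-P3 nearly coincide on axes 1-2; P4 vs P5 contrast on axis 2;
        # the close triple separates only on axes 3-4
        layout, params = table2
        sol = reduce_and_solve(params, layout)
        a = sol.coefficients[sol.nontrivial_axes()]  # rows: axes 1..4
        triple_spread = np.ptp(a[:2, :3], axis=1)
        assert np.all(triple_spread < 0.2 * np.abs(a[:2, 3:]).max(axis=1))
        assert abs(a[1, 3] - a[1, 4]) > 5 * triple_spread[1]
        late_spread = np.ptp(a[2:4, :3], axis=1)
        assert np.all(late_spread > 3 * triple_spread)


class TestSmallEigenvalues:
    def test_formula_and_multiplicity(self):
        lay = PopulationLayout(("P1",), (10,))
        assert small_eigenvalues(CovParams([1.0], [0.8], [[0.8]]), lay) == [
            (pytest.approx(0.2), 9)
        ]
        assert small_eigenvalues(CovParams([1.0], [0.0], [[0.0]]), lay) == [
            (pytest.approx(1.0), 9)
        ]

    def test_table1_merges_equal_values(self, table1):
        layout, params = table1
        [(val, mult)] = small_eigenvalues(params, layout)
        assert val == pytest.approx(0.2) and mult == 112


class TestTwoPopClosedForm:
    def test_coefficients_from_sizes_alone(self, rng):
        lay = PopulationLayout(("A", "B"), (5, 10))
        params = random_params(rng, 2)
        adj, _ = mean_adjust(params, lay)
        _, a = two_pop_closed_form(lay, adj)
        assert np.allclose(np.abs(a), [0.36515, 0.18257], atol=5e-6)

    def test_equal_sizes_symmetric(self, rng):
        lay = PopulationLayout(("A", "B"), (8, 8))
        adj, _ = mean_adjust(random_params(rng, 2), lay)
        _, a = two_pop_closed_form(lay, adj)
        assert np.allclose(np.abs(a), 1 / np.sqrt(16))

    def test_matches_solver_and_dense_oracle(self, rng):
        for _ in range(10):
            lay = random_layout(rng, 2, max_per_pop=40)
            params = random_params(rng, 2)
            adj, _ = mean_adjust(params, lay)
            lam, a = two_pop_closed_form(lay, adj)
            sol = solve_reduced(build_reduced(adj, lay))
            j = sol.nontrivial_axes()[0]
            assert lam == pytest.approx(sol.eigenvalues[j], abs=1e-10)
            assert np.allclose(a, sol.coefficients[j], atol=1e-10)
            dense = dense_spectrum(params, lay)
            assert np.min(np.abs(dense - lam)) < 1e-8

    def test_wrong_K_rejected(self, rng, table1):
        layout, params = table1
        adj, _ = mean_adjust(params, layout)
        with pytest.raises(ModelError):
            two_pop_closed_form(layout, adj)


class TestAsymptotic:
    def scenario(self):
        return freq_to_cov(subtle_structure_freq_model())

    def test_symmetric_case_closed_form(self, rng):
        # exchangeable populations: all nontrivial limit eigenvalues (c-d)/K
        K = 4
        params = CovParams(
            sigma2=np.full(K, 1.0), c=np.full(K, 0.6), d=np.full((K, K), 0.2)
        )
        sol = asymptotic_solve(params, np.full(K, 0.25))
        lams = sol.unit_eigenvalues[sol.nontrivial_axes()]
        assert np.allclose(lams, (0.6 - 0.2) / K, atol=1e-12)

    def test_convergence_of_finite_solver(self):
        params = self.scenario()
        w = np.full(4, 0.25)
        target = asymptotic_solve(params, w)
        n_per = 2500  # n = 1e4
        lay = PopulationLayout(("P1", "P2", "P3", "P4"), (n_per,) * 4)
        sol = reduce_and_solve(params, lay)
        a_fin = sol.coefficients[sol.nontrivial_axes()] * np.sqrt(lay.n)
        a_inf = target.coefficients[target.nontrivial_axes()]
        for j in range(3):
            diff = min(
                np.sqrt(np.sum(w * (a_fin[j] - a_inf[j]) ** 2)),
                np.sqrt(np.sum(w * (a_fin[j] + a_inf[j]) ** 2)),
            )
            assert diff < 1e-3

    def test_eigenvalues_grow_linearly_with_n(self, table1):
        # well past the critical size, nontrivial eigenvalues scale with n
        _, params = table1
        lams = {}
        for scale in (1, 2):
            lay = PopulationLayout(("P1", "P2", "P3"),
                                   (scale * 100, scale * 200, scale * 400))
            sol = reduce_and_solve(params, lay)
            lams[scale] = np.sort(sol.eigenvalues[sol.nontrivial_axes()])
        assert np.allclose(lams[2] / lams[1], 2.0, rtol=0.02)

    def test_coefficients_ignore_variances(self):
        params = self.scenario()
        w = np.full(4, 0.25)
        base = asymptotic_solve(params, w)
        bumped = asymptotic_solve(
            CovParams(sigma2=params.sigma2 + 0.5, c=params.c, d=params.d),
            w,
        )
        assert np.allclose(base.coefficients, bumped.coefficients, atol=1e-12)
        assert np.allclose(base.unit_eigenvalues, bumped.unit_eigenvalues,
                           atol=1e-12)

    def test_neglected_term(self):
        params = self.scenario()
        sol = asymptotic_solve(params, np.full(4, 0.25), n_ref=100)
        assert np.allclose(sol.neglected, (params.sigma2 - params.c) / 100)


class TestCriticalSize:
    def test_well_separated_closed_form(self):
        params = CovParams(
            sigma2=np.ones(3), c=np.full(3, 0.8), d=np.full((3, 3), 0.1)
        )
        assert critical_size(params) == pytest.approx(3 * 0.2 / 0.7)

    def test_diverges_as_populations_merge(self):
        sizes = []
        for d in (0.5, 0.7, 0.79):
            params = CovParams(
                sigma2=np.ones(3), c=np.full(3, 0.8), d=np.full((3, 3), d)
            )
            sizes.append(critical_size(params))
        assert sizes[0] < sizes[1] < sizes[2]
        with pytest.raises(ModelError, match="indistinguishable"):
            critical_size(
                CovParams(sigma2=np.ones(3), c=np.full(3, 0.8),
                          d=np.full((3, 3), 0.85))
            )

    def test_two_population_warning(self):
        params = CovParams(
            sigma2=np.ones(2), c=np.full(2, 0.8), d=np.full((2, 2), 0.1)
        )
        with pytest.warns(UserWarning, match="sample-size"):
            critical_size(params)

    def test_general_case_error_ratio_decays(self):
        params = self.params = freq_to_cov(subtle_structure_freq_model())
        w = np.full(4, 0.25)
        r1 = asymptotic_error_ratio(params, w, 100)
        r2 = asymptotic_error_ratio(params, w, 1000)
        assert r2 == pytest.approx(r1 / 10)


class TestRepresentativeDistances:
    def test_two_population_distance(self, rng):
        lay = PopulationLayout(("A", "B"), (5, 10))
        sol = reduce_and_solve(random_params(rng, 2), lay)
        j = sol.nontrivial_axes()[0]
        expected = np.sqrt(10 / (5 * 15)) + np.sqrt(5 / (10 * 15))
        assert representative_distances(sol, j, ("A", "B")) == pytest.approx(
            expected
        )

    def test_identical_populations_coincide(self):
        # two populations sharing a parameter row sit at the same point
        d = np.array(
            [[0.6, 0.6, 0.2], [0.6, 0.6, 0.2], [0.2, 0.2, 0.7]]
        )
        params = CovParams(sigma2=np.ones(3), c=np.diag(d).copy(), d=d)
        lay = PopulationLayout(("P1", "P2", "P3"), (10, 10, 12))
        sol = reduce_and_solve(params, lay)
        top = sol.nontrivial_axes()[0]
        assert representative_distances(sol, top, ("P1", "P2")) < 1e-9

    def test_trivial_axis_rejected(self, rng, table1):
        layout, params = table1
        sol = reduce_and_solve(params, layout)
        with pytest.raises(ModelError):
            representative_distances(sol, sol.trivial_index, ("P1", "P2"))
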