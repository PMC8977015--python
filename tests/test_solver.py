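import math
import random

import mpmath
import pytest
import sympy

import epistab as et
from epistab.errors import (
    InvalidArgumentError,
    SolverTimeoutError,
    UnsolvableConfigurationError,
)
from epistab.model import x, y
from epistab.solver import SolutionPrecisionWarning

from conftest import EXACT_X, EXACT_Y


class TestHeuristics:
    @pytest.mark.parametrize("order,expected", [(1, 240), (2, 540), (8, 4860)])
    def test_heuristic_timeout(self, order, expected):
        assert et.heuristic_timeout(order) == expected

    @pytest.mark.parametrize("order,expected", [(2, 1e-14), (8, 1e-8), (9, 1e-8)])
    def test_tolerable_error(self, order, expected):
        assert et.tolerable_error(order) == pytest.approx(expected, rel=0)

    def test_bad_config(self):
        with pytest.raises(InvalidArgumentError):
            et.SolverConfig(e0=1e-6, e_max=1e-8)


class TestBuildSystem:
    def test_order1_prevalence_system(self, additive1):
        system = et.build_system(additive1, [0.5], "prevalence", 0.5)
        expected = (
            sympy.Rational(1, 4) * x
            + sympy.Rational(1, 2) * x * (1 + y)
            + sympy.Rational(1, 4) * x * (1 + y) ** 2
        )
        assert sympy.simplify(system.main_equation.lhs - expected) == 0
        assert system.main_equation.rhs == sympy.Rational(1, 2)
        assert system.constraint_equation == sympy.Eq(x * (1 + y) ** 2, 1)

    def test_weights_cover_all_expressions(self, additive2):
        system = et.build_system(additive2, [0.25, 0.25], "prevalence", 0.3)
        assert sum(w for _, w in system.weights) == 1
        assert set(e for e, _ in system.weights) == set(additive2.distinct_expressions())

    def test_maf_count_mismatch(self, additive2):
        with pytest.raises(InvalidArgumentError):
            et.build_system(additive2, [0.25], "prevalence", 0.3)

    @pytest.mark.parametrize("value", [0, -0.1, 1.5])
    def test_fixed_value_domain(self, additive2, value):
        with pytest.raises(InvalidArgumentError):
            et.build_system(additive2, [0.25, 0.25], "prevalence", value)

    def test_unknown_parameter(self, additive2):
        with pytest.raises(InvalidArgumentError):
            et.build_system(additive2, [0.25, 0.25], "penetrance", 0.3)

    def test_simplified_system_equals_raw_sum(self, additive2):
        """The grouped/simplified main equation agrees with the raw
        3^order-term frequency-weighted sum at random probe points."""
        mafs = et.MafVector([0.2, 0.35])
        system = et.build_system(additive2, mafs, "heritability", 0.4)
        freqs = et.genotype_frequencies(mafs)
        mean = sum(p * e for (g, p), e in zip(freqs.items(), additive2.expressions))
        var = sum(
            p * (e - mean) ** 2
            for (g, p), e in zip(freqs.items(), additive2.expressions)
        )
        raw = var / (mean * (1 - mean))
        rng = random.Random(20240901)
        with mpmath.workdps(60):
            raw_fn = sympy.lambdify((x, y), raw, modules="mpmath")
            simp_fn = sympy.lambdify((x, y), system.main_equation.lhs, modules="mpmath")
            for _ in range(20):
                xv = mpmath.mpf(rng.uniform(0.05, 1.0))
                yv = mpmath.mpf(rng.uniform(0.01, 5.0))
                a, b = raw_fn(xv, yv), simp_fn(xv, yv)
                assert abs(a - b) <= abs(a) * mpmath.mpf("1e-20")


class TestSolveSystem:
    def test_order1_closed_form(self, closed_form_solution):
        _, solution = closed_form_solution
        assert float(solution.y_value) == pytest.approx(EXACT_Y, abs=1e-12)
        assert float(solution.x_value) == pytest.approx(EXACT_X, abs=1e-12)

    def test_flat_model_only_solvable_at_one(self, flat2):
        system = et.build_system(flat2, [0.25, 0.25], "prevalence", 1.0)
        solution = et.solve_system(system)
        assert float(solution.x_value) == 1.0
        assert float(solution.y_value) == 0.0  # canonical value; y is absent

        system = et.build_system(flat2, [0.25, 0.25], "prevalence", 0.5)
        with pytest.raises(UnsolvableConfigurationError):
            et.solve_system(system)

    def test_table4_additive_row_solves(self):
        """A configuration known to be hard for variable-precision solvers:
        additive order 4, uniform MAF 0.2, fixed heritability 0.8."""
        model = et.generate_bank_model("additive", 4)
        system = et.build_system(model, [0.2] * 4, "heritability", 0.8)
        solution = et.solve_system(system)
        assert solution.residual <= et.tolerable_error(4)

    def test_unreachable_prevalence(self):
        # threshold at MAF 0.4 cannot go below P(all loci carry a minor allele)
        model = et.generate_bank_model("threshold", 2)
        system = et.build_system(model, [0.4, 0.4], "prevalence", 0.1)
        with pytest.raises(UnsolvableConfigurationError):
            et.solve_system(system)

    def test_timeout_raised(self):
        model = et.generate_bank_model("multiplicative", 4)
        system = et.build_system(model, [0.2] * 4, "heritability", 0.5)
        with pytest.raises(SolverTimeoutError):
            et.solve_system(system, et.SolverConfig(timeout=1e-4))

    def test_non_polynomial_model_general_route(self):
        """A fractional-power model is not polynomial in y after eliminating
        x; the general solver route still finds the admissible root. With
        MAF 0.5 and prevalence 0.5 the substitution t = sqrt(1+y) recovers
        the order-1 additive closed form, so y = (1+sqrt(2))^2 - 1."""
        model = et.EpistasisModel.from_entries(
            "sqrtmod", [("AA", "x"), ("Aa", "x*(1+y)^(1/2)"), ("aa", "x*(1+y)")]
        )
        table = et.compute_table(model, [0.5], "prevalence", 0.5)
        assert float(table.y_value) == pytest.approx(2 + 2 * math.sqrt(2), abs=1e-10)
        assert table.prevalence == pytest.approx(0.5, abs=1e-12)
        assert [float(p) for p in table.penetrances] == pytest.approx(
            [EXACT_X, EXACT_Y - 1, 1.0], abs=1e-10
        )

    def test_constraint_satisfied_at_solution(self, additive2):
        system = et.build_system(additive2, [0.25, 0.25], "heritability", 0.3)
        solution = et.solve_system(system)
        max_pen = float(
            (x * (1 + y) ** 4).subs({x: sympy.Float(solution.x_value, 30),
                                     y: sympy.Float(solution.y_value, 30)})
        )
        assert abs(max_pen - 1) <= et.tolerable_error(2)

    def test_parameter_recovery_round_trip(self, additive2):
        mafs = et.MafVector([0.25, 0.25])
        t1 = et.compute_table(additive2, mafs, "prevalence", 0.3)
        t2 = et.compute_table(additive2, mafs, "heritability", t1.heritability)
        for a, b in zip(t1.penetrances, t2.penetrances):
            assert abs(float(a - b)) <= 1e-8

    def test_maximized_heritability_monotone_in_prevalence(self, additive2):
        values = [
            et.compute_table(additive2, [0.25, 0.25], "prevalence", p).heritability
            for p in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert values == sorted(values) or values == sorted(values, reverse=True)


class TestCheckSolution:
    def test_exact_solution_residual_tiny(self, closed_form_solution):
        system, solution = closed_form_solution
        assert et.check_solution(system, solution) <= 1e-14

    def test_perturbed_solution_warns(self, closed_form_solution):
        system, solution = closed_form_solution
        corrupted = et.Solution(
            x_value=solution.x_value,
            y_value=solution.y_value + mpmath.mpf("1e-3"),
            residual=solution.residual,
        )
        with pytest.warns(SolutionPrecisionWarning):
            residual = et.check_solution(system, corrupted)
        assert residual > et.tolerable_error(1)
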