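"""Constrained solver for prevalence/heritability-pinned penetrance models.

Given an epistasis model f_i(x, y), per-locus MAFs and one fixed population
parameter, the solver finds the (x, y) that realises the fixed parameter
while pinning the maximum penetrance to 1 (which maximizes the free
parameter). The two formulations are

fixed prevalence P(D):      sum_i f_i(x,y) P(g_i) = P(D),   max_i f_i = 1
fixed heritability h^2:     sum_i (f_i - P(D))^2 P(g_i)
                            ----------------------------- = h^2, max_i f_i = 1
                                  P(D) (1 - P(D))

with P(D) in the second system itself the frequency-weighted mean
penetrance. Genotype frequencies P(g_i) come from Hardy-Weinberg
proportions and are exact rationals, so the cleared main equation is a
univariate polynomial in y with rational coefficients once the constraint
is solved for x and substituted. Its real roots are isolated exactly and
refined to 50 significant digits; admissible roots (x > 0, penetrances in
[0, 1] within tolerance) are accepted when the recomputed parameter matches
the request within the current tolerance of a relaxation schedule.
"""

from __future__ import annotations

import math
import signal
import threading
import time
import warnings
from dataclasses import dataclass
from typing import Sequence

import mpmath
import sympy
from sympy import Eq, Expr, Poly, Rational, lambdify

from .errors import (
    InvalidArgumentError,
    SolverTimeoutError,
    UnsolvableConfigurationError,
    UnsupportedModelError,
)
from .genotypes import MafVector, genotype_frequencies
from .model import EpistasisModel, max_penetrance_expression, x, y

FIXED_PARAMETERS = ("prevalence", "heritability")

#: Working precision (significant digits) for root refinement and residuals.
WORKING_DPS = 50

#: Simplification is attempted symbolically only below this operation count;
#: larger systems keep the grouped form (already far smaller than the raw
#: 3^order-term sum) to bound build time.
SIMPLIFY_OP_LIMIT = 300


class SolutionPrecisionWarning(UserWarning):
    """Raised (as a warning) when a solution's residual exceeds the
    order-dependent tolerable error; the solution is reported anyway."""


def heuristic_timeout(order: int) -> int:
    """Order-scaled solver time budget in seconds: 60 * (order + 1)^2."""
    if order < 1:
        raise InvalidArgumentError(f"order must be >= 1, got {order}")
    return 60 * (order + 1) ** 2


def tolerable_error(order: int, e0: float = 1e-16, e_max: float = 1e-8) -> float:
    """Order-dependent residual cap: min(10^order * e0, e_max).

    The base error e0 (default 1e-16) scales with model order because the
    cleared equation's degree (and hence root conditioning) grows with it;
    e_max (default 1e-8) caps the tolerance so every accepted solution keeps
    a guaranteed maximum deviation of 1e-8.
    """
    if order < 1:
        raise InvalidArgumentError(f"order must be >= 1, got {order}")
    return min(10**order * e0, e_max)


@dataclass
class SolverConfig:
    """Solver options.

    timeout: ``None`` (no limit), a number of seconds, or ``"heuristic"``
    to use :func:`heuristic_timeout` of the model order. ``check`` re-derives
    the fixed parameter from the solution and warns when the deviation
    exceeds :func:`tolerable_error`. The relaxation schedule starts at
    ``start_tolerance`` and multiplies by ``relax_factor`` per retry until
    ``e_max``.
    """

    check: bool = True
    timeout: float | int | str | None = "heuristic"
    e0: float = 1e-16
    e_max: float = 1e-8
    dps: int = WORKING_DPS
    start_tolerance: float = 1e-30
    relax_factor: float = 1e4

    def __post_init__(self) -> None:
        if self.e0 > self.e_max:
            raise InvalidArgumentError(
                f"base error {self.e0} exceeds maximum error {self.e_max}"
            )

    def tolerance_schedule(self) -> list[float]:
        tols = []
        t = self.start_tolerance
        while t < self.e_max:
            tols.append(t)
            t *= self.relax_factor
        tols.append(self.e_max)
        return tols

    def resolve_timeout(self, order: int) -> float | None:
        t = self.timeout
        if t is None or t is False or (isinstance(t, str) and t.lower() in ("none", "off")):
            return None
        if t is True or (isinstance(t, str) and t.lower() in ("heuristic", "auto")):
            return float(heuristic_timeout(order))
        tv = float(t)
        if tv <= 0:
            raise InvalidArgumentError(f"timeout must be positive, got {t!r}")
        return tv


@dataclass
class EquationSystem:
    """The two-equation constrained system in the unknowns (x, y)."""

    fixed_parameter: str
    fixed_value: Rational
    main_equation: Eq
    constraint_equation: Eq
    model: EpistasisModel
    mafs: MafVector
    #: structurally distinct penetrance expressions with their total
    #: Hardy-Weinberg weight (sums to 1)
    weights: tuple[tuple[Expr, Rational], ...]

    @property
    def order(self) -> int:
        return self.model.order


@dataclass
class Solution:
    """An accepted (x, y) pair with its measured residual."""

    x_value: mpmath.mpf
    y_value: mpmath.mpf
    residual: float
    attempts: int = 1


def _grouped_weights(
    model: EpistasisModel, mafs: MafVector
) -> tuple[tuple[Expr, Rational], ...]:
    """Total Hardy-Weinberg frequency per structurally distinct expression."""
    freqs = genotype_frequencies(mafs)
    acc: dict[Expr, Rational] = {}
    for (g, p), e in zip(freqs.items(), model.expressions):
        acc[e] = acc.get(e, Rational(0)) + p
    return tuple(acc.items())


def build_system(
    model: EpistasisModel,
    mafs: MafVector | Sequence,
    fixed_parameter: str,
    fixed_value,
) -> EquationSystem:
    """Assemble the constrained system for one fixed population parameter.

    The main equation is built over the distinct penetrance expressions
    weighted by their aggregate genotype frequency (an exact regrouping of
    the full 3^order-term sum) and lightly simplified; the constraint pins
    the dominating expression to 1.
    """
    if not isinstance(mafs, MafVector):
        mafs = MafVector(mafs)
    if fixed_parameter not in FIXED_PARAMETERS:
        raise InvalidArgumentError(
            f"fixed_parameter must be one of {FIXED_PARAMETERS}, got {fixed_parameter!r}"
        )
    if len(mafs) != model.order:
        raise InvalidArgumentError(
            f"model order {model.order} requires {model.order} MAFs, got {len(mafs)}"
        )
    value = Rational(str(fixed_value)) if not isinstance(fixed_value, Rational) else fixed_value
    if not (0 < value <= 1):
        raise InvalidArgumentError(
            f"fixed {fixed_parameter} must lie in (0, 1], got {fixed_value}"
        )
    weights = _grouped_weights(model, mafs)
    mean = sum((w * e for e, w in weights), sympy.Integer(0))
    if fixed_parameter == "prevalence":
        main_lhs = mean
    else:
        variance = sum((w * (e - mean) ** 2 for e, w in weights), sympy.Integer(0))
        main_lhs = variance / (mean * (1 - mean))
    if sympy.count_ops(main_lhs) <= SIMPLIFY_OP_LIMIT:
        main_lhs = sympy.cancel(sympy.together(main_lhs))
    constraint = Eq(max_penetrance_expression(model), 1)
    return EquationSystem(
        fixed_parameter=fixed_parameter,
        fixed_value=value,
        main_equation=Eq(main_lhs, value),
        constraint_equation=constraint,
        model=model,
        mafs=mafs,
        weights=weights,
    )


class _Deadline:
    """Cooperative deadline with an optional SIGALRM hard interrupt.

    ``check()`` is called between solver stages; ``guard()`` wraps long
    uninterruptible pure-Python calls (root isolation) with a signal timer
    so they can be broken mid-call. The signal path only exists in the main
    thread; elsewhere the cooperative checks alone apply.
    """

    def __init__(self, budget: float | None):
        self.budget = budget
        self.start = time.monotonic()

    @property
    def elapsed(self) -> float:
        return time.monotonic() - self.start

    def remaining(self) -> float | None:
        if self.budget is None:
            return None
        return self.budget - self.elapsed

    def check(self) -> None:
        rem = self.remaining()
        if rem is not None and rem <= 0:
            raise SolverTimeoutError(
                f"solver exceeded its {self.budget:.0f} s budget "
                f"(elapsed {self.elapsed:.1f} s)",
                elapsed=self.elapsed,
            )

    def guard(self):
        return _AlarmGuard(self)


class _AlarmGuard:
    def __init__(self, deadline: _Deadline):
        self.deadline = deadline
        self.armed = False

    def __enter__(self):
        self.deadline.check()
        rem = self.deadline.remaining()
        if rem is not None and threading.current_thread() is threading.main_thread():
            def _on_alarm(signum, frame):
                raise SolverTimeoutError(
                    f"solver exceeded its {self.deadline.budget:.0f} s budget",
                    elapsed=self.deadline.elapsed,
                )

            self.prev = signal.signal(signal.SIGALRM, _on_alarm)
            signal.setitimer(signal.ITIMER_REAL, max(rem, 1e-3))
            self.armed = True
        return self

    def __exit__(self, *exc):
        if self.armed:
            signal.setitimer(signal.ITIMER_REAL, 0)
            signal.signal(signal.SIGALRM, self.prev)
        return False


def _solve_constraint_for_x(system: EquationSystem) -> Expr:
    """Express x from the max-penetrance constraint as a function of y."""
    constraint = system.constraint_equation
    max_expr = constraint.lhs
    if x not in max_expr.free_symbols:
        raise UnsupportedModelError(
            "the maximal penetrance expression does not involve x; the "
            "constraint cannot be solved for the baseline"
        )
    sols = sympy.solve(Eq(max_expr, 1), x)
    if not sols:
        raise UnsupportedModelError("cannot solve the max-penetrance constraint for x")
    # keep the branch positive for y > 0
    for s in sols:
        try:
            if float(s.subs(y, 1)) > 0:
                return s
        except (TypeError, ValueError):
            continue
    raise UnsupportedModelError(
        "no branch of the max-penetrance constraint gives a positive baseline x"
    )


def _cleared_polynomial(system: EquationSystem, xsub: Expr) -> Poly | None:
    """Numerator polynomial in y of the substituted main equation.

    Fast path: when every distinct expression factors as x * g(y) with g a
    polynomial and the constraint substitution is x = 1/u(y) with u a
    polynomial, the cleared equation is assembled with exact Poly
    arithmetic (this covers the bank families at any order). Otherwise a
    generic together/fraction route is used; returns None when the equation
    is not polynomial in y.
    """
    u_expr = sympy.cancel(1 / xsub)
    fast = u_expr.is_polynomial(y) and x not in u_expr.free_symbols
    gs = []
    if fast:
        for e, w in system.weights:
            g = sympy.cancel(e / x)
            if x in g.free_symbols or not g.is_polynomial(y):
                fast = False
                break
            gs.append((Poly(g, y), w))
    if fast:
        u = Poly(u_expr, y)
        a = Poly(0, y)
        for g, w in gs:
            a = a + g * w
        if system.fixed_parameter == "prevalence":
            num = a - u * system.fixed_value
        else:
            num = Poly(0, y)
            for g, w in gs:
                d = g - a
                num = num + d * d * w
            num = num - a * (u - a) * system.fixed_value
        return num if num.degree() >= 0 else None
    expr = (system.main_equation.lhs - system.fixed_value).subs(x, xsub)
    expr = sympy.together(sympy.cancel(expr))
    num, _den = sympy.fraction(expr)
    num = sympy.expand(num)
    if y not in num.free_symbols:
        return None
    try:
        return Poly(num, y)
    except sympy.PolynomialError:
        return None


def _nonnegative_poly_roots(poly: Poly, dps: int) -> list[mpmath.mpf]:
    """Real roots of ``poly`` with y >= 0, refined to ``dps`` digits.

    Exact isolation restricted to [0, inf) (``Poly.intervals(inf=0)``) is
    orders of magnitude cheaper than full real-root isolation at the
    degrees high-order models reach, and negative roots are never
    admissible anyway (dominance of the max-penetrance expression is only
    established for nonnegative effect sizes). Simple roots are refined by
    plain bisection in mpmath with generous guard precision; the caller's
    residual gate independently validates every refined root, so a
    (practically impossible) misrounded sign during refinement cannot
    produce a silently wrong solution. Roots of even multiplicity carry no
    sign change and are polished from the interval midpoint instead.
    """
    intervals = poly.intervals(inf=0)
    if not intervals:
        return []
    refine_dps = dps + 25
    roots: list[mpmath.mpf] = []
    with mpmath.workdps(refine_dps):
        coeffs = [_as_mpf(Rational(c), refine_dps) for c in poly.all_coeffs()]

        def pv(t):
            return mpmath.polyval(coeffs, t)

        def sgn(q: Rational) -> int:
            # exact sign, needed at interval endpoints which may themselves
            # be roots belonging to a neighbouring isolating interval
            v = poly.eval(q)
            return 0 if v == 0 else (1 if v > 0 else -1)

        width_target = mpmath.mpf(10) ** (-(dps + 5))
        n_bisect = int(3.4 * (dps + 10)) + 8
        for (a, b), mult in intervals:
            a, b = Rational(a), Rational(b)
            if a == b:
                roots.append(+_as_mpf(a, refine_dps))
                continue
            sa, sb = sgn(a), sgn(b)
            # pull a zero endpoint inside the interval without crossing the
            # single enclosed root: halve the step until the sign flips
            exact_hit = None
            for endpoint in (0, 1):
                limit = 200
                while (sa if endpoint == 0 else sb) == 0 and limit:
                    limit -= 1
                    step = (b - a) / 2 ** (201 - limit)
                    cand = (a + step) if endpoint == 0 else (b - step)
                    sc = sgn(cand)
                    if sc == 0:  # landed exactly on the enclosed root
                        exact_hit = cand
                        break
                    opposite = sb if endpoint == 0 else sa
                    if opposite != 0 and sc == opposite:
                        continue  # overshot the root; halve further
                    if endpoint == 0:
                        a, sa = cand, sc
                    else:
                        b, sb = cand, sc
                if exact_hit is not None:
                    break
            if exact_hit is not None:
                roots.append(+_as_mpf(exact_hit, refine_dps))
                continue
            lo, hi = _as_mpf(a, refine_dps), _as_mpf(b, refine_dps)
            if mult % 2 == 1 and sa * sb < 0:
                flo = mpmath.mpf(sa)
                for _ in range(n_bisect):
                    if hi - lo <= width_target * max(1, abs(lo)):
                        break
                    mid = (lo + hi) / 2
                    fmid = pv(mid)
                    if fmid == 0:
                        lo = hi = mid
                        break
                    if mpmath.sign(fmid) == mpmath.sign(flo):
                        lo, flo = mid, fmid
                    else:
                        hi = mid
                roots.append((lo + hi) / 2)
            else:
                # even multiplicity: no sign change across the isolating
                # interval; polish with damped Newton from the midpoint
                t = (lo + hi) / 2
                dcoeffs = [c * (len(coeffs) - 1 - i) for i, c in enumerate(coeffs[:-1])]
                for _ in range(200):
                    d = mpmath.polyval(dcoeffs, t)
                    if d == 0:
                        break
                    t_new = t - pv(t) / d
                    if t_new < lo or t_new > hi:
                        break
                    if abs(t_new - t) <= width_target * max(1, abs(t)):
                        t = t_new
                        break
                    t = t_new
                roots.append(t)
    with mpmath.workdps(dps):
        return [+r for r in roots]


@dataclass
class _Candidate:
    y_value: mpmath.mpf
    x_value: mpmath.mpf
    residual: mpmath.mpf
    penetrance_ok: bool


def _as_mpf(value, dps: int) -> mpmath.mpf:
    if isinstance(value, Rational):
        return mpmath.mpf(value.p) / mpmath.mpf(value.q)
    f = sympy.Float(value, dps) if not isinstance(value, sympy.Float) else value
    return mpmath.mpf(f._mpf_)


def solve_system(system: EquationSystem, config: SolverConfig | None = None) -> Solution:
    """Solve the constrained system for (x, y).

    The constraint is solved for x, substituted into the main equation, and
    the cleared numerator's real roots are isolated exactly and refined to
    ``config.dps`` digits. Admissible roots need x > 0 and every penetrance
    in [0, 1] within the order's tolerable error. Acceptance starts at a
    residual tolerance of ``start_tolerance`` and relaxes geometrically on
    failure (the ``attempts`` field of the solution records how often);
    among accepted roots the smallest y wins, making the output
    deterministic. Raises :class:`UnsolvableConfigurationError` when no
    admissible root exists and :class:`SolverTimeoutError` past the budget.
    """
    config = config or SolverConfig()
    deadline = _Deadline(config.resolve_timeout(system.order))
    p_eps = tolerable_error(system.order, config.e0, config.e_max)

    xsub = _solve_constraint_for_x(system)
    deadline.check()

    with mpmath.workdps(config.dps):
        fixed_mp = _as_mpf(system.fixed_value, config.dps)
        main_fn = lambdify((x, y), system.main_equation.lhs, modules="mpmath")
        pen_fns = [lambdify((x, y), e, modules="mpmath") for e, _ in system.weights]
        x_fn = lambdify(y, xsub, modules="mpmath")

        substituted = (system.main_equation.lhs - system.fixed_value).subs(x, xsub)
        if y not in substituted.free_symbols:
            # degenerate model: y cancelled out entirely (e.g. constant model)
            val = abs(_as_mpf(substituted.evalf(config.dps), config.dps))
            if val <= p_eps:
                xv = mpmath.mpf(x_fn(mpmath.mpf(0)))
                sol = Solution(x_value=xv, y_value=mpmath.mpf(0),
                               residual=float(val), attempts=1)
                if config.check:
                    check_solution(system, sol, e0=config.e0, e_max=config.e_max)
                return sol
            raise UnsolvableConfigurationError(
                f"the fixed {system.fixed_parameter} {system.fixed_value} is "
                "unreachable: the substituted system has no unknown left and "
                f"misses the target by {float(val):.3g}"
            )

        poly = _cleared_polynomial(system, xsub)
        deadline.check()
        if poly is not None:
            # rebuild over an assumption-free symbol: positivity assumptions
            # on y make CRootOf refinement recurse pathologically at high
            # degree, and the root set does not depend on them
            poly = Poly.from_list(poly.all_coeffs(), gens=sympy.Symbol("_y_root"))
            with deadline.guard():
                try:
                    root_values = _nonnegative_poly_roots(poly, config.dps)
                except SolverTimeoutError:
                    raise
                except Exception as exc:  # root isolation failure
                    raise UnsolvableConfigurationError(
                        f"real-root isolation failed: {exc}"
                    ) from exc
        else:
            # generic route for systems that are not polynomial in y
            # (e.g. fractional powers): delegate to sympy's solver
            try:
                with deadline.guard():
                    sols = sympy.solve(Eq(substituted, 0), y)
            except SolverTimeoutError:
                raise
            except Exception as exc:
                raise UnsolvableConfigurationError(
                    "the substituted main equation is not polynomial in y "
                    f"and the general solver failed: {exc}"
                ) from exc
            root_values = []
            for s in sols:
                if s.free_symbols:
                    continue
                sv = s.evalf(config.dps)
                if abs(sympy.im(sv)) > sympy.Float("1e-40"):
                    continue
                yv = _as_mpf(sympy.re(sv), config.dps)
                # dominance of the max-penetrance expression (and hence the
                # constraint itself) is only established for y >= 0; tiny
                # negatives are rounding noise on a y = 0 root
                if yv < 0:
                    if yv > -mpmath.mpf("1e-20"):
                        yv = mpmath.mpf(0)
                    else:
                        continue
                root_values.append(yv)
        deadline.check()

        candidates: list[_Candidate] = []
        for yv in root_values:
            deadline.check()
            try:
                xv = mpmath.mpf(x_fn(yv))
            except (ZeroDivisionError, ValueError, OverflowError):
                continue
            if not mpmath.isfinite(xv) or xv <= 0:
                continue
            try:
                pens = [mpmath.mpf(f(xv, yv)) for f in pen_fns]
                resid = abs(mpmath.mpf(main_fn(xv, yv)) - fixed_mp)
            except (ZeroDivisionError, ValueError, OverflowError):
                continue
            if not mpmath.isfinite(resid):
                continue
            ok = all(-p_eps <= p <= 1 + p_eps for p in pens)
            candidates.append(_Candidate(yv, xv, resid, ok))

        candidates.sort(key=lambda c: c.y_value)
        admissible = [c for c in candidates if c.penetrance_ok]
        for attempt, tol in enumerate(config.tolerance_schedule(), start=1):
            accepted = [c for c in admissible if c.residual <= tol]
            if accepted:
                best = accepted[0]  # smallest y among residual-tied roots
                sol = Solution(
                    x_value=best.x_value,
                    y_value=best.y_value,
                    residual=float(best.residual),
                    attempts=attempt,
                )
                if config.check:
                    check_solution(system, sol, e0=config.e0, e_max=config.e_max)
                return sol
        raise UnsolvableConfigurationError(
            f"no admissible real root for fixed {system.fixed_parameter} = "
            f"{system.fixed_value} ({len(root_values)} nonnegative real roots "
            f"examined, {len(admissible)} admissible, none within tolerance "
            f"{config.e_max:g})"
        )


def check_solution(
    system: EquationSystem,
    solution: Solution,
    e0: float = 1e-16,
    e_max: float = 1e-8,
) -> float:
    """Deviation of the fixed parameter recomputed at (x, y).

    Substitutes the solution into the main equation and returns the absolute
    deviation from the requested value. If it exceeds the order's tolerable
    error the solution is flagged with a :class:`SolutionPrecisionWarning`
    (a warning, not an error — the solution is still returned to the caller).
    """
    with mpmath.workdps(WORKING_DPS):
        main_fn = lambdify((x, y), system.main_equation.lhs, modules="mpmath")
        fixed_mp = _as_mpf(system.fixed_value, WORKING_DPS)
        try:
            value = mpmath.mpf(main_fn(solution.x_value, solution.y_value))
            residual = abs(value - fixed_mp)
        except (ZeroDivisionError, ValueError, OverflowError):
            residual = mpmath.inf
    residual_f = float(residual)
    if not math.isfinite(residual_f) or residual_f > tolerable_error(system.order, e0, e_max):
        warnings.warn(
            f"solution residual {residual_f:.3g} exceeds the tolerable error "
            f"{tolerable_error(system.order, e0, e_max):.3g} for order "
            f"{system.order}; the solution is considered invalid",
            SolutionPrecisionWarning,
            stacklevel=2,
        )
    return residual_f
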