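"""Independent brute-force solver used to cross-check the symbolic solver.

Exploits the structure of the max-penetrance constraint: when the
dominating expression factors as x * u(y) with u positive and increasing
for y >= 0 (true for the threshold/additive/multiplicative families), the
constraint gives x = 1/u(y) and the main equation collapses to a scalar
function of y alone. That function is evaluated numerically at high
precision:

- fixed prevalence: the frequency-weighted mean penetrance is decreasing
  in y (penetrances fall away from the pinned maximum as y grows), so a
  single sign change is bracketed by geometric expansion of the upper
  bound and refined by bisection;
- fixed heritability: the scalar function need not be monotone, so a
  logarithmic grid of 10^4 points is scanned for all sign changes, each is
  bisected, and the smallest admissible root is returned (matching the
  symbolic solver's smallest-y selection policy).

This module shares no solution path with :mod:`epistab.solver` beyond the
system definition: no polynomial clearing, no exact root isolation.
"""

from __future__ import annotations

from typing import Callable, Sequence

import mpmath
import sympy
from sympy import lambdify

from .errors import UnsolvableConfigurationError, UnsupportedModelError
from .genotypes import MafVector
from .model import EpistasisModel, max_penetrance_expression, x, y
from .solver import (
    FIXED_PARAMETERS,
    Solution,
    WORKING_DPS,
    _as_mpf,
    _grouped_weights,
    tolerable_error,
)
from sympy import Rational

#: bisection stops when the bracket width drops below this
BISECTION_TOL = 1e-15

#: upper-bound expansion: start at 10, double up to 2^40
Y_MAX_CAP = float(2**40)

#: points in the log-grid scan used for (possibly non-monotone)
#: heritability-fixed systems
SCAN_POINTS = 10_000


def _scalar_function(
    model: EpistasisModel,
    mafs: MafVector,
    fixed_parameter: str,
    fixed_value: Rational,
):
    """Build F(y) whose root is the solution, plus helpers (x(y), penetrances)."""
    weights = _grouped_weights(model, mafs)
    max_expr = max_penetrance_expression(model)
    u_expr = sympy.cancel(max_expr / x)
    if x in u_expr.free_symbols:
        raise UnsupportedModelError(
            "oracle requires the maximal penetrance to factor as x * u(y)"
        )
    u_fn = lambdify(y, u_expr, modules="mpmath")
    pen_fns = [(lambdify((x, y), e, modules="mpmath"), _as_mpf(w, WORKING_DPS))
               for e, w in weights]
    fixed_mp = _as_mpf(fixed_value, WORKING_DPS)

    def x_of_y(yv):
        return 1 / mpmath.mpf(u_fn(yv))

    def penetrances(yv):
        xv = x_of_y(yv)
        return xv, [mpmath.mpf(f(xv, yv)) for f, _ in pen_fns]

    def F(yv):
        xv, pens = penetrances(yv)
        mean = mpmath.mpf(0)
        for p, (_, w) in zip(pens, pen_fns):
            mean += p * w
        if fixed_parameter == "prevalence":
            return mean - fixed_mp
        if mean <= 0 or mean >= 1:
            return mpmath.nan
        var = mpmath.mpf(0)
        for p, (_, w) in zip(pens, pen_fns):
            var += (p - mean) ** 2 * w
        return var / (mean * (1 - mean)) - fixed_mp

    return F, x_of_y, penetrances


def _bisect(F: Callable, lo, hi) -> mpmath.mpf:
    flo = F(lo)
    for _ in range(200):
        if float(hi - lo) <= BISECTION_TOL:
            break
        mid = (lo + hi) / 2
        fmid = F(mid)
        if fmid == 0:
            return mid
        if mpmath.sign(fmid) == mpmath.sign(flo):
            lo, flo = mid, fmid
        else:
            hi = mid
    return (lo + hi) / 2


def oracle_solve(
    model: EpistasisModel,
    mafs: MafVector | Sequence,
    fixed_parameter: str,
    fixed_value,
) -> Solution:
    """Solve by 1-D bracketing/bisection on y after eliminating x.

    Raises :class:`UnsolvableConfigurationError` when no sign change is
    found up to the expansion cap — evidence, not proof, that the
    configuration is infeasible.
    """
    if not isinstance(mafs, MafVector):
        mafs = MafVector(mafs)
    if fixed_parameter not in FIXED_PARAMETERS:
        raise UnsupportedModelError(f"unknown fixed parameter {fixed_parameter!r}")
    value = Rational(str(fixed_value)) if not isinstance(fixed_value, Rational) else fixed_value
    with mpmath.workdps(WORKING_DPS):
        F, x_of_y, penetrances = _scalar_function(model, mafs, fixed_parameter, value)
        if fixed_parameter == "prevalence":
            yv = _solve_monotone(F)
        else:
            yv = _solve_scan(F, penetrances, model.order)
        xv = x_of_y(yv)
        residual = abs(F(yv))
        return Solution(x_value=xv, y_value=yv, residual=float(residual), attempts=1)


def _solve_monotone(F: Callable) -> mpmath.mpf:
    """Single-root bracketing for the decreasing prevalence-fixed function."""
    lo = mpmath.mpf("1e-12")
    flo = F(lo)
    if flo == 0:
        return lo
    if flo < 0:
        raise UnsolvableConfigurationError(
            "prevalence-fixed scalar function already negative at y ~ 0; "
            "the requested prevalence exceeds the attainable range"
        )
    hi = mpmath.mpf(10)
    while True:
        fhi = F(hi)
        if mpmath.isfinite(fhi) and fhi <= 0:
            break
        if float(hi) >= Y_MAX_CAP:
            raise UnsolvableConfigurationError(
                f"no sign change found for y up to {Y_MAX_CAP:.3g}; the "
                "configuration appears infeasible"
            )
        hi *= 2
    # sanity: sign pattern on a grid inside the bracket is monotone
    signs = [mpmath.sign(F(lo + (hi - lo) * k / 8)) for k in range(9)]
    changes = sum(1 for a, b in zip(signs, signs[1:]) if a != b and b != 0)
    if changes > 1:
        raise UnsupportedModelError(
            "prevalence-fixed scalar function is not monotone on the bracket"
        )
    return _bisect(F, lo, hi)


#: reduced precision for the bracket-hunting scan; brackets are then
#: refined by bisection at full working precision
SCAN_DPS = 25


def _solve_scan(F: Callable, penetrances: Callable, order: int) -> mpmath.mpf:
    """Log-grid scan + bisection for heritability-fixed systems."""
    p_eps = tolerable_error(order)
    y_lo = mpmath.mpf("1e-9")
    y_hi = mpmath.mpf(10)
    while float(y_hi) <= Y_MAX_CAP:
        with mpmath.workdps(SCAN_DPS):
            brackets = _scan_interval(F, y_lo, y_hi)
        admissible = []
        for lo, hi in brackets:
            r = _bisect(F, mpmath.mpf(lo), mpmath.mpf(hi))
            _, pens = penetrances(r)
            if all(-p_eps <= p <= 1 + p_eps for p in pens):
                admissible.append(r)
        if admissible:
            return min(admissible)
        y_hi *= 2
    raise UnsolvableConfigurationError(
        f"no admissible sign change found for y up to {Y_MAX_CAP:.3g}; the "
        "configuration appears infeasible"
    )


def _scan_interval(F: Callable, y_lo, y_hi) -> list[tuple]:
    """Sign-change brackets of F on a logarithmic grid over [y_lo, y_hi]."""
    log_lo = mpmath.log10(y_lo)
    log_hi = mpmath.log10(y_hi)
    step = (log_hi - log_lo) / (SCAN_POINTS - 1)
    brackets = []
    prev_y = None
    prev_f = None
    for k in range(SCAN_POINTS):
        yv = mpmath.mpf(10) ** (log_lo + step * k)
        fv = F(yv)
        if not mpmath.isfinite(fv):
            prev_y, prev_f = None, None
            continue
        if fv == 0:
            brackets.append((yv, yv))
        elif prev_f is not None and mpmath.sign(fv) != mpmath.sign(prev_f):
            brackets.append((prev_y, yv))
        prev_y, prev_f = yv, fv
    return brackets
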