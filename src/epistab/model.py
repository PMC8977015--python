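"""Epistasis models: symbolic penetrance expressions per genotype.

A model maps every multi-locus genotype to a penetrance expression in
exactly two free variables, a baseline ``x`` and an effect size ``y``.
The classic two-variable families (threshold, additive, multiplicative)
scale the baseline by powers of (1 + y) driven by the per-locus minor
allele counts; :func:`generate_bank_model` produces them at any order.

The on-disk format is a minimal CSV dialect: two comma-separated columns,
no header, column 1 the genotype string, column 2 the expression using
``+ - * / ^`` (``**`` is also accepted on input), numbers, parentheses and
the variables x and y. Lines starting with ``#`` and blank lines are
ignored. ``^`` is printed on output.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, TextIO

import sympy
from sympy import Expr, Integer, symbols

from .errors import (
    ExpressionError,
    InvalidArgumentError,
    MalformedModelError,
    UnsupportedModelError,
)
from .genotypes import MAX_ORDER, enumerate_genotypes, minor_allele_counts

#: The two model variables: baseline penetrance factor and effect size.
x, y = symbols("x y", positive=True)

BANK_FAMILIES = ("threshold", "additive", "multiplicative")

#: (x, y) points used to probe expressions numerically. All admissible
#: solutions have x in (0, 1] and y > 0; the grid spans that region with
#: x factored out where possible (bank expressions share the factor x, so
#: dominance depends on y alone).
PROBE_GRID = tuple((1, yv) for yv in (0.1, 1.0, 10.0, 100.0))

#: Extra points (x varied) used when validating that expressions stay
#: finite and nonnegative.
VALIDATION_GRID = tuple(
    (xv, yv) for xv in (1e-3, 0.5, 1.0) for yv in (0.1, 1.0, 10.0, 100.0)
)


def _parse_expression(text: str) -> Expr:
    source = text.strip().replace("^", "**")
    if not source:
        raise ExpressionError("empty penetrance expression")
    try:
        expr = sympy.sympify(source, locals={"x": x, "y": y}, rational=True)
    except (sympy.SympifyError, SyntaxError, TypeError) as exc:
        raise ExpressionError(f"cannot parse expression {text!r}: {exc}") from exc
    if not isinstance(expr, Expr):
        raise ExpressionError(f"expression {text!r} is not a scalar expression")
    extra = expr.free_symbols - {x, y}
    if extra:
        names = ", ".join(sorted(str(s) for s in extra))
        raise ExpressionError(
            f"expression {text!r} uses variables other than x, y: {names}"
        )
    return expr


def format_expression(expr: Expr) -> str:
    """Canonical text form of an expression, with ``^`` for powers."""
    return sympy.sstr(expr, order="lex").replace("**", "^")


@dataclass(frozen=True)
class EpistasisModel:
    """An ordered genotype → symbolic penetrance map of a given order.

    Entries are stored in canonical genotype order (see
    :func:`epistab.genotypes.enumerate_genotypes`); construction validates
    completeness of the genotype set and that every expression is a
    function of x and y only, finite and nonnegative on a probe grid.
    """

    name: str
    order: int
    genotypes: tuple[str, ...]
    expressions: tuple[Expr, ...]

    @classmethod
    def from_entries(
        cls, name: str, entries: Iterable[tuple[str, Expr | str]]
    ) -> "EpistasisModel":
        pairs = [(g, e) for g, e in entries]
        if not pairs:
            raise MalformedModelError("model has no entries")
        n = len(pairs)
        order = round(math.log(n, 3))
        if 3**order != n:
            raise MalformedModelError(
                f"model has {n} entries, not a power of 3"
            )
        if order > MAX_ORDER:
            raise MalformedModelError(f"model order {order} exceeds cap {MAX_ORDER}")
        first_len = len(pairs[0][0])
        if first_len != 2 * order:
            raise MalformedModelError(
                f"genotype strings of length {first_len} but {n} rows imply "
                f"order {order}"
            )
        by_genotype: dict[str, Expr] = {}
        parse_cache: dict[str, Expr] = {}
        for g, e in pairs:
            if g in by_genotype:
                raise MalformedModelError(f"duplicate genotype {g!r}")
            if isinstance(e, str):
                if e not in parse_cache:
                    parse_cache[e] = _parse_expression(e)
                e = parse_cache[e]
            by_genotype[g] = e
        canonical = enumerate_genotypes(order)
        missing = [g for g in canonical if g not in by_genotype]
        if missing:
            raise MalformedModelError(
                f"model is missing genotype(s): {', '.join(missing[:5])}"
            )
        unknown = set(by_genotype) - set(canonical)
        if unknown:
            raise MalformedModelError(
                f"unrecognised genotype(s): {', '.join(sorted(unknown)[:5])}"
            )
        exprs = tuple(by_genotype[g] for g in canonical)
        validated: set[Expr] = set()
        for g, e in zip(canonical, exprs):
            if e in validated:
                continue
            extra = e.free_symbols - {x, y}
            if extra:
                raise ExpressionError(
                    f"entry {g}: variables other than x, y: {sorted(map(str, extra))}"
                )
            _validate_numeric(g, e)
            validated.add(e)
        return cls(name=name, order=order, genotypes=tuple(canonical), expressions=exprs)

    def items(self):
        return zip(self.genotypes, self.expressions)

    def as_dict(self) -> dict[str, Expr]:
        return dict(self.items())

    def distinct_expressions(self) -> list[Expr]:
        """Structurally distinct expressions, in first-appearance order."""
        seen: dict[Expr, None] = {}
        for e in self.expressions:
            seen.setdefault(e)
        return list(seen)

    def __len__(self) -> int:
        return len(self.genotypes)


def _validate_numeric(genotype: str, expr: Expr) -> None:
    # evaluated in arbitrary precision: high-order expressions like
    # x*(1+y)^256 overflow a double at the large-y probe points
    for xv, yv in VALIDATION_GRID:
        val = expr.subs({x: sympy.Rational(str(xv)), y: sympy.Rational(str(yv))})
        val = val.evalf(20)
        if not val.is_number or val.is_real is False:
            raise ExpressionError(
                f"entry {genotype}: expression does not evaluate to a real "
                f"number at (x={xv}, y={yv})"
            )
        if val.is_finite is False or val < 0:
            raise ExpressionError(
                f"entry {genotype}: expression is {val} at (x={xv}, y={yv}); "
                "penetrance expressions must be finite and nonnegative"
            )


def parse_model_csv(source: str | os.PathLike | TextIO, name: str | None = None) -> EpistasisModel:
    """Read an epistasis model from the two-column CSV dialect.

    ``source`` may be a path or an open text stream. The model name defaults
    to the file stem (or "model" for streams).
    """
    if hasattr(source, "read"):
        stream: TextIO = source  # type: ignore[assignment]
        default_name = "model"
    else:
        stream = open(source, "r", encoding="utf-8")
        default_name = os.path.splitext(os.path.basename(os.fspath(source)))[0]
    try:
        entries: list[tuple[str, str]] = []
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",", 1)
            if len(parts) != 2:
                raise MalformedModelError(
                    f"line {lineno}: expected 'genotype,expression', got {raw!r}"
                )
            entries.append((parts[0].strip(), parts[1].strip()))
    finally:
        if stream is not source:
            stream.close()
    if not entries:
        raise MalformedModelError("model file contains no entries")
    return EpistasisModel.from_entries(name or default_name, entries)


def write_model_csv(model: EpistasisModel, destination: str | os.PathLike | TextIO) -> None:
    """Write a model in the two-column CSV dialect (round-trips with the parser)."""
    own = not hasattr(destination, "write")
    stream: TextIO = (
        open(destination, "w", encoding="utf-8") if own else destination  # type: ignore[assignment]
    )
    try:
        for g, e in model.items():
            stream.write(f"{g},{format_expression(e)}\n")
    finally:
        if own:
            stream.close()


def generate_bank_model(family: str, order: int) -> EpistasisModel:
    """One of the generalized threshold/additive/multiplicative families.

    With g_i the number of minor alleles at locus i (0, 1 or 2):

    - additive:        x * (1 + y) ** (g_1 + ... + g_k)
    - multiplicative:  x * (1 + y) ** (g_1 * ... * g_k)
    - threshold:       x * (1 + y) if every g_i >= 1, else x

    At order 2 the additive family reproduces the classic nine-cell
    two-locus table, rising from x at AABB to x(1+y)^4 at aabb.
    """
    if family not in BANK_FAMILIES:
        raise InvalidArgumentError(
            f"unknown family {family!r}; expected one of {BANK_FAMILIES}"
        )
    if not isinstance(order, (int, Integer)) or isinstance(order, bool) or order < 1:
        raise InvalidArgumentError(f"order must be a positive integer, got {order!r}")
    if order > MAX_ORDER:
        raise InvalidArgumentError(f"order {order} exceeds cap {MAX_ORDER}")
    entries = []
    for g in enumerate_genotypes(order):
        counts = minor_allele_counts(g)
        if family == "additive":
            expr = x * (1 + y) ** sum(counts)
        elif family == "multiplicative":
            expr = x * (1 + y) ** math.prod(counts)
        else:  # threshold
            expr = x * (1 + y) if all(c >= 1 for c in counts) else x
        entries.append((g, expr))
    return EpistasisModel.from_entries(f"{family}_{order}", entries)


def max_penetrance_expression(model: EpistasisModel) -> Expr:
    """The expression dominating all others for every x>0, y>0.

    Dominance is established symbolically where cheap (difference simplifies
    to a product of manifestly nonnegative factors under the positivity
    assumptions on x and y) and otherwise numerically on the probe grid
    ``PROBE_GRID``. For the bank families this is the all-minor-homozygote
    entry. If no single expression dominates at every probe point the
    max-penetrance constraint is ill-posed and the model is rejected.
    """
    distinct = model.distinct_expressions()
    if len(distinct) == 1:
        return distinct[0]
    # Candidate: the expression with the largest value at every probe point.
    best = None
    for xv, yv in PROBE_GRID:
        vals = [e.subs({x: xv, y: yv}).evalf(30) for e in distinct]
        top = max(vals)
        leaders = {i for i, v in enumerate(vals) if v >= top * (1 - sympy.Float("1e-12"))}
        best = leaders if best is None else best & leaders
    if not best:
        raise UnsupportedModelError(
            f"model {model.name!r}: no single expression dominates across the "
            "probe grid; the max-penetrance constraint is ill-posed"
        )
    if len(best) > 1:
        raise UnsupportedModelError(
            f"model {model.name!r}: {len(best)} distinct expressions tie for "
            "the maximum on the probe grid"
        )
    candidate = distinct[best.pop()]
    # Cheap symbolic confirmation where feasible: difference factors into
    # manifestly nonnegative parts under x, y > 0. Skipped for high-degree
    # expressions (factoring expands them densely); the numeric grid check
    # below covers those.
    for other in distinct:
        if other is candidate:
            continue
        if _symbolically_dominates(candidate, other):
            continue
        # denser numeric check along the y axis
        for yv in (1e-3, 0.01, 0.5, 2.0, 1e3):
            cv = candidate.subs({x: 1, y: sympy.Rational(str(yv))}).evalf(30)
            ov = other.subs({x: 1, y: sympy.Rational(str(yv))}).evalf(30)
            if cv < ov - sympy.Float("1e-15"):
                raise UnsupportedModelError(
                    f"model {model.name!r}: expression {format_expression(other)} "
                    f"exceeds {format_expression(candidate)} at y={yv}"
                )
    return candidate


def _symbolically_dominates(candidate: Expr, other: Expr) -> bool:
    try:
        if max(sympy.degree(candidate, y), sympy.degree(other, y)) > 16:
            return False
        return bool(sympy.factor(candidate - other).is_nonnegative)
    except (sympy.PolynomialError, RecursionError, TypeError):
        return False


def coverage_grid() -> list[tuple[str, int, float, str, float]]:
    """The full coverage experiment design.

    Every combination of family, order 2-8, uniform MAF 0.1-0.5 (step 0.1),
    fixed parameter value 0.1-0.9 (step 0.1) and fixed-parameter direction
    (prevalence or heritability). Returns tuples
    (family, order, maf, fixed_parameter, fixed_value); the grid has
    3 * 7 * 5 * 9 * 2 = 1890 configurations, half per direction.
    """
    grid = []
    mafs = [round(0.1 * i, 1) for i in range(1, 6)]
    values = [round(0.1 * i, 1) for i in range(1, 10)]
    for family in BANK_FAMILIES:
        for order in range(2, 9):
            for maf in mafs:
                for fixed in ("prevalence", "heritability"):
                    for v in values:
                        grid.append((family, order, maf, fixed, v))
    return grid
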