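"""Numeric penetrance tables and their CSV / GAMETES serializations.

A penetrance table is the evaluation of a solved model at the accepted
(x, y): one penetrance probability per genotype, in canonical genotype
order, together with the realized prevalence

    P(D) = sum_i P(D|g_i) P(g_i)

and realized heritability

    h^2 = sum_i (P(D|g_i) - P(D))^2 P(g_i) / (P(D) (1 - P(D)))

recomputed from the numeric entries. Entries are evaluated at 50
significant digits and only rounded when written, to 12 significant
digits. Tiny negative values (rounding artefacts within 1e-12) are clamped
to 0 and values within 1e-12 above 1 are clamped to 1; larger violations
are errors.

Output formats
--------------
CSV: one ``genotype,penetrance`` line per genotype, no header.

GAMETES-style model file: a header declaring one attribute per locus with
its MAF, the solved (x, y), a nested penetrance block — one line of three
values per last-locus triplet, labelled with the leading genotype prefix,
with a blank line whenever the first locus changes state — and a trailer
with the realized prevalence and heritability. The layout is pinned by
golden tests; byte-level compatibility with any specific GAMETES release
is not asserted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import TextIO

import mpmath
from sympy import lambdify

from .errors import InconsistentSolutionError, UndefinedHeritabilityError
from .genotypes import MafVector, genotype_frequencies
from .model import EpistasisModel, x, y
from .solver import WORKING_DPS, Solution, _as_mpf

#: significant digits used when printing penetrances
OUTPUT_DIGITS = 12

_CLAMP = 1e-12


@dataclass(frozen=True)
class PenetranceTable:
    """A solved model's genotype → penetrance map plus realized parameters."""

    name: str
    order: int
    mafs: MafVector
    genotypes: tuple[str, ...]
    penetrances: tuple[mpmath.mpf, ...]
    x_value: mpmath.mpf
    y_value: mpmath.mpf

    def items(self):
        return zip(self.genotypes, self.penetrances)

    def __len__(self) -> int:
        return len(self.genotypes)

    @property
    def prevalence(self) -> float:
        return realized_prevalence(self)

    @property
    def heritability(self) -> float:
        return realized_heritability(self)


def build_table(
    model: EpistasisModel, mafs: MafVector, solution: Solution
) -> PenetranceTable:
    """Evaluate every penetrance expression at the solved (x, y)."""
    if not isinstance(mafs, MafVector):
        mafs = MafVector(mafs)
    with mpmath.workdps(WORKING_DPS):
        values = []
        cache: dict = {}
        for g, e in model.items():
            fn = cache.get(e)
            if fn is None:
                fn = cache[e] = lambdify((x, y), e, modules="mpmath")
            v = mpmath.mpf(fn(solution.x_value, solution.y_value))
            if v < -_CLAMP or v > 1 + _CLAMP:
                raise InconsistentSolutionError(
                    f"penetrance {float(v):.6g} for genotype {g} lies outside "
                    "[0, 1] beyond rounding tolerance"
                )
            values.append(mpmath.mpf(0) if v < 0 else (mpmath.mpf(1) if v > 1 else v))
    return PenetranceTable(
        name=model.name,
        order=model.order,
        mafs=mafs,
        genotypes=model.genotypes,
        penetrances=tuple(values),
        x_value=solution.x_value,
        y_value=solution.y_value,
    )


def realized_prevalence(table: PenetranceTable) -> float:
    """Frequency-weighted mean penetrance, P(D) = sum_i P(D|g_i) P(g_i)."""
    with mpmath.workdps(WORKING_DPS):
        freqs = genotype_frequencies(table.mafs)
        total = mpmath.mpf(0)
        for p, (g, q) in zip(table.penetrances, freqs.items()):
            total += p * _as_mpf(q, WORKING_DPS)
        return float(total)


def realized_heritability(table: PenetranceTable) -> float:
    """Variance-ratio heritability of the table at its realized prevalence."""
    with mpmath.workdps(WORKING_DPS):
        freqs = genotype_frequencies(table.mafs)
        weights = [_as_mpf(q, WORKING_DPS) for q in freqs.probabilities]
        pd = mpmath.mpf(0)
        for p, w in zip(table.penetrances, weights):
            pd += p * w
        if pd <= 0 or pd >= 1:
            raise UndefinedHeritabilityError(
                f"heritability is undefined at prevalence {float(pd)}"
            )
        var = mpmath.mpf(0)
        for p, w in zip(table.penetrances, weights):
            var += (p - pd) ** 2 * w
        return float(var / (pd * (1 - pd)))


def format_penetrance(value) -> str:
    """A penetrance as text with 12 significant digits (no exponent noise
    for the [0, 1] range: mpmath's nstr with trailing-zero stripping)."""
    with mpmath.workdps(WORKING_DPS):
        s = mpmath.nstr(mpmath.mpf(value), OUTPUT_DIGITS, strip_zeros=True)
    if s.endswith(".0"):
        s = s[:-2]
    return s


def _open(destination, mode="w"):
    if hasattr(destination, "write"):
        return destination, False
    return open(destination, mode, encoding="utf-8"), True


def write_csv(table: PenetranceTable, destination: str | os.PathLike | TextIO) -> None:
    """One ``genotype,penetrance`` line per genotype, canonical order, no header."""
    stream, own = _open(destination)
    try:
        for g, p in table.items():
            stream.write(f"{g},{format_penetrance(p)}\n")
    finally:
        if own:
            stream.close()


def write_gametes(table: PenetranceTable, destination: str | os.PathLike | TextIO) -> None:
    """GAMETES-style model file (layout documented in the module docstring)."""
    stream, own = _open(destination)
    try:
        names = [f"P{i}" for i in range(table.order)]
        stream.write("Attribute names:\t" + "\t".join(names) + "\n")
        stream.write(
            "Minor allele frequencies:\t"
            + "\t".join(format_penetrance(_as_mpf(m, WORKING_DPS)) for m in table.mafs)
            + "\n"
        )
        stream.write(f"x: {format_penetrance(table.x_value)}\n")
        stream.write(f"y: {format_penetrance(table.y_value)}\n")
        stream.write("\nTable:\n\n")
        if table.order == 1:
            stream.write(
                ", ".join(format_penetrance(p) for p in table.penetrances) + "\n"
            )
        else:
            prev_first = None
            for block in range(0, len(table.genotypes), 3):
                prefix = table.genotypes[block][: 2 * (table.order - 1)]
                first = prefix[:2]
                if prev_first is not None and first != prev_first:
                    stream.write("\n")
                prev_first = first
                vals = ", ".join(
                    format_penetrance(p) for p in table.penetrances[block : block + 3]
                )
                stream.write(f"{prefix}\t{vals}\n")
        stream.write(f"\nPrevalence: {format_penetrance(realized_prevalence(table))}\n")
        stream.write(f"Heritability: {format_penetrance(realized_heritability(table))}\n")
    finally:
        if own:
            stream.close()
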