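"""Multi-locus genotypes and their Hardy-Weinberg population frequencies.

Loci are biallelic SNPs. Each locus is written with one letter (A for the
first locus, B for the second, ...); the uppercase letter is the major
allele (population frequency 1 - MAF) and the lowercase letter the minor
allele (frequency MAF). A genotype over ``order`` loci is the concatenation
of one allele pair per locus, e.g. ``"AaBB"`` for two loci.

Assuming linkage equilibrium between loci and Hardy-Weinberg proportions
within each locus, the population frequency of a genotype is the product of
the per-locus pair frequencies: (1-m)^2 for the major homozygote, 2m(1-m)
for the heterozygote and m^2 for the minor homozygote.

Frequencies are kept as exact :class:`sympy.Rational` numbers so that
downstream equation building loses no precision.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Iterator, Sequence

from sympy import Integer, Rational

from .errors import InvalidArgumentError

#: Largest supported interaction order (letters A..L).
MAX_ORDER = 12

_LETTERS = string.ascii_uppercase[:MAX_ORDER]


def _to_rational(value) -> Rational:
    """Convert a float/str/Rational to an exact Rational via its decimal form."""
    if isinstance(value, Rational):
        return value
    return Rational(str(value))


@dataclass(frozen=True)
class MafVector:
    """Per-locus minor allele frequencies, each strictly in (0, 0.5].

    Values are stored as exact rationals (``0.1`` becomes ``1/10``).
    """

    mafs: tuple[Rational, ...]

    def __init__(self, mafs: Sequence) -> None:
        vals = tuple(_to_rational(m) for m in mafs)
        if len(vals) == 0:
            raise InvalidArgumentError("MAF vector must contain at least one locus")
        for m in vals:
            if not (0 < m <= Rational(1, 2)):
                raise InvalidArgumentError(
                    f"MAF {m} outside (0, 0.5]; minor allele frequencies must be "
                    "positive and at most 0.5"
                )
        object.__setattr__(self, "mafs", vals)

    def __len__(self) -> int:
        return len(self.mafs)

    def __iter__(self) -> Iterator[Rational]:
        return iter(self.mafs)

    def __getitem__(self, i):
        return self.mafs[i]

    @property
    def order(self) -> int:
        return len(self.mafs)


@dataclass(frozen=True)
class GenotypeFrequencyTable:
    """Ordered (genotype, probability) pairs covering all 3^order genotypes."""

    genotypes: tuple[str, ...]
    probabilities: tuple[Rational, ...]

    def __len__(self) -> int:
        return len(self.genotypes)

    def items(self):
        return zip(self.genotypes, self.probabilities)

    def as_dict(self) -> dict[str, Rational]:
        return dict(self.items())

    @property
    def total(self) -> Rational:
        return sum(self.probabilities, Integer(0))


def _check_order(order: int) -> None:
    if not isinstance(order, (int, Integer)) or isinstance(order, bool):
        raise InvalidArgumentError(f"order must be an integer, got {order!r}")
    if order < 1 or order > MAX_ORDER:
        raise InvalidArgumentError(
            f"order must be in [1, {MAX_ORDER}], got {order}"
        )


def locus_pairs(locus_index: int) -> tuple[str, str, str]:
    """The three canonical allele pairs of a locus: (major-hom, het, minor-hom)."""
    upper = _LETTERS[locus_index]
    lower = upper.lower()
    return (upper + upper, upper + lower, lower + lower)


def enumerate_genotypes(order: int) -> list[str]:
    """All 3^order genotype strings in canonical order.

    Per locus the sequence is (major homozygote, heterozygote, minor
    homozygote); the last locus varies fastest, so for two loci the order is
    AABB, AABb, AAbb, AaBB, ..., aabb — the row-wise reading of the usual
    two-locus table layout.
    """
    _check_order(order)
    per_locus = [locus_pairs(i) for i in range(order)]
    return ["".join(combo) for combo in itertools.product(*per_locus)]


def minor_allele_counts(genotype: str) -> tuple[int, ...]:
    """Number of minor (lowercase) alleles at each locus, each in {0, 1, 2}."""
    if len(genotype) % 2 != 0:
        raise InvalidArgumentError(f"genotype string {genotype!r} has odd length")
    return tuple(
        sum(1 for ch in genotype[2 * i : 2 * i + 2] if ch.islower())
        for i in range(len(genotype) // 2)
    )


def genotype_frequencies(mafs: MafVector | Sequence) -> GenotypeFrequencyTable:
    """Hardy-Weinberg population frequency of every multi-locus genotype.

    For each genotype P(g) = prod over loci of {(1-m)^2, 2m(1-m), m^2}
    according to the locus state. The probabilities are exact rationals and
    sum to exactly 1.
    """
    if not isinstance(mafs, MafVector):
        mafs = MafVector(mafs)
    order = len(mafs)
    _check_order(order)
    per_locus_probs = []
    for m in mafs:
        per_locus_probs.append(((1 - m) ** 2, 2 * m * (1 - m), m**2))
    genotypes = []
    probs = []
    per_locus = [locus_pairs(i) for i in range(order)]
    for combo in itertools.product(*(range(3) for _ in range(order))):
        genotypes.append("".join(per_locus[i][s] for i, s in enumerate(combo)))
        p = Integer(1)
        for i, s in enumerate(combo):
            p *= per_locus_probs[i][s]
        probs.append(p)
    return GenotypeFrequencyTable(tuple(genotypes), tuple(probs))
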