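import io
import itertools
import math

import pytest
import sympy
from sympy import symbols

import epistab as et
from epistab.errors import (
    ExpressionError,
    InvalidArgumentError,
    MalformedModelError,
    UnsupportedModelError,
)
from epistab.model import x, y

# the classic second-order additive table, row-wise from AABB to aabb
TABLE2 = [
    ("AABB", "x"), ("AABb", "x*(1 + y)"), ("AAbb", "x*(1 + y)^2"),
    ("AaBB", "x*(1 + y)"), ("AaBb", "x*(1 + y)^2"), ("Aabb", "x*(1 + y)^3"),
    ("aaBB", "x*(1 + y)^2"), ("aaBb", "x*(1 + y)^3"), ("aabb", "x*(1 + y)^4"),
]


class TestParsing:
    def test_parse_table2(self):
        text = "".join(f"{g},{e}\n" for g, e in TABLE2)
        model = et.parse_model_csv(io.StringIO(text))
        assert model.order == 2
        assert model.as_dict()["aabb"] == x * (1 + y) ** 4

    def test_parse_reorders_to_canonical(self):
        text = "".join(f"{g},{e}\n" for g, e in reversed(TABLE2))
        model = et.parse_model_csv(io.StringIO(text))
        assert model.genotypes == tuple(et.enumerate_genotypes(2))

    def test_comments_blank_lines_and_double_star(self):
        text = "# a comment\nAA,x\n\nAa,x*(1+y)\naa,x*(1+y)**2\n"
        model = et.parse_model_csv(io.StringIO(text))
        assert model.as_dict()["aa"] == x * (1 + y) ** 2

    def test_empty_input(self):
        with pytest.raises(MalformedModelError):
            et.parse_model_csv(io.StringIO(""))

    def test_missing_genotype_is_named(self):
        rows = [r for r in TABLE2 if r[0] != "AaBb"]
        text = "".join(f"{g},{e}\n" for g, e in rows)
        with pytest.raises(MalformedModelError, match="AaBb|not a power of 3"):
            et.parse_model_csv(io.StringIO(text))

    def test_duplicate_genotype(self):
        rows = TABLE2[:-1] + [TABLE2[0]]
        text = "".join(f"{g},{e}\n" for g, e in rows)
        with pytest.raises(MalformedModelError, match="duplicate"):
            et.parse_model_csv(io.StringIO(text))

    def test_foreign_variable_rejected(self):
        text = "AA,x\nAa,x*z\naa,x*(1+y)\n"
        with pytest.raises(ExpressionError, match="z"):
            et.parse_model_csv(io.StringIO(text))

    def test_non_power_of_three_row_count(self):
        text = "".join(f"{g},{e}\n" for g, e in TABLE2[:5])
        with pytest.raises(MalformedModelError):
            et.parse_model_csv(io.StringIO(text))


class TestRoundTrip:
    @pytest.mark.parametrize(
        "family,order",
        [(f, o) for f in et.BANK_FAMILIES for o in (2, 3, 5)] + [("additive", 8)],
    )
    def test_write_parse_identity(self, family, order):
        model = et.generate_bank_model(family, order)
        buf = io.StringIO()
        et.write_model_csv(model, buf)
        lines = buf.getvalue().strip().split("\n")
        assert len(lines) == 3**order
        again = et.parse_model_csv(io.StringIO(buf.getvalue()))
        assert again.genotypes == model.genotypes
        assert again.expressions == model.expressions

    def test_caret_printed_not_double_star(self):
        buf = io.StringIO()
        et.write_model_csv(et.generate_bank_model("additive", 2), buf)
        assert "^" in buf.getvalue()
        assert "**" not in buf.getvalue()


class TestBankModels:
    def test_additive_2_is_table2(self):
        model = et.generate_bank_model("additive", 2)
        expected = {g: sympy.sympify(e.replace("^", "**"), {"x": x, "y": y})
                    for g, e in TABLE2}
        assert model.as_dict() == expected

    def test_multiplicative_exponent_is_product(self):
        model = et.generate_bank_model("multiplicative", 2).as_dict()
        assert model["aabb"] == x * (1 + y) ** 4
        assert model["Aabb"] == x * (1 + y) ** 2
        assert model["AAbb"] == x  # product 0*2 = 0

    def test_threshold_all_loci_condition(self):
        model = et.generate_bank_model("threshold", 3).as_dict()
        assert model["AaBbCc"] == x * (1 + y)
        assert model["AABbCc"] == x

    def test_unknown_family(self):
        with pytest.raises(InvalidArgumentError):
            et.generate_bank_model("dominant", 2)

    @pytest.mark.parametrize("order", [2, 3, 4])
    def test_distinct_expression_counts(self, order):
        """Brute-force enumeration of the defining exponent rules."""
        counts = [et.minor_allele_counts(g) for g in et.enumerate_genotypes(order)]
        expected = {
            "threshold": 2,
            "additive": len({sum(c) for c in counts}),
            "multiplicative": len({math.prod(c) for c in counts}),
        }
        assert expected["additive"] == 2 * order + 1
        for family, n in expected.items():
            model = et.generate_bank_model(family, order)
            assert len(model.distinct_expressions()) == n

    @pytest.mark.parametrize("family", et.BANK_FAMILIES)
    def test_nondecreasing_in_minor_allele_count(self, family):
        """At any y > 0, adding minor alleles never lowers the penetrance."""
        model = et.generate_bank_model(family, 2)
        lookup = model.as_dict()
        for yv in (0.1, 1.0, 10.0):
            subs = {x: 1, y: yv}
            for g in model.genotypes:
                counts = list(et.minor_allele_counts(g))
                for i, c in enumerate(counts):
                    if c == 2:
                        continue
                    bumped = counts.copy()
                    bumped[i] += 1
                    h = "".join(
                        et.genotypes.locus_pairs(j)[k] for j, k in enumerate(bumped)
                    )
                    assert float(lookup[h].subs(subs)) >= float(lookup[g].subs(subs))


class TestMaxPenetrance:
    def test_additive_2(self):
        model = et.generate_bank_model("additive", 2)
        assert et.max_penetrance_expression(model) == x * (1 + y) ** 4

    @pytest.mark.parametrize("order", [2, 4])
    def test_threshold_any_order(self, order):
        model = et.generate_bank_model("threshold", order)
        assert et.max_penetrance_expression(model) == x * (1 + y)

    def test_all_minor_corner_dominates_bank(self):
        for family in et.BANK_FAMILIES:
            model = et.generate_bank_model(family, 3)
            assert et.max_penetrance_expression(model) == model.expressions[-1]

    def test_single_expression_model(self, flat2):
        assert et.max_penetrance_expression(flat2) == x

    def test_crossing_expressions_rejected(self):
        # x*(2+y) beats x*(1+y)^2 for small y, loses for large y
        model = et.EpistasisModel.from_entries(
            "crossing", [("AA", "x"), ("Aa", "x*(2+y)"), ("aa", "x*(1+y)^2")]
        )
        with pytest.raises(UnsupportedModelError):
            et.max_penetrance_expression(model)
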