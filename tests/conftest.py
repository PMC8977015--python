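import pytest
from sympy import sqrt

import epistab as et


@pytest.fixture(scope="session")
def additive1():
    return et.generate_bank_model("additive", 1)


@pytest.fixture(scope="session")
def additive2():
    return et.generate_bank_model("additive", 2)


@pytest.fixture(scope="session")
def threshold2():
    return et.generate_bank_model("threshold", 2)


@pytest.fixture(scope="session")
def flat2():
    """Order-2 model with every penetrance equal to the baseline x."""
    return et.EpistasisModel.from_entries(
        "flat", [(g, "x") for g in et.enumerate_genotypes(2)]
    )


@pytest.fixture(scope="session")
def closed_form_solution(additive1):
    """Order-1 additive, MAF 0.5, fixed prevalence 0.5.

    Eliminating x via x = (1+y)^-2 turns the main equation into the
    quadratic t^2 - 2t - 1 = 0 in t = 1 + y, so y = sqrt(2) and
    x = 3 - 2*sqrt(2) exactly.
    """
    system = et.build_system(additive1, et.MafVector([0.5]), "prevalence", 0.5)
    solution = et.solve_system(system)
    return system, solution


EXACT_Y = float(sqrt(2))
EXACT_X = float(3 - 2 * sqrt(2))
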