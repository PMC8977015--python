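"""epistab: penetrance tables for high-order epistasis models.

Build a constrained nonlinear system from a symbolic epistasis model
f_i(x, y), per-locus minor allele frequencies and one fixed population
parameter (prevalence or heritability), solve it while pinning the maximum
penetrance to 1 (maximizing the other parameter), and emit the numeric
penetrance table in CSV or GAMETES model-file format.

Typical use::

    import epistab

    model = epistab.generate_bank_model("additive", 2)
    table = epistab.compute_table(model, mafs=[0.25, 0.25],
                                  fixed_parameter="prevalence",
                                  fixed_value=0.3)
    print(table.heritability)
    epistab.write_csv(table, "additive_2.csv")
"""

from .errors import (
    EpistabError,
    ExpressionError,
    InconsistentSolutionError,
    InvalidArgumentError,
    MalformedModelError,
    SolverTimeoutError,
    UndefinedHeritabilityError,
    UnsolvableConfigurationError,
    UnsupportedModelError,
)
from .genotypes import (
    MAX_ORDER,
    GenotypeFrequencyTable,
    MafVector,
    enumerate_genotypes,
    genotype_frequencies,
    minor_allele_counts,
)
from .model import (
    BANK_FAMILIES,
    EpistasisModel,
    coverage_grid,
    format_expression,
    generate_bank_model,
    max_penetrance_expression,
    parse_model_csv,
    write_model_csv,
)
from .oracle import oracle_solve
from .solver import (
    EquationSystem,
    Solution,
    SolutionPrecisionWarning,
    SolverConfig,
    build_system,
    check_solution,
    heuristic_timeout,
    solve_system,
    tolerable_error,
)
from .table import (
    PenetranceTable,
    build_table,
    realized_heritability,
    realized_prevalence,
    write_csv,
    write_gametes,
)

__version__ = "0.1.0"

__all__ = [
    "BANK_FAMILIES",
    "EpistabError",
    "EpistasisModel",
    "EquationSystem",
    "ExpressionError",
    "GenotypeFrequencyTable",
    "InconsistentSolutionError",
    "InvalidArgumentError",
    "MAX_ORDER",
    "MafVector",
    "MalformedModelError",
    "PenetranceTable",
    "Solution",
    "SolutionPrecisionWarning",
    "SolverConfig",
    "SolverTimeoutError",
    "UndefinedHeritabilityError",
    "UnsolvableConfigurationError",
    "UnsupportedModelError",
    "build_system",
    "build_table",
    "check_solution",
    "compute_table",
    "coverage_grid",
    "enumerate_genotypes",
    "format_expression",
    "generate_bank_model",
    "genotype_frequencies",
    "heuristic_timeout",
    "max_penetrance_expression",
    "minor_allele_counts",
    "oracle_solve",
    "parse_model_csv",
    "realized_heritability",
    "realized_prevalence",
    "solve_system",
    "tolerable_error",
    "write_csv",
    "write_gametes",
    "write_model_csv",
]


def compute_table(
    model: EpistasisModel,
    mafs,
    fixed_parameter: str,
    fixed_value,
    config: SolverConfig | None = None,
) -> PenetranceTable:
    """End-to-end convenience: build the system, solve it, build the table.

    ``fixed_parameter`` is ``"prevalence"`` (heritability is maximized) or
    ``"heritability"`` (prevalence is maximized).
    """
    if not isinstance(mafs, MafVector):
        mafs = MafVector(mafs)
    system = build_system(model, mafs, fixed_parameter, fixed_value)
    solution = solve_system(system, config)
    return build_table(model, mafs, solution)
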