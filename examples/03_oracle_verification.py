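"""Cross-check the symbolic solver against the independent bisection oracle.

The main solver eliminates x through the max-penetrance constraint and
isolates the real roots of the resulting polynomial exactly; the oracle
solves the same scalar problem by bracketing and bisection only. Agreement
to ~1e-9 on y (and entrywise on the table) is strong evidence both are
correct, since they share no numerics.
"""

import epistab as et

model = et.generate_bank_model("multiplicative", 3)
mafs = et.MafVector([0.2, 0.2, 0.2])

system = et.build_system(model, mafs, "heritability", 0.15)
symbolic = et.solve_system(system)
oracle = et.oracle_solve(model, mafs, "heritability", 0.15)

y_sym, y_orc = float(symbolic.y_value), float(oracle.y_value)
print(f"symbolic solver: y = {y_sym:.15g} (residual {symbolic.residual:.2e})")
print(f"bisection oracle: y = {y_orc:.15g} (residual {oracle.residual:.2e})")
print(f"relative disagreement: {abs(y_sym - y_orc) / y_orc:.2e}  (should be < 1e-9)")
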