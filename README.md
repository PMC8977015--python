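# epistab

Penetrance tables for high-order epistasis models, computed to a guaranteed
accuracy under a fixed prevalence or heritability.

## The problem

Methods that detect gene-gene interactions (epistasis) in GWAS data are
benchmarked on simulated case-control datasets in which the interaction is
known. The standard way to specify an interaction over k biallelic SNPs is a
*penetrance table*: for each of the 3^k genotype combinations g_i, the
probability P(D|g_i) of expressing the disease D. Simulators such as GAMETES
consume these tables, but producing a table that realizes a *prescribed*
prevalence P(D) and heritability h² is a constrained nonlinear problem that
becomes numerically hard as the interaction order grows — and many
(P(D), h²) pairs are jointly infeasible.

`epistab` takes a symbolic model f_i(x, y) (penetrance expressions in a
baseline x and effect size y), the per-locus minor allele frequencies
(MAFs), and **one** fixed parameter, and solves

```
  Σ_i f_i(x,y) · P(g_i) = P(D)            (fixed prevalence)       or
  Σ_i (f_i(x,y) − P(D))² · P(g_i)
  ───────────────────────────────  = h²   (fixed heritability)
        P(D) · (1 − P(D))
```

together with the constraint `max_i f_i(x, y) = 1`, which maximizes the
parameter that is left free. Genotype frequencies P(g_i) follow
Hardy-Weinberg proportions with linkage equilibrium between loci:
P(g) = Π_locus {(1−m)², 2m(1−m), m²}.

The constraint is solved for x, the cleared main equation becomes a
univariate polynomial in y with exact rational coefficients, its real roots
are isolated exactly and refined to 50 significant digits, and admissible
roots (x > 0, all penetrances in [0, 1]) are accepted against an
order-dependent tolerable error E_tol(k) = min(10^k · 10⁻¹⁶, 10⁻⁸) — so
every accepted table reproduces its fixed parameter to at worst 10⁻⁸, and
in practice to ~10⁻¹⁶ or better. An independent bracketing/bisection oracle
(`epistab.oracle_solve`) cross-checks the solver.

Built-in model families (generalized to any order, with g_i the minor-allele
count at locus i): **additive** x(1+y)^Σg_i, **multiplicative** x(1+y)^Πg_i,
**threshold** x(1+y) iff every g_i ≥ 1 else x. Custom models are read from a
two-column CSV (`genotype,expression`).

## Worked example

```python
import epistab as et

model = et.generate_bank_model("additive", 2)
table = et.compute_table(model, mafs=[0.25, 0.25],
                         fixed_parameter="prevalence", fixed_value=0.3)
```

Running `python examples/01_bank_model_table.py` prints:

```
model: additive_2, MAFs 0.25/0.25, fixed prevalence 0.3
solved baseline x = 0.1823193674, effect y = 0.530353632336
  AABB  0.1823193674
  AABb  0.279013106146
  ...
  aabb  1
realized prevalence   = 0.3   (requested 0.3)
realized heritability = 0.074947857563  (maximized)
```

Each line maps a two-locus genotype (uppercase = major allele) to its disease
probability; the all-minor-homozygote corner `aabb` carries the pinned
maximum penetrance 1. The frequency-weighted mean of the column reproduces
the requested prevalence exactly, and 0.0749 is the largest heritability an
additive two-locus model with these MAFs can express at that prevalence.

Tables serialize with `et.write_csv` (one `genotype,penetrance` line, 12
significant digits) or `et.write_gametes` (a GAMETES-style model file with
attribute MAFs, the solved x and y, the nested penetrance block, and the
realized prevalence/heritability). The other scripts in `examples/` show
custom model CSVs, the verification oracle, and a coverage scan.

## Command line

```sh
epistab multiplicative_4.csv --max_her 0.6 0.2 0.3 0.3 0.4 --gametes
```

fixes prevalence 0.6 for the order-4 multiplicative model at MAFs
0.2/0.3/0.3/0.4, maximizes heritability, and prints the GAMETES-format table
(`--max_prev` fixes heritability instead; `-o FILE` writes to a file,
`--timeout none|auto|SECONDS` and `--no-check` expose the solver options).
Exit codes: 0 success, 1 usage, 2 unsolvable/timeout, 3 I/O.

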