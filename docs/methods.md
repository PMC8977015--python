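# Methods

## The model

An epistasis model over k biallelic loci assigns every genotype combination
g_i (3^k of them) a symbolic penetrance f_i(x, y): the probability of
expressing the disease given that genotype, written in a baseline x and an
effect size y. The built-in families generalize the classic two-variable
two-locus models to any order, with g_i below the per-locus minor-allele
count (0, 1 or 2):

| family         | f(x, y)                                   |
|----------------|-------------------------------------------|
| additive       | x (1+y)^(g_1 + ... + g_k)                  |
| multiplicative | x (1+y)^(g_1 · ... · g_k)                  |
| threshold      | x (1+y) if every g_i ≥ 1, else x           |

Genotype population frequencies assume Hardy-Weinberg proportions within
each locus and linkage equilibrium between loci, so
P(g) = Π_locus {(1−m)², 2m(1−m), m²} with m the locus MAF, restricted to
(0, 0.5] (a "minor" allele above 0.5 is contradictory; exactly 0
degenerates the system). Uppercase letters denote the major allele. All
frequencies are exact `sympy.Rational`s, so equation building introduces no
rounding.

The population parameters of a numeric table are

    P(D) = Σ_i P(D|g_i) P(g_i)                       (prevalence)
    h²   = Σ_i (P(D|g_i) − P(D))² P(g_i) / (P(D)(1−P(D)))   (heritability)

Requiring both simultaneously is frequently infeasible, so the method fixes
one and pins the maximum penetrance to 1, which maximizes the free one.
Pinning max f_i = 1 maximizes the spread of the penetrance column for a
given shape, hence the variance ratio when prevalence is fixed, and (on the
returned branch, see Root selection) the prevalence when heritability is
fixed.

## Solver

1. **Grouping.** The main equation is assembled over the structurally
   distinct expressions of the model, each weighted by the total
   Hardy-Weinberg frequency of its genotypes. This is an exact regrouping
   of the 3^k-term sum: the additive family has 2k+1 distinct expressions,
   threshold 2, multiplicative k+2, so systems stay small at any order. For
   systems below ~300 operations the grouped form is additionally passed
   through sympy's cancel/together simplification; the simplified system is
   checked in the test suite to agree with the raw 3^k-term sum at random
   probe points to 1e-20 relative.
2. **Dominating expression.** The constraint needs the single expression
   that dominates all others for x > 0, y > 0. Dominance is established on
   the probe grid x = 1, y ∈ {0.1, 1, 10, 100} (every supported model
   factors the baseline x out, so dominance depends on y alone), confirmed
   symbolically where the difference factors cheaply (degree ≤ 16) and by a
   denser y-grid otherwise. Models without a single dominator are rejected
   as ill-posed.
3. **Elimination and clearing.** The constraint is solved for x
   (x = 1/u(y) for all bank families) and substituted. When every
   expression factors as x·g(y) with polynomial g — true for the bank
   families and typical custom models — the cleared main equation is built
   directly with exact polynomial arithmetic: fixed prevalence P gives
   A(y) − P·u(y), fixed heritability h² gives
   Σ_j w_j (g_j − A)² − h²·A·(u − A), with A = Σ_j w_j g_j. Other models
   fall back to a generic together/fraction route. Multiplying out the
   heritability denominator can introduce spurious roots where the
   prevalence is 0 or 1; these are eliminated by the residual gate below.
4. **Root isolation.** The nonnegative real roots of the cleared
   polynomial are isolated exactly (`Poly.intervals(inf=0)`; restricting
   to [0, ∞) is orders of magnitude cheaper than full isolation at the
   degree-512 systems order-8 multiplicative models produce) and each
   simple root is refined to 50 significant digits by bisection inside its
   isolating interval with 25 guard digits; the acceptance gate below
   independently re-evaluates every refined root, so refinement cannot
   silently go wrong. The polynomial is rebuilt over an assumption-free
   symbol first (positivity assumptions on y slow sympy's polynomial
   machinery pathologically at high degree). Exact arithmetic decides root
   existence, which is why coverage extends beyond what
   floating/variable-precision solvers reach (see Limitations).
5. **Admissibility and acceptance.** A root is admissible when y ≥ 0
   (dominance, hence the constraint itself, is only established for
   nonnegative effect sizes; a negative-y root can pass every numeric gate
   while describing a different model regime — tiny negatives below 1e-20
   are rounding noise on a y = 0 root and are clamped), x = 1/u(y) is
   positive and finite, and every penetrance lies in [0, 1] within the
   tolerable error E_tol(k) = min(10^k·10⁻¹⁶, 10⁻⁸). The residual — the
   fixed parameter recomputed from the main equation at (x, y) minus the
   request — must pass an acceptance tolerance that starts at 1e-30 and
   relaxes by 10⁴ per retry up to 10⁻⁸ (`Solution.attempts` records the
   schedule position). E_tol's base error 10⁻¹⁶ scales with order because
   the cleared degree (and root conditioning) grows with it; the 10⁻⁸ cap
   is the guaranteed worst-case deviation of any accepted table.
6. **Root selection.** Residuals of exactly-isolated roots sit at ~1e-45,
   far below every tolerance, so ordering by raw residual would compare
   noise. All admissible roots within the current tolerance are treated as
   residual-tied and the smallest y wins. This is deterministic and
   coincides with the oracle's smallest-admissible-y policy. For
   heritability-fixed systems, which are non-monotone in y, a given h² is
   typically attained at two prevalences; smallest y is the
   highest-prevalence branch, i.e. the branch on which prevalence is
   actually maximized. A consequence worth knowing: solving with a *low*
   fixed prevalence and re-fixing the realized heritability returns the
   other (higher-prevalence) table with the same h², not the original —
   exact round-tripping holds only on the maximizing branch.
7. **Checking.** With `check=True` (default) the fixed parameter is
   re-derived from the solution; a deviation above E_tol flags the solution
   with a warning (not an error), mirroring batch use where a flagged table
   is still written but marked suspect.
8. **Timeout.** `timeout="heuristic"` (default) budgets 60(k+1)² seconds.
   The deadline is checked cooperatively between stages, and long
   root-isolation calls run under a SIGALRM timer (main thread only) so
   they can be interrupted mid-call; `timeout=None` disables both,
   a number sets the budget directly.

## Verification oracle

`oracle_solve` shares only the system definition with the solver:
substituting x = 1/u(y) reduces the problem to a scalar root-find in y,
done purely numerically. Prevalence-fixed functions are decreasing in y
(penetrances fall away from the pinned maximum), so one bracket is found
by doubling the upper bound from 10 (cap 2^40) and bisected to a bracket
width of 1e-15; the monotone sign pattern is asserted on a grid first.
Heritability-fixed functions may be non-monotone, so a 10^4-point
logarithmic grid (evaluated at 25 digits) collects every sign change, each
bracket is bisected at 50 digits, and the smallest admissible root is
returned. Agreement between the two solvers to 1e-9 relative on y and
entrywise on tables is asserted across the battery at orders 2-3.

## Bank models as study conditions

The generated threshold/additive/multiplicative families are the study
conditions themselves, not an approximation of data: coverage and accuracy
are measured on them at uniform MAFs 0.1-0.5 and fixed values 0.1-0.9
(1890 configurations in the full design; `coverage_grid()` enumerates it).
What passing these checks does *not* show: behaviour on models with
non-factoring baselines, loci in linkage disequilibrium, non-biallelic
markers, or penetrance tables taken from fitted real-data models — all
outside the package's scope.

## Numerical choices

- Working precision 50 significant digits (mpmath); exact rational
  arithmetic up to the point of root refinement.
- Table entries are clamped to [0, 1] when within 1e-12 (rounding
  artefacts); larger violations raise. Note this is deliberately stricter
  than the solver's admissibility tolerance E_tol: a solution the solver
  accepts at order ≥ 5 can in principle carry a penetrance excursion in
  (1e-12, 1e-10] that table construction rejects; in the measured batteries
  this does not occur for y ≥ 0 roots.
- Output precision 12 significant digits in both CSV and GAMETES writers;
  the writers share the formatter, so both formats print identical values.
- Degenerate systems with y absent (e.g. a constant model) report y = 0
  canonically and solve only if the fixed value is reachable exactly.
- Ties among several genotypes carrying the same dominating expression are
  expected (threshold models); uniqueness is required at expression level,
  not entry level.

## Problem sizes used by the checks

The test battery spans orders 2-4 (plus coverage runs to order 8 and spot
checks at orders 5-6); the coverage scan in `scripts/acceptance.py` runs
threshold/additive to order 10 and multiplicative to order 8 (its
heritability system clears to a degree-512 polynomial, the largest the
scan touches); the full scan takes on the order of a minute on one CPU.
All inputs are generated programmatically; nothing is read from disk.

## Known limitations

- Multiplicative systems beyond order 8 (degree > 512 after clearing) are
  increasingly expensive to isolate exactly; the heuristic timeout is the
  intended guard. Historically such configurations were reported as
  unsolvable by variable-precision solvers; exact isolation shows many are
  solvable, merely slow, so "coverage" here reflects root existence plus
  the time budget.
- Penetrance expressions must be nonnegative and finite on the validation
  grid x ∈ {1e-3, 0.5, 1} × y ∈ {0.1, 1, 10, 100}; models violating this
  (e.g. protective effects that cross zero) are rejected rather than
  solved in an extended regime.
- The GAMETES writer pins this package's documented layout; byte-level
  compatibility with a specific GAMETES release has not been verified
  against that tool.
- Only two free variables (x, y) are supported; simultaneous
  prevalence-and-heritability targets are out of scope by design (that
  two-constraint system is the frequently-infeasible formulation this
  method replaces).
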