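# Methods

## The model

One cohort, one generation, no stochasticity in the core. The pipeline is

1. **Pre-adult survival.** `n0` pre-adult individuals of each sex are
   thinned deterministically: survivors = `round(n0 · (1 − mortality))`,
   rounding halves away from zero. On the canonical grid (cohorts of 30;
   mortalities 10/40/70%) the product is always exactly integral, so
   rounding never fires there; a *strict* mode raises
   `NonIntegralCountError` whenever the expected count deviates from an
   integer by more than 1e-9, for users who want the domain restricted to
   exact grids. Mortality is a single pre-adult episode; age-structured
   schedules and binomial (stochastic) survival are out of scope.

2. **Trait assignment.** A binary mate-acquisition trait is fixed among
   the `n` surviving males: either `k = round(level · n)` carriers
   (fixed proportion; strict mode as above) or `k = level` carriers
   (fixed number; an error if `level > n`, since carriers cannot exceed
   survivors). Carriers occupy the first `k` indices. This is a pure
   convention: every statistic the package reports is invariant to
   permutations of the trait vector, which the test suite asserts both
   property-based and exhaustively on small cases.

3. **Mate allocation.** Females mate exactly once; males may mate
   multiply; only carriers can mate. `F` females are shared among `k`
   carriers as equitably as possible under an integer constraint: each
   carrier gets `F // k`, and `F mod k` carriers get one extra.
   Consequences: mate counts sum to `F`, and the spread among carriers is
   at most 1. Which carriers receive the extras is the model's only
   arbitrary choice; the default gives them to the lowest-index carriers
   (bit-reproducible outputs), and a seeded random mode exists purely to
   demonstrate that the choice moves no reported statistic. `F < k` is
   permitted (some carriers unmated) even though the canonical grids
   never produce it.

4. **Selection statistics.** Relative fitness is the fitness component
   divided by its mean (mean exactly 1 after normalization; an all-zero
   component is an error). The selection differential is the
   **population covariance** (divide by `n`) of the trait with relative
   fitness: with that divisor the differential equals the
   within-generation change in trait mean caused by selection, which is
   the property that makes the number interpretable. A sample-covariance
   option (`ddof=1`) exists for comparison with n−1 conventions; the
   choice rescales every value by `n/(n−1)` and changes no ordering.

## Closed forms and their verification

With equitable allocation, `s_sex = cov(x_male, W_mat) = 1 − k/n` exactly,
independent of `F`: carriers jointly hold all matings, so the carrier term
of the covariance is pinned regardless of how many females there are.
Similarly `s_nat = cov(x_male, W_surv) = k_surv/m − t/n0` over the
pre-adult cohort. Both identities are *verified, not assumed*: the test
suite compares the pipeline against an exact-rational brute-force
covariance oracle (plain Python `fractions.Fraction`, no numpy, written
independently of the production path, which uses `np.cov`), exhaustively
for `n ≤ 30`, all `k`, `F ≤ 60`. Agreement is asserted at 1e-12 absolute
— floating-point exactness, since the pipeline computes `W_mat` as
`mates / (F/n)` in binary floats.

## Sex ratios

ASR = surviving males / surviving females. OSR counts **all** surviving
adult males as prepared to mate, not only trait carriers, and every
female as receptive once — so OSR = ASR here. Rationale: the model
attributes sex-ratio bias solely to sex-differential survival; a
trait-restricted OSR would be biased even under identical male and female
survival, conflating trait scarcity with demography. Users who want a
carrier-only ratio can form `k_carriers / n_females_adult` from the
reported counts.

## Viability-selection bounds

A scenario fixes the surviving-carrier count `k_surv` but says nothing
about the trait status of the `n0 − m` males that died. That status is
the only free degree of freedom consistent with the fixed adult state, so
the pre-adult carrier count `t` ranges over
`[k_surv, k_surv + (n0 − m)]`. `snat_bounds` enumerates every feasible
`t` and returns the extremes of `s_nat(t)` with the achieving `t` values;
because `s_nat(t)` is linear and decreasing in `t`, the maximum always
sits at `t = k_surv` (no dead carriers) and the minimum at the upper
endpoint (every dead male a carrier). Enumeration is kept as the
production path and cross-checked against the closed form and against
explicit cohort vectors in the tests. `s_nat_max = 0` exactly when nobody
dies or no carrier survives; it is otherwise positive.

## Standardization

Standardized differentials divide by a binary-trait SD `√(p(1−p))`. For
`s_sex` the population is unambiguous: the surviving adult males
(`p = k/n`), giving the intensity `√((1−p)/p)` under full
monopolization. For the `s_nat` bounds two populations are defensible and
the package exposes both:

- **adult** (`p = k_surv/m`, the frequency the scenario actually fixes) —
  the default;
- **pre-adult at the achieving t** (`p = t/n0`).

The default was chosen because it is the only one of the two that
preserves the qualitative structure of the raw bounds across the
mortality grid: under the pre-adult-at-t convention the standardized
minimum for 6 carriers is most negative at 70% rather than intermediate
mortality, so raw and standardized patterns would disagree. The adult
convention also divides `s_sex` and the `s_nat` bounds by the *same* SD
at each grid point, so the sign of the combined worst case
`s_sex + s_nat_min` survives standardization exactly.

Zero trait variance (no carriers, or all males carriers — e.g. 9 carriers
among 9 survivors at 70% mortality) makes any standardized value
undefined; it is reported as NaN with a `RuntimeWarning` rather than
raised, so grid sweeps run to completion, and ordering checks exclude
those points.

## Degenerate inputs and numerical choices

- No surviving females → sex ratios undefined (`ZeroDivisionError`).
- No trait carriers → no male can mate; mean mating success is zero and
  relative fitness undefined (`ValueError`), rather than silently
  reporting `s_sex = 0`.
- `k_surv > m`, infeasible `t`, mortalities outside [0, 1] → `ValueError`.
- Trait levels may be given as `fractions.Fraction` (e.g. `1/3` from a
  config file or CLI string), kept exact so strict-mode integrality
  checks are not at the mercy of decimal representations; plain floats
  work too, with the 1e-9 integrality tolerance absorbing float slop.
- Ties in the bounds enumeration (possible only at zero width) resolve to
  the smallest `t` for the maximum and the largest for the minimum.

## Problem sizes in the tests

The suite runs the four canonical 9-point grids end-to-end, the
exhaustive closed-form sweep (`n ≤ 30`, all `k`, `F ≤ 60`, with the
exact-rational oracle sampled at 2% of cases plus every targeted
example), and exhaustive remainder-permutation checks for up to 6
carriers; hypothesis property tests use a derandomized profile
(100 examples per property). The whole suite completes in a few seconds.

## What the model does and does not show

The generator of "data" here *is* the model: cohorts are constructed,
not sampled, so passing tests demonstrate internal consistency and the
claimed parameter-dependence patterns, not fit to any empirical
population. Real systems add stochastic survival, female choice and
fecundity variation, multi-episode selection, heritability — all out of
scope. In particular, mating success is taken as directly proportional to
fertilization success, so `s_sex` here is a mating differential; the
bounds analysis places no prior on the pre-adult trait frequency and so
brackets, rather than estimates, viability selection. Conclusions about
multi-generation dynamics require coupling these one-generation
differentials to a transmission model, which this package deliberately
does not include.
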