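# selcascade

How does mortality *before* adulthood shape sexual selection *after* it?
`selcascade` is a small, fully deterministic cohort model for evolutionary
ecologists studying that cascade. A cohort of pre-adult males and females
experiences sex-specific pre-adult mortality; survivors enter the adult
mating pool; a binary mate-acquisition trait (x_male ∈ {0, 1}) is fixed
among surviving males either as a **proportion** or as an **absolute
number** of carriers; and the limited female matings are shared among
carriers as equitably as possible under an integer constraint. The package
computes, for single runs and for full parameter grids:

- the **sexual selection differential** on the trait,
  `s_sex = cov(x_male, W_mat)`, where `W_mat` is mating success divided by
  its mean over surviving adult males (population covariance, so `s_sex`
  equals the within-generation change in trait mean);
- its **standardized** form (selection intensity), `s_sex / √(p(1−p))` with
  `p` the adult carrier frequency;
- the **adult and operational sex ratios** (ASR, OSR);
- the feasible **bounds on viability selection**,
  `s_nat = cov(x_male, W_surv)` over the pre-adult cohort: the scenario
  fixes how many surviving males carry the trait, but not how many of the
  dead did, so sweeping that unknown over its feasible range yields the
  strongest possible selection for and against the trait consistent with
  the adult state.

Under equitable allocation the model admits exact closed forms — with `n`
surviving males and `k` carriers, `s_sex = 1 − k/n`, and with `n0`
pre-adults, `m` survivors, `k` surviving carriers and `t` pre-adult
carriers, `s_nat = k/m − t/n0` — and the implementation cross-checks both
against brute-force covariance oracles in its test suite. The central
qualitative results: a fixed carrier *proportion* makes sexual selection
independent of pre-adult mortality, a fixed carrier *number* makes it
decline as mortality rises, and on the canonical grid the worst-case
viability cost of the trait never outweighs its sexual benefit
(`s_sex + s_nat_min ≥ 0`).

## Worked example

Nine of eighteen adult males carry the trait and 29 females are receptive;
29 = 9·3 + 2, so two carriers receive 4 mates and seven receive 3:

```text
$ selcascade example
29 receptive females, 18 adult males, 9 trait carriers
per-male mate counts (carriers first): 4 4 3 3 3 3 3 3 3 0 0 0 0 0 0 0 0 0
carrier allocations: [4, 4, 3, 3, 3, 3, 3, 3, 3]
s_sex = 0.500000   (closed form 1 - k/n = 0.500000)
s_sex_std = 1.000000
```

Half the males carry the trait and carriers monopolize every mating, so
selection shifts the carrier frequency by `s_sex = 1 − 9/18 = 0.5`; in
trait-SD units the intensity is 1.0. A full run from the pre-adult stage:

```text
$ selcascade run --male-mortality 0.1 --female-mortality 0.1 \
    --trait-mode fixed_number --trait-level 3
{
  ...
  "n_males_adult": 27,
  "n_females_adult": 27,
  "k_carriers": 3,
  "ASR": 1.0,
  "OSR": 1.0,
  "s_sex": 0.8888888888888884,
  "s_sex_std": 2.828427124746188
}
```

Three carriers among 27 survivors split all 27 matings (9 each):
`s_sex = 1 − 3/27 ≈ 0.889`, near the maximum possible for a binary trait —
few carriers plus many survivors means extreme mate monopolization.

Grid sweeps and the viability bounds:

```bash
selcascade sweep --scenario 3 --out results.csv --bounds-out bounds.csv
selcascade bounds --n0 30 --survivors 9 --k-surv 3
```

The same functionality is importable (`selcascade.run_scenario`,
`run_sweep`, `snat_bounds`, ...); the scripts in `examples/` walk through
each capability with commentary.

## Canonical scenarios

Sweeps start from 30 pre-adult males and 30 pre-adult females, male
mortality ∈ {10%, 40%, 70%}:

| scenario | female mortality | trait distribution |
|---|---|---|
| 1 | equal to male | fixed proportion ∈ {1/3, 2/3, 8/9} |
| 2 | fixed at 10% | fixed proportion ∈ {1/3, 2/3, 8/9} |
| 3 | equal to male | fixed number ∈ {3, 6, 9} |
| 4 | fixed at 10% | fixed number ∈ {3, 6, 9} |

Custom grids and single runs can be given as flat YAML config files (see
`selcascade.configfile`). Modelling conventions — rounding, the OSR
definition, covariance divisor, standardization populations, degenerate
cases — are documented in `docs/methods.md`.

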