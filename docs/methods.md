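# Methods

## Cohort decision tree

The unit of analysis is a hypothetical cohort of `N = 100,000` singleton
home live births. Four sequential branch points partition it: clean delivery
kit (CDK) receipt, misoprostol use given receipt, postpartum haemorrhage
(PPH), and death given PPH. With fractions `c`, `u`, `q_m`, `d_m`, `q_n`,
`d_n` the death count is

    deaths = N·c·u·q_m·d_m + N·(1 − c·u)·q_n·d_n.

Modelling assumptions worth making explicit:

- **Death probabilities are conditional on PPH**, not marginal; both branches
  use `Tri(0.2, 0.3, 0.4)%`, reflecting field evidence that mortality risk
  once PPH occurs is the same with and without misoprostol — the drug acts
  by lowering incidence.
- **Women who receive a kit but do not use the misoprostol merge with the
  never-received branch.** The elicitation table lists both "% used
  misoprostol | CDK" `Tri(80,94,100)` and its mirror "% did not use"
  `Tri(0,6,20)`; we sample the use fraction and derive non-use as its
  complement, so the population sums to `N` identically in every iteration.
  Sampling both independently would break conservation without changing the
  marginal law.
- **Per-iteration outputs are real-valued expectations** — the tree
  propagates assumption uncertainty and does not binomially resample
  individual women. At `N = 100,000` the binomial noise a resampling model
  would add (≈√51 ≈ 7 deaths SD at zero coverage) is incompatible with the
  zero-coverage forecast SD the product-of-triangulars model reproduces
  exactly, so expectation propagation is the right reading of the original
  spreadsheet model. Individual-level sampling lives in the synthetic-data
  generator instead.

## Distributions

All inputs are triangular `Tri(min, likeliest, max)` or degenerate "uniform"
set levels, stored on the percent scale exactly as elicited (assumption CSVs
round-trip verbatim; fractions appear only inside the tree). Sampling is
inverse-CDF on uniform variates from a seeded `numpy` generator —
deterministic given the seed, draws exactly inside the support, no rejection
step. Point masses short-circuit without consuming randomness. Closed-form
moments (`mean = (a+m+b)/3`, `var = (a²+m²+b²−am−ab−mb)/18`) are the test
oracles for the sampler and the engine. A non-degenerate uniform is
supported but unused by the packaged table. Beta-PERT or normal alternatives
are deliberately out of scope.

## Monte Carlo engine

Plain independent Monte Carlo, default 50,000 iterations per scenario (a
50,000-iteration run is ≈50 ms, so no variance-reduction machinery is
warranted, and Latin-hypercube or antithetic schemes would complicate the
reproducibility contract). Each iteration draws the six cells once and
evaluates the tree; the full 6 × 50,000 draw matrix is retained on the
results object so the sensitivity analysis needs no rerun. Scenario batches
spawn independent child seed-sequences from one base seed, so results do
not depend on execution order. The forecast summary is mean, sample SD
(ddof = 1), min and max of the per-iteration death counts; display rounding
is whole deaths for means/ranges and 2 d.p. for SDs.

Convergence contracts (enforced in tests): the run mean agrees with the
analytic expectation within 4 standard errors; the zero-coverage run SD
agrees within 5% with the exact product variance
`N²(E[q]²V[d] + E[d]²V[q] + V[q]V[d])`, which evaluates to an SD of 9.293
deaths for the packaged inputs.

### Known limitation: mid-coverage forecast SDs

The model reproduces the reference forecast SD at zero coverage (9.29 vs
9.30) and nearly so at high coverage (6.8 vs 7.0), but gives ≈6.5 and ≈6.8
at project (69%) and low (40%) coverage where the reference spreadsheet
reported 8.01 and 8.26. Exact moment algebra confirms the model cannot
produce those values with six independently sampled cells: they are instead
consistent with a single death-given-PPH draw shared across both branches.
That alternative, however, contradicts the two separate elicited death cells
and collapses the sensitivity decomposition (the users-PPH-incidence share
at high coverage drops to ≈41%, far from the reported 51%). We keep the
six-cell model; forecast means, the zero-coverage SD, MMR arithmetic and
sensitivity shares are unaffected.

## Sensitivity analysis

Contribution to variance is the normalised squared Spearman rank
correlation between each assumption's draws and the death counts — the
standard heuristic of spreadsheet risk tools, chosen over Sobol indices or
standardised regression coefficients to match how the reference results
were produced. Signed correlations are kept for tornado display. Point-mass
cells contribute exactly 0; an all-degenerate model raises rather than
dividing by zero. Alongside the six sampled cells the report carries the
derived population non-use fraction `1 − c·u`, labelled "not using
misoprostol"; as a monotone function of two sampled cells it double-counts
a small share (≤4 points) but mirrors the component naming users of the
original analysis expect. The estimator is validated at zero coverage
against the first-order analytic shares `E[d]²Var[q]` vs `E[q]²Var[d]`
(56.2% / 43.8% for the packaged inputs), which the rank-correlation shares
reproduce within 1 point at 50,000 iterations.

## MMR analysis

`cause_specific_mmr = deaths / live_births × 100,000`. The project
live-birth denominator defaults to 75,000, back-derived from 117 deaths at
an overall MMR of 156 (the true count was not published; 77,337 deliveries
and 67,611 home deliveries do not reproduce the published ratios — likely
stillbirths/twins/late enrolment). Scenario overall MMRs add the simulated
PPH-specific MMR to a fixed non-PPH total of 134 per 100,000; national
death counts apply the overall MMR to a default 3,038,000 annual births
(back-derived the same way; both are parameters). Display tables compute
overall MMR and national counts from the whole-number PPH MMR, matching the
reference table's rounding.

Observed-vs-expected comparisons use a two-sided exact Poisson test
(minimum-likelihood tail sum) of the observed count against
`expected_mmr × live_births / 100,000`. The reference analysis never names
its test, so its printed p-values are not reproduction targets; the exact
Poisson test is the defensible default for rare-event rates, and direction
and significance agree with the reference for the categories checked. A
zero expected count with observed deaths is flagged (`underflow=True`, p
reported as 0) rather than raising.

## Synthetic cohort generator

The generator emulates data *collection* in the field project: each woman
is an independent Bernoulli path through CDK receipt (0.69), misoprostol
use given receipt (0.94), blood-mat use (0.68), PPH (0.115 with misoprostol,
0.17 without — midpoints of the trial ranges; incidence uncertainty belongs
to the scenario model, not the data-generating world, so these are fixed),
and death given PPH (0.003). A competing non-PPH death hazard (63/75,000)
with the observed cause mix (eclampsia 27/63, other-direct 20/63, …) fills
out the death table; timing/place/attendant are drawn independently within
cause from the observed marginal weights. One PPH death with unknown
misoprostol status can optionally be injected to exercise missing-data
handling.

What the generator does **not** emulate: verbal-autopsy misclassification
(no rates were published), facility-birth pathways, referral and transfer,
within-population heterogeneity in mortality risk, and any joint structure
among death attributes (only marginals were published). Passing round-trip
tests therefore show the estimation pipeline is self-consistent under
idealised reporting, not that it is robust to real-world measurement error.

The packaged `table2_deaths.csv` is a deterministic synthetic
reconstruction of the 117 reference maternal deaths: attributes are
assigned blockwise within cause to match every published marginal count
exactly, with "unknown" padding where marginals fall short of the cause
total (e.g. place of delivery is unknown for 35 of 117). Any tabulation of
published totals or percentages from it is exact; joint distributions in it
are artefacts of the block assignment.

## Numerical choices and problem sizes

- Support checks on draws allow 1e-9 absolute slack against the bounds.
- Spearman correlations returning on constant columns are defined as 0.
- The Poisson test truncates the upper tail at
  `max(observed, λ + 10√λ + 30)`; the neglected mass is ≪ 1e-12.
- Default problem sizes — 50,000 iterations per scenario, 100,000-woman
  cohorts, 50,000-woman recovery cohorts over three seeds — keep every
  statistical contract at ≥4-standard-error resolution while the full test
  suite runs in seconds.
- Seeds are user-supplied; batch runs spawn per-scenario child streams so
  adding a scenario never perturbs the others.
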