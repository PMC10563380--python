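# Methods

## The problem

Early-phase trials of two-drug combinations explore a J x K grid of dose
pairs under severe information constraints: a few dozen patients, binary
endpoints, and a dose space in which only *partial* ordering is known —
toxicity increases along each drug's axis, but pairs like (j+1, k) and
(j, k+1) cannot be ranked a priori. The package implements two local
continual-reassessment designs on this grid plus the simulation machinery
to measure their operating characteristics:

* **LOCRM** targets the maximum tolerated dose combination (MTDC), the
  pair whose dose-limiting-toxicity (DLT) probability equals a target
  `phiT`, using toxicity data only.
* **LOCRM12** targets the optimal biological dose combination (OBDC),
  the most efficacious pair among the acceptably toxic ones, using
  toxicity and response jointly.

Both designs model only the *local* neighbourhood of the current dose
rather than the whole surface; the point is robustness — a global
parametric surface misfits badly with 51 patients spread over 15 cells,
whereas a local model is refit at every decision around wherever the
trial currently sits.

## Local toxicity model

For the current dose the local set `A` holds the dose itself and its
in-grid one-step axis neighbours (3 to 5 pairs). Within `A` the partial
order admits only a handful of complete toxicity orderings — 4 for an
interior dose, 2 at the (1,1) and (J,K) corners, 1 at (J,1) and (1,K).
`orderings.enumerate_orderings` enumerates them generically as the linear
extensions of the dominance poset (backtracking); the classical four
interior orderings and all edge cases fall out of the same code path,
and a brute-force permutation filter serves as the test oracle.

Each ordering `O_i` turns the neighbourhood into a one-dimensional dose
line and carries a one-parameter empiric (power) CRM model

    p_jk = pi(r_i(j,k)) ^ exp(a_i),      a_i ~ N(0, sigma_a^2),

where `r_i` is the toxicity rank of the dose under `O_i` and
`pi(1) < ... < pi(|A|)` is the skeleton of prior guesses. The posterior
of each `a_i` given the local counts is a smooth one-dimensional
integral; it is evaluated with a fixed 301-node Gauss–Legendre rule on
`a in [-10, 10]` (more than seven prior SDs at the default
`sigma_a^2 = 2`), which is deterministic, vectorizes over the doses of
`A`, and agrees with a 20,001-point trapezoid reference to better than
1e-6 relative error in the tests. Marginal likelihoods are accumulated
in log space so that Bayesian model averaging with equal prior model
probabilities,

    pbar_jk = sum_i Pr(O_i | D) * E[p_jk | D, O_i],

stays stable even at the large synthetic counts used by the posterior-
consistency test.

**Skeleton.** `skeleton.generate_skeleton` implements the
indifference-interval construction for the power model: the value at the
prior-MTD position equals the target exactly, and adjacent values are
linked by the boundary condition that at the parameter where the model
switches its recommendation between positions l and l+1, position l
sits at `target - delta` and position l+1 at `target + delta`
(closed-form recursion in log-log space; `delta = 0.05` by default).
The prior-MTD position is `|A| - 1` (3 -> 2, 4 -> 3, 5 -> 4), exposed as
`prior_mtd_rule` with a `"current_rank"` alternative. Skeletons are
cached per `(target, |A|, nu, delta)` since they are rebuilt at every
decision.

## The LOCRM trial engine

Cohorts (default 3 patients) start at (1,1). After each cohort:

1. **Overdose control.** A dose with at least `elim_min_n = 3` patients
   is eliminated, together with every componentwise-higher dose, when
   `Pr(p > phiT) > cT` under a Beta(1+y, 1+n-y) posterior built from
   that dose's own counts (uniform prior; the rule is deliberately
   model-free). Elimination is permanent and upward-closed; if (1,1) is
   eliminated the trial stops with no selection.
2. **Allocation.** The BMA toxicity estimates are refit on `A` and the
   next cohort goes to the admissible neighbour with `pbar` closest to
   `phiT`; exact ties (which arise by symmetry when no DLT has been
   seen) are broken uniformly at random, which reproduces the
   random-direction escalation behaviour at trial start.
3. **Termination.** The trial stops for selection at 51 patients.

At the end the observed DLT-rate matrix is smoothed by **weighted
bivariate isotonic regression** (weights `n_jk`) and the tried,
non-eliminated dose with smoothed rate closest to `phiT` is the MTDC;
ties go to the lower total dose level, then the lower drug-A level.
Untried cells enter the smoothing at the target rate with weight 1e-6 so
they cannot distort the fit and are excluded from selection anyway.

`isotonic.biviso` computes the exact weighted least-squares projection
onto the doubly-monotone cone by Dykstra's alternating projections
between the row- and column-monotone cones, each 1-D projection being
weighted PAVA (`scipy.optimize.isotonic_regression`); plain cyclic
row/column PAVA without the correction terms is not an exact projection.
Convergence threshold 1e-10 per sweep; an SLSQP solution of the
constrained least-squares problem is the test oracle.

## Efficacy model (LOCRM12)

Partial ordering cannot be assumed for response, and enumerating
response orderings of even a 5-dose neighbourhood is combinatorial, so
efficacy over the 9-dose neighbourhood `B` (axis plus diagonal
neighbours — deliberately wider than `A` because response surfaces are
less predictable) is modelled by robit regression on standardized doses,

    F_v^{-1}(q_jk) = alpha + beta1 dA + beta2 dB + gamma1 dA^2 + gamma2 dB^2,

with `F_v` the Student-t CDF. The quadratic terms let the surface bend
(plateaus, umbrella shapes); the estimated degrees of freedom `v`
interpolate between logistic-like (v ~ 7) and probit (v -> inf)
behaviour. No interaction term by default (flag available). Priors:
`alpha ~ N(0, 1.3)`, `beta ~ N(0.8, 1.3)` (positive mean to favour an
increasing surface where data are absent), `gamma ~ N(0, 1.3)`,
`v ~ half-t(0, 1, df)` (the stated t prior truncated to the positive
axis, the only reading respecting v > 0), `df ~ Uniform(2, 10)`.
Variances here are variances, not SDs.

Sampling is adaptive random-walk Metropolis on
`(theta, log v, df)` — a 7-dimensional smooth posterior over at most 9
binomial cells — with a global step-size adapted during burn-in toward
~0.3 acceptance. Defaults are 3,000 kept draws after 1,000 burn-in;
the benchmark reproduction runs use 1,500–2,000 kept draws after
500–700, which changes the operating characteristics by well under a
Monte-Carlo standard error (checked at 300–400 trials on the umbrella
scenario). Given the data, configuration and seed, the draw sequence is
bitwise reproducible.

## The LOCRM12 trial engine

* **Start-up stage** (budget 21 patients): model-free fast escalation —
  after a DLT-free cohort one randomly chosen drug is raised one level
  (the other drug if at its boundary; hold at the top corner). The first
  DLT in the most recent cohort, or an exhausted budget, hands over to
  the main stage seamlessly; start-up responses are kept and enter the
  efficacy model.
* **Main stage** (budget N = 30; total cap 51): each decision refits the
  local toxicity model, takes the local MTDC `(j*,k*)` (estimate closest
  to `phiT`), forms the admissible set `A~` of doses in `A` with
  estimate not exceeding that of `(j*,k*)` minus eliminated/futile
  doses, refits the robit model on `B`, and picks the admissible dose
  with the highest posterior-mean efficacy `(j+,k+)`. Exploration
  control: if `(j+,k+)` is tried and untried admissible doses remain, it
  is kept only if its efficacy estimate beats `((N - n)/N)^z` (n =
  main-stage patients, z = 2); otherwise the untried admissible dose
  with the highest efficacy estimate is explored (uniform-random
  exploration available as a config option). The cutoff is clamped at
  zero once `n >= N` — possible when start-up ends early — so it decays
  monotonically to pure exploitation instead of rising again under an
  even `z`.
* **Monitoring.** The overdose rule runs after every cohort (cutoff
  `cT = 0.85`, looser than LOCRM's 0.95 because dose optimization
  tolerates mild overshoot in exchange for efficacy, paired with the
  looser limit `phiT = 0.35`). Futility: a dose in `B` with at least 3
  patients is permanently dropped when the posterior puts more than
  `cE = 0.9` of its mass below `phiE = 0.2`; the check uses the same
  decision-time robit fit, so monitoring is folded into the allocation
  step rather than run as a separate post-cohort fit (the next action
  always refits on the updated data first, so the behaviour is
  identical). The trial stops with no selection when (1,1) is
  eliminated or every grid dose is eliminated or futile.
* **Selection.** MTDC* = tried, non-eliminated dose with isotonic
  toxicity estimate closest to `phiT`; the safe set is the tried doses
  with isotonic estimate not above MTDC*'s, minus futile/eliminated
  doses; the OBDC is the safe dose with the highest estimated efficacy,
  by default from a robit fit on all tried doses at trial end
  (`obdc_estimator="model"`; `"empirical"` uses raw response
  proportions). Ties go to the lower dose.

Degenerate paths: if every neighbour is inadmissible, the engine
de-escalates to the nearest admissible dose componentwise below the
current one (elimination is upward-closed, so any remaining admissible
dose lies there); if none exists the trial stops with no selection.

## Simulator and operating characteristics

Scenarios fix true per-dose toxicity (and optionally efficacy)
probabilities; the sixteen benchmark surfaces are shipped as YAML
fixtures with matrices printed the usual way (drug-B rows, drug-A
columns) and validated monotone in toxicity at load. Patient outcomes
are independent Bernoulli draws of the marginals — the generator does
not model toxicity–efficacy correlation within patients, patient
covariates, or accrual timing, so the operating characteristics say
nothing about designs' behaviour under correlated endpoints or staggered
enrolment. Derived sets per scenario: MTDCs (toxicity exactly `phiT`),
overdoses (above `phiT`), OBDCs (most efficacious among doses with
toxicity at most `phiT`) and TDCs (response at least 0.45 among those
safe doses).

`run_study` replays n seeded trials and aggregates selection
percentages and mean patient counts per category, the early-stopping
rate and unused budget. Per-trial seeds are spawned from the base seed
with `SeedSequence`, so results are identical whether trials run
serially or under joblib workers.

## Reproduction protocol and known limitations

`scripts/acceptance.py` reruns the benchmark studies at reduced
replication — 1,000 trials for the toxicity-only scenarios, 250–300
trials with 2,000-draw MCMC for the dose-optimization scenarios — which
keeps the whole reproduction in a few minutes on one core at
Monte-Carlo noise well inside the comparison tolerances.

Known limitations:

* On the toxicity-only benchmarks the MTDC selection percentage
  stabilizes about five points below the published values (about 68 vs
  73 on Scenario 1, 60 vs 65 on Scenario 4) although patient allocation,
  overdose exposure and early stopping match closely; an extensive
  sensitivity sweep (estimator form, smoothing weights, elimination
  posterior, prior family and variance, skeleton placement and
  halfwidth, tie-breaking) moved the figure by at most ~1 point in
  either direction, so the discrepancy most likely reflects an
  implementation detail of the original (unavailable) code rather than
  any parameter of the published design. The dose-optimization
  benchmarks reproduce within tolerance.
* Two drugs only; the p-drug generalization is out of scope.
* Futile doses never re-enter, mirroring permanent toxicity
  elimination; the alternative (re-admission on later evidence) is not
  implemented.
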