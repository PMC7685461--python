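# Methods

This note documents the statistical models and algorithms the package
implements, the choices made where the design was genuinely open, and what
the toy-scale tests do and do not establish.

## The simulator model

A political-ecological simulator couples an agent-based layer of political
*groups* with an individual/population-level *ecosystem* submodel.  Each
submodel is a small influence diagram (ID):

* **Group IDs** receive an *in-combination* `{time, input action, actor,
  subject}` on their input nodes, and choose an *out-combination*
  `{output action, target}` from a finite menu of size `K` by maximizing the
  Monte-Carlo estimate of the expected value of their terminal node,
  Overall Goal Attainment.  Ties break lexicographically on
  `(output_action, target)` (nothing in the decision theory picks an order;
  lexicographic is deterministic and menu-permutation invariant).
* **The ecosystem ID** carries `e >= 1` continuous output metrics (e.g.
  cheetah abundance); each run records the Monte-Carlo mean of every metric
  at every time step.

Two stochastic node families cover everything the downstream statistics
touch: categorical conditional probability tables (CPTs) for discrete
nodes, and conditional Gaussians whose mean is affine in the (numerically
encoded) parent values for continuous nodes.  Deterministic payoff tables
carry utility arithmetic and hold no parameters.  All parameters live in
one flat vector `B` indexed by `(submodel, conditioning context, name)`,
partitioned into the group block `B^(Grp)` and the ecosystem block
`B^(Eco)`.  CPT rows are registered as simplex groups so optimizers can
restore normalization by Euclidean projection after coordinate moves
(coordinate search moves one entry at a time and would otherwise break the
sum-to-one invariant; projection is the cheapest feasible repair).

Time is decimal years with a default step of 13/365.25 (a 13-day step keeps
a handful of political actions per interval at realistic action rates).
Randomness is disciplined by one base seed per job: every (time step,
submodel) pair draws from its own deterministic substream, so runs are
bit-reproducible, and objective evaluations at different trial parameter
vectors share common random numbers — comparisons inside an optimization
are paired rather than independently noisy.

Co-simulation wiring — which group receives whose postings, and how action
counts and lagged metric means drive the ecosystem's input nodes — is a
package convention (declared routes and bindings), since only the submodel
mathematics, not the message-passing schedule, enters the statistics.

## Distances and agreement functions

**PDPF and Hellinger distance.**  The joint law of an ID's chance nodes is
a mixed discrete/continuous density-mass function (a "probability density
probability function").  The distance between the laws at two parameter
vectors is the Hellinger distance, estimated by Monte Carlo: draw `n`
design points uniformly over the chance-node domains/ranges, estimate each
PDPF at those points with a product kernel (exact frequency match per
discrete coordinate, Gaussian kernel with Silverman's rule-of-thumb
bandwidth per continuous coordinate; a declared minimum bandwidth guards
zero-variance draws), and form

    D^2 = (1/2) * sum_j w_j * (sqrt(f1(u_j)) - sqrt(f2(u_j)))^2,
    w_j = 1 / (n q(u_j)),

with `q` the uniform sampling density, so the sum consistently estimates
the Hellinger integral and `D` lies in `[0, 1]` (estimates pushed outside
by Monte-Carlo noise are clamped, and the clamp is logged).  For purely
discrete IDs the joint is enumerated and the finite-sum closed form is
exact — this "discrete-exact" mode is also the default wherever it applies.
Both PDPFs in a comparison share one design sample and one random
substream, so the distance of a vector to itself is exactly zero.

The kernel estimator targets the kernel-smoothed density, so its Hellinger
estimates carry a small smoothing bias (for unit-variance Gaussians, the
closed form with variance `1 + h^2` rather than `1`); the tests account for
this explicitly instead of hiding it in loose tolerances.

**Agreement functions.**  With an observed actions dataset `S`:

* `gS_grp` — the fraction of observed `(group, time)` out-combinations the
  simulator reproduces (both action and target; action-only and target-only
  fractions are reported alongside).  Observation times snap to the nearest
  grid point; multiple postings per time point count with multiplicity.
  Only groups with at least one observation enter.
* `gS_eco = 1 - mean_ij |z_ij - zhat_ij| / R_i` with `R_i` the observed
  range of metric `i`; zero-range metrics are excluded (their term is
  undefined) with a logged warning.
* `gS` is the mean of the defined components; when a dataset has no usable
  ecosystem series (or no group records) the defined component stands
  alone.
* `gH` — mean over IDs of one minus the mean per-conditioning-combination
  Hellinger distance to the hypothesis parameterization; `l_i`, the number
  of conditioning combinations of ID `i`, is the product of its input-node
  cardinalities (including, for groups, the decision nodes; continuous
  inputs must declare a finite discretization to be enumerable).
* `gCA = (1 - cH) gS + cH gH`, `cH` in `[0, 1]` the manager's priority on
  staying near theory; `cH = 0` is a pure minimum simulated distance
  estimator.  Inside optimization loops the smooth Euclidean surrogate
  `eH = -||B - B_H||` (blockwise, over active entries) replaces `gH`;
  Hellinger-mode values are recomputed for reporting.

## Consistency analysis

Specify (`B_H`) / Initialize / Maximize / Analyze:

* **Initialize** shifts the choice-relevant CPT rows of each observed group
  toward the empirical frequencies of its observed actions — a convex
  combination with weight `lam` (default 0.5), renormalized.  The procedure
  is this package's design: frequency matching is the natural moment
  condition for the scenario-style groups below, and the entries it moves
  define the *active set*, reducing the optimization's dimensionality
  exactly as a fit that touches only data-informed parameters should.
* **Maximize** runs the MDAS pattern search (below) over the active entries
  on the surrogate `gCA`, projecting touched CPT rows back onto the simplex
  after every move.
* **Analyze** ranks `|beta_H - beta_C|` descending, pointing at the areas
  of subject-matter theory the data most disagrees with.

Defaults: `cH = 0.99`, 1000 Monte-Carlo realizations per in-loop decision
and per ecosystem step, 5000 for reporting-grade agreement values.  The
in-loop decision count is a noise-control parameter, not just a cost dial:
the argmax decision must be estimated with enough realizations that its
Monte-Carlo flip probability is negligible relative to the smallest
choice-probability gap, otherwise rare flips create spurious one-match
improvements that let the pattern search random-walk off the initialization
(at a 0.19 gap, 1000 realizations put a flip at ~8.7 sigma; 200 put it at
~3.9 sigma, close enough to happen once in a 2000-step history).

**What identifies the choice probabilities.**  The built-in toy groups tie
the action choice to a categorical *scenario* node via a payoff of 1 when
the chosen action matches the scenario: the choice distribution equals the
scenario CPT row, so observed action frequencies estimate those entries
directly.  The synthetic-data generator samples each decision with a single
Monte-Carlo realization (shared across the menu by common random numbers),
which makes posted actions categorical draws from the CPT — the behavioural
variability of a real actions history.  During fitting, decisions use many
realizations and are therefore modal; around the frequency-matched
initialization the match objective is then piecewise constant, so Maximize
only moves when it can strictly improve the match and the Initialize step
carries the identification.  On simulators with an ecosystem series the
match objective can instead reward trial points whose decision noise mimics
the observed action mix; the recovery test therefore runs on the group-only
toy, and recovery there demonstrates the frequency-matching pipeline, not
identification through the ecosystem channel.

## MDAS — multiple-dimensions-ahead search

A batch-synchronous parallel coordinate pattern search (Hooke–Jeeves
family) for stochastic objectives under box bounds and an optional
feasibility predicate.  Blocks of `M` dimensions (default 3) are searched
with axial `+/-step` proposals (documented order, clipped, deduplicated),
the whole batch is evaluated through the task executor, and the best strict
improvement becomes the incumbent; a block is repeated until it stops
improving, then the search moves on; a full no-improvement pass shrinks all
steps by 0.5.  Defaults: initial step 10% of each bound range (start
magnitude for unbounded dimensions), convergence at 1e-6 of range.  The
aggressive tolerance is deliberate: the benchmark reproduction of the Bukin
F4 global minimum needs the final pattern steps several orders below the
target coordinate accuracy, and the cost of the extra shrink passes is a
few dozen evaluations.  Because batches are synchronous and ties break
first-in-order, results are identical under the serial and process-pool
backends.  Improvements append to a checkpoint file, so an interrupted run
resumes from its incumbent.

## Delete-d jackknife

`n_jack` without-replacement subsamples of size `r = floor(n^tau)`
(truncation — the worked subsample size 546^0.97 -> 451 implies it;
`tau = 0.97` default satisfies the consistency condition `r/n -> 0`), one
re-estimate per subsample run as a concurrent task, and per-parameter
shortest intervals containing `ceil((1 - alpha) n_jack)` replicates (ties
to the lowest window).  A replicate whose estimator fails is retried once,
then dropped with a warning and the intervals recomputed on the survivors.
`n_jack = 5` is the operational default; statistical tests use larger
`n_jack`, where window quantiles are non-degenerate.  Note the coverage of
shortest intervals over few replicates sits below the central-interval
Gaussian approximation — the coverage test simulates the replicate theory
directly rather than pretending nominal coverage holds at desk scale.

## Prediction error rates

From a start offset `s` (years after the first observation), the simulator
is refitted every `v` years (quarterly default, `v = (4*3)/52 = 0.2308`) on
all data up through the scheduled time, each refit a concurrent task, and
run through the next scheduled time.  The schedule length is
`n_pred = floor((T_D - 1 - s)/v) + 1` with `T_D` the span of the data; the
printed formula mixes index and time notation, and this package reads `s`
and `T_D` as times measured from the first observation.  Estimators:

* `zeta = mean_j (1 - n_match_j / n_obs_j)` over scheduled steps with at
  least one observed out-combination (steps without observations are
  skipped with a warning);
* `epsilon_i` — RMS error of the refitted simulator's metric predictions;
* `delta_i` — RMS error of the naive forecast (each observation predicted
  by the previous one).  `epsilon_i > delta_i` means the naive forecast is
  preferred and the model needs rework;
* per-group blind-guessing threshold `1 - 1/K`: the simulator's action
  predictions are only worth having when `zeta` falls below it.

## Deterministic sensitivity analysis

A skeptic specifies conditions `c_DSA` and responses `r_DSA` (required
actions, forbidden "complement" actions, and ecosystem responses).  The
scenario is cast as a pseudo-observed dataset; the group block is
initialized so complement actions are never chosen (choice-node mass on
forbidden labels floored and rows renormalized), menu filtering guarantees
no trial point can post a forbidden action; and the consistency Maximize
step runs at `cH = 0.1` over a declared variable block.  The most sensitive
parameter is the active parameter with the *smallest nonzero* movement
`|beta_H - beta_DSA|` — a parameter the scenario never moved says nothing
about sensitivity, so zero differences are only reported when nothing moved
at all.  The skeptic is supported when that value lies inside the
parameter's 95% confidence interval or inside a user-declared plausibility
range ("scientifically plausible" is an explicit per-parameter range here;
it cannot be computed from the model).

## MPEMP and political feasibility

Given a desired state `q_d` (expected metric values at designated times)
and an action constraint set, the most practical ecosystem management plan
maximizes

    gH(B^(Grp)) - ||E[Q(B)] - q_d|| / ||q_H - q_d||,   q_H = E[Q(B_H)],

over a variable group block (Euclidean norm throughout; the surrogate `eH`
stands in for `gH` in-loop, Hellinger-mode for reporting).  The search is
seeded by the consistency Initialize step on the required actions — this
matters: with near-modal decisions the metric response is a step function
of the choice probabilities, and the seeding places the start on the
correct side of the decision threshold.  Forbidden actions are enforced by
menu filtering, required actions by a feasibility check on a confirmation
run, and a final confirmation simulation hard-verifies both.  Political
feasibility is `psi = gH^(Grp)(B_MPEMP) / gH^(Grp)(B_H)` with identical
Monte-Carlo settings in numerator and denominator; `psi` near 1 predicts
little political resistance, near 0 a plan that demands wholesale belief
change.

## Task execution

All five jobs decompose into batches of pure tasks run under a bag-of-tasks
master–worker contract: the master posts a batch and waits for all of it
before posting the next.  Backends: serial and a local process pool; both
give identical results for pure tasks, so runs scale out unchanged.
Completed results append to a JSON-lines checkpoint (pickled payloads,
base64-encoded) and reruns skip finished task ids; failing tasks retry up
to a limit and then fail the batch by name.  No network-distributed backend
is provided: the abstraction boundary is the backend interface, and a local
pool exercises the full master–worker semantics at desk scale.

## Synthetic data: what it does and does not emulate

The generator runs a declared simulator at known true parameters and emits
its postings and metric means as an observed dataset.  It reproduces the
*structural* features the estimators consume — irregular action mixes from
categorical choice draws, autocorrelated metric series from the lagged
dynamics, multiple postings per step, group codes — under exactly the
model family the estimators assume.  It does not emulate model
misspecification, observation error on metrics, missing or misclassified
actions, or exogenous shocks; passing recovery and coverage tests therefore
demonstrates internal correctness of the estimation machinery, not
robustness of the method on real actions histories.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by choice: 2000-step
histories for recovery, 10–20 seeds for Hellinger oracle comparisons with
1500 design points and 15000 draws, 200 repeats for jackknife coverage,
tens of optimizer evaluations per toy fit.  Other conventions: observation
times align to the nearest grid point; Hellinger estimates are clamped to
`[0, 1]`; degenerate probability rows (all-zero) raise; CPT rows are
projected, not renormalized by division, to keep projections Euclidean;
`decide` requires at least one menu element and one Monte-Carlo
realization.

## Known limitations

* The influence-diagram engine is deliberately minimal: no general
  Bayesian-network inference, no continuous decision nodes, categorical and
  conditional-Gaussian families only.
* `gS_grp`-based fitting identifies choice probabilities through the
  Initialize step, not through the match objective itself (see above);
  simulators whose groups lack a scenario-style choice node keep their
  group parameters fixed at `B_H` during Initialize.
* The jackknife treats records as exchangeable; serial dependence in real
  actions histories would call for block subsampling.
* Shortest-interval coverage at small `n_jack` is materially below nominal;
  intervals at the operational default `n_jack = 5` are descriptive, not
  calibrated.
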