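# Methods

## Pipeline overview

`sepsisrl` estimates optimal vasopressor/IV-fluid dosing policies for septic
ICU patients by offline tabular reinforcement learning. The stages are:
cohort rules and temporal harmonization (`preprocessing`), state/action
discretization (`features`, `discretize`), MDP estimation (`mdp`), solvers
(`solvers`), weighted-importance-sampling off-policy evaluation (`ope`), and
the repeated-trial comparison protocol (`experiments`). A synthetic cohort
generator (`cohort`) supplies data with a known ground truth. Discretizers
follow the scikit-learn estimator convention (`fit`/`transform`, fitted
attributes with trailing underscores) and delegate the standard numerics —
k-means++, PCA, standardization, percentiles — to scikit-learn and numpy;
the MDP estimation, rare-transition filter, policy iteration, SARSA and the
WIS estimator with bootstrap bounds are implemented here.

## Cohort rules and preprocessing

A patient qualifies as septic when a microbiological sampling precedes an
antibiotic given no more than 72 h later, or follows an antibiotic within
24 h (implemented as the half-open gap (0, 24]); onset is the earliest event
of the earliest qualifying pair. Exclusions: age < 18, undocumented mortality
or fluid administration, and treatment withdrawal (death within 24 h of the
end of recording, with no vasopressor in the final recorded 24 h but at least
one earlier administration).

Observations are aggregated into 4-h bins over [onset − 24 h, onset + 48 h);
within a bin, level-like variables are averaged and flow-like variables
(fluid volumes, urine output) are summed. The vasopressor dose is a rate and
is averaged within a bin; fluid is a volume and is summed. Values are capped
to plausible physiological ranges. Missing values are imputed by zero-order
hold (carry the last observation forward), leading gaps are back-filled from
the first observation, and a variable never observed for a patient falls back
to the training-cohort median — the patient-level 80/20 split precedes
imputation so no test-set information enters the medians. The back-fill and
median fallback are this package's choices where the procedure is otherwise
underspecified; both are simple and leakage-free.

## State and action spaces

State representations: the full 48-variable vector; NO LAB (22 non-laboratory
variables); CARDIO (heart rate, systolic and diastolic blood pressure, shock
index, SpO2, mechanical ventilation); BASELINE (gender, total fluid input,
chloride, body temperature, weight, readmission — a low-information reference
set); or the leading principal components of the standardized full vector
(PCA80 keeps 25 components, ~80% of variance; PCA15 keeps 2, ~15%).
Standardizer and PCA loadings are fitted on training rows only. Features are
standardized before clustering because k-means is scale-sensitive and the
variables have heterogeneous units; binary variables are standardized like
continuous ones for uniformity.

States are k-means++ clusters (scikit-learn `KMeans`, one seeded
initialization, tolerance 1e-4, max 300 iterations) of the training rows;
`k = 750` for the full representation, 250 for reduced ones, plus absorbing
states `k` (survived) and `k+1` (dead). Assignment is nearest-centroid with
ties to the lowest centroid index.

Dose bins reserve bin 0 for exactly zero dose; bins 1–4 are right-closed
intervals bounded by the 25th/50th/75th percentiles (linear interpolation) of
the *nonzero* training doses. Percentiles over nonzero doses only: a bin is
already reserved for zeros, and including them would collapse the edges
whenever zeros exceed half the data. Composite action id =
`5·vaso_bin + fluid_bin`.

## MDP estimation and solution

Transition counts are tallied per `(s, a, s′)` cell; cells with fewer than 5
observations are zeroed (the rare-transition filter), and `(s, a)` pairs with
no surviving cell become unavailable to the learned policy. Rewards are
terminal-only, ±100, attached to the transition entering the absorbing state;
absorbing states self-loop rewardlessly. The discount γ defaults to 0.99 and
is configurable; the comparison protocol uses 0.99, while the
policy-recovery experiment evaluates at γ = 1 (see below).

Policy evaluation solves the linear Bellman system directly (the state space
is at most 752, so a dense solve is exact and cheap); at γ = 1 a
filtering-induced recurrent class can make the system singular, in which case
a minimum-norm least-squares solution is used and values are clipped to
[−100, 100]. Policy iteration starts from the lowest-index available action
and alternates evaluation with greedy improvement until the policy or the
value function is unchanged (the value test catches cycling among value-tied
policies at γ = 1).

**Greedy tie-breaking.** Among actions whose Q lies within 1e-9 of the
state's maximum, the action with the largest retained transition count is
chosen (lowest id as the final tie-break). Exact value ties are common near
absorption: after filtering, many `(s, a)` rows retain only the transition
into the survived state and their Q is exactly the survival reward. A
naive lowest-id rule would systematically select whichever such degenerate
row has the smallest id — typically "no treatment" — so the tie rule prefers
the action clinicians actually took, the same safety rationale as the filter
itself. The rule is deterministic.

The clinicians' policy π_C is the empirical action frequency per state from
the unfiltered counts of the whole log, with add-δ smoothing (δ = 0.01) over
the actions observed at least once in the state; never-observed actions keep
probability zero. Estimating π_C from the whole log (not the training split
alone) guarantees every logged evaluation action has positive behavior
probability. TD (SARSA) evaluation of the behavior policy sweeps the logged
`(s, a, r, s′, a′)` tuples in seeded random order with a multiplicatively
decayed step size (defaults α₀ = 0.1, decay 0.99, 200 sweeps, all
configurable; none of these constants is canonical). Note that batch SARSA
converges to the Q-function of the *empirical* transition model, not of the
generating process.

## Off-policy evaluation

Deterministic learned policies are softened before evaluation: the greedy
action keeps mass 0.99 and the remainder spreads uniformly over the other
available actions. Without softening, a single logged deviation zeroes a
trajectory's entire weight and almost all data is discarded. In states the
learned policy never saw, the clinician-majority action receives the greedy
mass.

The WIS estimator is self-normalized: each trajectory's cumulative importance
ratio is frozen at its own horizon, the running average at the final step is
the normalizer, and the estimate reduces to `Σ ρ_i G_i / Σ ρ_i` — a weighted
average of returns, hence bounded by ±100 and exact under self-evaluation.
(Normalizing each trajectory by the running average at its *own* horizon, an
alternative reading for variable-length stays, breaks boundedness and was
rejected.) Zero-weight trajectories contribute exactly zero. Confidence lower
bounds are the 5th/1st percentiles of the estimate over B = 2000 trajectory
resamples (percentile bootstrap; B and the method are conventions). The
"mean policy value" reported per trial is the bootstrap mean.

WIS on deterministic-leaning targets is heavy-tailed and selection-prone:
weight concentrates on the few trajectories that match the target policy
throughout, which at small effective sample sizes favors policies that
recommend whatever actions *surviving* patients happened to receive. The
trial values should be read as comparative scores under a fixed protocol,
not as unbiased mortality predictions.

## Synthetic cohort generator

The generator emulates the statistical structure of a septic EHR extract,
not physiology. Each patient carries a latent severity level `z ∈ {0..4}`:
level 0 is absorbing recovery — the patient is discharged and exits
observation as a survivor — and level 4 is the pre-death state, from which
death occurs with probability `mortality_base = 0.4` per 4-h bin. Untreated
dynamics deteriorate (stay 0.55 / worsen 0.35 / improve 0.10 per bin). If
the administered action equals the latent-optimal action, the transition is
replaced with probability `1 − exp(−treatment_effect)` by a one-level
improvement; at `treatment_effect = 0` the dynamics are exactly the untreated
baseline, making outcomes independent of treatment. Patients present with at
least moderate dysfunction (start distribution 0.20/0.30/0.30/0.20 over
levels 1–4 shifted to 2–4; a sepsis-onset cohort is sick at entry), giving
~30% cohort mortality at the default `treatment_effect = 1` — the septic-
shock range.

The latent-optimal actions form the dose-grid diagonal
`[0, 6, 12, 18, 24]`: both treatment bins equal the severity level, i.e.
escalation with severity. The behavior ("clinician") policy is ε-optimal: it
takes the latent-optimal action with probability 0.5 and otherwise draws
doses from zero-inflated lognormal marginals (vasopressor median
0.1 µg/kg/min, zero with probability 0.7; fluid median 250 mL/4 h, zero with
probability 0.25). Because the dose bins sit at the quartiles of those same
lognormals, the exploratory nonzero mass is uniform over bins 1–4, giving
every action positive probability — the overlap WIS requires. Optimal-branch
doses are the discrete midpoint-quantile dose of the target bin, mimicking
the standard titration increments clinicians actually order; the point
masses also keep fitted quartile edges aligned with the generator's bin
semantics.

Features are Gaussian emissions of the latent level plus a shared low-rank
factor term: 12 factors following a per-patient AR(1) (lag-1 correlation
0.8 — physiological axes drift slowly, so a stale forward-filled lab still
reflects the current state), with a factor-to-idiosyncratic variance ratio
of 4 for most variables but 0.5 for the six cardiorespiratory ones, which
instead carry severity slopes of 1.2–2.0 sd per level (shock-range
excursions). This makes the feature matrix realistically collinear — the
leading 25 principal components of the standardized 48-column matrix carry
roughly 80% of the variance, and the first 2 about 15–18% — while the
severity signal lives mainly in the cardiorespiratory block. Laboratory
values are deleted per bin with probability 0.7 (labs are sparse);
demographics are patient-constant; gender/readmission/ventilation are
binary. Dose magnitudes and correlations are conventions, not estimates of
any real cohort.

What the generator does *not* emulate: real pharmacodynamics, feedback from
treatment to individual vitals, measurement error structure, inter-site
coding differences, or informative missingness. Passing tests therefore
demonstrate the pipeline's correctness and its ability to recover a
recoverable signal — not clinical validity on real data.

Determinism: patient `i` draws from the dedicated substream `(seed, i)`, so
output is bit-reproducible and independent of generation order.

## Validation experiments and problem sizes

- **Solver oracle** — 50 random absorbing MDPs (2–20 states, 2–5 actions,
  γ ∈ {0.9, 0.95, 0.99, 1.0}); policy-iteration values must match a
  10 000-iteration value-iteration oracle to 1e-8 and weakly dominate 100
  random deterministic policies per MDP.
- **WIS identities** — self-evaluation equals the empirical mean discounted
  return; a single trajectory self-normalizes to its own return; scaling all
  cumulative ratios by a constant changes nothing (checked at a common
  horizon, since scaling per-step probabilities by c multiplies ρ by c^T).
- **OPE consistency** — a known 10-state, 4-action MDP with at least 15%
  absorbing mass per step (bounding episode lengths, hence the importance-
  ratio products); behavior = 0.7·greedy + 0.3·uniform; the RMSE of the WIS
  estimate over 5 replicate simulations must be ≤ 10 at N = 5000 and not
  exceed the RMSE at N = 500.
- **Policy recovery** — 5000 patients, `treatment_effect = 2`, 50 CARDIO
  states, evaluated at γ = 1 (the objective is pure survival probability,
  matching the terminal-only reward design; at γ < 1 the filter's degenerate
  pure-survival rows outrank the true optimal action by exactly one discount
  step, an estimation artifact rather than a property of the policy). The
  learned action must equal the latent-optimal action in ≥ 70% of training
  state-visits.
- **Feature informativeness** — with emission slopes zeroed outside the
  cardiorespiratory block (`informative="cardio_only"`), CARDIO's median mean
  policy value over 20 re-clustered trials must exceed BASELINE's.

These sizes keep the full validation run within a few minutes on one CPU
while leaving comfortable statistical margins.

## Known limitations

- WIS with softened deterministic targets remains heavy-tailed; per-trial
  effective sample sizes can be small and the bootstrap bounds inherit that
  variance. Doubly-robust estimators are out of scope.
- The rare-transition filter trades variance for a survivorship-flavored
  bias in near-terminal states; the γ = 1 + count-tie-break combination
  mitigates but does not remove it.
- The clinician policy's smoothing (δ = 0.01) slightly flattens very
  concentrated states.
- With 48 largely factor-driven variables, FULL/NO_LAB clusterings are
  noisier than CARDIO at the same k — the intended phenomenon under study,
  but worth remembering when adding representations.
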