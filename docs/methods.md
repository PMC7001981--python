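# Methods

## Task and world model

The environment is a double T-maze with ten locations. The agent enters at
location 1, must move up to the central junction (3), choose a corridor
(2 or 4), climb to a second junction (6 or 9) and enter one of four terminal
arms (5, 7, 8, 10). Terminals absorb: only `stay` is available there. A trial
is exactly four moves.

One terminal is baited per trial, determined by a hidden context:
A → 5, B → 7, C → 8, D → 10. At the baited terminal the agent observes a red
(reward) cue with probability `p_reward` (default 0.95) and a white cue
otherwise; everywhere else the cue is white with certainty. A failed delivery
is modelled as non-delivery (white cue at the correct arm), never as
relocation of the reward. The context is constant within a trial and follows
a trial-level schedule; the study protocol is context A for trials 1–20 and
context D for trials 21–40.

## Generative model

Hidden states factorise as location × context (10 × 4 = 40 states, indexed
`(location − 1) × 4 + context`, so location 5 in context A is state 17 and
location 10 in context D is state 40). Outcomes factorise as location × cue
(10 × 2 = 20). The components are:

* **A** (20 × 40): the likelihood mirrors the world's cue statistics,
  including the delivery probability (`p_reward_model`, by default equal to
  the world's `p_reward`; it is separately configurable to study model–world
  mismatch).
* **B** (one 40 × 40 matrix per action): the deterministic move graph on the
  location factor tensored with the identity on context. Undefined moves
  fall back to `stay` semantics; the enumerated policies never use them.
* **lnC**: log preferences over outcomes — a softmax putting `utility`
  log-units on every red outcome (default 1.3).
* **D**: the initial-state prior of a trial. The location factor is a point
  mass on the start; the context factor is the previous trial's context
  posterior smoothed by a stability kernel that keeps the context with
  probability `stability` (default 0.99) and spreads the remainder equally
  over the other three. Only the context marginal survives between trials.
* **Policies**: all allowable four-move action sequences. `stay` is
  unavailable on the first move (the agent must enter the maze), available
  everywhere afterwards, and the only action at terminals. This rule yields
  exactly 17 sequences, verified at model-build time against the count and
  by a brute-force enumeration oracle in the tests; exactly 4 of them reach
  a terminal arm. Policies are ordered lexicographically
  (up < left < right < stay), so policy 1 is (up, left, up, left).

## Deliberative control

At each of the four decision points the agent:

1. updates its posterior over the 40 states from the latest observation by
   exact discrete Bayesian filtering (exact at this model size; no
   variational approximation is needed);
2. scores every policy π by the path integral of expected free energy over
   the remaining steps,
   `G_π = Σ_τ [ −H[P(o|s)]·ŝ_π(τ) − (ln ô_π(τ) − lnC)·ô_π(τ) ]`,
   an ambiguity term (expected outcome entropy given states) plus a risk
   term (KL divergence of predicted from preferred outcomes); both terms are
   non-positive, so G_π ≤ 0. No separate state-information-gain term is
   included; the ambiguity term is the only epistemic component;
3. maps scores to a policy posterior with a precision-weighted softmax,
   `π̂ ∝ exp(γ·G_π)` (max-subtraction for numerical safety), conditioned on
   the action history: policies whose earlier actions differ from those
   already executed receive exactly zero mass. All 17 policies are still
   *scored* at every decision point — the cost of a fully deliberative trial
   is therefore always 4 × 17 = 68 evaluations — but only executable ones
   compete for selection. This conditioning is what lets the posterior
   sharpen along the path: late in a rewarded trial it concentrates on the
   single policy actually being executed;
4. samples the next action from the posterior's action marginal and acts.

Ties in any argmax resolve to the lowest policy id. A trial starts with an
uninformative white cue at the start location, conditioned against the prior
D without a prediction step.

## The policy cache and the delta rule

The cache stores P(π|s) — a probability over the 17 policies for each of the
40 states, initialised uniform (no habit can fire before learning). After
every policy-posterior computation on a deliberative trial, every state's
column moves towards the current posterior in proportion to how strongly the
agent believes it occupies that state:

    P(π|s) ← P(π|s) + η · ŝ(s) · (π̂(π) − P(π|s)).

The update preserves each column's normalisation identically and keeps all
entries in [0, 1]. One further update is applied after the trial's final
observation, with the posterior collapsed onto the one policy consistent
with all four executed actions, weighted by the final belief ŝ(T). This
end-of-trial write is what stamps the terminal states' columns (e.g. states
17 and 40), which no decision-point belief ever occupies; those columns
carry the highest cached values and are precisely what Scheme 1 reads.
Habitually executed portions of a trial never update the cache.

The cache read-out under a belief is the expectation
`E_ŝ[P(π|s)] = Σ_i ŝ_i · P(π|s_i)`; a habit fires when the maximum over
policies strictly exceeds the habitisation threshold `p_th` (default 0.90).

## The three habitisation schemes

* **Scheme 1 — cache at action selection.** Before the trial begins, the
  read-out is taken under the *previous trial's final belief*. If it
  crosses `p_th`, the winning policy's four actions are executed open-loop:
  no planning, no policy evaluation, no cache update, zero cost. Belief
  filtering still runs on every observation, so the context posterior stays
  current and a context change is eventually noticed — after a delay, which
  is exactly the perseveration window. Trial 1 is always deliberative.
* **Scheme 2 — cache at planning.** At each decision point, each
  still-executable policy's one-step predicted state is formed and the
  read-out of that policy's own cached probability taken over it. A crossing
  hands the remainder of the trial to that policy. Because the one-step
  check can only see the *next* states, whose cached values are lower than
  the terminal ones, habitisation starts at the 4th choice point and creeps
  backwards over trials; with the default threshold the 1st choice point
  never habitises.
* **Scheme 3 — cache at policy evaluation.** Policies are scanned in id
  order; while a policy's path integral is accumulated term by term, the
  read-out is taken over each predicted state. The first crossing (for an
  executable policy) terminates all evaluation and adopts that policy for
  the rest of the trial. Because the scan looks all the way to the terminal
  states, crossings are usually found already at the first choice point, so
  habitual control covers all four choice points at once.

Cost is reported as `n_efe_evals` (completed policy evaluations; 68 per
fully deliberative trial) and `n_efe_terms` (raw per-(policy, τ) integral
steps; 170 per fully deliberative trial), the latter being the granularity
at which Scheme 3 truncates. Wall-clock time is deliberately not used as the
cost measure: it is hardware-bound, whereas evaluation counts are exact and
reproducible.

## Experiment harness

`run_experiment` runs `n_reps` independent repetitions of an
`n_trials`-trial session (defaults 100 × 40, context A→D at trial 21). Each
repetition draws its random stream from a seed sequence spawned from
`(seed, rep)`, so results are bit-reproducible and enlarging `n_reps` never
perturbs earlier repetitions. Recorded per (rep, trial): reward; the
end-of-trial context posterior and its entropy normalised by ln 4
("uncertainty"); per-choice-point habit flags and the first habitised choice
point; the maximum cache read-out (for Scheme 1, the pre-trial check value;
for Schemes 2–3, the maximum encountered during the trial); the executed
policy; and the two cost counters. "Performance" on a trial is the fraction
of repetitions rewarded.

## Parameter defaults and calibration

| parameter | default | meaning |
|---|---|---|
| `p_reward` | 0.95 | delivery probability at the baited arm |
| `stability` | 0.99 | between-trial context-stability prior |
| `p_th` | 0.90 | habitisation threshold on the cache read-out |
| `gamma` | 3.0 | softmax precision on expected free energy |
| `utility` | 1.3 | log-preference for reward cues |
| `eta` | 0.85 | cache learning rate |

The precision, utility and learning rate are not dictated by the task and
were calibrated once, jointly, against the qualitative shape of the
reference dynamics, then frozen. The calibration is governed by a narrow
trade-off window:

* γ·ΔG (ΔG = score gap between the best policy and a non-rewarding one under
  a known context) is bounded **above** by Scheme 2's habitisation ordering:
  the cached value at the one-step-ahead states must remain below `p_th`
  while the terminal state's value crosses it, otherwise habits would appear
  at the trial's first choice immediately rather than creeping backwards
  from the last.
* It is bounded **below** by performance: too little precision and the agent
  keeps sampling non-rewarding policies even when certain of the context.
* For a fixed γ·ΔG, a *smaller* utility with a *larger* precision improves
  early exploration — the 13 policies that end at no arm are suppressed
  relative to the 4 arm-reaching ones even under an uncertain context —
  which determines how fast the first habit forms.
* η < 1 is required for the backward creep of Scheme 2's habitisation: with
  η = 1 every reachable cache column converges in a single trial and all
  choice points would habitise simultaneously.

With the frozen defaults the Scheme-1 agent's averaged cache read-out first
exceeds 0.9 at trials 6–7, collapses shortly after the switch, re-crosses at
trials 28–29, and the stale policy predominates through trial 22 (checked
over several seeds). The §-level protocol sizes (40 trials, 100 repetitions)
are used as-is throughout; tests use smaller repetition counts where only a
qualitative property is asserted.

## Numerical choices and degenerate inputs

* Beliefs, predicted outcomes, policy posteriors and preference
  distributions are normalised and checked at 1e−10; the cache's per-state
  normalisation is preserved to 1e−12 over arbitrarily long update
  sequences.
* The expected-free-energy path integral accumulates its per-τ terms in one
  shared code path, so Scheme 3's truncated integrals and the full scheme's
  complete ones are floating-point identical; with `p_th > 1` all three
  schemes replay the full-inference trajectory bit for bit under a shared
  seed.
* An observation with zero probability under the predicted states raises an
  explicit impossible-observation error rather than renormalising silently.
* `p_reward = 1` or `0`, `stability = 1`, `utility = 0` and `p_th > 1` are
  all valid degenerate settings and are exercised in the tests.

## What the simulations do and do not show

The world generator implements exactly the study conditions: a single agent,
a fixed maze, trial-level context switches, and stochastic delivery at one
arm. It does not emulate richer features of animal experiments — no motor
noise, no variable trial lengths, no within-trial context volatility, no
devaluation procedure — so passing results demonstrate the internal
consistency of the caching account (habit formation, perseveration and
transfer of control under these conditions), not a fit to behavioural data.
Known limitations: habits are restricted to the 17-policy repertoire (no
habit acquisition beyond it); precision γ is fixed rather than inferred; and
under rapidly alternating contexts Scheme 1 perseverates by construction,
since its check precedes any inference about the current trial.
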