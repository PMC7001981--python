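# habitcache

Discrete-state Active Inference in a double T-maze, with three
policy-caching schemes that model **habit formation** — the transfer of
control from deliberate, model-based planning to cheap, automatic habits,
and back again when the world changes.

The package is for computational neuroscientists and behavioural modellers
who want a self-contained, reproducible implementation of the
caching account of habitisation: habits as *cached policy probabilities*
layered on top of a deliberative agent, rather than as a separately learned
model-free controller.

## The model

An artificial rat forages in a double T-maze with 10 locations. It starts at
location 1 and can reach one of four terminal arms (5, 7, 8, 10) in four
moves; which arm is baited is set by a hidden context (A–D) that is stable
across trials with prior probability 0.99, and reward is delivered at the
correct arm 95% of the time. The agent's generative model has 40 hidden
states (10 locations × 4 contexts), 20 outcomes (10 locations × 2 cues) and
17 exhaustively enumerated four-move policies, of which 4 reach an arm.

Deliberative control scores every policy π by the path integral of expected
free energy over the remaining steps,

    G_π = Σ_τ [ −H[P(o|s)] · ŝ_π(τ) − (ln ô_π(τ) − ln C) · ô_π(τ) ],

an *ambiguity* term plus a *risk* (KL-control) term, and samples actions
from a precision-weighted softmax, π̂ ∝ exp(γ G_π). On top of this, the
agent caches P(π|s) — the policy probabilities conditioned on each hidden
state — with a delta rule weighted by state occupancy,

    P(π|s) ← P(π|s) + η ŝ(s) (π̂(π) − P(π|s)),

and reads the cache out through the expectation E_ŝ[P(π|s)] = Σᵢ ŝᵢ P(π|sᵢ).
When the read-out exceeds a threshold (p_th = 0.9), control transfers to the
cached policy. Three schemes differ in *when* the cache is consulted:
before the trial (Scheme 1, replacing all inference), during one-step
planning (Scheme 2, habitising the trial's tail), or inside the policy-
evaluation path integral, which is truncated at the first crossing
(Scheme 3).

## Worked example

`examples/habit_formation.py` runs the full study protocol for Scheme 1 —
40 trials, context A for trials 1–20 and D afterwards, averaged over 100
repetitions — and prints per-trial aggregates (excerpt):

```
trial  reward  habitised  max E[P(pi|s)]  P(ctx A)
    1    0.19       0.00           0.059     0.442
    7    0.91       0.78           0.919     0.972
   20    0.88       0.92           0.971     0.973
   21    0.00       0.88           0.964     0.782
   22    0.06       0.00           0.800     0.360
   28    0.73       0.66           0.910     0.018

cache read-out first exceeds 0.9 at trial 7 (habit forms),
collapses after the switch at trial 21, re-crosses at trial 28;
the stale policy (up,left,up,left) predominates through trial 22.
```

Reading the columns: *reward* is the fraction of repetitions rewarded on
that trial; *habitised* the fraction controlled by the cache;
*max E[P(π|s)]* the cache read-out compared against the 0.9 threshold; and
*P(ctx A)* the agent's end-of-trial belief in context A. The run shows the
three signatures of the caching account: a habit forms once context
uncertainty resolves (around trial 7); after the unsignalled switch the
agent briefly *perseverates* with the stale policy while its context belief
catches up (trials 21–22); deliberation then resumes, the new context is
identified, and a new habit forms (read-out re-crossing around trial 28).

Other examples: `examples/policy_repertoire.py` (the 17 policies and their
expected free energies), `examples/full_inference_session.py` (purely
deliberative context learning), `examples/scheme_comparison.py`
(deliberation cost and habitised choice points across all three schemes).

There is also a thin CLI:

```
habitcache run --scheme scheme1 --seed 7 --out out/   # trials.csv, aggregate.csv, manifest.json
habitcache policies                                   # the 17-policy table
habitcache model                                      # model matrices as JSON
habitcache sweep --param p_th --values 0.8,0.9 --out sweep/
```

## Layout

```
src/habitcache/
  world.py        # ground-truth maze, cue sampling, context schedule
  model.py        # A/B/lnC/D, state indexing, policy enumeration
  inference.py    # filtering, expected free energy, softmax, trial loop
  caching.py      # the policy cache, delta rule, habit schemes 1-3
  experiments.py  # batch harness, tidy metrics, aggregation
  cli.py          # thin command-line interface
docs/methods.md   # model, parameters, calibration, limitations
examples/         # narrative scripts, one per capability
tests/            # pytest suite incl. end-to-end dynamics checks
```
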