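"""One fully deliberative session: context learning without any caching.

Runs a single 20-trial session of the full Active Inference loop in a fixed
context A and prints, per trial, whether the agent was rewarded and how
certain it is about the context afterwards. Early trials are exploratory
(the agent does not know which arm is baited); once the context posterior
sharpens, it heads for location 5 almost every trial.
"""

import numpy as np

from habitcache import run_trial_full, build_model

model = build_model()
rng = np.random.default_rng(0)
prev_ctx = np.full(4, 0.25)

print("trial  rewarded  P(context=A)  actions")
for trial in range(1, 21):
    rec = run_trial_full(model, prev_ctx, "A", 0.95, rng)
    prev_ctx = rec.context_posterior
    print(
        f"{trial:>5}  {str(rec.rewarded):>8}  {prev_ctx[0]:12.3f}  "
        f"{','.join(rec.actions)}"
    )
print()
print(
    "Each trial costs 68 expected-free-energy evaluations (17 policies at\n"
    "each of 4 decision points). The context posterior is carried between\n"
    "trials through a 99%-stability prior, so evidence accumulates."
)
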