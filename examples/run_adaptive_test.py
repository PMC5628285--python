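"""A single adaptive CES-D assessment, step by step.

Simulates one respondent with moderately elevated depressive symptoms
(theta = 1.2) and administers the CAT: most-informative item first,
re-estimate after every answer, stop at SE <= 0.32 (reliability ~0.90).
Prints the item-by-item trajectory and the final maximum-likelihood
estimate.
"""

import numpy as np

import cesdcat as cc

bank = cc.cesd_item_bank()
true_theta = 1.2
rng = np.random.default_rng(7)

result = cc.run_cat(bank, cc.simulated_responder(bank, true_theta, rng),
                    cc.CATConfig(se_stop=0.32))

print(f"{'step':>4} {'item':>5} {'resp':>4} {'theta':>7} {'SE':>6}")
for k, (iid, x, est) in enumerate(
    zip(result.administered, result.responses, result.trajectory), 1
):
    print(f"{k:>4} {iid:>5} {x:>4} {est.theta:7.3f} {est.se:6.3f}")

print(f"\nstopped after {result.n_items} of {len(bank)} items "
      f"({result.stop_reason})")
print(f"final ML estimate {result.final.theta:+.3f} (SE {result.final.se:.3f}); "
      f"true theta {true_theta:+.3f}")
print("Reading: the full 20-item questionnaire is cut roughly in half while "
      "keeping reliability near 0.90.")
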