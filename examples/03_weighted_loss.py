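"""Class weighting for imbalanced sample sets.

Shows how the per-class weights eta_i = (1 - beta_i) / beta_i are derived from
sample counts, and that the batch cost (beta * eta weighting) reduces to the
closed form (1 - beta) * (-log p_true) per sample.
"""

import numpy as np

from chirpid import BatchPrediction, batch_cost, class_weights

counts = [100, 60, 20]
weights = class_weights(counts)
print("class counts:", counts)
for i, (b, e) in enumerate(zip(weights.beta, weights.eta)):
    print(f"  class {i}: beta = {b:.3f}  eta = {e:.3f}  "
          f"effective weight beta*eta = {b * e:.3f}")

rng = np.random.default_rng(0)
probs = rng.dirichlet([2.0, 2.0, 2.0], size=8)
idx = rng.integers(0, 3, 8)
y = np.zeros_like(probs)
y[np.arange(8), idx] = 1.0
cost = batch_cost(BatchPrediction(y, probs), weights)
closed = np.mean((1 - weights.beta[idx]) * -np.log(probs[np.arange(8), idx]))
print(f"\nbatch cost           : {cost:.6f}")
print(f"closed form (1-beta) : {closed:.6f}")
print("\nThe rarest class carries the largest effective weight, so its"
      "\nmisclassifications dominate the cost; the two numbers above agree"
      "\nbecause beta * eta = 1 - beta identically.")
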