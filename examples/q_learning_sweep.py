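"""Sweep softmax greediness across conflict and volatility conditions.

For each environment cell, Q-learning agents with different inverse
temperatures beta play 500-trial sessions; the return-maximising beta per
cell shows that more uncertain environments favour more exploratory
(lower-beta) policies.
"""

import numpy as np

from driftbandit.rl_agent import optimal_beta_map

res = optimal_beta_map(
    conflict_grid=[0.55, 0.75, 0.90],
    volatility_grid=[10.0, 30.0, 100.0],
    beta_grid=np.linspace(0.1, 3.0, 12),
    n_iter=100,
    rng=np.random.default_rng(1),
)

print("return-maximising beta per (P, lambda) cell:")
print("           " + "  ".join(f"lam={l:5.0f}" for l in res.volatility_grid))
for i, p in enumerate(res.conflict_grid):
    row = "  ".join(f"{b:9.2f}" for b in res.best_beta[i])
    print(f"P={p:.2f}  {row}")
print("\nhigher P (less conflict) and higher lambda (less volatility) both "
      "push the best policy toward greedier selection (larger beta)")
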