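"""Generate dynamic two-armed bandit sessions and summarise their volatility.

Builds sessions under the low-volatility design (Poisson epoch mean 25,
reward probability 0.75 for the optimal target) and prints the fraction of
change-point trials, which should sit near the design hazard 1/25 = 0.04.
"""

import numpy as np

from driftbandit.task_env import TaskConfig, change_point_fraction, generate_session

rng = np.random.default_rng(0)
cfg = TaskConfig(lambda_mean=25.0, p_optimal=0.75, n_trials=600)

mean, sd, _ = change_point_fraction(cfg, n_sessions=24, rng=rng)
print(f"change-point trial fraction over 24 sessions: {mean:.4f} +/- {sd:.4f}")
print("  -> one switch in the optimal target roughly every 25 trials")

session = generate_session(cfg, rng)
print(f"\nfirst session: {session['is_change_point'].sum()} change points "
      f"in {len(session)} trials")
print(session.head(8).to_string(index=False))
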