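import numpy as np
import pytest

from driftbandit.linking import LinkingParams, simulate_linked_subject
from driftbandit.observer import ObserverConfig
from driftbandit.task_env import TaskConfig


@pytest.fixture(scope="session")
def linked_session():
    """One medium-sized linked synthetic subject shared across tests."""
    task = TaskConfig(
        lambda_mean=25, p_optimal=0.75, n_trials=1200, rt_bounds=(0.1, 2.5), seed=42
    )
    obs = ObserverConfig.from_task(task)
    link = LinkingParams(v0=1.2, a0=0.8, beta_v=0.5, beta_a=0.1, t_r=0.26)
    rng = np.random.default_rng(42)
    data = simulate_linked_subject(task, obs, link, rng)
    return task, obs, link, data
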