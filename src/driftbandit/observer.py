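"""Reduced Bayesian change-point ideal observer.

The observer tracks a belief B about the mean reward of each target,
learning from the delivered points with a learning rate that adapts to two
sources of uncertainty: the probability that the latest outcome reflects a
change point (omega), and the imprecision of the current belief
(1 - phi, relative uncertainty).  Per trial, in order:

    delta  = r - B_chosen                          (prediction error)
    omega  = U(r) H / (U(r) H + N(r | B_chosen, sigma_t^2) (1 - H))
    alpha  = omega + (1 - omega)(1 - phi)
    B_chosen   += alpha * delta
    B_unchosen  = B_unchosen (1 - omega) + omega * E(r)
    RU     = N / (N + sigma_n^2),
             N = omega sigma_n^2 + (1-omega)(1-phi) sigma_n^2
                 + omega (1-omega) (delta * phi)^2
    phi'   = 1 - RU
    sigma_t^2' = sigma_n^2 + (1 - phi') sigma_n^2 / phi'

where H is the global hazard rate of change points, sigma_n^2 the variance
of the generative point distribution, U a uniform density over the
plausible outcome range, and E(r) the pooled expected value of the two
targets.  The signed belief difference delta_B = B_optimal - B_suboptimal
and omega are the two uncertainty signals handed to the decision model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_env import TaskConfig

_SIGMA_T2_CEIL = 1e12  # cap when confidence collapses to zero


@dataclass
class ObserverConfig:
    """Fixed quantities the observer knows about the task.

    ``expected_rewards`` are the imposed per-target expectations
    (r_opt, r_subopt) from the design's reward probabilities; their mean is
    the pooled E(r) used to reset the unchosen belief at change points.
    """

    sigma_n: float = 1.0
    hazard: float = 0.04
    expected_rewards: tuple[float, float] = (2.25, 0.75)
    uniform_support: tuple[float, float] = (0.0, 6.0)
    phi_init: float = 0.5
    b_init: float | None = None  # default: pooled E(r) for both targets

    def __post_init__(self) -> None:
        if self.sigma_n <= 0:
            raise ValueError(f"sigma_n must be > 0, got {self.sigma_n}")
        if not (0.0 <= self.hazard <= 1.0):
            raise ValueError(f"hazard must be in [0, 1], got {self.hazard}")
        lo, hi = self.uniform_support
        if hi <= lo:
            raise ValueError(f"degenerate uniform_support {self.uniform_support}")
        if not (0.0 < self.phi_init <= 1.0):
            raise ValueError(f"phi_init must be in (0, 1], got {self.phi_init}")

    @classmethod
    def from_task(
        cls, task: TaskConfig, hazard: float | None = None, **kwargs
    ) -> "ObserverConfig":
        """Observer matched to a task design: H = 1/lambda unless given."""
        return cls(
            sigma_n=task.reward_sigma,
            hazard=1.0 / task.lambda_mean if hazard is None else hazard,
            expected_rewards=task.expected_rewards,
            **kwargs,
        )

    @property
    def pooled_expected_reward(self) -> float:
        return 0.5 * (self.expected_rewards[0] + self.expected_rewards[1])


@dataclass
class ObserverState:
    """Mutable trialwise observer quantities (points units unless noted)."""

    B: np.ndarray  # belief per target
    phi: float  # model confidence in [0, 1]
    sigma_t2: float  # predictive variance, >= sigma_n^2
    omega: float = 0.0  # change-point probability of the last outcome
    alpha_t: float = 0.0  # learning rate applied on the last outcome
    delta: float = 0.0  # last prediction error
    RU: float = 0.5  # relative uncertainty

    @classmethod
    def initial(cls, config: ObserverConfig) -> "ObserverState":
        b0 = (
            config.pooled_expected_reward
            if config.b_init is None
            else config.b_init
        )
        phi0 = config.phi_init
        return cls(
            B=np.array([b0, b0], dtype=float),
            phi=phi0,
            sigma_t2=config.sigma_n**2 + (1.0 - phi0) * config.sigma_n**2 / phi0,
        )

    def delta_B(self, optimal_id: int) -> float:
        """Signed belief difference, optimal-coded."""
        return float(self.B[optimal_id] - self.B[1 - optimal_id])


def prediction_error(reward: float, belief_chosen: float) -> float:
    return reward - belief_chosen


def change_point_probability(
    reward: float,
    belief_chosen: float,
    sigma_t2: float,
    hazard: float,
    uniform_support: tuple[float, float],
) -> float:
    """Posterior probability that the outcome came from a changed regime.

    Likelihood-ratio form: uniform "anything could happen" density times the
    hazard, against the current Gaussian predictive density.  Rewards
    outside the uniform support are clamped onto it (the density would
    otherwise be zero on both hypotheses).
    """
    if not (0.0 <= hazard <= 1.0):
        raise ValueError(f"hazard must be in [0, 1], got {hazard}")
    lo, hi = uniform_support
    r = min(max(reward, lo), hi)
    u_dens = 1.0 / (hi - lo)
    n_dens = np.exp(-((r - belief_chosen) ** 2) / (2.0 * sigma_t2)) / np.sqrt(
        2.0 * np.pi * sigma_t2
    )
    num = u_dens * hazard
    den = num + n_dens * (1.0 - hazard)
    if den == 0.0:
        return 1.0 if hazard > 0 else 0.0
    return float(num / den)


def observer_step(
    state: ObserverState, config: ObserverConfig, chosen: int, reward: float
) -> ObserverState:
    """One trial of the observer; returns the updated state (input untouched)."""
    sn2 = config.sigma_n**2
    B = state.B.copy()
    phi = state.phi

    delta = prediction_error(reward, B[chosen])
    omega = change_point_probability(
        reward, B[chosen], state.sigma_t2, config.hazard, config.uniform_support
    )
    alpha = omega + (1.0 - omega) * (1.0 - phi)

    B[chosen] = B[chosen] + alpha * delta
    B[1 - chosen] = B[1 - chosen] * (1.0 - omega) + omega * config.pooled_expected_reward

    num = (
        omega * sn2
        + (1.0 - omega) * (1.0 - phi) * sn2
        + omega * (1.0 - omega) * (delta * phi) ** 2
    )
    RU = num / (num + sn2)
    phi_new = 1.0 - RU
    if phi_new <= 0.0:
        sigma_t2_new = _SIGMA_T2_CEIL
    else:
        sigma_t2_new = sn2 + (1.0 - phi_new) * sn2 / phi_new
        sigma_t2_new = min(sigma_t2_new, _SIGMA_T2_CEIL)

    return ObserverState(
        B=B,
        phi=phi_new,
        sigma_t2=sigma_t2_new,
        omega=omega,
        alpha_t=alpha,
        delta=delta,
        RU=RU,
    )


OBSERVER_COLUMNS = [
    "B0",
    "B1",
    "delta_B",
    "omega",
    "phi",
    "sigma_t2",
    "alpha",
    "delta",
]


def run_observer(
    session: pd.DataFrame, config: ObserverConfig
) -> pd.DataFrame:
    """Run the observer over a played session.

    Requires ``choice`` and per-trial delivered reward; unrewarded choices
    contribute r = 0 (the task shows "0 points" as explicit feedback).
    The emitted row for trial t holds the state *entering* the trial
    (pre-update beliefs and the omega/alpha produced by the previous
    outcome): these are the quantities available to drive the decision on
    trial t.  Rows with a missing choice carry the state forward and are
    flagged.
    """
    state = ObserverState.initial(config)
    n = len(session)
    out = np.empty((n, len(OBSERVER_COLUMNS)))
    flags = np.zeros(n, dtype=bool)
    choices = session["choice"].to_numpy()
    optimal = session["optimal_id"].to_numpy().astype(int)
    for t in range(n):
        out[t] = (
            state.B[0],
            state.B[1],
            state.delta_B(optimal[t]),
            state.omega,
            state.phi,
            state.sigma_t2,
            state.alpha_t,
            state.delta,
        )
        c = choices[t]
        if np.isnan(c):
            flags[t] = True
            continue
        c = int(c)
        reward = _delivered_reward(session, t, c)
        state = observer_step(state, config, c, reward)
    result = pd.DataFrame(out, columns=OBSERVER_COLUMNS, index=session.index)
    result["missing_choice"] = flags
    return result


def _delivered_reward(session: pd.DataFrame, t: int, choice: int) -> float:
    if session[f"reward_available_{choice}"].iloc[t]:
        return float(session["points"].iloc[t])
    return 0.0
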