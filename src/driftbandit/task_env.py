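"""Dynamic two-armed bandit environments with controlled conflict and volatility.

A session is a sequence of *epochs*: runs of trials during which one of the
two targets is "optimal" (rewarded with probability ``p_optimal``, the other
with ``1 - p_optimal``).  Epoch lengths are Poisson distributed; the first
trial of each new epoch after the first is a *change point*, where the
identity of the optimal target switches.  Reward magnitudes on rewarded
trials are integer points drawn from Normal(reward_mu, reward_sigma),
floored at zero.

Conflict is controlled by ``p_optimal`` (closer to 0.5 = higher conflict);
volatility by ``lambda_mean`` (shorter epochs = more change points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SESSION_COLUMNS = [
    "trial",
    "optimal_id",
    "is_change_point",
    "reward_available_0",
    "reward_available_1",
    "points",
    "choice",
    "rt",
    "correct",
]


class InvalidConfigError(ValueError):
    """Raised when a task or agent configuration violates its invariants."""


@dataclass
class TaskConfig:
    """Design parameters of one bandit session.

    Parameters
    ----------
    lambda_mean
        Mean epoch length in trials (Poisson lambda). Must be >= 1.
    p_optimal
        Probability of reward for the currently optimal target, in (0.5, 1].
        The suboptimal target rewards with probability ``1 - p_optimal``.
    n_trials
        Session length in trials.
    reward_mu, reward_sigma
        Mean and SD of the point-magnitude distribution (points).
    rt_bounds
        Admissible reaction-time window in seconds; simulated RTs outside it
        are redrawn.
    seed
        Optional RNG seed used when no generator is passed explicitly.
    """

    lambda_mean: float = 25.0
    p_optimal: float = 0.75
    n_trials: int = 600
    reward_mu: float = 3.0
    reward_sigma: float = 1.0
    rt_bounds: tuple[float, float] = (0.1, 1.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.5 < self.p_optimal <= 1.0):
            raise InvalidConfigError(
                f"p_optimal must be in (0.5, 1], got {self.p_optimal}"
            )
        if self.lambda_mean < 1:
            raise InvalidConfigError(
                f"lambda_mean must be >= 1, got {self.lambda_mean}"
            )
        if self.n_trials < 1:
            raise InvalidConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.reward_sigma <= 0:
            raise InvalidConfigError(
                f"reward_sigma must be > 0, got {self.reward_sigma}"
            )
        if self.rt_bounds[0] >= self.rt_bounds[1]:
            raise InvalidConfigError(f"degenerate rt_bounds {self.rt_bounds}")

    def rng(self, rng: np.random.Generator | None = None) -> np.random.Generator:
        if rng is not None:
            return rng
        return np.random.default_rng(self.seed)

    @property
    def expected_rewards(self) -> tuple[float, float]:
        """Imposed expected reward (points) for (optimal, suboptimal) targets.

        The integer conversion of N(mu, sigma) draws barely moves the mean,
        so the imposed expectation is p * mu and (1-p) * mu.
        """
        return (
            self.p_optimal * self.reward_mu,
            (1.0 - self.p_optimal) * self.reward_mu,
        )


def draw_epoch_lengths(
    lambda_mean: float, n_trials: int, rng: np.random.Generator
) -> list[int]:
    """Draw Poisson epoch lengths until they cover ``n_trials`` trials.

    Zero draws are resampled to >= 1 (a zero-length epoch has no meaning);
    the final epoch is truncated so the lengths sum exactly to ``n_trials``.
    """
    if n_trials < 1:
        raise InvalidConfigError(f"n_trials must be >= 1, got {n_trials}")
    if lambda_mean < 1:
        raise InvalidConfigError(f"lambda_mean must be >= 1, got {lambda_mean}")
    lengths: list[int] = []
    total = 0
    while total < n_trials:
        draw = int(rng.poisson(lambda_mean))
        while draw == 0:
            draw = int(rng.poisson(lambda_mean))
        draw = min(draw, n_trials - total)
        lengths.append(draw)
        total += draw
    return lengths


def generate_session(
    config: TaskConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate one session as a trial-level DataFrame (``SESSION_COLUMNS``).

    ``choice``/``rt``/``correct`` are left NaN: a session is an environment
    record until an agent (or human) plays it.  ``reward_available_k`` is the
    per-target Bernoulli outcome, drawn independently per target;
    ``points`` is the magnitude delivered *if* the chosen target's outcome is
    a reward (integerised Normal draw, floored at 0).
    """
    rng = config.rng(rng)
    lengths = draw_epoch_lengths(config.lambda_mean, config.n_trials, rng)
    n = config.n_trials

    optimal_id = np.zeros(n, dtype=int)
    is_cp = np.zeros(n, dtype=bool)
    start = 0
    current = int(rng.integers(0, 2))
    for i, length in enumerate(lengths):
        if i > 0:
            current = 1 - current
            is_cp[start] = True
        optimal_id[start : start + length] = current
        start += length

    p = config.p_optimal
    p_target = np.where(optimal_id[:, None] == np.arange(2)[None, :], p, 1.0 - p)
    reward_available = rng.random((n, 2)) < p_target

    magnitudes = _integer_points(
        rng.normal(config.reward_mu, config.reward_sigma, size=n)
    )

    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "optimal_id": optimal_id,
            "is_change_point": is_cp,
            "reward_available_0": reward_available[:, 0],
            "reward_available_1": reward_available[:, 1],
            "points": magnitudes,
            "choice": np.full(n, np.nan),
            "rt": np.full(n, np.nan),
            "correct": np.full(n, np.nan),
        }
    )


def _integer_points(draws: np.ndarray) -> np.ndarray:
    """Round half away from zero, then floor at 0 points."""
    rounded = np.sign(draws) * np.floor(np.abs(draws) + 0.5)
    return np.maximum(rounded, 0.0).astype(int)


def reward_for_choice(session: pd.DataFrame, trial: int, choice: int) -> float:
    """Points delivered for choosing ``choice`` on ``trial`` (0 if unrewarded)."""
    row = session.iloc[trial]
    if row[f"reward_available_{choice}"]:
        return float(row["points"])
    return 0.0


def hazard_rate(session: pd.DataFrame) -> float:
    """Global change-point probability H = n_change_points / n_trials."""
    if len(session) == 0:
        raise ValueError("empty session has no hazard rate")
    return float(session["is_change_point"].sum()) / len(session)


def change_point_fraction(
    config: TaskConfig, n_sessions: int, rng: np.random.Generator
) -> tuple[float, float, np.ndarray]:
    """Mean and SD (across sessions) of the fraction of change-point trials.

    Returns ``(mean, sd, per_session_fractions)``.
    """
    fractions = np.empty(n_sessions)
    for s in range(n_sessions):
        lengths = draw_epoch_lengths(config.lambda_mean, config.n_trials, rng)
        fractions[s] = (len(lengths) - 1) / config.n_trials
    return float(fractions.mean()), float(fractions.std(ddof=1)), fractions
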