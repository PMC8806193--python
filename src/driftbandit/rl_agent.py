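"""Tabular Q-learning on the dynamic bandit and the conflict x volatility sweep.

The agent keeps one value per target, chooses with a softmax policy whose
inverse temperature beta sets its greediness, and learns with a constant
delta rule Q <- Q + alpha (r - Q) from binary reward.  Sweeping beta across
a grid of conflict (p_optimal) and volatility (lambda) conditions and
keeping the return-maximising beta per cell reproduces the classic result
that more uncertain environments favour more exploratory policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task_env import InvalidConfigError, TaskConfig, draw_epoch_lengths


@dataclass
class QAgentConfig:
    alpha: float = 0.1
    beta: float = 1.0
    q_init: float = 0.5  # E(r) for binary reward

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise InvalidConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise InvalidConfigError(f"beta must be >= 0, got {self.beta}")


@dataclass
class GridSearchResult:
    conflict_grid: np.ndarray
    volatility_grid: np.ndarray
    beta_grid: np.ndarray
    mean_return: np.ndarray  # (n_conflict, n_volatility, n_beta)
    best_beta: np.ndarray  # (n_conflict, n_volatility)
    returns: np.ndarray | None = None  # (n_conflict, n_volatility, n_beta, n_iter)

    def bootstrap_best_beta(
        self, cell: tuple[int, int], n_boot: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Bootstrap distribution of the return-maximising beta for one cell."""
        if self.returns is None:
            raise ValueError("grid search was run without keep_returns")
        draws = self.returns[cell[0], cell[1]]  # (n_beta, n_iter)
        n_iter = draws.shape[1]
        out = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n_iter, n_iter)
            out[b] = self.beta_grid[np.argmax(draws[:, idx].mean(axis=1))]
        return out


def softmax_policy(q_values: np.ndarray, beta: float) -> np.ndarray:
    """Action probabilities proportional to exp(beta * Q), overflow-safe."""
    if beta < 0:
        raise InvalidConfigError(f"beta must be >= 0, got {beta}")
    q = np.asarray(q_values, dtype=float)
    scaled = beta * q
    scaled -= scaled.max(axis=-1, keepdims=True)
    expq = np.exp(scaled)
    return expq / expq.sum(axis=-1, keepdims=True)


def q_update(
    q_values: np.ndarray, choice: int, reward: float, alpha: float
) -> np.ndarray:
    """Delta-rule update of the chosen entry only."""
    if not (0.0 <= alpha <= 1.0):
        raise InvalidConfigError(f"alpha must be in [0, 1], got {alpha}")
    q = np.array(q_values, dtype=float)
    q[choice] += alpha * (reward - q[choice])
    return q


def simulate_agent(
    agent_config: QAgentConfig,
    task_config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
) -> float:
    """Run one agent for ``n_trials`` and return total binary reward."""
    returns = _simulate_agents_batch(
        alpha=agent_config.alpha,
        beta=agent_config.beta,
        q_init=agent_config.q_init,
        p_optimal=task_config.p_optimal,
        lambda_mean=task_config.lambda_mean,
        n_trials=n_trials,
        n_agents=1,
        rng=rng,
    )
    return float(returns[0])


def _simulate_agents_batch(
    alpha: float,
    beta: float,
    q_init: float,
    p_optimal: float,
    lambda_mean: float,
    n_trials: int,
    n_agents: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised agent runs: ``n_agents`` independent agents/environments.

    Each agent gets its own change-point schedule and Bernoulli reward
    stream; the trial loop is shared so large iteration counts stay cheap.
    """
    # Per-agent optimal-target identity over trials.
    optimal = np.empty((n_agents, n_trials), dtype=np.int8)
    for i in range(n_agents):
        lengths = draw_epoch_lengths(lambda_mean, n_trials, rng)
        ids = (np.arange(len(lengths)) + rng.integers(0, 2)) % 2
        optimal[i] = np.repeat(ids, lengths)[:n_trials]

    q = np.full((n_agents, 2), q_init, dtype=float)
    total = np.zeros(n_agents)
    u_choice = rng.random((n_agents, n_trials))
    u_reward = rng.random((n_agents, n_trials))
    rows = np.arange(n_agents)
    for t in range(n_trials):
        scaled = beta * q
        scaled -= scaled.max(axis=1, keepdims=True)
        expq = np.exp(scaled)
        p0 = expq[:, 0] / expq.sum(axis=1)
        choice = (u_choice[:, t] >= p0).astype(np.int8)
        p_rew = np.where(choice == optimal[:, t], p_optimal, 1.0 - p_optimal)
        reward = (u_reward[:, t] < p_rew).astype(float)
        total += reward
        q[rows, choice] += alpha * (reward - q[rows, choice])
    return total


def optimal_beta_map(
    conflict_grid: np.ndarray,
    volatility_grid: np.ndarray,
    beta_grid: np.ndarray | None = None,
    n_iter: int = 200,
    n_trials: int = 500,
    alpha: float = 0.1,
    rng: np.random.Generator | None = None,
    keep_returns: bool = False,
) -> GridSearchResult:
    """Mean return per (P, lambda, beta) cell and the return-maximising beta.

    Defaults mirror the published sweep: 500-trial runs, 200 iterations per
    cell, beta spanning 0.1-3.  Ties in the argmax resolve to the smaller
    beta.
    """
    conflict_grid = np.atleast_1d(np.asarray(conflict_grid, dtype=float))
    volatility_grid = np.atleast_1d(np.asarray(volatility_grid, dtype=float))
    if beta_grid is None:
        beta_grid = np.linspace(0.1, 3.0, 30)
    beta_grid = np.atleast_1d(np.asarray(beta_grid, dtype=float))
    if conflict_grid.size == 0 or volatility_grid.size == 0 or beta_grid.size == 0:
        raise InvalidConfigError("grids must be non-empty")
    if n_iter < 1:
        raise InvalidConfigError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng() if rng is None else rng

    mean_return = np.empty(
        (conflict_grid.size, volatility_grid.size, beta_grid.size)
    )
    all_returns = (
        np.empty((conflict_grid.size, volatility_grid.size, beta_grid.size, n_iter))
        if keep_returns
        else None
    )
    for ci, p in enumerate(conflict_grid):
        for vi, lam in enumerate(volatility_grid):
            for bi, beta in enumerate(beta_grid):
                returns = _simulate_agents_batch(
                    alpha=alpha,
                    beta=float(beta),
                    q_init=0.5,
                    p_optimal=float(p),
                    lambda_mean=float(lam),
                    n_trials=n_trials,
                    n_agents=n_iter,
                    rng=rng,
                )
                mean_return[ci, vi, bi] = returns.mean()
                if all_returns is not None:
                    all_returns[ci, vi, bi] = returns
    # argmax returns the first (smallest-beta) maximiser, the stated tie-break
    best_beta = beta_grid[np.argmax(mean_return, axis=2)]
    return GridSearchResult(
        conflict_grid=conflict_grid,
        volatility_grid=volatility_grid,
        beta_grid=beta_grid,
        mean_return=mean_return,
        best_beta=best_beta,
        returns=all_returns,
    )
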