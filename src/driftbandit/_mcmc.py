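"""Small MCMC toolkit: adaptive Metropolis-within-Gibbs and bridge sampling.

Kept deliberately minimal — random-walk coordinate updates with Robbins-
Monro step adaptation during burn-in are adequate for the low-dimensional
posteriors fitted here, and a moment-matched Gaussian bridge estimator is a
stable route to marginal likelihoods from posterior draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

TARGET_ACCEPT = 0.44  # optimal scalar random-walk acceptance rate


@dataclass
class SamplerSettings:
    n_samples: int = 20000  # total draws including burn-in
    burn: int = 5000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.burn >= self.n_samples:
            raise ValueError("burn must be < n_samples")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_samples - self.burn + self.thin - 1) // self.thin


def metropolis_within_gibbs(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    settings: SamplerSettings,
    rng: np.random.Generator,
    step0: np.ndarray | None = None,
    log_like: Callable[[np.ndarray], float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinate-wise random-walk Metropolis with burn-in step adaptation.

    Returns ``(draws, loglik_trace, accept_rate)``; ``loglik_trace`` is the
    value of ``log_like`` (or ``log_post`` if none given) at each kept draw.
    """
    x = np.array(x0, dtype=float)
    d = x.size
    steps = np.full(d, 0.1) if step0 is None else np.array(step0, dtype=float)
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("log posterior not finite at the initial point")
    kept = np.empty((settings.n_kept, d))
    ll_trace = np.empty(settings.n_kept)
    accepts = np.zeros(d)
    proposals = np.zeros(d)
    k = 0
    adapt_acc = np.zeros(d)
    adapt_n = np.zeros(d)
    for it in range(settings.n_samples):
        for j in range(d):
            prop = x.copy()
            prop[j] += steps[j] * rng.standard_normal()
            lp_prop = log_post(prop)
            proposals[j] += 1
            adapt_n[j] += 1
            if np.log(rng.random()) < lp_prop - lp:
                x = prop
                lp = lp_prop
                accepts[j] += 1
                adapt_acc[j] += 1
        if it < settings.burn and (it + 1) % 50 == 0:
            rate = adapt_acc / np.maximum(adapt_n, 1)
            steps *= np.exp((rate - TARGET_ACCEPT) * 1.0)
            adapt_acc[:] = 0
            adapt_n[:] = 0
        if it >= settings.burn and (it - settings.burn) % settings.thin == 0:
            kept[k] = x
            ll_trace[k] = log_like(x) if log_like is not None else lp
            k += 1
    return kept[:k], ll_trace[:k], accepts / np.maximum(proposals, 1)


def slice_sample_1d(
    log_f: Callable[[float], float],
    x0: float,
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
    lower: float = -np.inf,
    upper: float = np.inf,
) -> float:
    """Univariate slice sampler with stepping-out (Neal 2003)."""
    logy = log_f(x0) + np.log(rng.random())
    u = rng.random()
    left = max(x0 - u * w, lower)
    right = min(left + w, upper)
    for _ in range(max_steps):
        if left <= lower or log_f(left) < logy:
            break
        left = max(left - w, lower)
    for _ in range(max_steps):
        if right >= upper or log_f(right) < logy:
            break
        right = min(right + w, upper)
    for _ in range(100):
        x1 = left + rng.random() * (right - left)
        if log_f(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # degenerate shrinkage; keep the current point


def bridge_sampling_log_ml(
    draws: np.ndarray,
    log_post_unnorm: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    n_proposal: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> float:
    """Log marginal likelihood from posterior draws via bridge sampling.

    The proposal is a Gaussian moment-matched to the draws; the optimal
    bridge function is iterated to convergence (Meng & Wong 1996).
    """
    draws = np.atleast_2d(draws)
    n1, d = draws.shape
    n2 = n1 if n_proposal is None else n_proposal
    mu = draws.mean(axis=0)
    cov = np.cov(draws.T) if d > 1 else np.array([[draws.var(ddof=1)]])
    cov = np.atleast_2d(cov) + 1e-10 * np.eye(d)
    L = np.linalg.cholesky(cov)
    prop = mu + rng.standard_normal((n2, d)) @ L.T

    def log_q(x: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(x) - mu
        sol = np.linalg.solve(L, diff.T)
        return (
            -0.5 * d * np.log(2.0 * np.pi)
            - np.log(np.diag(L)).sum()
            - 0.5 * (sol**2).sum(axis=0)
        )

    lp_post_at_post = np.array([log_post_unnorm(x) for x in draws])
    lp_post_at_prop = np.array([log_post_unnorm(x) for x in prop])
    lq_at_post = log_q(draws)
    lq_at_prop = log_q(prop)

    # l1 = log p*(x)/q(x) at posterior draws; l2 at proposal draws
    l1 = lp_post_at_post - lq_at_post
    l2 = lp_post_at_prop - lq_at_prop
    l2 = l2[np.isfinite(l2)]
    if l2.size == 0:
        raise RuntimeError("no finite posterior density at proposal draws")
    lstar = np.median(l1)
    s1 = n1 / (n1 + l2.size)
    s2 = l2.size / (n1 + l2.size)
    log_r = 0.0  # current estimate of log ml minus lstar
    for _ in range(max_iter):
        num = np.exp(l2 - lstar) / (s1 * np.exp(l2 - lstar) + s2 * np.exp(log_r))
        den = 1.0 / (s1 * np.exp(l1 - lstar) + s2 * np.exp(log_r))
        log_r_new = np.log(num.mean()) - np.log(den.mean())
        if abs(log_r_new - log_r) < tol:
            log_r = log_r_new
            break
        log_r = log_r_new
    return float(log_r + lstar)
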