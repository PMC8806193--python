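"""Drift-diffusion decision process: simulation, closed forms, and likelihood.

The decision variable follows dx = (v + dc) dt + sigma dW from z_rel * a,
absorbed at a (upper) or 0 (lower); reaction time is non-decision time t_r
plus the first-passage time.  Three independent routes into the same
process are provided:

* an Euler-Maruyama simulator (`simulate_trial`, `simulate_trials_batch`);
* closed-form absorption probability and mean decision time for the
  two-barrier Wiener process (`choice_prob_closed_form`,
  `mean_decision_time_closed_form`);
* the first-passage-time density (`wfpt_density`) via the dual
  small-time/large-time series with automatic truncation, which serves as
  the likelihood kernel for model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DDMParams:
    """Decision-policy parameters.

    v : drift rate (evidence/s); a : boundary separation (evidence units);
    z_rel : relative start point z/a in (0, 1); t_r : non-decision time (s);
    sigma : diffusion coefficient (evidence/sqrt(s)); dc : drift criterion,
    an additive stimulus-independent drift offset (evidence/s).
    """

    v: float
    a: float
    z_rel: float = 0.5
    t_r: float = 0.26
    sigma: float = 0.1
    dc: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"boundary a must be > 0, got {self.a}")
        if not (0.0 < self.z_rel < 1.0):
            raise ValueError(f"z_rel must be in (0, 1), got {self.z_rel}")
        if self.t_r < 0:
            raise ValueError(f"t_r must be >= 0, got {self.t_r}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class PolicySurface:
    a_grid: np.ndarray
    v_grid: np.ndarray
    p_upper: np.ndarray  # (n_a, n_v)
    mean_decision_time: np.ndarray  # seconds, excluding t_r
    mean_rt: np.ndarray  # seconds, including t_r
    n_trials: int
    n_censored: np.ndarray


def choice_prob_closed_form(
    v: float | np.ndarray,
    a: float | np.ndarray,
    z_rel: float | np.ndarray = 0.5,
    sigma: float | np.ndarray = 0.1,
) -> float | np.ndarray:
    """P(absorption at the upper boundary) for the two-barrier Wiener process.

    P = (1 - exp(-2 v z / sigma^2)) / (1 - exp(-2 v a / sigma^2)), with the
    drift-free limit z_rel handled by series expansion.
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    z_rel_arr = np.asarray(z_rel, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    k = 2.0 * v * a / sigma**2  # dimensionless drift strength
    small = np.abs(k) < 1e-8
    k_safe = np.where(small, 1.0, k)
    with np.errstate(over="ignore"):
        p = np.expm1(-k_safe * z_rel_arr) / np.expm1(-k_safe)
    p = np.where(small, z_rel_arr, p)
    # extreme drift: expm1(-k) saturates; clamp to the correct limit
    p = np.where(k > 700, 1.0, np.where(k < -700, 0.0, p))
    if p.ndim == 0:
        return float(p)
    return p


def mean_decision_time_closed_form(
    v: float | np.ndarray,
    a: float | np.ndarray,
    sigma: float | np.ndarray = 0.1,
) -> float | np.ndarray:
    """Mean first-passage time for an unbiased start (z = a/2).

    E[T] = (a / 2v) * tanh(v a / (2 sigma^2)); the v -> 0 limit is
    a^2 / (4 sigma^2).
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    small = np.abs(v) < 1e-12
    v_safe = np.where(small, 1.0, v)
    t = (a / (2.0 * v_safe)) * np.tanh(v_safe * a / (2.0 * sigma**2))
    t = np.where(small, a**2 / (4.0 * sigma**2), t)
    if t.ndim == 0:
        return float(t)
    return t


def simulate_trial(
    params: DDMParams,
    dt: float = 1e-3,
    rng: np.random.Generator | None = None,
    max_time: float = 20.0,
) -> tuple[int, float, bool]:
    """One Euler-Maruyama trial.

    Returns ``(choice, rt, censored)`` with choice 1 for the upper boundary,
    0 for the lower, and rt = t_r + first-passage time in seconds.  If the
    walk is not absorbed within ``max_time`` of decision time, the trial is
    flagged censored (choice -1, rt nan).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    rng = np.random.default_rng() if rng is None else rng
    choice, dtime, censored = _simulate_batch(
        v=np.array([params.v + params.dc]),
        a=np.array([params.a]),
        z_rel=params.z_rel,
        sigma=params.sigma,
        dt=dt,
        max_time=max_time,
        rng=rng,
    )
    if censored[0]:
        return -1, float("nan"), True
    return int(choice[0]), float(params.t_r + dtime[0]), False


def simulate_trials_batch(
    params: DDMParams,
    n_trials: int,
    dt: float = 1e-3,
    rng: np.random.Generator | None = None,
    max_time: float = 20.0,
    v: np.ndarray | None = None,
    a: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate independent trials stepping in lockstep (fast path).

    ``v``/``a`` may be per-trial arrays (length ``n_trials``) overriding the
    scalars in ``params``; the drift criterion is always added on top.
    Returns ``(choices, rts, censored)``; censored entries have choice -1
    and rt nan.
    """
    rng = np.random.default_rng() if rng is None else rng
    v_eff = np.full(n_trials, params.v) if v is None else np.asarray(v, float)
    a_eff = np.full(n_trials, params.a) if a is None else np.asarray(a, float)
    choice, dtime, censored = _simulate_batch(
        v=v_eff + params.dc,
        a=a_eff,
        z_rel=params.z_rel,
        sigma=params.sigma,
        dt=dt,
        max_time=max_time,
        rng=rng,
    )
    rts = np.where(censored, np.nan, params.t_r + dtime)
    return choice, rts, censored


def _simulate_batch(
    v: np.ndarray,
    a: np.ndarray,
    z_rel: float,
    sigma: float,
    dt: float,
    max_time: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = v.size
    x = z_rel * a.copy()
    choice = np.full(n, -1, dtype=int)
    dtime = np.full(n, np.nan)
    active = np.arange(n)
    sqrt_dt = np.sqrt(dt)
    max_steps = int(np.ceil(max_time / dt))
    step = 0
    while active.size and step < max_steps:
        # block of steps sized to the expected remaining horizon
        block = min(256, max_steps - step)
        incr = v[active][:, None] * dt + sigma * sqrt_dt * rng.standard_normal(
            (active.size, block)
        )
        a_act = a[active][:, None]
        paths = x[active][:, None] + np.cumsum(incr, axis=1)
        prev = np.concatenate([x[active][:, None], paths[:, :-1]], axis=1)
        hit_up = paths >= a_act
        hit_lo = paths <= 0.0
        # Brownian-bridge correction: the walk may have crossed within a
        # step even if both endpoints lie inside; without it first-passage
        # probabilities carry an O(sqrt(dt)) bias.
        inside = ~hit_up & ~hit_lo
        with np.errstate(over="ignore", under="ignore"):
            p_bridge_up = np.exp(
                -2.0 * (a_act - prev) * (a_act - paths) / (sigma**2 * dt)
            )
            p_bridge_lo = np.exp(-2.0 * prev * paths / (sigma**2 * dt))
        u = rng.random(paths.shape)
        bridge_up = inside & (u < p_bridge_up)
        bridge_lo = inside & ~bridge_up & (u - p_bridge_up < p_bridge_lo)
        hit_up = hit_up | bridge_up
        hit_lo = hit_lo | bridge_lo
        hit_any = hit_up | hit_lo
        first = np.argmax(hit_any, axis=1)
        absorbed = hit_any[np.arange(active.size), first]
        idx = active[absorbed]
        fa = first[absorbed]
        choice[idx] = hit_up[np.flatnonzero(absorbed), fa].astype(int)
        dtime[idx] = (step + fa + 1) * dt
        x[active] = paths[:, -1]
        active = active[~absorbed]
        step += block
    censored = choice == -1
    return choice, dtime, censored


# ---------------------------------------------------------------------------
# First-passage-time density (dual-series expansion)
# ---------------------------------------------------------------------------


def _fpt_lower_standard(tt: np.ndarray, w: np.ndarray, err_tol: float) -> np.ndarray:
    """Density of the scaled (a=1, sigma=1, v=0) process at the lower bound.

    ``tt`` is normalised time t / a^2; the small-time and large-time series
    are selected per element by comparing their required term counts.
    """
    tt = np.maximum(tt, 1e-12)
    # terms needed for the large-time (Fourier) series
    with np.errstate(invalid="ignore", divide="ignore"):
        kl = np.sqrt(-2.0 * np.log(np.pi * tt * err_tol) / (np.pi**2 * tt))
    kl = np.where(np.pi * tt * err_tol < 1, np.maximum(kl, 1.0 / (np.pi * np.sqrt(tt))), 1.0 / (np.pi * np.sqrt(tt)))
    # terms needed for the small-time (image) series
    with np.errstate(invalid="ignore", divide="ignore"):
        ks = 2.0 + np.sqrt(-2.0 * tt * np.log(2.0 * err_tol * np.sqrt(2.0 * np.pi * tt)))
    ks = np.where(
        2.0 * err_tol * np.sqrt(2.0 * np.pi * tt) < 1,
        np.maximum(ks, np.sqrt(tt) + 1.0),
        2.0,
    )
    use_small = ks < kl
    out = np.empty_like(tt)

    if np.any(use_small):
        t_s = tt[use_small]
        w_s = w[use_small]
        K = int(np.ceil(ks[use_small].max() / 2.0)) + 1
        k_range = np.arange(-K, K + 1)
        terms = (w_s[:, None] + 2.0 * k_range[None, :]) * np.exp(
            -((w_s[:, None] + 2.0 * k_range[None, :]) ** 2) / (2.0 * t_s[:, None])
        )
        out[use_small] = terms.sum(axis=1) / np.sqrt(2.0 * np.pi * t_s**3)

    use_large = ~use_small
    if np.any(use_large):
        t_l = tt[use_large]
        w_l = w[use_large]
        K = int(np.ceil(kl[use_large].max()))
        k_range = np.arange(1, K + 1)
        terms = (
            k_range[None, :]
            * np.exp(-(k_range[None, :] ** 2) * np.pi**2 * t_l[:, None] / 2.0)
            * np.sin(k_range[None, :] * np.pi * w_l[:, None])
        )
        out[use_large] = np.pi * terms.sum(axis=1)
    return np.maximum(out, 0.0)


def wfpt_density(
    rt: float | np.ndarray,
    choice: int | np.ndarray,
    params: DDMParams,
    err_tol: float = 1e-6,
    v: np.ndarray | None = None,
    a: np.ndarray | None = None,
) -> float | np.ndarray:
    """First-passage density (1/s) at the chosen boundary, at total RT.

    choice 1 = upper boundary, 0 = lower.  RTs at or below t_r return 0.
    Per-trial drift/boundary arrays may override the scalars in ``params``
    (the likelihood path for trialwise regression models).
    """
    if err_tol <= 0:
        raise ValueError("err_tol must be > 0")
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    ch = np.broadcast_to(np.atleast_1d(np.asarray(choice, dtype=int)), rt_arr.shape)
    v_eff = np.broadcast_to(
        np.atleast_1d(params.v if v is None else np.asarray(v, float)), rt_arr.shape
    ).astype(float) + params.dc
    a_eff = np.broadcast_to(
        np.atleast_1d(params.a if a is None else np.asarray(a, float)), rt_arr.shape
    ).astype(float)

    t = rt_arr - params.t_r
    valid = t > 0
    out = np.zeros_like(rt_arr)
    if np.any(valid):
        # rescale to unit diffusion coefficient
        vv = v_eff[valid] / params.sigma
        aa = a_eff[valid] / params.sigma
        tv = t[valid]
        w = np.full(tv.shape, params.z_rel)
        upper = ch[valid] == 1
        # upper-boundary density via start-point reflection
        vv = np.where(upper, -vv, vv)
        w = np.where(upper, 1.0 - w, w)
        f0 = _fpt_lower_standard(tv / aa**2, w, err_tol)
        dens = (
            f0
            / aa**2
            * np.exp(-vv * aa * w - vv**2 * tv / 2.0)
        )
        out[valid] = dens
    if np.isscalar(rt) or np.ndim(rt) == 0:
        return float(out[0])
    return out


def wfpt_loglike(
    rt: np.ndarray,
    choice: np.ndarray,
    params: DDMParams,
    v: np.ndarray | None = None,
    a: np.ndarray | None = None,
    err_tol: float = 1e-7,
) -> float:
    """Summed log first-passage density; -inf if any observation is impossible.

    Dispatches to a jitted per-trial kernel (the series expansion is the
    same as `wfpt_density`, which remains the reference implementation).
    """
    from ._wfpt_fast import wfpt_loglike_fast

    rt_arr = np.ascontiguousarray(np.atleast_1d(rt), dtype=float)
    ch = np.ascontiguousarray(
        np.broadcast_to(np.atleast_1d(choice), rt_arr.shape), dtype=np.int64
    )
    v_eff = np.ascontiguousarray(
        np.broadcast_to(params.v if v is None else v, rt_arr.shape), dtype=float
    ) + params.dc
    a_eff = np.ascontiguousarray(
        np.broadcast_to(params.a if a is None else a, rt_arr.shape), dtype=float
    )
    t = (rt_arr - params.t_r)
    ll = wfpt_loglike_fast(
        t,
        ch,
        v_eff / params.sigma,
        a_eff / params.sigma,
        params.z_rel,
        err_tol,
    )
    return ll if ll > -1e299 else -np.inf


def policy_surface(
    a_grid: np.ndarray | None = None,
    v_grid: np.ndarray | None = None,
    n_trials: int = 1500,
    t_r: float = 0.26,
    sigma: float = 0.1,
    dt: float = 1e-3,
    rng: np.random.Generator | None = None,
) -> PolicySurface:
    """Choice probability and mean RT over an (a, v) grid, z = a/2.

    Grid defaults follow the published sweep: a in [0.05, 0.2] and v in
    [0, 0.3], both in 0.005 steps, 1500 trials per cell, t_r = 0.26 s.
    """
    if a_grid is None:
        a_grid = np.arange(0.05, 0.2 + 1e-9, 0.005)
    if v_grid is None:
        v_grid = np.arange(0.0, 0.3 + 1e-9, 0.005)
    a_grid = np.asarray(a_grid, float)
    v_grid = np.asarray(v_grid, float)
    rng = np.random.default_rng() if rng is None else rng
    shape = (a_grid.size, v_grid.size)
    p_upper = np.empty(shape)
    mean_dt = np.empty(shape)
    n_cens = np.zeros(shape, dtype=int)
    for i, a in enumerate(a_grid):
        for j, v in enumerate(v_grid):
            params = DDMParams(v=v, a=a, z_rel=0.5, t_r=t_r, sigma=sigma)
            choices, rts, censored = simulate_trials_batch(
                params, n_trials, dt=dt, rng=rng
            )
            ok = ~censored
            n_cens[i, j] = int(censored.sum())
            p_upper[i, j] = choices[ok].mean() if ok.any() else np.nan
            mean_dt[i, j] = (rts[ok] - t_r).mean() if ok.any() else np.nan
    return PolicySurface(
        a_grid=a_grid,
        v_grid=v_grid,
        p_upper=p_upper,
        mean_decision_time=mean_dt,
        mean_rt=mean_dt + t_r,
        n_trials=n_trials,
        n_censored=n_cens,
    )
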