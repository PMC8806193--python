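"""Decision-vector geometry: (a, v) trajectories as angles, circular models.

After z-scoring the trialwise boundary-height and drift-rate series, each
consecutive pair of (a, v) coordinates defines a step whose Euclidean norm
is the vector length and whose direction

    theta = atan2(dv, da)   (degrees in [0, 360), measured from the +a axis)

summarises how the decision policy moved.  A Bayesian projected-normal
circular regression models theta as a function of predictors (time
relative to a change point, condition, pupil components), and competing
models are scored by bridge-sampled marginal likelihoods, Bayes factors,
and posterior model probabilities under equal priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._mcmc import bridge_sampling_log_ml

COEF_PRIOR_SD = 10.0  # weakly informative Gaussian prior on PN coefficients


def zscore_trajectory(
    a_series: np.ndarray, v_series: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardise each series by its own mean/SD over the analysis window."""
    a = np.asarray(a_series, dtype=float)
    v = np.asarray(v_series, dtype=float)
    if a.size < 2 or v.size < 2:
        raise ValueError("need >= 2 trials to z-score a trajectory")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite values in trajectory")
    if a.std() == 0 or v.std() == 0:
        raise ValueError("zero-variance series cannot be z-scored")
    return (a - a.mean()) / a.std(), (v - v.mean()) / v.std()


def decision_angles(
    a_z: np.ndarray, v_z: np.ndarray
) -> pd.DataFrame:
    """Angles and lengths of consecutive steps through z-scored (a, v) space.

    Returns a frame with one row per transition: ``theta`` (degrees in
    [0, 360), NaN where the step has zero length), ``length``, and
    ``step`` (index of the transition's first trial).
    """
    a_z = np.asarray(a_z, dtype=float)
    v_z = np.asarray(v_z, dtype=float)
    da = np.diff(a_z)
    dv = np.diff(v_z)
    length = np.hypot(da, dv)
    theta = np.degrees(np.arctan2(dv, da)) % 360.0
    theta = np.where(theta >= 360.0, 0.0, theta)
    theta = np.where(length == 0.0, np.nan, theta)
    return pd.DataFrame(
        {"step": np.arange(da.size), "theta": theta, "length": length}
    )


def circular_mean(angles_deg: np.ndarray, tol: float = 1e-12) -> float:
    """Mean direction in degrees; NaN (with a warning) if the resultant vanishes."""
    ang = np.asarray(angles_deg, dtype=float)
    ang = ang[~np.isnan(ang)]
    if ang.size == 0:
        raise ValueError("no angles supplied")
    rad = np.radians(ang)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    if np.hypot(s, c) < tol:
        warnings.warn("resultant length ~0: circular mean undefined")
        return float("nan")
    deg = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return 0.0 if deg >= 360.0 else deg  # guard the -0.0 % 360 == 360.0 edge


def circular_distance(a_deg: float, b_deg: float) -> float:
    """Smallest absolute angular difference in degrees, in [0, 180]."""
    d = (a_deg - b_deg) % 360.0
    return float(min(d, 360.0 - d))


def peri_cp_transition_angles(
    a_z: np.ndarray,
    v_z: np.ndarray,
    cp_flags: np.ndarray,
    window: tuple[int, int] = (-1, 3),
) -> pd.DataFrame:
    """Pool transition angles by position relative to each change point.

    Transition ``dt_k`` (k >= 1) joins relative trials (window[0] + k - 1)
    and (window[0] + k); epochs shorter than the window contribute only
    their available positions.  Returns rows (cp_index, dt, theta, length).
    """
    cp_idx = np.flatnonzero(np.asarray(cp_flags, bool))
    n = len(a_z)
    rows = []
    for cp in cp_idx:
        for k in range(1, window[1] - window[0] + 1):
            i = cp + window[0] + k - 1
            j = i + 1
            if i < 0 or j >= n:
                continue
            da, dv = a_z[j] - a_z[i], v_z[j] - v_z[i]
            length = float(np.hypot(da, dv))
            theta = (
                float(np.degrees(np.arctan2(dv, da)) % 360.0)
                if length > 0
                else np.nan
            )
            rows.append((cp, k, theta, length))
    return pd.DataFrame(rows, columns=["cp_index", "dt", "theta", "length"])


# ---------------------------------------------------------------------------
# Projected-normal circular regression
# ---------------------------------------------------------------------------


def projected_normal_logpdf(theta_rad: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Log density of angles under PN2(mu, I).

    ``mu`` has shape (n, 2).  With u = (cos theta, sin theta) and
    t = u . mu:  f(theta) = (1/2pi) exp(-|mu|^2/2) [1 + t Phi(t)/phi(t)].
    """
    theta_rad = np.atleast_1d(theta_rad)
    u = np.stack([np.cos(theta_rad), np.sin(theta_rad)], axis=1)
    t = (u * mu).sum(axis=1)
    norm2 = (mu**2).sum(axis=1)
    # log(1 + t Phi(t)/phi(t)) computed stably for large |t|
    log_phi = stats.norm.logpdf(t)
    log_Phi = stats.norm.logcdf(t)
    ratio = np.exp(np.clip(log_Phi - log_phi, -np.inf, 700.0))
    inner = 1.0 + t * ratio
    inner = np.maximum(inner, 1e-300)
    return -np.log(2.0 * np.pi) - 0.5 * norm2 + np.log(inner)


@dataclass
class CircRegResult:
    """Posterior of a projected-normal circular regression."""

    predictor_names: list[str]
    draws_cos: np.ndarray  # (n_kept, p) coefficients of the cos component
    draws_sin: np.ndarray  # (n_kept, p)
    design: np.ndarray
    theta_deg: np.ndarray
    log_marginal_likelihood: float | None = None

    def fitted_direction(self, x: np.ndarray) -> np.ndarray:
        """Posterior draws of the mean direction (degrees) at covariate row x."""
        x = np.asarray(x, dtype=float)
        mc = self.draws_cos @ x
        ms = self.draws_sin @ x
        return np.degrees(np.arctan2(ms, mc)) % 360.0

    def mean_direction(self, x: np.ndarray) -> float:
        return circular_mean(self.fitted_direction(x))


_SQRT2PI = np.sqrt(2.0 * np.pi)


def _npdf(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / _SQRT2PI


def _sample_latent_lengths(
    m: np.ndarray, u01: np.ndarray, n_bisect: int = 40
) -> np.ndarray:
    """Draw r ~ p(r) propto r * phi(r - m) on r > 0, by inverse CDF.

    Closed-form CDF: C(r) = [phi(m) - phi(r-m) + m (Phi(r-m) - Phi(-m))] / Z
    with Z = phi(m) + m Phi(m); inverted by vectorised bisection.
    """
    from scipy.special import ndtr

    pdf_m = _npdf(m)
    cdf_neg_m = ndtr(-m)
    Z = pdf_m + m * (1.0 - cdf_neg_m)
    target = u01 * Z
    lo = np.zeros_like(m)
    hi = np.maximum(m, 0.0) + 10.0
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        c = pdf_m - _npdf(mid - m) + m * (ndtr(mid - m) - cdf_neg_m)
        below = c < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def circ_regress(
    theta_deg: np.ndarray,
    design: np.ndarray,
    predictor_names: list[str] | None = None,
    n_samples: int = 10000,
    burn: int = 1000,
    rng: np.random.Generator | None = None,
    compute_ml: bool = False,
) -> CircRegResult:
    """Bayesian projected-normal circular regression by Gibbs sampling.

    The latent representation y_i = r_i (cos theta_i, sin theta_i) with
    y_i ~ N2(B' x_i, I) admits conjugate coefficient updates and a
    closed-form inverse-CDF draw for the latent lengths r_i.  Coefficients
    carry N(0, COEF_PRIOR_SD^2) priors.
    """
    theta_deg = np.asarray(theta_deg, dtype=float)
    ok = ~np.isnan(theta_deg)
    theta = np.radians(theta_deg[ok])
    X = np.atleast_2d(np.asarray(design, dtype=float))[ok]
    n, p = X.shape
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        # name the offending columns for the caller
        _, R = np.linalg.qr(X)
        bad = [predictor_names[j] for j in range(p) if abs(R[j, j]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    rng = np.random.default_rng() if rng is None else rng

    u = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    XtX = X.T @ X
    prec_prior = np.eye(p) / COEF_PRIOR_SD**2
    post_prec = XtX + prec_prior
    post_cov = np.linalg.inv(post_prec)
    L = np.linalg.cholesky(post_cov)

    B = np.zeros((p, 2))
    r = np.ones(n)
    kept_c = np.empty((n_samples, p))
    kept_s = np.empty((n_samples, p))
    for it in range(burn + n_samples):
        mu = X @ B
        m = (u * mu).sum(axis=1)
        r = _sample_latent_lengths(m, rng.random(n))
        y = r[:, None] * u
        mean_B = post_cov @ (X.T @ y)
        B = mean_B + L @ rng.standard_normal((p, 2))
        if it >= burn:
            kept_c[it - burn] = B[:, 0]
            kept_s[it - burn] = B[:, 1]

    result = CircRegResult(
        predictor_names=predictor_names,
        draws_cos=kept_c,
        draws_sin=kept_s,
        design=X,
        theta_deg=np.degrees(theta) % 360.0,
    )
    if compute_ml:
        result.log_marginal_likelihood = _log_ml(result, rng)
    return result


def _log_ml(result: CircRegResult, rng: np.random.Generator) -> float:
    X = result.design
    theta = np.radians(result.theta_deg)
    p = X.shape[1]

    def log_post(flat: np.ndarray) -> float:
        B = flat.reshape(p, 2)
        mu = X @ B
        ll = projected_normal_logpdf(theta, mu).sum()
        lp = stats.norm.logpdf(flat, 0.0, COEF_PRIOR_SD).sum()
        return float(ll + lp)

    draws = np.concatenate([result.draws_cos, result.draws_sin], axis=1)
    # thin for the bridge estimator; a few hundred draws suffice
    step = max(1, draws.shape[0] // 500)
    flat = np.concatenate(
        [
            result.draws_cos[::step],
            result.draws_sin[::step],
        ],
        axis=1,
    )
    # reorder columns to reshape(p, 2) layout: (c0, s0, c1, s1, ...)
    idx = np.ravel([[j, j + p] for j in range(p)])
    flat = flat[:, idx]
    return bridge_sampling_log_ml(flat, log_post, rng)


@dataclass
class ModelComparison:
    names: list[str]
    log_ml: dict[str, float]
    bf01: pd.DataFrame  # BF of row model over column model
    posterior_prob: dict[str, float]


def compare_models(
    theta_deg: np.ndarray,
    designs: dict[str, tuple[np.ndarray, list[str]]],
    n_samples: int = 4000,
    burn: int = 500,
    rng: np.random.Generator | None = None,
) -> ModelComparison:
    """Fit competing circular-regression models and compare their evidence.

    ``designs`` maps model name -> (design matrix, predictor names).
    Marginal likelihoods come from bridge sampling; BF01[i, j] is the
    evidence ratio of model i over model j, and posterior model
    probabilities assume equal priors.
    """
    if len(designs) < 2:
        raise ValueError("need >= 2 models to compare")
    rng = np.random.default_rng() if rng is None else rng
    log_ml: dict[str, float] = {}
    for name, (X, pred_names) in designs.items():
        fit = circ_regress(
            theta_deg,
            X,
            pred_names,
            n_samples=n_samples,
            burn=burn,
            rng=rng,
            compute_ml=True,
        )
        log_ml[name] = float(fit.log_marginal_likelihood)
    names = list(designs)
    bf = pd.DataFrame(
        {
            cj: {ci: np.exp(log_ml[ci] - log_ml[cj]) for ci in names}
            for cj in names
        }
    )
    lml = np.array([log_ml[n] for n in names])
    w = np.exp(lml - lml.max())
    w /= w.sum()
    return ModelComparison(
        names=names,
        log_ml=log_ml,
        bf01=bf,
        posterior_prob=dict(zip(names, w)),
    )
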