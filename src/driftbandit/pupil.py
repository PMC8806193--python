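"""Task-evoked pupillometry: preprocessing, features, PCA, synthetic traces.

Raw traces are 1000 Hz diameter samples with blink flags and trial onsets.
Per trial the pipeline segments a window from 500 ms before onset to the
end of the 1500 ms trial, linearly interpolates blink/invalid/outlier
samples, zero-phase bandpass filters (0.01-5 Hz, second-order Butterworth),
subtracts the pre-stimulus 500 ms median baseline, and z-scores by session.
Each processed window is then summarised by the evoked-response metrics
(mean, onset/offset/peak latencies, peak amplitude, area under the curve)
which feed a PCA with bootstrapped feature importances.

The synthetic generator builds traces from a known pupillary impulse
response (Hoeks & Levelt gamma family) plus pink noise and blink artifacts,
with truncated-exponential inter-trial intervals, and emits the planted
per-trial ground truth so the pipeline's recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import PCA

FS = 1000  # Hz, fixed sampling rate
PRE_MS = 500
TRIAL_MS = 1500
WINDOW_MS = PRE_MS + TRIAL_MS

FEATURE_NAMES = [
    "mean_diameter",
    "peak_onset_latency",
    "peak_offset_latency",
    "peak_latency",
    "peak_amplitude",
    "auc",
]


@dataclass
class RawPupilTrace:
    samples: np.ndarray  # diameter, arbitrary units, 1000 Hz
    blink_flags: np.ndarray
    trial_onsets: np.ndarray  # sample indices
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.blink_flags = np.asarray(self.blink_flags, dtype=bool)
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=int)
        if self.samples.shape != self.blink_flags.shape:
            raise ValueError("samples and blink_flags must align")
        if np.any(np.diff(self.trial_onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")


def segment_trials(
    trace: RawPupilTrace, margin_ms: int = 0
) -> tuple[list[np.ndarray], list[np.ndarray], list[int]]:
    """Cut (-500 ms, +1500 ms) windows around each onset.

    ``margin_ms`` adds real data on both sides (used to absorb the
    zero-phase filter's edge transients; trimmed after filtering).
    Returns (windows, blink windows, kept trial indices); trials whose
    window would exceed the trace are dropped.
    """
    windows, blinks, kept = [], [], []
    n = len(trace.samples)
    for i, onset in enumerate(trace.trial_onsets):
        lo = onset - PRE_MS - margin_ms
        hi = onset + TRIAL_MS + margin_ms
        if lo < 0 or hi > n:
            continue
        windows.append(trace.samples[lo:hi].copy())
        blinks.append(trace.blink_flags[lo:hi].copy())
        kept.append(i)
    return windows, blinks, kept


def clean_trace(
    window: np.ndarray,
    blink_flags: np.ndarray | None = None,
    session_mean: float | None = None,
    session_sd: float | None = None,
) -> np.ndarray | None:
    """Interpolate invalid samples: blinks/non-positive first, then 3-SD outliers.

    Outliers are judged against session-level statistics when given (else
    the window's own).  Invalid runs at the edges are extended from the
    nearest valid sample.  Returns None (trial dropped) if nothing valid.
    """
    w = np.asarray(window, dtype=float).copy()
    bad = ~np.isfinite(w) | (w <= 0.0)
    if blink_flags is not None:
        bad |= np.asarray(blink_flags, bool)
    w = _interpolate(w, bad)
    if w is None:
        return None
    mu = float(w.mean()) if session_mean is None else session_mean
    sd = float(w.std()) if session_sd is None else session_sd
    if sd > 0:
        outlier = np.abs(w - mu) > 3.0 * sd
        w = _interpolate(w, outlier)
    return w


def _interpolate(w: np.ndarray, bad: np.ndarray) -> np.ndarray | None:
    if not bad.any():
        return w
    good = np.flatnonzero(~bad)
    if good.size == 0:
        return None
    idx = np.arange(w.size)
    w[bad] = np.interp(idx[bad], good, w[good])
    return w


def bandpass_filter(window: np.ndarray, margin_ms: int = 0) -> np.ndarray:
    """Zero-phase 0.01-5 Hz second-order Butterworth; trims ``margin_ms``.

    The band edges are applied as a high-pass/low-pass cascade: the 0.01 Hz
    pole's time constant dwarfs a trial window, and the cascade keeps the
    edge transients confined to the (discarded) margin.
    """
    sos_lo = signal.butter(2, 5.0, btype="low", fs=FS, output="sos")
    sos_hi = signal.butter(2, 0.01, btype="high", fs=FS, output="sos")
    y = signal.sosfiltfilt(sos_lo, window)
    # drop half the margin between stages: the low-pass edge transient
    # would otherwise bias the high-pass stage's slow-trend estimate
    m1 = margin_ms // 2
    if m1 > 0:
        y = y[m1:-m1]
    y = signal.sosfiltfilt(sos_hi, y)
    m2 = margin_ms - m1
    if m2 > 0:
        y = y[m2:-m2]
    return y


def filter_baseline_zscore(
    windows: list[np.ndarray], margin_ms: int = 0
) -> tuple[list[np.ndarray], bool]:
    """Filter, subtract the pre-stimulus median, z-score by session.

    Returns (processed windows, z-scored flag); with fewer than two trials
    the z-scoring step is skipped and flagged.
    """
    based = []
    for w in windows:
        f = bandpass_filter(w, margin_ms=margin_ms)
        baseline = np.median(f[:PRE_MS])
        based.append(f - baseline)
    if len(based) < 2:
        return based, False
    pooled = np.concatenate(based)
    mu, sd = pooled.mean(), pooled.std()
    if sd == 0:
        return based, False
    return [(w - mu) / sd for w in based], True


def extract_features(
    window: np.ndarray, onset_frac: float = 0.1
) -> dict[str, float]:
    """Evoked-response metrics of one processed window.

    Peak = maximum after stimulus onset; onset/offset latencies are the
    first/last crossings of ``onset_frac`` * peak amplitude around the
    peak; AUC is the trapezoidal area of the post-onset response.  All
    latencies in ms post-onset.  A flat window yields zero amplitude and
    NaN latencies.
    """
    w = np.asarray(window, dtype=float)
    post = w[PRE_MS:]
    mean_d = float(w.mean())
    peak_i = int(np.argmax(post))
    amp = float(post[peak_i])
    auc = float(np.trapezoid(post, dx=1.0))
    if amp <= 0 or np.allclose(post, post[0]):
        return {
            "mean_diameter": mean_d,
            "peak_onset_latency": np.nan,
            "peak_offset_latency": np.nan,
            "peak_latency": np.nan,
            "peak_amplitude": 0.0,
            "auc": auc,
        }
    thresh = onset_frac * amp
    above = post >= thresh
    # first crossing at or before the peak
    below_before = np.flatnonzero(~above[: peak_i + 1])
    onset_lat = float(below_before[-1] + 1) if below_before.size else 0.0
    below_after = np.flatnonzero(~above[peak_i:])
    offset_lat = (
        float(peak_i + below_after[0] - 1)
        if below_after.size
        else float(post.size - 1)
    )
    return {
        "mean_diameter": mean_d,
        "peak_onset_latency": onset_lat,
        "peak_offset_latency": offset_lat,
        "peak_latency": float(peak_i),
        "peak_amplitude": amp,
        "auc": auc,
    }


def process_session(
    trace: RawPupilTrace, zscore: bool = True, return_windows: bool = False
):
    """Full per-session pipeline: segment, clean, filter, z-score, featurise.

    With ``zscore=False`` the session z-scoring is skipped, leaving features
    in raw diameter units (useful for absolute recovery checks); z-scoring
    is an affine map so latencies are unaffected either way.
    """
    margin = 500
    windows, blinks, kept = segment_trials(trace, margin_ms=margin)
    # session-level outlier statistics from the blink-interpolated trace
    full = trace.samples.copy()
    bad = ~np.isfinite(full) | (full <= 0) | trace.blink_flags
    full = _interpolate(full, bad)
    if full is None:
        raise ValueError("session trace has no valid samples")
    mu, sd = float(full.mean()), float(full.std())
    cleaned, kept2 = [], []
    for w, b, i in zip(windows, blinks, kept):
        c = clean_trace(w, b, session_mean=mu, session_sd=sd)
        if c is not None:
            cleaned.append(c)
            kept2.append(i)
    if zscore:
        processed, _ = filter_baseline_zscore(cleaned, margin_ms=margin)
    else:
        processed = []
        for w in cleaned:
            f = bandpass_filter(w, margin_ms=margin)
            processed.append(f - np.median(f[:PRE_MS]))
    rows = [extract_features(w) for w in processed]
    out = pd.DataFrame(rows)
    out.insert(0, "trial", kept2)
    out.insert(0, "session", trace.session_id)
    if return_windows:
        return out, processed
    return out


@dataclass
class PupilPCAResult:
    loadings: pd.DataFrame  # components x features
    explained_variance_ratio: np.ndarray
    n_retained: int
    feature_importance: pd.DataFrame  # mean |loading| with bootstrap CI
    scores: np.ndarray  # trials x retained components
    dropped_features: list[str]


def pca_features(
    features: pd.DataFrame,
    variance_threshold: float = 0.95,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> PupilPCAResult:
    """PCA of standardized evoked-response metrics.

    Components are retained up to the minimal set explaining
    ``variance_threshold`` of the variance; feature importance is the
    absolute loading on each retained component, with bootstrap CIs over
    trials.  Constant feature columns are dropped (flagged in the result).
    """
    rng = np.random.default_rng() if rng is None else rng
    cols = [c for c in features.columns if c in FEATURE_NAMES or features[c].dtype.kind == "f"]
    cols = [c for c in cols if c not in ("trial",)]
    X = features[cols].to_numpy(dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 complete trials and >= 2 features")
    keep = X.std(axis=0) > 0
    dropped = [c for c, k in zip(cols, keep) if not k]
    cols = [c for c, k in zip(cols, keep) if k]
    X = X[:, keep]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)

    pca = PCA()
    scores = pca.fit_transform(Xs)
    evr = pca.explained_variance_ratio_
    n_retained = int(np.searchsorted(np.cumsum(evr), variance_threshold) + 1)
    n_retained = min(n_retained, len(evr))

    boot_loadings = np.empty((n_boot, n_retained, len(cols)))
    n = Xs.shape[0]
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        Xb = Xs[idx]
        Xb = Xb - Xb.mean(axis=0)
        pb = PCA(n_components=n_retained).fit(Xb)
        comp = pb.components_
        # align bootstrap component signs/order to the full-sample solution
        ref = pca.components_[:n_retained]
        for k in range(n_retained):
            if np.dot(comp[k], ref[k]) < 0:
                comp[k] = -comp[k]
        boot_loadings[b] = np.abs(comp)
    imp_rows = []
    for k in range(n_retained):
        for j, c in enumerate(cols):
            lo, hi = np.percentile(boot_loadings[:, k, j], [2.5, 97.5])
            imp_rows.append(
                {
                    "component": k + 1,
                    "feature": c,
                    "importance": float(np.abs(pca.components_[k, j])),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return PupilPCAResult(
        loadings=pd.DataFrame(
            pca.components_[:n_retained], columns=cols,
            index=[f"PC{k + 1}" for k in range(n_retained)],
        ),
        explained_variance_ratio=evr,
        n_retained=n_retained,
        feature_importance=pd.DataFrame(imp_rows),
        scores=scores[:, :n_retained],
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# Synthetic traces
# ---------------------------------------------------------------------------


def pupil_impulse_response(
    t_ms: np.ndarray, t_max_ms: float = 900.0, shape: float = 10.1
) -> np.ndarray:
    """Gamma-family pupillary impulse response, unit peak at ``t_max_ms``."""
    t = np.maximum(np.asarray(t_ms, dtype=float), 0.0)
    h = (t / t_max_ms) ** shape * np.exp(shape * (1.0 - t / t_max_ms))
    return h


@dataclass
class SynthPupilDesign:
    """Per-trial planted effects and session-level noise settings."""

    n_trials: int = 20
    amplitudes: np.ndarray | None = None  # per-trial pulse amplitude (a.u.)
    peak_latencies_ms: np.ndarray | None = None  # per-trial pulse peak time
    baseline: float = 1000.0
    mains_hz: float = 60.0  # display/mains artifact frequency
    mains_amplitude: float = 2.0  # deterministic ripple, removed by the 5 Hz lowpass
    noise_sd: float = 0.0  # pink-noise SD in raw units
    blink_rate: float = 0.0  # expected blinks per second
    blink_dur_ms: tuple[int, int] = (50, 150)
    iti_rate: float = 2.0  # 1/s, truncated exponential
    iti_bounds_s: tuple[float, float] = (4.0, 16.0)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximate 1/f noise via spectral shaping, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / FS)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    pink = np.fft.irfft(spec, n)
    return pink / pink.std()


def synth_pupil_session(
    design: SynthPupilDesign, rng: np.random.Generator | None = None
) -> tuple[RawPupilTrace, pd.DataFrame]:
    """Build a raw trace with known per-trial pulses; returns ground truth too.

    Trial onsets are spaced by truncated-exponential ITIs (4-16 s, rate 2);
    each trial contributes one impulse-response pulse with its planted
    amplitude and peak latency, on a constant baseline plus pink noise,
    with blink artifacts inserted as zero runs.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_trials = design.n_trials
    amps = (
        np.full(n_trials, 1.2)
        if design.amplitudes is None
        else np.asarray(design.amplitudes, float)
    )
    lats = (
        np.full(n_trials, 900.0)
        if design.peak_latencies_ms is None
        else np.asarray(design.peak_latencies_ms, float)
    )
    lo, hi = design.iti_bounds_s
    itis = lo + rng.exponential(1.0 / design.iti_rate, size=n_trials)
    itis = np.minimum(itis, hi)
    onsets = (np.cumsum(itis) * FS).astype(int)
    total = int(onsets[-1] + TRIAL_MS + 2 * FS)

    trace = np.full(total, design.baseline)
    if design.mains_amplitude > 0:
        # high-frequency display/mains ripple: present in any real recording,
        # fully outside the 0.01-5 Hz analysis band
        trace = trace + design.mains_amplitude * np.sin(
            2.0 * np.pi * design.mains_hz * np.arange(total) / FS
        )
    for onset, amp, lat in zip(onsets, amps, lats):
        t_ms = np.arange(0, 3000)
        pulse = amp * pupil_impulse_response(t_ms, t_max_ms=lat)
        end = min(onset + 3000, total)
        trace[onset:end] += pulse[: end - onset]
    if design.noise_sd > 0:
        trace = trace + design.noise_sd * _pink_noise(total, rng)

    blink_flags = np.zeros(total, dtype=bool)
    if design.blink_rate > 0:
        n_blinks = rng.poisson(design.blink_rate * total / FS)
        for _ in range(n_blinks):
            start = int(rng.integers(0, total - design.blink_dur_ms[1]))
            dur = int(rng.integers(*design.blink_dur_ms))
            trace[start : start + dur] = 0.0
            blink_flags[start : start + dur] = True

    truth = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "amplitude": amps,
            "peak_latency_ms": lats,
            "onset_sample": onsets,
        }
    )
    return (
        RawPupilTrace(
            samples=trace, blink_flags=blink_flags, trial_onsets=onsets
        ),
        truth,
    )
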