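# Methods

This note documents the models implemented in `driftbandit`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Task environment

Sessions are dynamic two-armed bandits. Epoch lengths (trials between
switches of the optimal target) are Poisson(λ); draws of zero are
resampled to ≥ 1 because a zero-length epoch leaves "switch" undefined,
and the final epoch is truncated so lengths sum exactly to the session
length. The first trial is never a change point. The optimal target pays
reward with probability P ∈ (0.5, 1], the other with 1 − P; the two
targets' outcomes are drawn independently per trial (only the chosen
target's outcome is ever revealed). Reward magnitudes are integerised
draws from Normal(μ = 3, σ = 1) points, rounded half away from zero and
floored at 0 — the integer conversion is not specified beyond
"converted to an integer", so round-half-away-from-zero was fixed once.
Conflict is 1 − |2P − 1| (how close the arms are); volatility is 1/λ.

Reaction-time bounds are carried as task metadata. For simulated agents,
out-of-bounds RTs are redrawn rather than repeated-with-penalty; the human
penalty scheme (point loss, trial repetition) is out of scope.

## Q-learning sweep

A tabular agent with softmax policy π ∝ exp(βQ) and delta rule
Q ← Q + α(r − Q), binary reward. α is held at 0.1 (a standard tabular
value; the sweep's conclusions are about β) and Q is initialised at the
pooled expectation 0.5. The sweep runs 500-trial sessions, 200 iterations
per (P, λ, β) cell, β on an even grid over [0.1, 3]; the return-maximising
β per cell is reported with ties resolved to the smaller (more
exploratory) β. The batched implementation runs all iterations of a cell
in lockstep, which is why the full sweep is cheap.

## Drift-diffusion core

The decision variable follows dx = (v + dc) dt + σ dW from z = z_rel · a,
absorbed at {0, a}; RT = t_r + first-passage time. σ is never implicit:
the policy-surface replication uses σ = 0.1 (the classic scaling that
matches boundaries in [0.05, 0.2]), while model fitting uses the σ = 1
convention, with parameters quoted on whichever scale is in use.

The Euler–Maruyama simulator (dt = 1 ms) applies a Brownian-bridge
crossing correction on every step: without it, first-passage probabilities
carry an O(√dt) bias that is visible at 10⁴–10⁵ trials (the simulator is
held to within 3 Monte-Carlo SEs of the closed-form absorption probability
and to KS distance < 0.01 against the analytic RT density at 10⁵ draws).
Walks not absorbed within 20 s are flagged censored and excluded from
summaries, never silently dropped.

Closed forms used as oracles: absorption probability
(1 − e^{−2vz/σ²})/(1 − e^{−2va/σ²}) with series handling of v → 0, and
the unbiased-start mean first-passage time (a/2v)·tanh(va/2σ²).

The first-passage density uses the standard dual small-time/large-time
series with per-observation truncation chosen from the error tolerance
(default 10⁻⁶/10⁻⁷), upper-boundary densities via start-point reflection.
Two implementations exist deliberately: a vectorised numpy reference
(`ddm.wfpt_density`) and a jitted per-trial kernel used inside MCMC
(`_wfpt_fast`); the test suite holds them equal to ~10⁻⁹.

## Ideal observer

The reduced change-point observer tracks per-target reward beliefs B.
Within a trial the update order is: prediction error δ = r − B_c; then
change-point probability Ω as the likelihood ratio of a uniform outcome
density times the hazard H against the Gaussian predictive density
N(r | B_c, σ_t²); then learning rate α = Ω + (1 − Ω)(1 − φ); then the
belief updates (chosen: B += αδ; unchosen: shrunk toward the pooled
expectation by Ω); then relative uncertainty
RU = N/(N + σ_n²) with N = Ωσ_n² + (1−Ω)(1−φ)σ_n² + Ω(1−Ω)(δφ)²,
confidence φ' = 1 − RU, and predictive variance
σ_t²' = σ_n² + (1−φ')σ_n²/φ'. Each quantity uses pre-update values of its
inputs; this ordering is the one consistent with the reduced-observer
lineage the model descends from.

Open-choice defaults: uniform support [0, 6] points (μ ± 3σ of the point
distribution, floored at 0); beliefs initialised at the pooled expected
reward with φ = 0.5 (maximal uncertainty, unbiased start); unrewarded
trials feed r = 0 (the task displays "0 points" as explicit feedback);
H defaults to the generative 1/λ when the design is known, otherwise the
empirical change-point rate. If confidence collapses to zero the
predictive variance is capped at a large finite ceiling and flagged.
Degenerate likelihood (outcome outside the uniform support) is handled by
clamping the outcome onto the support.

The emitted per-trial series reports the state *entering* each trial
(beliefs and the Ω produced by the previous outcome): these are the
quantities available to drive that trial's decision. ΔB is optimal-coded
(B_optimal − B_suboptimal given the current true optimal), which is why it
flips sign at a change point before the observer has seen any evidence.

## Linking model and fitting

The linking model is the regression form v_t = v0 + β_v·ΔB_t,
a_t = a0 + β_a·Ω_t. A literal cumulative drift update
(v_{t+1} = v_t + β_v ΔB_t) is available behind `cumulative_v=True` but is
not the default: the boundary equation has an explicit intercept and the
fitting procedure is a regression, so the regression reading is used
throughout. Trialwise boundaries are clamped at 0.01 with a flag.

The generative simulator closes the loop per trial: observer state →
(v_t, a_t) → accuracy-coded diffusion trial (upper boundary = optimal
choice) → choice and reward feed the observer. For recovery studies the
simulator is run with wide RT bounds so the likelihood (which carries no
truncation term) is correctly specified for the data it sees; narrow human
RT windows would otherwise bias t_r and boundary estimates through
unmodelled censoring. The closed-loop simulator also uses a finer Euler
step (0.25 ms) than the standalone simulator's 1 ms: its output feeds
likelihood-based fits at thousands of trials, a regime sharp enough to
resolve the residual O(dt) bias of the coarser step and displace recovered
coefficients by more than a credible-interval width.

Fitting is coordinate-wise random-walk Metropolis with Robbins–Monro step
adaptation during burn-in (target acceptance 0.44), on the Wiener
first-passage log-likelihood at σ = 1. Priors are weakly informative:
v0 ~ N(0, 2²); a0 ~ N(1, 1²) truncated above 0.05; t_r ~ U(0.05, 0.5);
z_rel ~ Beta(2, 2); dc, β_v, β_a ~ N(0, 1²). Reference sampler settings
are 20 000 draws, 5 000 burned, thinning 5; the test suite uses reduced
settings (≈2 000 post-burn draws) which are ample for these posteriors.
The model ladder (I: ΔB→v, Ω→a; II crossed; III/IV single drift maps;
V/VI single boundary maps; VII intercept-only) is compared by
DIC = D̄ + p_D with p_D = D̄ − D(θ̄); negative p_D is flagged.

Peri-change-point trialwise fits pool trials by position relative to the
change point (window −1..+3 by default); one decision parameter varies by
position while the others are shared across positions (the sharing choice
is a default, not a claim about the original analysis). Change sensitivity
uses the overlap coefficient ∫min(p̂_a, p̂_b) of adjacent-position
posteriors, computed with Gaussian KDEs (Silverman bandwidth) on a common
512-point grid spanning the pooled 0.1–99.9 percentile range — a
deterministic function of the samples — with < 5% overlap read as a
change-point-sensitive parameter.

## Decision geometry

Boundary and drift series are z-scored over the analysis window; each
consecutive (a, v) pair gives a step of length √(Δa² + Δv²) and angle
θ = atan2(Δv, Δa), degrees in [0, 360), measured from the +a axis toward
+v. The arctangent convention is not dictated by anything upstream, so
absolute angles are convention-dependent and treated as qualitative;
zero-length steps yield missing angles rather than an arbitrary 0°.
Epochs shorter than the peri-change-point window contribute the positions
they have.

Circular regression uses the projected-normal likelihood: the angle is the
direction of a latent bivariate normal y ~ N₂(B'x, I). A Gibbs sampler
alternates closed-form inverse-CDF draws of the latent vector lengths
(density ∝ r·φ(r − m), inverted by vectorised bisection) with conjugate
Gaussian updates of the coefficients (prior N(0, 10²) per component).
A von Mises density is available for cross-checks. Marginal likelihoods
come from iterative bridge sampling with a moment-matched Gaussian
proposal; Bayes factors and posterior model probabilities assume equal
model priors, and the null-versus-evoked gate is evaluated before
condition/pupil-augmented models, mirroring the sequential logic of the
analysis it reproduces.

## Pupillometry

Windows span −500 ms to +1500 ms around trial onset at 1000 Hz. Cleaning
interpolates blink-flagged and non-positive samples first, then samples
beyond 3 SD of the session mean (statistics from the blink-interpolated
full trace); edge-invalid runs extend from the nearest valid sample. The
0.01–5 Hz second-order Butterworth bandpass is applied zero-phase as a
low-pass/high-pass cascade on windows segmented with an extra 500 ms
margin of real data; half the margin is dropped between the stages and
half after, because the 0.01 Hz pole's time constant (~16 s) dwarfs a 2 s
window and its edge transient would otherwise bias the slow-trend
estimate across the whole trial. Baseline is the pre-stimulus 500 ms
median; z-scoring is per session (skipped and flagged with < 2 trials).

Features per trial: window mean, peak amplitude (post-onset maximum),
peak latency, onset/offset latencies at 10%-of-peak crossings around the
peak (the threshold is configurable; the operational definition is not
fixed by the source analysis), and trapezoidal AUC of the post-onset
baseline-subtracted response. Six metrics are implemented as the default
set; the advertised seventh cannot be identified from the text and is left
as a configurable extra rather than guessed. PCA standardises features,
retains the minimal set of components reaching the 95% variance threshold,
and reports absolute loadings as importances with bootstrap CIs over
trials (bootstrap components sign-aligned to the full-sample solution).

The synthetic generator emulates: impulse-response pulses (gamma family,
unit peak, default peak 900 ms), constant baseline, optional pink noise,
blink artifacts as zero runs, a deterministic high-frequency display/mains
ripple (60 Hz, amplitude 2 by default — present in any real recording and
entirely outside the analysis band, it gives the session realistic raw
variance so the 3-SD outlier rule targets artifacts rather than genuine
evoked peaks), and truncated-exponential inter-trial intervals
(min 4 s, max 16 s, rate 2/s). It does not emulate gaze-dependent
foreshortening, luminance responses, tonic arousal drift within the
analysis band, or overlap of successive evoked responses; pipeline
recovery on these traces therefore bounds measurement error of the
pipeline itself, not biological variability.

## Problem sizes in the test suite

The acceptance-level tests run the study-scale designs where they are
cheap (24 × 600-trial sessions; 5 × 5 policy subgrid at 2000 trials/cell;
200 iterations/cell for the exploration gradient) and scaled-down sampler
settings where they are not: linking-model recovery uses 20 replicates of
3600-trial subjects with ~2000 post-burn draws, and the DIC ladder
re-enactment uses 1200-trial sessions. These sizes were chosen once as
adequate for the statistical claims being checked.

## Known limitations

* The Metropolis sampler is adequate for the ≤ 8-parameter posteriors
  fitted here but has no gradient information; strongly correlated or
  hierarchical posteriors would need longer chains.
* The group-level (hierarchical) fit is per-subject by default; a shared
  hyperprior layer is a natural extension but not implemented.
* DIC is reported because it is the ladder's historical criterion; it is
  known to under-penalise complexity in some regimes (the pure-noise
  regressor check in the tests guards the cases used here).
* Bridge-sampling estimates carry Monte-Carlo error; comparisons within
  ~1 nat should not be over-read.
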