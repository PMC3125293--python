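# Methods

`updown` segments continuous cortical signals — local field potential (LFP),
EEG, or intracellular membrane potential (MP) — into the alternating UP
(depolarized, active) and DOWN (hyperpolarized, quiescent) states of
slow-wave sleep and anesthesia. This note documents the model, the
inference machinery, the defaults and the reasoning behind the choices that
were genuinely open.

## Signal features

UDS inference operates not on the raw trace but on a derived *observation
sequence* at a reduced rate (default 50 Hz):

- **LF amplitude** — the 0.05–2 Hz band-passed signal, z-scored. Under
  clear UDS its distribution is bimodal, and it is the default (and, on the
  kinds of data this method targets, most separable) feature.
- **HF power** — the 20–80 Hz band-passed signal, squared, smoothed with a
  Gaussian kernel (σ = 150 ms), log-transformed with a floor (10⁻³ of the
  median power, so silent stretches stay finite), and z-scored.

Filters are zero-phase (forward–backward) Butterworth — order 2 for the
slow band to minimize ringing at very low frequencies, order 4 for the fast
band; resampling is polyphase with anti-alias filtering. Band-limiting the
feature acts as a soft prior against sub-200 ms state flickers without
imposing a hard minimum-duration rule. Z-scoring moments are computed over
retained epochs only, so excluded stretches cannot bias the scale. LFP
input is inverted once so that UP states are positive deflections in every
signal class.

### Epoch selection

Desynchronized stretches (no slow-oscillation structure) are excluded
before inference. A multitaper spectrogram (15 s windows, 50% overlap,
time–bandwidth product 4, 7 DPSS tapers) yields two statistics per window:
the maximum power in the UDS band (0.05–2 Hz) and the integral of the log
power over a reference band (4–40 Hz). A window is excluded only when UDS
power is *below* its threshold **and** reference power is *above* its
threshold; the second condition protects epochs whose slow power is low
merely because of very long DOWN states, which also lose broadband power.
Thresholds are deliberately user-set per experiment batch (a plotting
helper supports the choice); there is no automatic calibration. The 50%
overlap is our choice — the window length is the resolution that matters.

## Observation model

Each state k ∈ {DOWN, UP} emits Gaussian observations
y_t ~ N(μ_k(t), Σ_k). The means are allowed to vary slowly in time:
recordings of tens of minutes show substantial amplitude drift (AC-coupled
amplifier artifacts and genuine physiological change), and a static mixture
cannot track it. In the M step, μ_k(t) is the posterior-weighted average of
the observations inside a symmetric boxcar window centred on t (default
50 s — about 25 UDS cycles, a good trade-off between tracking and
stability; a Gaussian window is available). A window spanning the whole
record reduces the update to the classical constant-mean M step exactly,
and `mean_window_s=None` requests that directly. Covariances and the
transition structure are pooled across discontinuous data segments;
initial-state distributions are per segment.

Because the windowed mean update is a smoothed, not exact, maximizer of the
expected complete-data log-likelihood, EM monotonicity is not guaranteed by
theory for the time-varying-mean variant. In practice the trace is
monotone on all study conditions we generate; as a guard, a step that
would decrease the log-likelihood reverts to the previous parameters and
stops. The duration, covariance, transition and initial-distribution
updates are exact M steps.

**Robust fallback.** Large artifacts produce samples far from both state
means; there the plain model assigns them to whichever state has the larger
variance, which can label a deep negative transient as UP. Samples whose
Mahalanobis distance exceeds a trigger (default 4 SD) under *both* states
are therefore re-scored under a pooled equal-covariance model, so the
nearer-mean state wins. The trigger value is our choice.

## Standard HMM

The two-state Gaussian HMM (`GaussianHMM(obs).fit()`) uses classical scaled
forward–backward recursions (per-step normalization with stored scaling
factors) and log-domain Viterbi, per segment. It serves three roles: a
comparison method, the initializer of the explicit-duration model, and the
source of the initial dwell-time samples. Viterbi ties break toward DOWN
(the lower label); this is measure-zero but documented.

## Explicit-duration HMM

A standard HMM implicitly forces geometric dwell times; empirical UP/DOWN
dwell distributions are unimodal with a mode well away from zero, which a
geometric pmf cannot express. The explicit-duration HMM (a hidden
semi-Markov model) draws each run length d from a per-state pmf p_k(d) on
integer support [1, d_max]; self-transitions are prohibited, so with two
states the transition matrix is fixed to the swap matrix. d_max defaults to
30 s of the feature rate.

### Dwell-time models

Continuous gamma or inverse-Gaussian densities are evaluated at integer
step counts and renormalized over [1, d_max] ("censored" discrete
distributions); truncated geometric and nonparametric pmfs complete the
family set. Whether to evaluate at integers or integrate over unit bins is
an open discretization choice; we evaluate at integers. The default family
is the inverse Gaussian — it is also the first-passage-time distribution
of a drifting diffusion, a natural phenomenological model for a
noise-driven transition process, and it wins the per-sample log-likelihood
comparison (`loglik_per_sample`) on both simulated and (in the source
literature) recorded dwell sequences.

Fitting uses the exponential-family structure: on a fixed finite support,
censored ML for a family with natural statistics T(d) — (log d, d) for
gamma, (d, 1/d) for inverse Gaussian — is exactly the parameter vector
whose model expectations of T(d) match the target's. The EDHMM duration
M step therefore (i) forms the nonparametric ML pmf proportional to the
posterior run-occupancy mass and (ii) moment-matches the family to it with
a two-dimensional root find in log-parameter space, started from the
moment-based direct estimates. The parametric family is refit every EM
iteration (iterations are few). Uncensored ML from raw dwell samples
(Newton–Raphson for the gamma shape, closed form for the inverse Gaussian)
initializes the chain; with negligible censoring the two routes agree to
well under 1%.

### Inference

Exact inference runs in the log domain over run *end* positions: F[t, k] is
the log-probability of the data up to t with a run of state k ending at t,
G[t, k] the corresponding backward quantity, and cumulative emission sums
make each recursion step a vectorized reduction over durations (cost
O(T·d_max) per state and pass, hence quadratic in the sampling rate at
fixed maximum dwell seconds — the reason decoding runs at 50 Hz, not
2 kHz). The published variants of this recursion propagate
posterior-normalized probabilities instead; log-domain arithmetic achieves
the same stability and the implementation is checked against exhaustive
segmentation enumeration (posteriors, duration mass, and MAP path) on
hundreds of random instances. State marginals are recovered from run
posteriors with a difference-array accumulation rather than O(T·d_max)
memory.

Within each data segment the first run starts at the segment start and the
last ends at the segment end. This slightly biases boundary dwell
statistics; boundary runs can be excluded from downstream duration
summaries (`durations(..., exclude_boundary=True)`). Viterbi decoding is
the longest path in the DAG whose nodes are (state, run span) with
emission-plus-duration log-probability weights; ties resolve toward DOWN
and shorter final durations.

## Initialization

EM reaches the global optimum only from a sensible start, so
initialization is staged:

1. **State means** — Gaussian KDE in sliding 50 s windows (step = window/10),
   bandwidth from the oversmoothing (maximal-smoothing) rule
   h = 1.144 σ̂ n^(−1/5), evaluated on a 512-point grid over the window's
   range. Two modes (prominence ≥ 5% of the density maximum) give the DOWN
   (lower) and UP (upper) means. A unimodal window assigns its mode to DOWN
   when the sample skewness is ≥ 0 (a DOWN-dominated sample has a positive
   tail; exact zero is a documented tie-break) and offsets the other state
   by the mean inter-mode separation of the bimodal windows in the same
   segment. Windows with three or more prominent modes keep the two most
   prominent. Means are interpolated linearly between window centres. A
   recording with *no* bimodal window anywhere is rejected — it likely
   lacks UDS.
2. **Covariances** — two-component Gaussian mixtures fit to the residuals
   (observations minus each state's mean trajectory); the component nearest
   zero supplies that state's covariance.
3. **Transitions** — stay probability 1 − 1/(f_s·1 s), i.e. a geometric
   expected dwell of exactly 1 s per state.
4. **Durations** — a standard HMM is fit and Viterbi-decoded; uncensored ML
   estimates on the decoded dwell lengths seed the duration models.

## Transition-time alignment

Decoding at 50 Hz on band-limited features blurs transition times. The
decoded transitions are therefore realigned to the broadband signal
resampled to 252 Hz (only acquisition filtering): per-state Gaussians are
estimated on the target sequence from the posteriors (transferred by
nearest neighbour in time — the posteriors are piecewise-smooth), and a
dynamic program selects integer perturbations δ_i ∈ [−P, P] (default
P = 150 ms) of each transition time maximizing the target-sequence
likelihood of the perturbed segmentation. The DP enforces strict ordering
of perturbed transitions inside the recursion (never by clipping), is exact
(equals exhaustive search over perturbation combinations), and never
worsens the likelihood since δ = 0 is admissible. Ties prefer the smallest
|δ|, negative first. Target models are estimated once, not iterated after
alignment.

## Evaluation machinery

- **Separability** — the Bhattacharyya distance between the two
  state-conditional Gaussians, closed form; with time-varying means the
  mean term is the time-averaged Mahalanobis distance. It is the criterion
  for choosing signal features without calibration experiments.
- **Threshold-crossing baselines** — a fixed threshold from a static
  two-component Gaussian mixture (equal-responsibility point between the
  component means, "SMM") or from the lowest local KDE minimum between the
  component means ("Np", falling back to SMM when no interior minimum
  exists); UP wherever the feature exceeds it. The search interval between
  the component means is our reading of the method.
- **Correspondence and errors** — state sequences decoded from paired
  signals (e.g. LFP and MP) are compared by (i) the instantaneous error
  e_i = P(false UP) + P(false DOWN) over shared samples and (ii) the state
  error e_s = (extra + missed states)/(number of reference states), after
  greedily linking nearest-in-time UP transitions (then DOWN transitions),
  removing crossed links by dropping the more separated one. The e_s
  denominator (reference = second sequence's state count) is our choice; a
  state counts as unmatched when none of its bounding transitions is
  linked. Greedy ties link the earlier first-sequence transition.

## Synthetic data

No public recordings accompany the method, so a generator
(`simulate_uds`) produces ground-truthed surrogates: alternating
inverse-Gaussian dwells (mean 1 s per state, shape 4 s → CV 0.5, ~2 s
cycles), state-conditional amplitudes (means ∓1, +1; SD 0.5, a nominal
Gaussian separability D_B = 2), slow amplitude drift (gain modulation of
the state-mean component, amplitude 0.5 pooled SD, period 200 s), a
state-dependent 20–80 Hz component, optional desynchronized insertions
(broadband 4–40 Hz noise, no state structure), optional large transients,
and an optional paired MP-like channel sharing the state sequence with
independent Gaussian transition jitter (SD 50 ms).

Two generator choices deserve emphasis. First, the contract is stated at
the *feature* level: the generator calibrates its output through the
analysis band so that the extracted LF-amplitude feature carries the
configured state-conditional Gaussians — the mean step is rescaled for the
band-pass attenuation of its square-wave component, the residual
transition-blur variance is charged against the state-SD budget, and the
noise is pre-compensated for the second filter pass at feature extraction.
Second, the low-frequency noise budget is split between an in-band
(0.05–2 Hz) component and a faster 2–10 Hz component (25% of the
variance): real recordings contain supra-band noise whose leakage through
the 2 Hz corner produces the brief spurious threshold crossings that
duration modelling exists to suppress, and purely in-band noise is too
smooth to generate them at all. Drift is multiplicative (gain) rather than
additive because an additive 0.005 Hz baseline drift is removed by the
0.05 Hz high-pass and would never reach the feature.

What the generator does *not* emulate: non-Gaussian emission tails,
state-dependent autocorrelation structure, the spatial relationships of
multi-electrode data, spike waveforms riding on the MP, or genuinely
non-stationary dwell statistics. Tests passing on these surrogates
demonstrate correctness of the inference machinery and the claimed
qualitative orderings under the stated conditions — not performance on any
particular real recording.

## Numerical choices and degenerate inputs

- EM stops at relative log-likelihood improvement < 10⁻⁵ (HMM cap 100
  iterations, EDHMM cap 30 — a handful usually suffices).
- A state whose posterior mass falls below 10 samples keeps its previous
  covariance (warned); near-singular covariances get a diagonal load of
  10⁻⁶·trace/D.
- All-equal dwell samples make the inverse-Gaussian shape estimate diverge
  and are rejected with guidance.
- Duration moment matching that fails to converge falls back to the
  moment-based direct estimates with a warning.
- NaN in input signals is an error at load time, not silently propagated.

## Problem sizes

The shipped tests and the acceptance script run on simulations of 1.5–20
minutes at a 500 Hz raw rate (features at 50 Hz, alignment at 252 Hz),
sizes at which every qualitative result above is stable; enumeration
oracles cover instances up to T = 12 with d_max = 6 exhaustively.

## Known limitations

- Two states only; no mixture-of-Gaussians emissions; no autoregressive
  emission structure.
- Time-varying means but static covariances.
- Segment boundaries clamp the first and last run; no censored-boundary
  relaxation.
- Epoch-selection thresholds are manual by design.
- The alignment pass is single-shot (target models are not re-estimated
  after realignment).
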