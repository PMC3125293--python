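# updown

Explicit-duration hidden Markov model inference of cortical **UP–DOWN
states** (UDS) from continuous electrophysiological signals — LFP, EEG, or
intracellular membrane potential.

Under slow-wave sleep and many anesthetics, cortical networks alternate
every couple of seconds between a depolarized, active UP state and a
quiescent DOWN state. Knowing exactly when each state starts and ends is
the basis for studying state-dependent coding, cross-regional coordination
and sleep-related consolidation, but extracellular signals are noisy,
drift over tens of minutes, and are interrupted by desynchronized epochs —
conditions under which fixed-threshold classification breaks down. This
package provides a statistically principled alternative for anyone who
needs UDS timing from continuous recordings: a two-state hidden semi-Markov
model with Gaussian emissions, fitted by EM and decoded exactly.

## The model

A derived signal feature y_t (by default the 0.05–2 Hz LFP amplitude,
z-scored and down-sampled to 50 Hz) is modelled per state k ∈ {DOWN, UP} as

  y_t | z_t = k  ~  N(μ_k(t), Σ_k),

where the state means μ_k(t) vary slowly (estimated as 50 s windowed,
posterior-weighted averages) to absorb amplitude drift. Instead of the
geometric dwell times a standard HMM imposes, each run of state k has an
explicit duration pmf p_k(d) on d ∈ [1, d_max] — a censored discrete
inverse-Gaussian (or gamma, geometric, nonparametric) distribution, refit
each EM iteration by exponential-family moment matching against the
posterior dwell distribution. Decoding is exact (longest path in a DAG of
candidate runs), and decoded transition times are realigned to the
broadband signal at 252 Hz by a dynamic program over per-transition
perturbations (±150 ms). Feature quality is scored by the Bhattacharyya
distance D_B between the two state-conditional Gaussians; accuracy against
a paired reference signal is scored by instantaneous (e_i) and state-level
(e_s) error probabilities after a greedy transition correspondence.

See `docs/methods.md` for the full model, defaults, and design rationale.

## Worked example

No recordings ship with the package; the built-in simulator generates
ground-truthed surrogates with the statistical structure of
anesthetized-cortex LFP (inverse-Gaussian dwells, ~2 s cycles, drifting
amplitudes, D_B = 2 feature separability):

```python
from updown import PipelineConfig, run_pipeline
from updown.simulate import SimConfig, simulate_uds, downsample_labels

sim = simulate_uds(SimConfig(duration_s=300.0, seed=7))
res = run_pipeline(sim.lfp, PipelineConfig(seed=1))

truth = downsample_labels(sim.states, res.obs.fs, res.obs.n_samples)
print(f"accuracy vs ground truth: {res.decoded.accuracy(truth):.3f}")
print(res.edhmm.summary())
```

prints

```
accuracy vs ground truth: 0.967
Two-state explicit-duration HMM
====================================================
samples: 15000  segments: 1  features: 1  fs: 50 Hz
duration family: invgauss  d_max: 1500 steps (30.0 s)
EM iterations: 5  converged: True
log-likelihood: -8967.6108 (-0.5978 per sample)
DOWN: mean(t) avg [-0.919] sd [0.406]  dwell invgauss(mu=50.28, lam=217.7) mean 1.006 s
UP: mean(t) avg [0.877] sd [0.419]  dwell invgauss(mu=52.46, lam=231.3) mean 1.049 s
```

96.7% of 50 Hz samples are labelled correctly, and the fitted
inverse-Gaussian dwell means (1.01 s DOWN, 1.05 s UP) recover the
generating 1 s means. `res.aligned` carries the same segmentation with
transition times refined on the 252 Hz broadband grid, and
`res.edhmm.posterior().gamma` gives per-sample state probabilities — the
model's own uncertainty about each moment.

The same pipeline is available from the shell, stage by stage or end to
end:

```
updown simulate --duration-s 300 --seed 7 --out sig.txt
updown run-all sig.txt --seed 1 --out-prefix run
```

which writes interval tables (`run.states.tsv`, `run.aligned.tsv`),
features, posteriors, and a per-iteration EM log.

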