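"""End-to-end UDS inference: epochs -> features -> HMM -> EDHMM -> alignment.

The full procedure: select epochs with clear UDS (multitaper criterion),
extract the chosen signal feature(s) down-sampled to the feature rate,
initialize with the sliding-window KDE, fit a standard HMM, use its Viterbi
dwell times to seed the duration models, fit the explicit-duration HMM,
decode, and realign the decoded transition times to the broadband signal at
the alignment rate.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np

from .alignment import align_state_sequence
from .containers import (ObservationSequence, SegmentSet, SignalRecording,
                         StateSequence)
from .edhmm import EDHMMResults, ExplicitDurationHMM
from .hmm import GaussianHMM, HMMResults
from .preprocessing import (compute_hf_power, compute_lf_amplitude,
                            detect_uds_epochs, resample)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "broadband_target"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the full inference pipeline (defaults are the
    method's standard operating point)."""

    feature: str = "lf_amplitude"        # lf_amplitude | hf_power | both
    lf_band: tuple = (0.05, 2.0)
    hf_band: tuple = (20.0, 80.0)
    hf_sigma_s: float = 0.15
    fs_features: float = 50.0
    fs_align: float = 252.0
    d_max_s: float = 30.0
    mean_window_s: float | None = 50.0
    duration_family: str = "invgauss"
    em_tol: float = 1e-5
    hmm_max_iter: int = 100
    edhmm_max_iter: int = 30
    max_pert_s: float = 0.15
    robust_trigger_sd: float | None = 4.0
    # epoch selection; None for both thresholds skips exclusion entirely
    uds_thresh: float | None = None
    ref_thresh: float | None = None
    epoch_win_s: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if self.feature not in ("lf_amplitude", "hf_power", "both"):
            raise ValueError("feature must be lf_amplitude, hf_power or both")
        if self.fs_features <= 0 or self.fs_align <= 0:
            raise ValueError("sampling rates must be positive")
        if (self.uds_thresh is None) != (self.ref_thresh is None):
            raise ValueError("set both epoch thresholds or neither")


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    segments: SegmentSet
    obs: ObservationSequence
    hmm: HMMResults
    edhmm: EDHMMResults
    decoded: StateSequence          # EDHMM Viterbi on the feature grid
    aligned: StateSequence          # transitions realigned to the broadband grid
    target_obs: ObservationSequence
    log: list = field(default_factory=list)


@contextmanager
def _stage(name: str, hint: str):
    try:
        yield
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{name}' failed: {e} ({hint})") from e


def broadband_target(rec: SignalRecording, fs_align: float,
                     segments: SegmentSet) -> ObservationSequence:
    """The raw signal resampled to the alignment rate, z-scored over
    retained epochs, cut to the retained-segment structure."""
    y = resample(rec.channel(), rec.fs, fs_align)
    seg = segments.rescale(fs_align, n_out=len(y))
    mask = np.zeros(len(y), dtype=bool)
    for s, e in seg:
        mask[s:e] = True
    mu, sd = y[mask].mean(), y[mask].std()
    y = (y - mu) / (sd if sd > 0 else 1.0)
    feats = np.concatenate([y[s:e] for s, e in seg])
    return ObservationSequence(feats, fs_align, seg)


def extract_features(rec: SignalRecording, cfg: PipelineConfig,
                     segments: SegmentSet) -> ObservationSequence:
    lf = hf = None
    if cfg.feature in ("lf_amplitude", "both"):
        lf = compute_lf_amplitude(rec, *cfg.lf_band, out_fs=cfg.fs_features,
                                  segments=segments)
    if cfg.feature in ("hf_power", "both"):
        hf = compute_hf_power(rec, *cfg.hf_band, smooth_sigma_s=cfg.hf_sigma_s,
                              out_fs=cfg.fs_features, segments=segments)
    if cfg.feature == "lf_amplitude":
        return lf
    if cfg.feature == "hf_power":
        return hf
    return ObservationSequence(np.column_stack([lf.features, hf.features]),
                               cfg.fs_features, lf.segment_map)


def run_pipeline(rec: SignalRecording, cfg: PipelineConfig | None = None,
                 verbose: bool = False) -> PipelineResult:
    """Run the full UDS inference pipeline on a recording.

    Raises a stage-labelled ``RuntimeError`` on failure (e.g. "no UDS
    epochs" when the whole recording is desynchronized).
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    log: list[str] = []

    with _stage("epoch selection", "check thresholds against "
                "plot_epoch_statistics; lower uds_thresh to retain more data"):
        if cfg.uds_thresh is not None:
            segments = detect_uds_epochs(rec, uds_band=cfg.lf_band,
                                         win_s=cfg.epoch_win_s,
                                         uds_thresh=cfg.uds_thresh,
                                         ref_thresh=cfg.ref_thresh)
            if len(segments) == 0:
                raise ValueError("no UDS epochs retained")
        else:
            segments = SegmentSet.whole(rec.n_samples, rec.fs)
        log.append(f"epochs: retained {segments.total_samples / rec.fs:.1f} s "
                   f"in {len(segments)} segment(s)")

    with _stage("feature extraction", "verify bands lie inside Nyquist"):
        obs = extract_features(rec, cfg, segments)
        log.append(f"features: {obs.n_samples} samples x {obs.n_features} "
                   f"at {obs.fs:g} Hz")

    with _stage("HMM fit", "check the recording shows bimodal UDS amplitude"):
        hmm = GaussianHMM(obs, cfg.mean_window_s,
                          robust_trigger_sd=cfg.robust_trigger_sd,
                          random_state=cfg.seed)
        hmm_res = hmm.fit(tol=cfg.em_tol, max_iter=cfg.hmm_max_iter)
        for i, ll in enumerate(hmm_res.loglik_trace):
            log.append(f"HMM EM iter {i}: loglik {ll:.6f}")

    with _stage("EDHMM fit", "inspect HMM dwell durations; adjust d_max_s"):
        ed = ExplicitDurationHMM(obs, cfg.duration_family, cfg.d_max_s,
                                 cfg.mean_window_s,
                                 robust_trigger_sd=cfg.robust_trigger_sd,
                                 random_state=cfg.seed)
        init = ed.initialize(hmm_results=hmm_res)
        ed_res = ed.fit(init=init, tol=cfg.em_tol,
                        max_iter=cfg.edhmm_max_iter, verbose=verbose)
        for i, ll in enumerate(ed_res.loglik_trace):
            log.append(f"EDHMM EM iter {i}: loglik {ll:.6f}")

    with _stage("decoding", "numerical issue in Viterbi; check features"):
        decoded = ed_res.decode()

    with _stage("alignment", "fs_align must not exceed the raw rate"):
        target = broadband_target(rec, cfg.fs_align, segments)
        aligned = align_state_sequence(decoded, ed_res.posterior().gamma,
                                       obs, target, cfg.max_pert_s)
        log.append(f"alignment: {sum(len(l) for l in aligned.labels)} samples "
                   f"at {cfg.fs_align:g} Hz, max_pert {cfg.max_pert_s * 1e3:.0f} ms")

    return PipelineResult(segments, obs, hmm_res, ed_res, decoded, aligned,
                          target, log)
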