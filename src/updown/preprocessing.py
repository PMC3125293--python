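"""Signal-feature extraction and UDS-epoch selection.

Two scalar features are informative about cortical UP-DOWN states:

* the **low-frequency amplitude** (default 0.05-2 Hz band-passed signal),
  which is bimodal under clear UDS, and
* the **high-frequency power** (default 20-80 Hz), log-transformed and
  Gaussian-smoothed, which is elevated during UP states.

Both are z-scored and down-sampled (default 50 Hz) before model fitting.
Epochs of desynchronized activity -- stretches lacking slow-oscillation
power but retaining broadband power -- are located with a multitaper
spectrogram criterion and excluded before any inference.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d
from scipy.signal.windows import dpss

from .containers import ObservationSequence, SegmentSet, SignalRecording

__all__ = [
    "bandpass",
    "resample",
    "compute_lf_amplitude",
    "compute_hf_power",
    "epoch_statistics",
    "detect_uds_epochs",
    "plot_epoch_statistics",
    "remove_spikes",
]


def bandpass(x: np.ndarray, fs: float, low_hz: float, high_hz: float,
             order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass filter."""
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError(f"high corner {high_hz} Hz is at/above Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, x)


def resample(x: np.ndarray, fs: float, out_fs: float) -> np.ndarray:
    """Polyphase resampling with anti-alias filtering."""
    if out_fs > fs:
        raise ValueError("out_fs must not exceed the input rate")
    if out_fs == fs:
        return np.asarray(x, dtype=float)
    frac = Fraction(out_fs / fs).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def _zscore_on(x: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    ref = x if mask is None else x[mask]
    sd = ref.std()
    if sd == 0:
        return x - ref.mean()
    return (x - ref.mean()) / sd


def _check_length(rec: SignalRecording, low_hz: float) -> None:
    # ~3 time constants of the low corner; shorter records cannot support
    # a meaningful estimate of the slow band
    if rec.duration_s < 3.0 / low_hz:
        raise ValueError(
            f"record of {rec.duration_s:.1f} s is shorter than three filter "
            f"time constants ({3.0 / low_hz:.1f} s) for low corner {low_hz} Hz")


def _finalize(filtered: np.ndarray, rec: SignalRecording, out_fs: float,
              segments: SegmentSet | None) -> ObservationSequence:
    """Z-score over retained samples, resample, and cut into segments."""
    if segments is not None:
        mask = np.zeros(rec.n_samples, dtype=bool)
        for s, e in segments:
            mask[s:e] = True
    else:
        mask = None
    z = _zscore_on(filtered, mask)
    y = resample(z, rec.fs, out_fs)
    if segments is None:
        return ObservationSequence(y, out_fs)
    seg_out = segments.rescale(out_fs, n_out=len(y))
    feats = np.concatenate([y[s:e] for s, e in seg_out])
    return ObservationSequence(feats, out_fs, seg_out)


def compute_lf_amplitude(rec: SignalRecording, low_hz: float = 0.05,
                         high_hz: float = 2.0, out_fs: float = 50.0,
                         order: int = 2,
                         segments: SegmentSet | None = None) -> ObservationSequence:
    """Low-frequency amplitude feature: band-pass, z-score, down-sample.

    Filtering is zero-phase, so state transitions are not delayed. When
    ``segments`` is given (retained UDS epochs on the raw sample axis), the
    z-scoring moments are computed over retained samples only and the output
    sequence carries the corresponding segment structure at ``out_fs``.
    """
    _check_length(rec, low_hz)
    filt = bandpass(rec.channel(), rec.fs, low_hz, high_hz, order=order)
    return _finalize(filt, rec, out_fs, segments)


def compute_hf_power(rec: SignalRecording, low_hz: float = 20.0,
                     high_hz: float = 80.0, smooth_sigma_s: float = 0.15,
                     out_fs: float = 50.0, order: int = 4,
                     log_floor_frac: float = 1e-3,
                     segments: SegmentSet | None = None) -> ObservationSequence:
    """Smoothed log high-frequency power feature.

    Band-pass (default 20-80 Hz), square, convolve with a Gaussian kernel of
    SD ``smooth_sigma_s``, log-transform with a floor (``log_floor_frac`` of
    the median smoothed power, guarding silent stretches), z-score, resample.
    """
    if smooth_sigma_s <= 0:
        raise ValueError("smooth_sigma_s must be positive")
    filt = bandpass(rec.channel(), rec.fs, low_hz, high_hz, order=order)
    power = gaussian_filter1d(filt ** 2, smooth_sigma_s * rec.fs)
    med = np.median(power)
    eps = log_floor_frac * med if med > 0 else 1.0
    logp = np.log(power + eps)
    return _finalize(logp, rec, out_fs, segments)


def epoch_statistics(rec: SignalRecording, uds_band=(0.05, 2.0),
                     ref_band=(4.0, 40.0), win_s: float = 15.0,
                     tw: float = 4.0, n_tapers: int = 7):
    """Per-window multitaper statistics used for UDS-epoch selection.

    The recording is z-scored, a multitaper spectrogram is computed in
    ``win_s`` windows with 50% overlap (``n_tapers`` DPSS tapers,
    time-bandwidth product ``tw``), and two statistics are extracted per
    window: the maximum power in ``uds_band`` ("UDS power") and the
    integral of the log power over ``ref_band`` ("reference power").

    Returns
    -------
    starts : ndarray of window start sample indices
    win_len : window length in samples
    uds_power, ref_power : per-window statistics
    """
    x = _zscore_on(rec.channel(), None)
    W = int(round(win_s * rec.fs))
    if W > len(x):
        raise ValueError("recording shorter than one spectrogram window")
    tapers = dpss(W, tw, Kmax=n_tapers)
    hop = W // 2
    starts = np.arange(0, len(x) - W + 1, hop)
    freqs = np.fft.rfftfreq(W, 1.0 / rec.fs)
    uds_sel = (freqs >= uds_band[0]) & (freqs <= uds_band[1])
    ref_sel = (freqs >= ref_band[0]) & (freqs <= ref_band[1])
    if not uds_sel.any() or not ref_sel.any():
        raise ValueError("frequency bands resolve to empty bins at this window length")
    uds_power = np.empty(len(starts))
    ref_power = np.empty(len(starts))
    for i, s in enumerate(starts):
        seg = x[s:s + W]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        psd = (np.abs(spec) ** 2).mean(axis=0) / rec.fs
        uds_power[i] = psd[uds_sel].max()
        ref_power[i] = np.trapezoid(np.log10(psd[ref_sel] + 1e-300),
                                    freqs[ref_sel])
    return starts, W, uds_power, ref_power


def detect_uds_epochs(rec: SignalRecording, uds_band=(0.05, 2.0),
                      ref_band=(4.0, 40.0), win_s: float = 15.0,
                      tw: float = 4.0, n_tapers: int = 7,
                      uds_thresh: float | None = None,
                      ref_thresh: float | None = None) -> SegmentSet:
    """Locate epochs with clear UP-DOWN states; drop desynchronized ones.

    A window is excluded iff its UDS-band power is *below* ``uds_thresh``
    AND its reference-band power is *above* ``ref_thresh``.  The reference
    criterion protects stretches whose slow power is low merely because of
    very long DOWN states: those also lose high-frequency power and are
    retained.  Contiguous retained windows are merged into segments on the
    raw sample axis (a sample is retained if any retained window covers it).

    Thresholds are data-scale quantities chosen per experiment batch by
    visual inspection (see :func:`plot_epoch_statistics`); there is no
    automatic calibration.
    """
    if uds_thresh is None or ref_thresh is None:
        raise ValueError(
            "uds_thresh and ref_thresh must be set; inspect the two window "
            "statistics (plot_epoch_statistics / epoch_statistics) and choose "
            "a single threshold per experiment batch")
    starts, W, uds_power, ref_power = epoch_statistics(
        rec, uds_band, ref_band, win_s, tw, n_tapers)
    excluded = (uds_power < uds_thresh) & (ref_power > ref_thresh)
    retained_mask = np.zeros(rec.n_samples, dtype=bool)
    for i, s in enumerate(starts):
        if not excluded[i]:
            end = rec.n_samples if i == len(starts) - 1 else s + W
            retained_mask[s:end] = True
    # any leading samples before the first window follow the first window
    if not excluded[0]:
        retained_mask[:starts[0]] = True
    # convert mask runs to intervals
    d = np.diff(retained_mask.astype(int))
    run_starts = list(np.flatnonzero(d == 1) + 1)
    run_ends = list(np.flatnonzero(d == -1) + 1)
    if retained_mask[0]:
        run_starts.insert(0, 0)
    if retained_mask[-1]:
        run_ends.append(rec.n_samples)
    return SegmentSet(list(zip(run_starts, run_ends)), rec.fs)


def plot_epoch_statistics(rec: SignalRecording, uds_thresh=None, ref_thresh=None,
                          ax=None, **kwargs):
    """Diagnostic plot of the two window statistics, to support choosing
    the epoch-selection thresholds manually."""
    import matplotlib.pyplot as plt

    starts, W, uds_power, ref_power = epoch_statistics(rec, **kwargs)
    t = (starts + W / 2) / rec.fs
    if ax is None:
        _, ax = plt.subplots()
    ax2 = ax.twinx()
    ax.plot(t, uds_power, color="C0", label="UDS power (max in band)")
    ax2.plot(t, ref_power, color="C3", label="reference power (int. log)")
    if uds_thresh is not None:
        ax.axhline(uds_thresh, color="C0", ls="--")
    if ref_thresh is not None:
        ax2.axhline(ref_thresh, color="C3", ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("UDS power")
    ax2.set_ylabel("reference power")
    return ax


def remove_spikes(rec: SignalRecording, hp_hz: float = 10.0,
                  thresh_sd: float = 5.0, pad_s: float = 0.003) -> SignalRecording:
    """Interpolate over fast suprathreshold deflections (MP spike removal).

    Samples where the 10 Hz high-passed trace exceeds ``thresh_sd`` robust
    standard deviations (1.4826 x MAD) are blanked together with a
    ``pad_s`` margin on each side and filled by linear interpolation.
    """
    x = rec.channel().copy()
    sos = signal.butter(4, hp_hz, btype="highpass", fs=rec.fs, output="sos")
    hp = signal.sosfiltfilt(sos, x)
    robust_sd = 1.4826 * np.median(np.abs(hp - np.median(hp)))
    if robust_sd == 0:
        return SignalRecording(x, rec.fs, rec.channel_kind, rec.inverted)
    bad = np.abs(hp) > thresh_sd * robust_sd
    pad = max(1, int(round(pad_s * rec.fs)))
    bad = np.convolve(bad.astype(int), np.ones(2 * pad + 1, int), "same") > 0
    if bad.all():
        warnings.warn("entire trace flagged as spike; returning unchanged")
        return SignalRecording(x, rec.fs, rec.channel_kind, rec.inverted)
    idx = np.arange(len(x))
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return SignalRecording(x, rec.fs, rec.channel_kind, rec.inverted)
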