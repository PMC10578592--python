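"""Broadband high-frequency amplitude (HFA, 70-150 Hz) extraction.

The HFA proxy for local population firing is computed per epoch: a
4th-order zero-phase Butterworth bandpass, the magnitude of the analytic
(Hilbert) signal, a 300 ms centered moving average, and z-scoring against
the -3..-2 s pre-event baseline.  Filtering runs on the full extracted
slice (which extends well before the analysis window) so that the
-1000..1000 ms analysis window is free of filter edge transients; the
``edge_trim_ms`` margin marks the outer samples excluded from any
statistic.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len

from .preprocess import EpochSet

__all__ = ["bandpass_hilbert_amplitude", "smooth_envelope", "zscore_baseline"]


def bandpass_hilbert_amplitude(
    epochs: EpochSet,
    band=(70.0, 150.0),
    order: int = 4,
    edge_trim_ms: float = 100.0,
) -> EpochSet:
    """Bandpass (zero-phase Butterworth) then analytic-signal magnitude.

    Returns an EpochSet in envelope units (non-negative).  ``edge_trim_ms``
    is recorded on the result: statistics downstream must not use the
    outer margin, where the forward-backward filter and the epoch-wise
    Hilbert transform are unreliable.
    """
    if epochs.units != "uV":
        raise ValueError("bandpass_hilbert_amplitude expects raw uV epochs")
    lo, hi = band
    nyq = epochs.fs / 2.0
    if hi >= nyq:
        raise ValueError(
            f"band upper edge {hi} Hz is not below Nyquist ({nyq} Hz)"
        )
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    sos = signal.butter(order, band, btype="bandpass", fs=epochs.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    n = filtered.shape[-1]
    nfft = next_fast_len(n)
    env = np.abs(signal.hilbert(filtered, N=nfft, axis=-1)[..., :n])
    return replace(
        epochs, data=env, units="envelope", edge_trim_ms=edge_trim_ms,
        reject_mask=epochs.reject_mask.copy(),
        reject_reasons=list(epochs.reject_reasons),
    )


def smooth_envelope(epochs: EpochSet, window_ms: float = 300.0) -> EpochSet:
    """Centered moving average of the envelope.

    The window shrinks at the epoch edges (the average is taken over the
    available samples), so a constant envelope is unchanged everywhere
    and a unit impulse becomes a plateau of height 1/W in the interior.
    """
    if window_ms <= 0:
        raise ValueError("smoothing window must be positive")
    w = int(round(window_ms / 1000.0 * epochs.fs))
    n = epochs.n_times
    if w >= n:
        raise ValueError("smoothing window exceeds epoch length")
    if w <= 1:
        return epochs
    x = epochs.data
    half = w // 2
    cs = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    idx_lo = np.clip(np.arange(n) - half, 0, n)
    idx_hi = np.clip(np.arange(n) - half + w, 0, n)
    sums = cs[..., idx_hi] - cs[..., idx_lo]
    counts = (idx_hi - idx_lo).astype(float)
    sm = sums / counts
    return replace(
        epochs, data=sm, smoothed=True,
        reject_mask=epochs.reject_mask.copy(),
        reject_reasons=list(epochs.reject_reasons),
    )


def zscore_baseline(epochs: EpochSet, baseline=(-3000.0, -2000.0)) -> EpochSet:
    """Z-score each (trial, channel) epoch against its pre-event baseline.

    The mean and SD are taken over the ``baseline`` window (ms relative
    to the event, clipped to the epoch's edge-trimmed interior) and
    applied to the whole epoch.  Epochs whose baseline SD is zero are
    flagged ("zero_baseline_sd") and excluded.
    """
    if epochs.units not in ("uV", "envelope"):
        raise ValueError("epochs are already z-scored")
    t0 = max(baseline[0], epochs.t_start_ms + epochs.edge_trim_ms)
    sl = epochs.time_slice(t0, baseline[1])
    if sl.stop - sl.start < 2:
        raise ValueError(
            f"baseline window {baseline} not contained in epoch span"
        )
    seg = epochs.data[..., sl]
    mu = seg.mean(axis=-1, keepdims=True)
    sd = seg.std(axis=-1, keepdims=True)
    bad = sd[..., 0] == 0.0
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    z = (epochs.data - mu) / sd_safe
    out = replace(
        epochs, data=z, units="z",
        baseline_stats=(mu[..., 0], sd[..., 0]),
        reject_mask=epochs.reject_mask.copy(),
        reject_reasons=list(epochs.reject_reasons),
    )
    out.add_rejections(bad, "zero_baseline_sd")
    return out
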