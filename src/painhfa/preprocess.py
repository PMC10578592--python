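"""Re-referencing, epoching, artifact rejection, and downsampling.

The preprocessing contract, in order:

1. artifact detection on raw (unreferenced) microvolt epochs — the
   flat-channel and amplifier-saturation rules are only meaningful before
   the common median is subtracted;
2. common-median re-referencing of the continuous recording;
3. epoch extraction around the hand-on / hand-off events with a long
   pre-span so the -3..-2 s baseline is available;
4. downsampling to 500 Hz for spectral analysis.

Each rejection rule records a reason code per (trial, channel) epoch;
rejected epochs never enter later statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import Recording

__all__ = [
    "EpochSet",
    "common_median_reference",
    "extract_epochs",
    "detect_artifacts",
    "mad_outlier_flag",
    "downsample",
    "DEFAULT_THRESHOLDS",
]

# the four rejection rules' printed thresholds
DEFAULT_THRESHOLDS = dict(
    line_noise_psd=100.0,   # uV^2/Hz at 60 Hz (Welch, 1 s Hann, 50% overlap)
    transient_slope=300.0,  # uV/ms
    min_variance=1.0,       # uV^2
    saturation=6553.0,      # uV, amplifier code limit
)

MAD_SCALE = 1.4826  # normal-consistent MAD scaling


@dataclass
class EpochSet:
    """Trials x channels x time array aligned to one trial event.

    ``units`` tracks the processing state ("uV" raw, "envelope" after
    filter-Hilbert, "z" after baseline normalization); ``reject_mask``
    marks (trial, channel) epochs excluded from statistics, with reason
    codes in ``reject_reasons``.
    """

    data: np.ndarray
    fs: float
    event: str
    t_start_ms: float
    trial_ids: np.ndarray
    patient_id: str = ""
    channels: list = field(default_factory=list)
    units: str = "uV"
    referenced: bool = False
    downsampled: bool = False
    smoothed: bool = False
    edge_trim_ms: float = 0.0
    reject_mask: np.ndarray | None = None
    reject_reasons: list = field(default_factory=list)
    dropped_trials: list = field(default_factory=list)
    baseline_stats: tuple | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if self.reject_mask is None:
            self.reject_mask = np.zeros(self.data.shape[:2], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def t_axis(self) -> np.ndarray:
        """Time in ms relative to the event, one entry per sample."""
        return self.t_start_ms + np.arange(self.n_times) * 1000.0 / self.fs

    def time_slice(self, start_ms: float, end_ms: float) -> slice:
        """Half-open [start, end) window as a sample slice."""
        t = self.t_axis
        i0 = int(np.searchsorted(t, start_ms - 1e-9))
        i1 = int(np.searchsorted(t, end_ms - 1e-9))
        return slice(i0, i1)

    def add_rejections(self, mask: np.ndarray, reason: str):
        """Flag epochs; reasons accumulate even if already flagged by an
        earlier rule."""
        have = {(t, c) for t, c, r in self.reject_reasons if r == reason}
        for ti, ci in np.argwhere(mask):
            if (int(ti), int(ci)) not in have:
                self.reject_reasons.append((int(ti), int(ci), reason))
        self.reject_mask |= mask

    def reasons_for(self, trial_idx: int, ch_idx: int) -> list:
        return [r for t, c, r in self.reject_reasons
                if t == trial_idx and c == ch_idx]


def common_median_reference(recording: Recording) -> Recording:
    """Subtract the per-sample median across channels from every channel.

    More robust to large-amplitude transients than the common average.
    Idempotent up to floating point: the median of the referenced data is
    exactly zero at every sample.
    """
    if recording.n_channels < 2:
        raise ValueError("common median reference requires >= 2 channels")
    med = np.median(recording.samples, axis=0, keepdims=True)
    return Recording(
        samples=recording.samples - med,
        fs=recording.fs,
        channels=list(recording.channels),
        patient_id=recording.patient_id,
        referenced=True,
    )


def extract_epochs(
    recording: Recording,
    trial_table,
    event: str = "hand_on",
    span=(-3000.0, 1000.0),
) -> EpochSet:
    """Slice fixed windows around each trial's event sample.

    ``span`` is (start, end) in ms relative to the event, half-open.
    Trials whose span exceeds the recording bounds are dropped and logged
    in ``dropped_trials``.  No filtering happens here: epoch values equal
    the corresponding recording slice exactly.
    """
    if event not in trial_table.columns:
        raise ValueError(f"event column {event!r} not in trial table")
    fs = recording.fs
    i0 = int(round(span[0] / 1000.0 * fs))
    i1 = int(round(span[1] / 1000.0 * fs))
    if i1 <= i0:
        raise ValueError("empty epoch span")
    slices, trial_ids, dropped = [], [], []
    for _, row in trial_table.iterrows():
        ev = int(row[event])
        lo, hi = ev + i0, ev + i1
        if lo < 0 or hi > recording.n_samples:
            dropped.append(int(row["trial_id"]))
            continue
        slices.append(recording.samples[:, lo:hi])
        trial_ids.append(int(row["trial_id"]))
    if not slices:
        data = np.zeros((0, recording.n_channels, i1 - i0))
    else:
        data = np.stack(slices).astype(np.float64)
    return EpochSet(
        data=data,
        fs=fs,
        event=event,
        t_start_ms=i0 * 1000.0 / fs,
        trial_ids=np.asarray(trial_ids, dtype=int),
        patient_id=recording.patient_id,
        channels=list(recording.channels),
        referenced=recording.referenced,
        dropped_trials=dropped,
    )


def _check_raw(epochs: EpochSet, op: str):
    if epochs.units != "uV":
        raise ValueError(f"{op} must run on raw uV epochs, got {epochs.units!r}")
    if epochs.downsampled:
        raise ValueError(f"{op} must run before downsampling")


def detect_artifacts(epochs: EpochSet, thresholds: dict | None = None) -> EpochSet:
    """Flag (trial, channel) epochs violating the four rejection rules.

    Rules (reason codes): 60 Hz Welch PSD above ``line_noise_psd``
    ("line_noise"); max |dV/dt| above ``transient_slope`` ("transient");
    variance below ``min_variance`` ("variance"); any sample at the
    amplifier saturation code value ("saturation").  Runs on raw
    unreferenced microvolt epochs at native resolution.
    """
    _check_raw(epochs, "detect_artifacts")
    if epochs.referenced:
        raise ValueError(
            "artifact detection must run before the common-median reference "
            "(flat and saturation rules act on raw code values)"
        )
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(thresholds or {})
    out = replace(epochs, data=epochs.data,
                  reject_mask=epochs.reject_mask.copy(),
                  reject_reasons=list(epochs.reject_reasons))
    x = epochs.data
    fs = epochs.fs
    if x.shape[0] == 0:
        return out
    # (a) 60 Hz line-noise power
    nperseg = min(int(fs), x.shape[-1])
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )
    i60 = int(np.argmin(np.abs(freqs - 60.0)))
    out.add_rejections(psd[..., i60] > thr["line_noise_psd"], "line_noise")
    # (b) transient slope, uV/ms at native resolution
    slope = np.abs(np.diff(x, axis=-1)).max(axis=-1) * fs / 1000.0
    out.add_rejections(slope > thr["transient_slope"], "transient")
    # (c) flat: variance below 1 uV^2
    out.add_rejections(x.var(axis=-1) < thr["min_variance"], "variance")
    # (d) amplifier saturation, equality at the +/- code limit
    sat = (np.abs(np.abs(x) - thr["saturation"]) < 0.5).any(axis=-1)
    out.add_rejections(sat, "saturation")
    return out


def mad_outlier_flag(epochs: EpochSet, k: float = 3.0) -> EpochSet:
    """Flag epochs containing spike/epileptiform outliers ("mad_outlier").

    Per channel, each retained epoch is summarized by its peak absolute
    deviation from the channel median, ``m_e = max_t |v - median|``; an
    epoch is flagged when ``m_e`` exceeds the median of the peaks by more
    than ``k`` scaled MADs (1.4826 x raw MAD, the normal-consistent
    convention).  The reference population is the channel's retained
    epochs for the session.  If the peak MAD is zero (degenerate channel)
    the rule falls back to flagging any epoch whose peak differs from the
    median peak; identical epochs everywhere are therefore never flagged.
    """
    _check_raw(epochs, "mad_outlier_flag")
    out = replace(epochs, data=epochs.data,
                  reject_mask=epochs.reject_mask.copy(),
                  reject_reasons=list(epochs.reject_reasons))
    if np.isinf(k):
        return out
    x = epochs.data
    flag = np.zeros(epochs.reject_mask.shape, dtype=bool)
    for ci in range(epochs.n_channels):
        keep = ~epochs.reject_mask[:, ci]
        if keep.sum() < 3:
            continue
        vals = x[keep, ci, :]
        center = np.median(vals)
        peaks = np.abs(x[:, ci, :] - center).max(axis=-1)  # all trials
        ref = peaks[keep]
        med = np.median(ref)
        mad = np.median(np.abs(ref - med))
        if mad == 0.0:
            flag[:, ci] = keep & (peaks != med)
        else:
            flag[:, ci] = keep & (peaks > med + k * MAD_SCALE * mad)
    out.add_rejections(flag, "mad_outlier")
    return out


def downsample(obj, target_fs: float = 500.0):
    """Anti-alias filter and decimate to ``target_fs``.

    Accepts a Recording or an EpochSet; the native rate must be an
    integer multiple of the target.  Uses a zero-phase FIR anti-aliasing
    filter (cutoff below the target Nyquist, unit DC gain).
    """
    fs = obj.fs
    ratio = fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"sampling rate {fs} is not an integer multiple of {target_fs}"
        )
    if q == 1:
        return obj
    if isinstance(obj, Recording):
        ds = signal.decimate(obj.samples, q, axis=-1, ftype="fir",
                             zero_phase=True)
        return Recording(samples=ds, fs=target_fs, channels=list(obj.channels),
                         patient_id=obj.patient_id, referenced=obj.referenced)
    if isinstance(obj, EpochSet):
        ds = signal.decimate(obj.data, q, axis=-1, ftype="fir",
                             zero_phase=True)
        return replace(
            obj, data=ds, fs=target_fs, downsampled=True,
            reject_mask=obj.reject_mask.copy(),
            reject_reasons=list(obj.reject_reasons),
        )
    raise TypeError(f"cannot downsample {type(obj).__name__}")
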