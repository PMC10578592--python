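"""Synthetic tonic-pain study generator with known ground truth.

Emulates the psychophysical task and the intracranial recordings end to
end: an adaptive Bayesian staircase picks each trial's temperature, a
logistic observer produces the binary "was that painful?" report and a
noisy graded 0-10 rating, and per-patient multichannel LFPs are
synthesized whose 70-150 Hz band power around the hand-on / hand-off
events is modulated by region-specific effect sizes tied to the
observer's latent pain drive.  Line noise, transients, flat channels,
amplifier saturation and spike outliers can be injected at known
locations so that every preprocessing rejection rule can be scored
against ground truth.

Timeline: each trial occupies a fixed slot of ``hand_on_duration + iti``
seconds, with the hand-on event placed ``iti - 1.5`` s into the slot so
that the -3..-2 s pre-event baseline always falls inside the preceding
inter-trial interval and a full post-event epoch fits before the slot
ends.  Total duration is exactly ``n_trials * (hand_on_duration + iti)``
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.special import expit

from .io import ChannelMeta, Recording, validate_trial_table

__all__ = [
    "ObserverModel",
    "StaircaseState",
    "GroundTruth",
    "ArtifactRecord",
    "StudyData",
    "quest_propose",
    "quest_update",
    "simulate_observer",
    "synth_lfp",
    "inject_artifacts",
    "simulate_study",
    "DEFAULT_REGION_PATIENT_COUNTS",
    "ARTIFACT_KINDS",
]

# Region -> number of unique patients carrying contacts there, mirroring the
# sampling of a 20-patient sEEG cohort (amygdala through posterior STS).
DEFAULT_REGION_PATIENT_COUNTS = {
    "Amyg": 11, "CG": 20, "FuG": 9, "Hipp": 18, "IFG": 17, "INS": 12,
    "ITG": 6, "MFG": 17, "MTG": 19, "OFC": 18, "PrG": 3, "SFG": 13,
    "STG": 11, "Str": 10, "Tha": 5, "pSTS": 3,
}

ARTIFACT_KINDS = ("line_noise", "transient", "flat", "saturation", "spike_outlier")

# rejection-rule reason code that must fire for each injected kind
KIND_TO_REASON = {
    "line_noise": "line_noise",
    "transient": "transient",
    "flat": "variance",
    "saturation": "saturation",
    "spike_outlier": "mad_outlier",
}

SATURATION_UV = 6553.0


# --------------------------------------------------------------------- #
# observer
# --------------------------------------------------------------------- #

@dataclass(frozen=True)
class ObserverModel:
    """Logistic psychometric observer for the thermal pain task.

    ``threshold_temp`` is the temperature (deg C) at which the observer
    reports pain with probability 0.5 (before lapses); ``slope`` (1/degC)
    is the psychometric steepness; the graded rating grows linearly at
    ``vas_gain`` VAS units per degC above threshold with gaussian
    reporting noise, clamped to [0, 10] and rounded to integers.
    """

    threshold_temp: float
    slope: float = 2.0
    vas_gain: float = 1.5
    vas_noise_sd: float = 0.8
    lapse_rate: float = 0.02

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("psychometric slope must be positive")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse rate must lie in [0, 0.1]")

    def latent_pain(self, temperature) -> float:
        """Expected latent pain drive in (0, 1): the lapse-free logistic."""
        return expit((np.asarray(temperature, float) - self.threshold_temp) * self.slope)

    def response_probability(self, temperature) -> float:
        """P("yes") including symmetric lapses."""
        lp = self.latent_pain(temperature)
        return self.lapse_rate / 2.0 + (1.0 - self.lapse_rate) * lp

    def draw_trial(self, temperature: float, rng):
        """Draw one trial: (binary, vas, latent).

        The observer perceives ``x = T - threshold + eps`` with
        ``eps ~ Logistic(0, 1/slope)`` (perceptual trial-to-trial noise),
        reports pain when ``x > 0`` — which makes the marginal
        psychometric exactly ``logistic((T - threshold) * slope)`` — and
        rates ``vas_gain * max(0, x)`` with gaussian reporting noise,
        clamped to [0, 10] and rounded to integers.  The returned latent
        drive ``logistic(slope * x)`` is the quantity the neural effect
        sizes multiply: both reports and the HFA modulation share the
        same percept, so HFA carries information about the report beyond
        the temperature itself.
        """
        u = rng.random()
        eps = (np.log(u) - np.log1p(-u)) / self.slope  # Logistic(0, 1/slope)
        x = temperature - self.threshold_temp + eps
        binary = int(x > 0)
        if self.lapse_rate > 0 and rng.random() < self.lapse_rate:
            binary = int(rng.random() < 0.5)
        raw = self.vas_gain * max(0.0, x) + rng.normal(0.0, self.vas_noise_sd)
        vas = int(round(min(10.0, max(0.0, raw))))
        latent = float(expit(self.slope * x))
        return binary, vas, latent


def simulate_observer(model: ObserverModel, temperature: float, rng):
    """Draw one (binary response, VAS rating) pair.

    Marginally the binary report is Bernoulli in the lapse-adjusted
    logistic psychometric; see :meth:`ObserverModel.draw_trial` for the
    shared-percept construction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    binary, vas, _ = model.draw_trial(temperature, rng)
    return binary, vas


# --------------------------------------------------------------------- #
# adaptive staircase
# --------------------------------------------------------------------- #

@dataclass(frozen=True)
class StaircaseState:
    """Grid-based Bayesian threshold staircase.

    Maintains a posterior over candidate thresholds on ``temperature_grid``
    under a logistic psychometric of assumed steepness ``assumed_slope``;
    the proposed temperature is the posterior-mean threshold quantized to
    the grid.
    """

    temperature_grid: np.ndarray
    posterior: np.ndarray
    trial_history: tuple = ()
    assumed_slope: float = 2.0

    @classmethod
    def initialize(cls, temperature_grid, prior=None, assumed_slope: float = 2.0):
        grid = np.asarray(temperature_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("temperature grid is empty")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if prior is None:
            prior = np.full(grid.size, 1.0 / grid.size)
        prior = np.asarray(prior, dtype=float)
        prior = prior / prior.sum()
        return cls(temperature_grid=grid, posterior=prior,
                   assumed_slope=assumed_slope)

    @property
    def posterior_mean(self) -> float:
        return float(self.temperature_grid @ self.posterior)

    @property
    def posterior_mode(self) -> float:
        return float(self.temperature_grid[int(np.argmax(self.posterior))])


def quest_propose(state: StaircaseState) -> float:
    """Next temperature: the posterior-mean threshold snapped to the grid."""
    if state.temperature_grid.size == 0:
        raise ValueError("temperature grid is empty")
    mean = state.posterior_mean
    idx = int(np.argmin(np.abs(state.temperature_grid - mean)))
    return float(state.temperature_grid[idx])


def quest_update(state: StaircaseState, temperature: float, response) -> StaircaseState:
    """Bayesian posterior update after one trial.

    The likelihood of a "yes" at temperature T given candidate threshold
    theta is ``logistic((T - theta) * assumed_slope)``.
    """
    if response not in (0, 1, True, False):
        raise ValueError(f"response must be binary, got {response!r}")
    response = int(response)
    p_yes = expit((temperature - state.temperature_grid) * state.assumed_slope)
    like = p_yes if response == 1 else 1.0 - p_yes
    post = state.posterior * like
    total = post.sum()
    if total <= 0:
        # all mass annihilated by numerical underflow; fall back to likelihood
        post = like / like.sum()
    else:
        post = post / total
    return replace(
        state,
        posterior=post,
        trial_history=state.trial_history + ((float(temperature), response),),
    )


# --------------------------------------------------------------------- #
# ground truth bookkeeping
# --------------------------------------------------------------------- #

@dataclass(frozen=True)
class ArtifactRecord:
    patient_id: str
    trial_id: int
    channel: int
    kind: str
    start: int  # absolute sample index
    stop: int


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    region_effects: dict = field(default_factory=dict)
    artifact_log: list = field(default_factory=list)
    observer_params: dict = field(default_factory=dict)
    latent_pain: dict = field(default_factory=dict)
    regions: list = field(default_factory=list)

    def effect_for(self, region, event=None, window=None) -> float:
        if event is None:
            return sum(
                e for (r, _, _), e in self.region_effects.items() if r == region
            )
        return self.region_effects.get((region, event, tuple(window)), 0.0)


@dataclass
class StudyData:
    """A complete simulated study: per-patient recordings and trials."""

    recordings: dict  # patient_id -> Recording
    trial_tables: dict  # patient_id -> DataFrame
    ground_truth: GroundTruth
    fs: float

    @property
    def patient_ids(self):
        return list(self.recordings)

    def all_trials(self) -> pd.DataFrame:
        return pd.concat(self.trial_tables.values(), ignore_index=True)

    def save(self, directory) -> None:
        """Write per-patient HDF5+JSON recordings, TSV trial tables, and
        the ground-truth JSON into ``directory``."""
        import json
        from pathlib import Path

        from .io import write_recording, write_trial_table

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for pid, rec in self.recordings.items():
            write_recording(rec, d / f"{pid}.h5")
            write_trial_table(self.trial_tables[pid], d / f"{pid}_trials.tsv")
        gt = self.ground_truth
        payload = dict(
            fs=self.fs,
            regions=gt.regions,
            region_effects=[
                dict(region=r, event=e, window=list(w), effect=v)
                for (r, e, w), v in gt.region_effects.items()
            ],
            artifact_log=[vars(a) for a in gt.artifact_log],
            observer_params={
                pid: vars(m) for pid, m in gt.observer_params.items()
            },
            latent_pain={pid: list(map(float, v))
                         for pid, v in gt.latent_pain.items()},
        )
        (d / "ground_truth.json").write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, directory) -> "StudyData":
        import json
        from pathlib import Path

        from .io import read_recording, read_trial_table

        d = Path(directory)
        recordings, trial_tables = {}, {}
        for h5 in sorted(d.glob("P*.h5")):
            pid = h5.stem
            recordings[pid] = read_recording(h5)
            trial_tables[pid] = read_trial_table(d / f"{pid}_trials.tsv")
        if not recordings:
            raise FileNotFoundError(f"no patient recordings under {d}")
        gt = GroundTruth()
        gt_path = d / "ground_truth.json"
        fs = next(iter(recordings.values())).fs
        if gt_path.exists():
            payload = json.loads(gt_path.read_text())
            fs = payload.get("fs", fs)
            gt = GroundTruth(
                region_effects={
                    (e["region"], e["event"], tuple(e["window"])): e["effect"]
                    for e in payload.get("region_effects", [])
                },
                artifact_log=[ArtifactRecord(**a)
                              for a in payload.get("artifact_log", [])],
                observer_params={
                    pid: ObserverModel(**m)
                    for pid, m in payload.get("observer_params", {}).items()
                },
                latent_pain={pid: np.asarray(v) for pid, v in
                             payload.get("latent_pain", {}).items()},
                regions=payload.get("regions", []),
            )
        return cls(recordings=recordings, trial_tables=trial_tables,
                   ground_truth=gt, fs=fs)


# --------------------------------------------------------------------- #
# LFP synthesis
# --------------------------------------------------------------------- #

def _pink_split(n, fs, rng, f_floor=0.3, band=(70.0, 150.0), n_channels=1):
    """Pink-noise realizations split into their 70-150 Hz component and
    the rest (both unit-free; caller rescales).

    Returns ``(out_part, band_part)`` with shape (n_channels, n); single
    precision throughout (the recording's storage dtype).
    """
    from scipy.fft import irfft, rfft

    white = rng.standard_normal((n_channels, n)).astype(np.float32)
    coef = rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = (1.0 / np.sqrt(np.maximum(f, f_floor))).astype(np.float32)
    scale[0] = 0.0
    coef = coef * scale
    in_band = (f >= band[0]) & (f <= band[1])
    band_part = irfft(coef * in_band, n, axis=-1)
    out_part = irfft(coef * ~in_band, n, axis=-1)
    return out_part, band_part


def _envelope_calibration(fs, noise_sd, band=(70.0, 150.0), smooth_ms=300.0,
                          seed=12345, dur=60.0, analysis_fs=500.0):
    """Empirical smoothed-envelope statistics of the background noise.

    Emulates the analysis chain (decimation to ``analysis_fs``, 70-150 Hz
    zero-phase Butterworth, Hilbert magnitude, moving average) on a long
    background realization and returns ``(m0, v0)``: the envelope mean
    and its typical within-1-s-segment SD.  These translate a requested
    z-unit effect into the multiplicative band-power gain that produces
    it in the pipeline's z units.
    """
    from scipy.signal import decimate

    rng = np.random.default_rng(seed)
    n = int(dur * fs)
    out_part, band_part = _pink_split(n, fs, rng, band=band)
    x = (out_part + band_part)[0].astype(np.float64)
    x *= noise_sd / x.std()
    q = int(round(fs / analysis_fs))
    if q > 1 and abs(fs / analysis_fs - q) < 1e-9:
        x = decimate(x, q, ftype="fir", zero_phase=True)
        fs_eff = analysis_fs
    else:
        fs_eff = fs
    sos = butter(4, band, btype="bandpass", fs=fs_eff, output="sos")
    env = np.abs(hilbert(sosfiltfilt(sos, x)))
    w = int(round(smooth_ms / 1000.0 * fs_eff))
    kernel = np.ones(w) / w
    sm = np.convolve(env, kernel, mode="valid")
    m0 = float(sm.mean())
    seg = int(fs_eff)  # 1 s segments, matching the baseline window length
    n_seg = sm.size // seg
    sds = sm[: n_seg * seg].reshape(n_seg, seg).std(axis=1)
    v0 = float(np.mean(sds))
    return m0, v0


_CALIB_CACHE: dict = {}


def _calibration(fs, noise_sd):
    key = (round(fs, 3), round(noise_sd, 6))
    if key not in _CALIB_CACHE:
        _CALIB_CACHE[key] = _envelope_calibration(fs, noise_sd)
    return _CALIB_CACHE[key]


def _gain_profile(n, fs, events, effects, latent, ramp_ms=50.0, z_to_gain=0.2):
    """Multiplicative gain on the 70-150 Hz band component.

    ``effects`` maps ``(event, (start_ms, end_ms)) -> z-unit effect``;
    the gain in each window is ``1 + effect * latent[trial] * z_to_gain``
    with raised-cosine on/off ramps.
    """
    g = np.ones(n)
    ramp = int(round(ramp_ms / 1000.0 * fs))
    up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp))) if ramp > 1 else np.ones(0)
    for (event, window), eff in effects.items():
        if eff == 0.0:
            continue
        start_ms, end_ms = window
        for trial, ev_sample in enumerate(events[event]):
            amp = eff * latent[trial] * z_to_gain
            lo = ev_sample + int(round(start_ms / 1000.0 * fs))
            hi = ev_sample + int(round(end_ms / 1000.0 * fs))
            lo, hi = max(lo, 0), min(hi, n)
            if hi <= lo:
                continue
            prof = np.full(hi - lo, amp)
            k = min(ramp, prof.size // 2)
            if k > 1:
                prof[:k] *= up[:k]
                prof[-k:] *= up[:k][::-1]
            g[lo:hi] += prof
    return np.maximum(g, 0.05)


def synth_lfp(
    trials: pd.DataFrame,
    channels: list,
    effects: dict,
    latent: np.ndarray,
    fs: float = 1000.0,
    n_samples: int | None = None,
    noise_sd: float = 40.0,
    line_amp: float = 5.0,
    rng=None,
    patient_id: str = "",
) -> Recording:
    """Synthesize one patient's multichannel LFP.

    Background is 1/f noise plus a (sub-threshold) 60 Hz line component;
    the 70-150 Hz band component is multiplied by an event-locked gain so
    that the post-pipeline z-scored envelope in an effect window moves by
    approximately ``effect * latent`` z units.

    Parameters
    ----------
    effects : dict
        ``(region, event, (start_ms, end_ms)) -> effect`` (z units per unit
        latent pain).  Regions must exist among ``channels``.
    latent : array
        Per-trial latent pain drive in [0, 1].
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    present = {c.region for c in channels}
    for (region, event, _w) in effects:
        if region not in present:
            raise ValueError(f"effect region {region!r} has no channel")
        if event not in ("hand_on", "hand_off"):
            raise ValueError(f"unknown event {event!r}")
    if n_samples is None:
        n_samples = int(trials["hand_off"].max() + 5 * fs)
    events = {
        "hand_on": trials["hand_on"].to_numpy(),
        "hand_off": trials["hand_off"].to_numpy(),
    }
    m0, v0 = _calibration(fs, noise_sd)
    z_to_gain = v0 / m0
    t = np.arange(n_samples, dtype=np.float32) / np.float32(fs)
    out_all, band_all = _pink_split(n_samples, fs, rng,
                                    n_channels=len(channels))
    data = np.empty((len(channels), n_samples), dtype=np.float32)
    for i, ch in enumerate(channels):
        out_part, band_part = out_all[i], band_all[i]
        raw_sd = np.sqrt(out_part.var(dtype=np.float64)
                         + band_part.var(dtype=np.float64))
        scale = np.float32(noise_sd / raw_sd)
        out_part = out_part * scale
        band_part = band_part * scale
        ch_eff = {
            (ev, w): e for (r, ev, w), e in effects.items() if r == ch.region
        }
        g = _gain_profile(n_samples, fs, events, ch_eff, latent,
                          z_to_gain=z_to_gain).astype(np.float32)
        phase = np.float32(rng.uniform(0, 2 * np.pi))
        line = (np.float32(line_amp)
                * np.sin(np.float32(2 * np.pi * 60.0) * t + phase))
        data[i] = out_part + g * band_part + line
    return Recording(samples=data, fs=fs, channels=list(channels),
                     patient_id=patient_id)


# --------------------------------------------------------------------- #
# artifact injection
# --------------------------------------------------------------------- #

def _epoch_peaks(samples_ch, events, fs, span_ms=(-1000, 1000)):
    lo = int(span_ms[0] / 1000 * fs)
    hi = int(span_ms[1] / 1000 * fs)
    med = float(np.median(samples_ch))
    peaks = []
    for ev in events:
        seg = samples_ch[max(ev + lo, 0): ev + hi]
        if seg.size:
            peaks.append(np.abs(seg - med).max())
    return np.asarray(peaks), med


def inject_artifacts(
    recording: Recording,
    trials: pd.DataFrame,
    artifact_spec,
    rng=None,
    margin: float = 3.0,
):
    """Insert artifacts that exceed the rejection thresholds by ``margin``.

    ``artifact_spec`` is a sequence of kinds (each injected once) or a
    ``{kind: count}`` mapping.  Artifacts are placed inside the +/-1 s
    analysis epoch around randomly chosen hand-on events, each on a
    randomly chosen channel, and logged.

    Returns a new Recording and the list of :class:`ArtifactRecord`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(artifact_spec, dict):
        spec = [(k, int(n)) for k, n in artifact_spec.items()]
    else:
        spec = [(k, 1) for k in artifact_spec]
    for kind, _ in spec:
        if kind not in ARTIFACT_KINDS:
            raise ValueError(
                f"unknown artifact kind {kind!r}; known: {ARTIFACT_KINDS}"
            )
    fs = recording.fs
    samples = recording.samples.astype(np.float32, copy=True)
    events = trials["hand_on"].to_numpy()
    trial_ids = trials["trial_id"].to_numpy()
    log = []
    # avoid stacking two artifacts in one (trial, channel) epoch
    used = set()
    candidates = [(ti, ci) for ti in range(len(events))
                  for ci in range(recording.n_channels)]
    order = rng.permutation(len(candidates))
    it = iter([candidates[i] for i in order])

    def next_slot():
        for ti, ci in it:
            if (ti, ci) not in used:
                used.add((ti, ci))
                return ti, ci
        raise ValueError("not enough trial x channel slots for artifacts")

    for kind, count in spec:
        for _ in range(count):
            ti, ci = next_slot()
            ev = int(events[ti])
            # epoch-wide artifacts must cover the widest extraction span
            epoch_lo = max(ev - int(3.2 * fs), 0)
            epoch_hi = min(ev + int(1.2 * fs), samples.shape[1])
            if kind == "line_noise":
                # 60 Hz power above 100 uV^2/Hz in a 1 s Hann Welch segment
                # (equivalent noise bandwidth 1.5 * 1 Hz)
                amp = np.sqrt(2.0 * 100.0 * 1.5 * margin)
                tt = np.arange(epoch_lo, epoch_hi) / fs
                samples[ci, epoch_lo:epoch_hi] += (
                    amp * np.sin(2 * np.pi * 60.0 * tt)
                ).astype(np.float32)
                lo, hi = epoch_lo, epoch_hi
            elif kind == "transient":
                # one-sample step whose slope exceeds 300 uV/ms, decaying back
                amp = 300.0 * margin * 1000.0 / fs
                start = ev + int(rng.integers(-int(0.9 * fs), int(0.7 * fs)))
                decay = np.exp(-np.arange(int(0.05 * fs)) / (0.01 * fs))
                seg = slice(start, start + decay.size)
                samples[ci, seg] += (amp * decay[: samples[ci, seg].size]).astype(
                    np.float32
                )
                lo, hi = start, start + decay.size
            elif kind == "flat":
                med = float(np.median(samples[ci, epoch_lo:epoch_hi]))
                samples[ci, epoch_lo:epoch_hi] = med
                lo, hi = epoch_lo, epoch_hi
            elif kind == "saturation":
                sign = 1.0 if rng.random() < 0.5 else -1.0
                start = ev + int(rng.integers(-int(0.9 * fs), int(0.8 * fs)))
                width = int(0.1 * fs)
                samples[ci, start:start + width] = sign * SATURATION_UV
                lo, hi = start, start + width
            elif kind == "spike_outlier":
                # smooth bump: beyond 3 scaled MADs of the channel's epoch
                # peaks, but too slow for the slope rule
                peaks, med = _epoch_peaks(samples[ci], events, fs)
                mad = np.median(np.abs(peaks - np.median(peaks)))
                thr = np.median(peaks) + 3.0 * 1.4826 * mad
                amp = thr * margin - np.median(peaks)
                center = ev + int(rng.integers(-int(0.8 * fs), int(0.8 * fs)))
                sigma = 0.025 * fs
                k = int(4 * sigma)
                x = np.arange(-k, k + 1)
                bump = amp * np.exp(-0.5 * (x / sigma) ** 2)
                seg = slice(center - k, center + k + 1)
                samples[ci, seg] += bump[: samples[ci, seg].size].astype(np.float32)
                lo, hi = center - k, center + k + 1
            log.append(
                ArtifactRecord(
                    patient_id=recording.patient_id,
                    trial_id=int(trial_ids[ti]),
                    channel=ci,
                    kind=kind,
                    start=int(lo),
                    stop=int(hi),
                )
            )
    out = Recording(samples=samples, fs=fs, channels=list(recording.channels),
                    patient_id=recording.patient_id,
                    referenced=recording.referenced)
    return out, log


# --------------------------------------------------------------------- #
# full study
# --------------------------------------------------------------------- #

def _assign_regions(region_counts, patient_ids, rng):
    """Assign each region to the requested number of unique patients."""
    n = len(patient_ids)
    assignment = {pid: [] for pid in patient_ids}
    for region, count in region_counts.items():
        if count > n:
            raise ValueError(
                f"region {region!r} requests {count} patients but only {n} exist"
            )
        chosen = rng.choice(n, size=count, replace=False)
        for idx in chosen:
            assignment[patient_ids[idx]].append(region)
    return assignment


def simulate_study(
    n_patients: int = 20,
    region_counts: dict | None = None,
    trials_per_patient: int = 20,
    channels_per_region=1,
    fs: float = 1000.0,
    effects: dict | None = None,
    artifacts=None,
    artifact_margin: float = 3.0,
    hand_on_duration: float = 10.0,
    iti: float = 5.0,
    noise_sd: float = 40.0,
    line_amp: float = 5.0,
    temperature_grid=None,
    threshold_mean: float = 44.5,
    threshold_sd: float = 1.0,
    observer_slope: float = 2.0,
    seed: int | None = 0,
) -> StudyData:
    """Generate a complete synthetic study.

    Per patient: an adaptive staircase selects ``trials_per_patient``
    temperatures for a logistic observer (threshold ~ N(threshold_mean,
    threshold_sd), clipped to the grid interior); LFPs are synthesized for
    one or more contacts in each of the patient's assigned regions, with
    70-150 Hz band power around the events modulated by ``effects``
    (``(region, event, (start_ms, end_ms)) -> z units per unit latent
    pain``); requested artifacts are injected and logged.

    ``artifacts`` is a per-patient spec passed to :func:`inject_artifacts`
    (``None`` disables injection).
    """
    if region_counts is None:
        region_counts = DEFAULT_REGION_PATIENT_COUNTS
    if temperature_grid is None:
        temperature_grid = np.arange(40.0, 48.5, 0.5)
    temperature_grid = np.asarray(temperature_grid, dtype=float)
    effects = dict(effects or {})
    if iti < 4.6:
        raise ValueError("iti must be >= 4.6 s so baselines stay clean")
    slot = hand_on_duration + iti
    pre = iti - 1.5  # hand-on offset within the slot
    n_samples = int(round(trials_per_patient * slot * fs))

    root = np.random.SeedSequence(seed)
    patient_seeds = root.spawn(n_patients + 1)
    assign_rng = np.random.default_rng(patient_seeds[-1])
    patient_ids = [f"P{i:02d}" for i in range(n_patients)]
    region_of = _assign_regions(region_counts, patient_ids, assign_rng)

    truth = GroundTruth(
        region_effects={(r, e, tuple(w)): v for (r, e, w), v in effects.items()},
        regions=sorted(region_counts),
    )
    recordings, trial_tables = {}, {}
    for pid, pseed in zip(patient_ids, patient_seeds[:-1]):
        rng = np.random.default_rng(pseed)
        thr = float(
            np.clip(
                rng.normal(threshold_mean, threshold_sd),
                temperature_grid[1],
                temperature_grid[-2],
            )
        )
        observer = ObserverModel(threshold_temp=thr, slope=observer_slope)
        truth.observer_params[pid] = observer

        state = StaircaseState.initialize(
            temperature_grid, assumed_slope=observer_slope
        )
        rows, latents = [], []
        for k in range(trials_per_patient):
            temp = quest_propose(state)
            binary, vas, latent = observer.draw_trial(temp, rng)
            latents.append(latent)
            state = quest_update(state, temp, binary)
            hand_on = int(round((k * slot + pre) * fs))
            hand_off = hand_on + int(round(hand_on_duration * fs))
            rows.append(
                dict(
                    patient_id=pid, trial_id=k, temperature=temp,
                    hand_on=hand_on, hand_off=hand_off,
                    binary_response=binary, vas=vas,
                )
            )
        trials = validate_trial_table(pd.DataFrame(rows), fs=fs,
                                      hand_on_duration=hand_on_duration)
        latent = np.asarray(latents)
        truth.latent_pain[pid] = latent

        channels = []
        for region in sorted(region_of[pid]):
            n_ch = (channels_per_region.get(region, 1)
                    if isinstance(channels_per_region, dict)
                    else channels_per_region)
            for j in range(n_ch):
                channels.append(
                    ChannelMeta(
                        name=f"{pid}-{region}-{j + 1}",
                        atlas_label=f"{region}_L_1_{j + 1}",
                    )
                )
        rec = synth_lfp(
            trials, channels, effects, latent, fs=fs, n_samples=n_samples,
            noise_sd=noise_sd, line_amp=line_amp, rng=rng, patient_id=pid,
        )
        if artifacts is not None:
            rec, log = inject_artifacts(rec, trials, artifacts, rng=rng,
                                        margin=artifact_margin)
            truth.artifact_log.extend(log)
        recordings[pid] = rec
        trial_tables[pid] = trials
    return StudyData(recordings=recordings, trial_tables=trial_tables,
                     ground_truth=truth, fs=fs)
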