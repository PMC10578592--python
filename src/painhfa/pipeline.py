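"""End-to-end orchestration: recordings -> features -> window models.

``preprocess_patient`` turns one patient's raw recording into z-scored
HFA epochs per event (artifact detection on raw epochs, common-median
reference, downsampling to 500 Hz, filter-Hilbert, smoothing, baseline
z-scoring).  ``analyze_study`` runs the full region x event x window x
family grid of mixed models with permutation significance and returns a
tidy results table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hfa as hfa_mod
from . import preprocess as pre
from .io import filter_regions
from .modeling import PainGlme, build_features, window_grid
from .synth import StudyData

__all__ = ["preprocess_patient", "assemble_features", "analyze_study"]

EVENTS = ("hand_on", "hand_off")
# pipeline epoch span: 100 ms wider than the -3000..1000 ms statistical
# span so the baseline and the latest window are clear of filter edges
PIPELINE_SPAN = (-3100.0, 1100.0)
EDGE_TRIM_MS = 100.0


def preprocess_patient(
    recording,
    trial_table,
    events=EVENTS,
    span=PIPELINE_SPAN,
    target_fs: float = 500.0,
    thresholds: dict | None = None,
    mad_k: float = 3.0,
    band=(70.0, 150.0),
    smooth_ms: float = 300.0,
    baseline=(-3000.0, -2000.0),
) -> dict:
    """Raw recording -> z-scored smoothed HFA epochs, one set per event."""
    referenced = pre.common_median_reference(recording)
    out = {}
    for event in events:
        raw_ep = pre.extract_epochs(recording, trial_table, event=event,
                                    span=span)
        raw_ep = pre.detect_artifacts(raw_ep, thresholds=thresholds)
        raw_ep = pre.mad_outlier_flag(raw_ep, k=mad_k)
        ep = pre.extract_epochs(referenced, trial_table, event=event,
                                span=span)
        ep.reject_mask = raw_ep.reject_mask.copy()
        ep.reject_reasons = list(raw_ep.reject_reasons)
        ep = pre.downsample(ep, target_fs=target_fs)
        env = hfa_mod.bandpass_hilbert_amplitude(ep, band=band,
                                                 edge_trim_ms=EDGE_TRIM_MS)
        env = hfa_mod.smooth_envelope(env, window_ms=smooth_ms)
        out[event] = hfa_mod.zscore_baseline(env, baseline=baseline)
    return out


def assemble_features(
    hfa_by_patient: dict,
    trials_by_patient: dict,
    channel_idx_by_patient: dict,
    window,
) -> pd.DataFrame:
    """Concatenate one region window's features over patients.

    Patients contributing zero retained trials for the region are
    dropped (the model sees only contributing patients).
    """
    parts = []
    for pid, ep in hfa_by_patient.items():
        idx = channel_idx_by_patient.get(pid)
        if idx is None or len(idx) == 0:
            continue
        feats = build_features(ep, trials_by_patient[pid], idx, window)
        if len(feats):
            parts.append(feats)
    if not parts:
        return pd.DataFrame()
    df = pd.concat(parts, ignore_index=True)
    df.attrs["window"] = tuple(window)
    return df


def analyze_study(
    study: StudyData,
    events=EVENTS,
    families=("binomial", "gaussian"),
    windows: dict | None = None,
    n_perm: int = 1000,
    seed: int | None = 0,
    min_patients: int = 3,
    target_fs: float = 500.0,
    return_fits: bool = False,
    progress: bool = False,
):
    """Run the full sliding-window permutation harness on a study.

    Returns a results DataFrame (one row per region x event x window x
    family) and, when ``return_fits``, a dict of the fitted models keyed
    by (region, event, window, family).  ``windows`` maps event -> list
    of (start, end) ms; defaults to the standard grids.
    """
    rng = np.random.default_rng(seed)
    channels, patient_of_channel = [], []
    for pid, rec in study.recordings.items():
        for ch in rec.channels:
            channels.append(ch)
            patient_of_channel.append(pid)
    regions, mask = filter_regions(channels, patient_of_channel,
                                   min_patients=min_patients)

    hfa_by_patient = {}
    for pid, rec in study.recordings.items():
        hfa_by_patient[pid] = preprocess_patient(
            rec, study.trial_tables[pid], events=events,
            target_fs=target_fs,
        )
        if progress:
            print(f"preprocessed {pid}")

    # per-region channel indices within each patient's recording
    region_channels = {r: {} for r in regions}
    offset = 0
    for pid, rec in study.recordings.items():
        n = rec.n_channels
        for local_i, ch in enumerate(rec.channels):
            if mask[offset + local_i] and ch.region in region_channels:
                region_channels[ch.region].setdefault(pid, []).append(local_i)
        offset += n

    if windows is None:
        windows = {ev: window_grid(ev) for ev in events}
    rows, fits = [], {}
    for region in regions:
        ch_map = region_channels[region]
        for event in events:
            hfa_ev = {pid: hfa_by_patient[pid][event] for pid in ch_map}
            trials = {pid: study.trial_tables[pid] for pid in ch_map}
            for window in windows[event]:
                feats = assemble_features(hfa_ev, trials, ch_map, window)
                if len(feats) == 0:
                    continue
                n_pat = feats["patient_id"].nunique()
                if n_pat < min_patients:
                    continue  # region fell below the rule after rejection
                for family in families:
                    try:
                        fit = PainGlme(feats, family=family,
                                       min_patients=min_patients).fit()
                        perm = fit.permutation_test(
                            n_perm=n_perm,
                            seed=int(rng.integers(2**31 - 1)),
                        )
                    except (ValueError, RuntimeError):
                        continue
                    rows.append(
                        dict(
                            region=region, event=event,
                            window_start=window[0], window_end=window[1],
                            family=family, beta=fit.beta, se=fit.se_beta,
                            t_real=perm.t_real, p_value=perm.p_value,
                            significant=perm.significant,
                            bound_lo=perm.bounds[0],
                            bound_hi=perm.bounds[1],
                            n_trials=len(feats), n_patients=n_pat,
                            n_eff_perm=perm.n_effective,
                            converged=fit.converged,
                            unreliable=perm.unreliable,
                        )
                    )
                    if return_fits:
                        fits[(region, event, tuple(window), family)] = fit
            if progress:
                print(f"modeled {region} {event}")
    results = pd.DataFrame(rows)
    if return_fits:
        return results, fits
    return results
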