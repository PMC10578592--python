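"""Data model and on-disk formats for sEEG pain-task datasets.

A dataset is a set of patients, each with a continuous multichannel
recording (HDF5 ``samples`` dataset + JSON sidecar with sampling rate and
channel metadata) and a trial table (TSV).  Channel metadata carries the
anatomical atlas label; analysis happens at the level of collapsed gyral
regions (e.g. ``Amyg_L_2_1`` -> ``Amyg``), with white-matter contacts and
regions sampled in fewer than three patients excluded from group models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ChannelMeta",
    "Recording",
    "collapse_label",
    "filter_regions",
    "region_summary",
    "validate_trial_table",
    "read_trial_table",
    "write_trial_table",
    "read_recording",
    "write_recording",
]

TRIAL_COLUMNS = [
    "patient_id",
    "trial_id",
    "temperature",
    "hand_on",
    "hand_off",
    "binary_response",
    "vas",
]


def collapse_label(atlas_label: str) -> str:
    """Collapse a Brainnetome-style atlas label to its gyral region.

    The region is the token before the first underscore, which drops the
    hemisphere and subdivision markers (``"Amyg_L_2_1"`` -> ``"Amyg"``).
    Labels without underscores are returned unchanged, so the operation is
    idempotent.
    """
    if not atlas_label:
        raise ValueError("empty atlas label")
    return atlas_label.split("_", 1)[0]


@dataclass
class ChannelMeta:
    """Metadata for one electrode contact."""

    name: str
    atlas_label: str = ""
    region: str = ""
    white_matter: bool = False
    mni_xyz: tuple | None = None

    def __post_init__(self):
        if not self.region and self.atlas_label:
            self.region = collapse_label(self.atlas_label)
        if self.atlas_label and self.region != collapse_label(self.atlas_label):
            raise ValueError(
                f"region {self.region!r} does not match collapsed atlas label "
                f"{collapse_label(self.atlas_label)!r}"
            )


@dataclass
class Recording:
    """Continuous multichannel recording in microvolts.

    ``samples`` is channels x time; ``referenced`` records whether the
    common-median reference has been applied (downstream epoching requires
    it).
    """

    samples: np.ndarray
    fs: float
    channels: list = field(default_factory=list)
    patient_id: str = ""
    referenced: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channels)} channel metadata entries"
            )
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    @property
    def regions(self) -> list:
        return [c.region for c in self.channels]


# --------------------------------------------------------------------- #
# region inclusion and summaries
# --------------------------------------------------------------------- #

def filter_regions(channels, patient_of_channel, min_patients: int = 3):
    """Apply the gray-matter and minimum-patient region inclusion rules.

    White-matter contacts are excluded outright; a region is retained only
    if, after that exclusion, contacts from at least ``min_patients`` unique
    patients remain.

    Returns
    -------
    regions : list of str
        Included regions, sorted.
    mask : ndarray of bool
        Aligned to ``channels``; True for contacts entering the analysis.
    """
    patient_of_channel = list(patient_of_channel)
    if len(patient_of_channel) != len(channels):
        raise ValueError("patient_of_channel must align with channels")
    gray = np.array([not c.white_matter for c in channels], dtype=bool)
    patients_by_region: dict = {}
    for ch, pid, ok in zip(channels, patient_of_channel, gray):
        if ok:
            patients_by_region.setdefault(ch.region, set()).add(pid)
    included = sorted(
        r for r, pats in patients_by_region.items() if len(pats) >= min_patients
    )
    inc = set(included)
    mask = gray & np.array([c.region in inc for c in channels], dtype=bool)
    return included, mask


def region_summary(channels, patient_of_channel) -> pd.DataFrame:
    """Per-region sampling summary: unique patients, unique contacts, and
    mean +/- SD contacts per contributing patient.

    The mean is total contacts divided by contributing patients, rounded to
    one decimal; the SD is over per-patient contact counts (ddof=1, zero
    for a single patient).
    """
    rows: dict = {}
    for ch, pid in zip(channels, patient_of_channel):
        rows.setdefault(ch.region, {}).setdefault(pid, 0)
        rows[ch.region][pid] += 1
    out = []
    for region in sorted(rows):
        counts = np.array(list(rows[region].values()), dtype=float)
        n_pat = counts.size
        n_con = int(counts.sum())
        sd = float(np.std(counts, ddof=1)) if n_pat > 1 else 0.0
        out.append(
            dict(
                region=region,
                unique_patients=n_pat,
                unique_contacts=n_con,
                mean_contacts=round(n_con / n_pat, 1),
                sd_contacts=round(sd, 1),
            )
        )
    return pd.DataFrame(
        out,
        columns=["region", "unique_patients", "unique_contacts",
                 "mean_contacts", "sd_contacts"],
    )


# --------------------------------------------------------------------- #
# trial tables
# --------------------------------------------------------------------- #

def validate_trial_table(trials: pd.DataFrame, fs: float | None = None,
                         hand_on_duration: float = 10.0) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if (trials["hand_off"] <= trials["hand_on"]).any():
        raise ValueError("hand_off must come after hand_on")
    if ((trials["vas"] < 0) | (trials["vas"] > 10)).any():
        raise ValueError("VAS ratings must lie in [0, 10]")
    if not trials["binary_response"].isin([0, 1]).all():
        raise ValueError("binary_response must be 0/1")
    if fs is not None:
        dur = (trials["hand_off"] - trials["hand_on"]) / fs
        if (np.abs(dur - hand_on_duration) > 0.5).any():
            raise ValueError(
                f"hand-on durations deviate from {hand_on_duration} s"
            )
    return trials


def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t")
    return validate_trial_table(trials)


# --------------------------------------------------------------------- #
# recordings: HDF5 samples + JSON sidecar
# --------------------------------------------------------------------- #

def _sidecar_path(h5_path) -> Path:
    return Path(h5_path).with_suffix(".json")


def write_recording(rec: Recording, h5_path) -> None:
    """Write samples to HDF5 and metadata to a JSON sidecar."""
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
    meta = dict(
        fs=rec.fs,
        patient_id=rec.patient_id,
        referenced=rec.referenced,
        channels=[
            dict(
                name=c.name,
                atlas_label=c.atlas_label,
                region=c.region,
                white_matter=bool(c.white_matter),
                mni_xyz=list(c.mni_xyz) if c.mni_xyz is not None else None,
            )
            for c in rec.channels
        ],
    )
    _sidecar_path(h5_path).write_text(json.dumps(meta, indent=1))


def read_recording(h5_path) -> Recording:
    h5_path = Path(h5_path)
    meta = json.loads(_sidecar_path(h5_path).read_text())
    with h5py.File(h5_path, "r") as f:
        samples = f["samples"][()]
    channels = [
        ChannelMeta(
            name=c["name"],
            atlas_label=c.get("atlas_label", ""),
            region=c.get("region", ""),
            white_matter=bool(c.get("white_matter", False)),
            mni_xyz=tuple(c["mni_xyz"]) if c.get("mni_xyz") else None,
        )
        for c in meta["channels"]
    ]
    return Recording(
        samples=samples,
        fs=meta["fs"],
        channels=channels,
        patient_id=meta.get("patient_id", ""),
        referenced=bool(meta.get("referenced", False)),
    )
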