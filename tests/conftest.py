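"""Shared fixtures: small synthetic datasets built programmatically."""

import numpy as np
import pandas as pd
import pytest

import painhfa as ph
from painhfa.io import ChannelMeta

# Region sampling of the 20-patient cohort: (unique patients, unique contacts)
TABLE1_COUNTS = {
    "Amyg": (11, 44), "CG": (20, 51), "FuG": (9, 16), "Hipp": (18, 115),
    "IFG": (17, 94), "INS": (12, 30), "ITG": (6, 19), "MFG": (17, 116),
    "MTG": (19, 140), "OFC": (18, 190), "PrG": (3, 15), "SFG": (13, 32),
    "STG": (11, 36), "Str": (10, 41), "Tha": (5, 19), "pSTS": (3, 9),
}


@pytest.fixture(scope="session")
def table1_channels():
    """Channel metadata reproducing the cohort's per-region patient and
    contact counts (contacts spread as evenly as possible)."""
    channels, patients = [], []
    rng = np.random.default_rng(0)
    for region, (n_pat, n_con) in TABLE1_COUNTS.items():
        pat_ids = [f"P{i:02d}" for i in rng.choice(20, n_pat, replace=False)]
        base, extra = divmod(n_con, n_pat)
        for j, pid in enumerate(pat_ids):
            for k in range(base + (1 if j < extra else 0)):
                channels.append(
                    ChannelMeta(name=f"{pid}-{region}-{k}",
                                atlas_label=f"{region}_L_1_{k + 1}")
                )
                patients.append(pid)
    return channels, patients


@pytest.fixture(scope="session")
def artifact_study():
    """Small study with two of each artifact kind injected per patient."""
    kinds = {k: 2 for k in ph.synth.ARTIFACT_KINDS}
    return ph.simulate_study(
        n_patients=4,
        region_counts={"Amyg": 4, "Hipp": 4, "OFC": 4},
        trials_per_patient=12,
        channels_per_region=2,
        artifacts=kinds,
        seed=2024,
    )


@pytest.fixture(scope="session")
def tiny_study():
    """Minimal clean study reused by pipeline-level tests."""
    return ph.simulate_study(
        n_patients=4,
        region_counts={"ITG": 4, "MTG": 4, "Hipp": 4},
        trials_per_patient=10,
        effects={("ITG", "hand_on", (0, 1000)): 1.5},
        seed=7,
    )


def make_features(n_patients=8, n_trials=25, beta=0.0, seed=0):
    """Feature table drawn directly from the window model's own data
    model (logistic in A with patient effects), bypassing the LFP
    pipeline; used for unit tests of the modeling layer."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        b0 = rng.normal(0, 0.4)
        temps = rng.choice(np.round(np.arange(43, 47.5, 0.5), 1), n_trials)
        for t in range(n_trials):
            a = rng.normal(0, 1)
            eta = -0.2 + b0 + beta * a
            y = int(rng.random() < 1 / (1 + np.exp(-eta)))
            vas = max(0.0, min(10.0, 1.0 + beta * a + b0 + rng.normal(0, 1)))
            rows.append(dict(patient_id=f"P{p:02d}", trial_id=t,
                             temperature=float(temps[t]), A=a,
                             y_binary=y, y_vas=vas))
    return pd.DataFrame(rows)
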