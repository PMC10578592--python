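"""Synthetic task and recording generator."""

import numpy as np
import pytest
from scipy.special import expit

import painhfa as ph
from painhfa.synth import (
    ObserverModel,
    StaircaseState,
    inject_artifacts,
    quest_propose,
    quest_update,
    simulate_observer,
    simulate_study,
)


class TestStaircase:
    def test_uniform_prior_proposes_grid_mean(self):
        state = StaircaseState.initialize(np.arange(40.0, 49.0))
        assert quest_propose(state) == 44.0

    def test_degenerate_posterior_proposes_that_point(self):
        grid = np.arange(40.0, 49.0)
        post = np.zeros(grid.size)
        post[6] = 1.0
        state = StaircaseState(temperature_grid=grid, posterior=post)
        assert quest_propose(state) == grid[6]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            StaircaseState.initialize(np.array([]))

    def test_yes_shifts_mass_to_lower_thresholds(self):
        state = StaircaseState.initialize(np.arange(40.0, 49.0))
        new = quest_update(state, 44.0, 1)
        # P(threshold < T) grows after a "yes" at T
        below = state.temperature_grid < 44.0
        assert new.posterior[below].sum() > state.posterior[below].sum()
        assert new.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_binary_response_rejected(self):
        state = StaircaseState.initialize(np.arange(40.0, 49.0))
        with pytest.raises(ValueError):
            quest_update(state, 44.0, 0.5)

    def test_alternating_responses_keep_mode_at_test_temperature(self):
        """Exact Bayes oracle on a 5-point grid: yes/no pairs at one
        temperature concentrate the posterior where P(yes) = 0.5."""
        grid = np.array([43.0, 44.0, 45.0, 46.0, 47.0])
        slope = 2.0
        state = StaircaseState.initialize(grid, assumed_slope=slope)
        for resp in [1, 0, 1, 0, 1, 0]:
            state = quest_update(state, 45.0, resp)
        # oracle: independent exact computation of the unnormalized posterior
        p = expit((45.0 - grid) * slope)
        oracle = (p**3) * ((1 - p) ** 3)
        assert np.argmax(state.posterior) == np.argmax(oracle)
        assert grid[np.argmax(state.posterior)] == 45.0
        np.testing.assert_allclose(
            state.posterior, oracle / oracle.sum(), atol=1e-12
        )

    def test_staircase_converges_to_true_threshold(self):
        """With a (nearly) deterministic observer, 40 adaptive trials pin
        the posterior-mean threshold to within one grid step."""
        grid = np.arange(40.0, 48.5, 0.5)
        true_thr = 45.0
        rng = np.random.default_rng(11)
        observer = ObserverModel(threshold_temp=true_thr, slope=20.0,
                                 lapse_rate=0.0)
        state = StaircaseState.initialize(grid, assumed_slope=2.0)
        for _ in range(40):
            temp = quest_propose(state)
            resp, _ = simulate_observer(observer, temp, rng)
            state = quest_update(state, temp, resp)
        assert abs(state.posterior_mean - true_thr) <= 0.5


class TestObserver:
    def test_probability_half_at_threshold(self):
        model = ObserverModel(threshold_temp=45.0, slope=2.0, lapse_rate=0.0)
        assert model.response_probability(45.0) == pytest.approx(0.5)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ObserverModel(threshold_temp=45.0, slope=-1.0)
        with pytest.raises(ValueError):
            ObserverModel(threshold_temp=45.0, lapse_rate=0.5)

    def test_empirical_rate_matches_logistic(self):
        """Monte-Carlo check against the closed form: P(yes) at
        threshold + 1/slope is logistic(1) ~ 0.731."""
        model = ObserverModel(threshold_temp=45.0, slope=2.0, lapse_rate=0.0)
        rng = np.random.default_rng(3)
        temp = 45.0 + 1.0 / model.slope
        n = 10_000
        hits = sum(
            simulate_observer(model, temp, rng)[0] for _ in range(n)
        )
        p_true = expit(1.0)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(hits / n - p_true) < 3 * se

    def test_vas_zero_far_below_threshold(self):
        model = ObserverModel(threshold_temp=45.0, slope=2.0)
        rng = np.random.default_rng(0)
        ratings = [simulate_observer(model, 38.0, rng)[1] for _ in range(50)]
        # clamped at the floor: ratings are ~0 up to reporting noise
        assert np.median(ratings) == 0
        assert np.mean(ratings) < 0.5

    def test_vas_within_scale_and_integer(self):
        model = ObserverModel(threshold_temp=44.0, slope=2.0, vas_gain=3.0)
        rng = np.random.default_rng(1)
        ratings = [simulate_observer(model, t, rng)[1]
                   for t in np.linspace(40, 50, 200)]
        assert all(isinstance(v, int) and 0 <= v <= 10 for v in ratings)

    def test_latent_consistent_with_report(self):
        model = ObserverModel(threshold_temp=45.0, slope=2.0, lapse_rate=0.0)
        rng = np.random.default_rng(5)
        for temp in [43.0, 45.0, 47.0]:
            binary, _, latent = model.draw_trial(temp, rng)
            assert 0.0 < latent < 1.0
            assert binary == int(latent > 0.5)


class TestStudyGeneration:
    def test_duration_bookkeeping(self):
        study = simulate_study(n_patients=2,
                               region_counts={"Amyg": 2, "Hipp": 2},
                               trials_per_patient=5, seed=0)
        rec = study.recordings["P00"]
        assert rec.n_samples == int(5 * (10 + 5) * rec.fs)
        tt = study.trial_tables["P00"]
        assert ((tt["hand_off"] - tt["hand_on"]) == 10 * rec.fs).all()

    def test_vas_ratings_mostly_low(self):
        study = simulate_study(n_patients=6,
                               region_counts={"Amyg": 6, "Hipp": 6},
                               trials_per_patient=20, seed=4)
        vas = study.all_trials()["vas"]
        assert (vas <= 4).mean() > 0.8

    def test_determinism_bit_identical(self):
        kw = dict(n_patients=2, region_counts={"Amyg": 2, "Hipp": 2},
                  trials_per_patient=4,
                  artifacts=["saturation"], seed=99)
        s1, s2 = simulate_study(**kw), simulate_study(**kw)
        for pid in s1.patient_ids:
            np.testing.assert_array_equal(
                s1.recordings[pid].samples, s2.recordings[pid].samples
            )
            assert s1.trial_tables[pid].equals(s2.trial_tables[pid])
        s3 = simulate_study(**{**kw, "seed": 100})
        assert not np.array_equal(
            s1.recordings["P00"].samples, s3.recordings["P00"].samples
        )

    def test_effect_region_must_have_channels(self):
        with pytest.raises(ValueError, match="no channel"):
            simulate_study(n_patients=2, region_counts={"Amyg": 2, "Hipp": 2},
                           trials_per_patient=3,
                           effects={("OFC", "hand_on", (0, 500)): 1.0},
                           seed=0)

    def test_effect_map_covers_all_regions(self):
        study = simulate_study(n_patients=2,
                               region_counts={"Amyg": 2, "Hipp": 2},
                               trials_per_patient=3,
                               effects={("Amyg", "hand_on", (0, 500)): 1.0},
                               seed=0)
        gt = study.ground_truth
        for region in gt.regions:
            gt.effect_for(region)  # defined (zero allowed) for every region
        assert gt.effect_for("Amyg", "hand_on", (0, 500)) == 1.0
        assert gt.effect_for("Hipp", "hand_on", (0, 500)) == 0.0


class TestEffectInjection:
    def test_envelope_rises_monotonically_with_effect_size(self):
        """With identical noise (same seed), the post-onset z-scored
        envelope in the effect region grows with the injected effect."""
        means = []
        for eff in (0.0, 1.0, 2.0):
            study = simulate_study(
                n_patients=3,
                region_counts={"ITG": 3, "MTG": 3, "Hipp": 3},
                trials_per_patient=10,
                channels_per_region={"ITG": 2},
                effects={("ITG", "hand_on", (0, 1000)): eff},
                seed=21,
            )
            vals = []
            for pid in study.patient_ids:
                rec = study.recordings[pid]
                hf = ph.preprocess_patient(
                    rec, study.trial_tables[pid], events=("hand_on",)
                )["hand_on"]
                idx = [i for i, r in enumerate(rec.regions) if r == "ITG"]
                sl = hf.time_slice(250.0, 750.0)
                vals.append(hf.data[:, idx, sl].mean())
            means.append(float(np.mean(vals)))
        assert means[0] < means[1] < means[2]


class TestArtifactInjection:
    def test_unknown_kind_rejected(self, tiny_study):
        rec = tiny_study.recordings["P00"]
        tt = tiny_study.trial_tables["P00"]
        with pytest.raises(ValueError, match="unknown artifact kind"):
            inject_artifacts(rec, tt, ["zap"], rng=0)

    def test_every_artifact_is_logged(self, artifact_study):
        log = artifact_study.ground_truth.artifact_log
        # 4 patients x 5 kinds x 2 each
        assert len(log) == 40
        kinds = {a.kind for a in log}
        assert kinds == set(ph.synth.ARTIFACT_KINDS)

    def test_saturation_writes_code_value(self, artifact_study):
        for a in artifact_study.ground_truth.artifact_log:
            if a.kind != "saturation":
                continue
            rec = artifact_study.recordings[a.patient_id]
            seg = rec.samples[a.channel, a.start:a.stop]
            assert np.all(np.abs(seg) == pytest.approx(6553.0))

    def test_flat_writes_constant(self, artifact_study):
        for a in artifact_study.ground_truth.artifact_log:
            if a.kind != "flat":
                continue
            rec = artifact_study.recordings[a.patient_id]
            seg = rec.samples[a.channel, a.start:a.stop]
            assert seg.var() < 1.0

    def test_transient_exceeds_slope_threshold(self, artifact_study):
        fs = artifact_study.fs
        for a in artifact_study.ground_truth.artifact_log:
            if a.kind != "transient":
                continue
            rec = artifact_study.recordings[a.patient_id]
            seg = rec.samples[a.channel, a.start - 2:a.stop]
            slope = np.abs(np.diff(seg)).max() * fs / 1000.0
            assert slope > 300.0
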