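"""Synthetic session generator: determinism, trial structure, ground truth."""

import numpy as np
import pandas as pd
import pytest

from alloptical import roc
from alloptical import traces as tr
from alloptical.simulate import (
    ConfigurationError,
    SimConfig,
    generate_choices,
    generate_session,
    generate_video_features,
)


class TestConfigValidation:
    def test_bad_trial_mix_rejected(self):
        cfg = SimConfig(trial_mix={"ts": 0.8, "catch": 0.4})
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_bad_neuropil_coefficient_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(neuropil_coeff_true=1.4).validate()

    def test_coding_fractions_bounded(self):
        with pytest.raises(ConfigurationError):
            SimConfig(frac_contra_coding=0.6, frac_ipsi_coding=0.6).validate()


class TestDeterminism:
    def test_same_seed_identical_bundles(self):
        cfg = SimConfig(n_neurons=30, n_trials=60, n_targets_per_group=8,
                        n_offtarget_in_zones=2, seed=5)
        a = generate_session(cfg)
        b = generate_session(SimConfig(**{**cfg.__dict__}))
        np.testing.assert_array_equal(a.raw_soma, b.raw_soma)
        np.testing.assert_array_equal(a.raw_neuropil, b.raw_neuropil)
        pd.testing.assert_frame_equal(a.trial_table, b.trial_table)
        pd.testing.assert_frame_equal(a.video_features, b.video_features)
        np.testing.assert_array_equal(
            a.ground_truth.opsin_efficacy, b.ground_truth.opsin_efficacy
        )

    def test_different_seeds_differ(self):
        cfg1 = SimConfig(n_neurons=30, n_trials=60, n_targets_per_group=8, seed=5)
        cfg2 = SimConfig(n_neurons=30, n_trials=60, n_targets_per_group=8, seed=6)
        assert not np.array_equal(
            generate_session(cfg1).raw_soma, generate_session(cfg2).raw_soma
        )


class TestTrialStructure:
    def test_trial_mix_frequencies(self):
        cfg = SimConfig(n_neurons=24, n_trials=1200, n_targets_per_group=6, seed=2)
        table = generate_session(cfg).trial_table
        freqs = table["trial_type"].value_counts(normalize=True)
        for ttype, frac in cfg.trial_mix.items():
            assert abs(freqs.get(ttype, 0.0) - frac) < 0.02

    def test_ps_groups_balanced(self, small_session):
        tsps = small_session.trial_table.query("trial_type == 'ts_ps'")
        counts = tsps["ps_group"].value_counts()
        assert abs(counts.get("contra", 0) - counts.get("ipsi", 0)) <= 1


class TestSilentConfiguration:
    def test_no_signal_no_noise_gives_flat_dff(self):
        cfg = SimConfig(
            n_neurons=12,
            n_trials=40,
            n_targets_per_group=3,
            n_offtarget_in_zones=0,
            frac_contra_coding=0.0,
            frac_ipsi_coding=0.0,
            noise_sd=0.0,
            spont_rate_hz=0.0,
            neuropil_sd_f=0.0,
            trial_mix={"ts": 0.3, "catch": 0.3, "uni_contra": 0.2, "uni_ipsi": 0.2},
            seed=3,
        )
        bundle = generate_session(cfg)
        corrected = tr.subtract_neuropil(
            bundle.raw_soma, bundle.raw_neuropil, cfg.neuropil_coeff_true
        )
        dff = tr.compute_dff(corrected).dff
        np.testing.assert_allclose(dff, 0.0, atol=1e-9)


class TestGroundTruth:
    def test_every_neuron_has_one_class(self, small_session):
        gt = small_session.ground_truth
        assert set(np.unique(gt.true_class)) <= {"contra", "ipsi", "non"}
        assert gt.true_class.shape[0] == small_session.raw_soma.shape[0]

    def test_activated_counts_bounded_by_group_size(self, small_session):
        gt = small_session.ground_truth
        n = small_session.config.n_targets_per_group
        for g, count in gt.true_activated_count.items():
            assert 0 <= count <= n
            assert count == int(gt.true_ps_responder[gt.target_ids[g]].sum())

    def test_centroids_inside_fov(self, small_session):
        xy = small_session.roi_centroids[["x_um", "y_um"]].to_numpy()
        assert (xy >= 0).all() and (xy <= small_session.config.fov_size_um).all()

    def test_forced_responder_count(self):
        cfg = SimConfig(n_neurons=80, n_trials=40, n_targets_per_group=15,
                        responders_per_group=9, n_offtarget_in_zones=0, seed=4)
        gt = generate_session(cfg).ground_truth
        assert gt.true_activated_count == {"contra": 9, "ipsi": 9}

    def test_selectivity_recovery_tracks_amplitude(self, small_session,
                                                   small_preprocessed,
                                                   small_ensembles):
        """Estimated selectivity AUC tracks the true signed response amplitude
        and the detected fraction of contra-coding neurons rises with it."""
        from scipy.stats import spearmanr

        gt = small_session.ground_truth
        trials = small_session.trial_table
        uc = (trials["trial_type"] == "uni_contra").to_numpy()
        ui = (trials["trial_type"] == "uni_ipsi").to_numpy()
        evoked = small_preprocessed.evoked
        aucs = np.array(
            [roc.auc(evoked[i, uc], evoked[i, ui]) for i in range(evoked.shape[0])]
        )
        signed_amp = np.where(
            gt.true_class == "contra", gt.true_amp,
            np.where(gt.true_class == "ipsi", -gt.true_amp, 0.0),
        )
        rho = spearmanr(signed_amp, aucs).statistic
        assert rho > 0.7

        # detection rate of true contra-coding cells by amplitude halves
        detected = (small_ensembles["class"] == "contra-coding").to_numpy()
        contra = gt.true_class == "contra"
        amps = gt.true_amp[contra]
        hit = detected[contra]
        lo, hi = amps < np.median(amps), amps >= np.median(amps)
        assert hit[hi].mean() >= hit[lo].mean()
        assert hit[hi].mean() > detected[gt.true_class == "non"].mean()


class TestGenerateChoices:
    def test_symmetry_at_zero_bias(self, rng):
        stim = np.tile([0.5, 0.5], (4000, 1))
        out = generate_choices(stim, 0, 0.0, "symmetric", rng=rng)
        assert (out["report"] == "contra").mean() == pytest.approx(0.5, abs=0.03)

    def test_logistic_closed_form_shift(self, rng):
        stim = np.tile([0.5, 0.5], (20000, 1))
        out = generate_choices(stim, 20, 0.01, "symmetric", rng=rng)
        expected = 1.0 / (1.0 + np.exp(-0.01 * 20))
        assert (out["report"] == "contra").mean() == pytest.approx(expected, abs=0.02)

    def test_asymmetric_contingency_swaps_lick_not_report(self, rng):
        stim = np.tile([1.0, 0.0], (500, 1))
        out = generate_choices(stim, 0, 0.0, "asymmetric", rng=rng)
        dec = out[~out["miss"]]
        swapped = dec["report"] != dec["lick"]
        assert swapped.all()

    def test_miss_rate(self, rng):
        stim = np.tile([0.5, 0.5], (4000, 1))
        out = generate_choices(stim, 0, 0.0, "symmetric", p_miss=0.3, rng=rng)
        assert out["miss"].mean() == pytest.approx(0.3, abs=0.03)


@pytest.fixture(scope="module")
def video_and_trials():
    trials = pd.DataFrame(
        {
            "trial_id": [0, 1],
            "trial_type": ["ts", "ts"],
            "stim_contra": [0.5, 0.5],
            "stim_ipsi": [0.5, 0.5],
            "report": ["contra", "none"],
            "miss": [False, True],
            "rt_ms": [1600.0, np.nan],
        }
    )
    video = generate_video_features(trials, rng=np.random.default_rng(9))
    return video, trials


class TestVideoFeatures:
    def test_miss_trial_has_no_lick_frames(self, video_and_trials):
        from alloptical.movement import detect_licks

        video, _ = video_and_trials
        miss_rows = video[video["trial_id"] == 1]
        assert not detect_licks(miss_rows).any()

    def test_first_lick_frame_matches_rt(self, video_and_trials):
        from alloptical.movement import detect_licks

        video, _ = video_and_trials
        rows = video[video["trial_id"] == 0]
        flags = detect_licks(rows)
        first = int(np.argmax(flags))
        expected = 30 + int(round(1.6 * 30))
        assert first == expected

    def test_session_motion_max_is_one(self, video_and_trials):
        video, _ = video_and_trials
        assert video[["whisk_contra", "whisk_ipsi", "body"]].max().max() == pytest.approx(1.0)
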