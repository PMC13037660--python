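"""Stochastic generators: ground-truth sidecars, invariants, determinism,
and recovery of injected effects at small scale."""

import numpy as np
import pytest

from cravemod.erp import gfp_timecourse
from cravemod.errors import ConfigError
from cravemod.gaze import sign_tracking_slope
from cravemod.synth import (
    BehavEffectSpec,
    ComponentSpec,
    EegEffectSpec,
    GazeEffectSpec,
    StudyEffects,
    default_components,
    simulate_behavioural_dataset,
    simulate_eeg_dataset,
    simulate_gaze_dataset,
    simulate_study,
)


class TestEegSimulator:
    def test_zero_noise_epochs_identical_and_peak_at_latency(self):
        spec = EegEffectSpec(components=(default_components()[0],),
                             noise_sd_uv=0.0, subject_amp_sd=0.0,
                             n_epochs=4, sfreq=256)
        data, truth = simulate_eeg_dataset(2, spec, seed=0)
        ep = data[0]["pre_go"]
        assert np.allclose(ep.data, ep.data[:, :, :1])
        tc = gfp_timecourse(ep.data[:, :, 0])
        assert abs(ep.times_ms[tc.argmax()] - 85.0) <= 1000.0 / 256  # one TF
        assert truth["components"][0]["latency_ms"] == 85.0

    def test_zero_effect_condition_differences_shrink_with_n(self):
        def grand_diff(n_sub, n_epochs):
            spec = EegEffectSpec(n_epochs=n_epochs, sfreq=128, subject_amp_sd=0.0)
            data, _ = simulate_eeg_dataset(n_sub, spec, seed=3)
            conds = ["pre_go", "pre_nogo", "post_go", "post_nogo"]
            means = {
                c: np.mean([d[c].data.mean(axis=2) for d in data], axis=0)
                for c in conds
            }
            return np.abs(means["post_nogo"] - means["pre_go"]).mean()

        assert grand_diff(12, 24) < grand_diff(2, 4)

    def test_interaction_injected_only_in_n2(self):
        comps = default_components(n2_interaction_uv=2.0)
        assert comps[0].interaction_effect == 0.0
        assert comps[1].interaction_effect == 2.0
        # interaction contrast of the four amplitudes equals the injected value
        c = comps[1]
        contrast = (
            c.amplitude("post_nogo") - c.amplitude("post_go")
            - c.amplitude("pre_nogo") + c.amplitude("pre_go")
        )
        assert contrast == pytest.approx(2.0)

    def test_window_must_cover_latencies(self):
        with pytest.raises(ConfigError):
            EegEffectSpec(components=(ComponentSpec("late", 900.0, 20.0, "occipital"),))

    def test_determinism(self):
        spec = EegEffectSpec(n_epochs=3, sfreq=128)
        a, _ = simulate_eeg_dataset(2, spec, seed=5)
        b, _ = simulate_eeg_dataset(2, spec, seed=5)
        assert np.array_equal(a[1]["post_nogo"].data, b[1]["post_nogo"].data)


class TestBehaviouralSimulator:
    def test_fast_rt_bookkeeping_matches_configured_rate(self):
        spec = BehavEffectSpec(fast_src_rate=0.10, fast_rating_rate=0.05)
        tables, truth = simulate_behavioural_dataset(30, spec, seed=2)
        frac_src = (tables["src"]["rt_ms"] < 200).mean()
        assert frac_src == pytest.approx(0.10, abs=0.02)
        frac_rating = (tables["ratings"]["rt_ms"] < 300).mean()
        assert frac_rating == pytest.approx(0.05, abs=0.02)

    def test_ground_truth_sidecar_complete(self):
        tables, truth = simulate_behavioural_dataset(5, seed=0)
        assert truth["cell_means"].shape == (5, 4)
        assert truth["subject_devaluation"].shape == (5,)
        assert set(tables) == {"ratings", "src", "gng_performance"}

    def test_injected_interaction_contrast_has_requested_d(self):
        # many subjects: the empirical contrast d approaches the spec value
        spec = BehavEffectSpec(devaluation_d=0.8, item_noise_sd=0.0)
        tables, truth = simulate_behavioural_dataset(400, spec, seed=4)
        cells = (
            tables["ratings"]
            .groupby(["subject", "session", "category"])["rating"]
            .mean()
            .unstack(["session", "category"])
        )
        contrast = (
            cells[("pre", "go")] - cells[("pre", "nogo")]
            - cells[("post", "go")] + cells[("post", "nogo")]
        )
        d = -contrast.mean() / contrast.std(ddof=1)  # devaluation sign
        assert d == pytest.approx(0.8, abs=0.15)


class TestGazeSimulator:
    def test_proportions_always_valid(self):
        spec = GazeEffectSpec(noise_sd=0.5)  # large noise forces clipping
        with pytest.warns(UserWarning):
            table, _ = simulate_gaze_dataset(5, spec, seed=1)
        assert (table["t_cs_ms"] >= 0).all()
        assert (table["t_us_ms"] >= 0).all()
        assert ((table["t_cs_ms"] + table["t_us_ms"]) <= table["window_ms"] + 1e-9).all()

    def test_noise_free_slopes_recovered_exactly(self):
        spec = GazeEffectSpec(noise_sd=0.0)
        table, truth = simulate_gaze_dataset(
            3, spec, seed=2, true_slopes=np.array([0.1, 0.05, -0.02])
        )
        for subj, grp in table.groupby("subject"):
            res = sign_tracking_slope(grp)
            assert res.slope == pytest.approx(truth["true_slopes"][subj], abs=1e-9)
            assert res.se == pytest.approx(0.0, abs=1e-9)

    def test_zero_slope_population_mean_near_zero(self):
        spec = GazeEffectSpec(slope_mean=0.0, slope_sd=0.0, noise_sd=0.1)
        table, _ = simulate_gaze_dataset(40, spec, seed=3)
        slopes = [sign_tracking_slope(g).slope for _, g in table.groupby("subject")]
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(len(slopes)) + 1e-3


class TestStudySimulator:
    def test_bundle_structure_and_coupling(self):
        eff = StudyEffects(n_subjects=8, n_subjects_eeg=2, simulate_eeg=False,
                           moderation_beta_sign=100.0, devaluation_noise_sd=0.0)
        bundle = simulate_study(eff, seed=0)
        truth = bundle["truth"]
        # devaluation is exactly linear in the sign-tracking slope here
        slopes = truth["sign_tracking_slopes"]
        delta = truth["subject_devaluation"]
        r = np.corrcoef(slopes, delta)[0, 1]
        assert r > 0.99
        assert len(bundle["two_step"]) == 8
        assert len(bundle["forced_choice"]) == 8

    def test_study_determinism(self):
        eff = StudyEffects(n_subjects=5, simulate_eeg=False)
        a = simulate_study(eff, seed=9)
        b = simulate_study(eff, seed=9)
        assert a["ratings"].equals(b["ratings"])
        assert np.array_equal(a["truth"]["w"], b["truth"]["w"])
        assert a["two_step"][0]["trials"].equals(b["two_step"][0]["trials"])
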