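"""Synthetic cohort generator: determinism, class structure, stream shape."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, spearmanr

import frailscreen as fs
from frailscreen import energy, gait, hrr, references
from frailscreen.errors import ConfigurationError
from frailscreen.synthetic import (
    ActivityBudget,
    CohortConfig,
    LatentParticipant,
    cohort_frame,
    generate_accel_stream,
    generate_cohort,
    generate_hr_stream,
    write_cohort,
)


def small_config(**overrides) -> CohortConfig:
    base = dict(n_participants=6, duration_days=0.25, accel_rate_hz=25.0, seed=9)
    base.update(overrides)
    return CohortConfig(**base)


def manual_participant(cls="robust", speed=1.0, cadence=1.65, hrr_bpm=25.0,
                       seed=1234) -> LatentParticipant:
    return LatentParticipant(
        id="PX", frailty_class=cls, true_hrr_bpm=hrr_bpm,
        true_gait_speed_mps=speed, true_cadence_sps=cadence,
        resting_hr_bpm=70.0, seed=seed,
    )


class TestConfigValidation:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="frailty_mix"):
            CohortConfig(frailty_mix=(0.5, 0.4, 0.2)).validate()

    def test_at_least_one_participant(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_participants=0).validate()

    def test_hrr_means_strictly_decreasing(self):
        with pytest.raises(ConfigurationError, match="decreasing"):
            CohortConfig(hrr_means_bpm=(10.0, 17.0, 25.0)).validate()

    def test_minimum_sampling_rate_and_duration(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(accel_rate_hz=10.0).validate()
        with pytest.raises(ConfigurationError):
            CohortConfig(duration_days=0.01).validate()


class TestGenerateCohort:
    def test_seeded_determinism_is_byte_identical(self):
        cfg = CohortConfig(n_participants=200, seed=1)
        df1 = cohort_frame(generate_cohort(cfg))
        df2 = cohort_frame(generate_cohort(cfg))
        assert df1.to_csv(index=False) == df2.to_csv(index=False)

    def test_degenerate_mixture_all_robust(self):
        cfg = CohortConfig(n_participants=5, frailty_mix=(1.0, 0.0, 0.0))
        cohort = generate_cohort(cfg)
        assert len(cohort) == 5
        assert all(p.frailty_class == "robust" for p, _ in cohort)

    def test_default_mix_near_reference_composition(self):
        """n=22 with the 41/45/14 mix lands near (9, 10, 3) robust/prefrail/
        frail, within multinomial sampling error (3 SDs)."""
        cfg = CohortConfig(n_participants=22, seed=7)
        df = cohort_frame(generate_cohort(cfg))
        counts = df.frailty_class.value_counts()
        for cls, expected, p in [("robust", 9, 0.41), ("prefrail", 10, 0.45),
                                 ("frail", 3, 0.14)]:
            sd = np.sqrt(22 * p * (1 - p))
            assert abs(counts.get(cls, 0) - expected) <= 3 * sd + 1

    def test_frail_category_matches_latent_class(self):
        """FRAIL categories agree with the latent class for >= 80 % of
        participants at default assessment noise."""
        cohort = generate_cohort(CohortConfig(n_participants=200, seed=2))
        agree = sum(
            references.frail_classify(a.frail_items)[1] == p.frailty_class
            for p, a in cohort
        )
        assert agree / len(cohort) >= 0.8

    def test_hrr_class_separation_stochastic(self):
        """Frail true HRR is stochastically smaller than robust (n=200)."""
        df = cohort_frame(generate_cohort(CohortConfig(n_participants=200, seed=5)))
        frail = df[df.frailty_class == "frail"].true_hrr_bpm
        robust = df[df.frailty_class == "robust"].true_hrr_bpm
        assert mannwhitneyu(frail, robust, alternative="less").pvalue < 0.01

    def test_cadence_tracks_gait_speed(self):
        df = cohort_frame(generate_cohort(CohortConfig(n_participants=50, seed=3)))
        rho = spearmanr(df.true_cadence_sps, df.true_gait_speed_mps).statistic
        assert rho > 0

    def test_write_cohort_round_trip(self, tmp_path):
        import json
        import pandas as pd

        cfg = small_config()
        cohort = generate_cohort(cfg)
        write_cohort(cohort, cfg, tmp_path)
        df = pd.read_csv(tmp_path / "cohort.csv")
        assert len(df) == cfg.n_participants
        sidecar = json.loads((tmp_path / "config.json").read_text())
        assert sidecar["seed"] == cfg.seed


class TestAccelStream:
    def test_schedule_bookkeeping_matches_detection(self):
        cfg = small_config().zero_noise()
        p, _ = generate_cohort(cfg)[0]
        accel = generate_accel_stream(p, cfg)
        injected = sum(b.n_steps for b in accel.schedule if b.kind == "walk")
        assert injected > 0
        assert len(gait.detect_steps(accel)) == injected

    def test_bouts_below_and_above_forty_steps(self):
        cfg = small_config()
        p, _ = generate_cohort(cfg)[0]
        accel = generate_accel_stream(p, cfg)
        steps = [b.n_steps for b in accel.schedule if b.kind == "walk"]
        assert any(n < 40 for n in steps) and any(n >= 40 for n in steps)

    def test_zero_activity_budget_means_no_walking(self):
        budgets = {c: ActivityBudget(0, 0, 0) for c in ("robust", "prefrail", "frail")}
        cfg = small_config(activity_budget=budgets)
        p, _ = generate_cohort(cfg)[0]
        accel = generate_accel_stream(p, cfg)
        assert accel.schedule == []
        bouts = gait.segment_bouts(gait.detect_steps(accel))
        assert sum(b.qualifies for b in bouts) == 0

    def test_gravity_baseline_at_rest(self):
        cfg = small_config()
        p, _ = generate_cohort(cfg)[0]
        accel = generate_accel_stream(p, cfg)
        # first scheduled bout starts after a rest gap; check the lead-in
        first = min(b.t_start_s for b in accel.schedule)
        rest = accel.magnitude()[accel.t_s < first - 1.0]
        assert abs(np.median(rest) - 1.0) < 0.2

    def test_robust_walks_at_least_as_much_as_frail(self):
        cfg = small_config()
        robust = manual_participant("robust", speed=1.05, cadence=1.7, seed=77)
        frail = manual_participant("frail", speed=0.45, cadence=1.0, seed=77)
        n_robust = sum(b.n_steps for b in generate_accel_stream(robust, cfg).schedule)
        n_frail = sum(b.n_steps for b in generate_accel_stream(frail, cfg).schedule)
        assert n_robust >= n_frail

    def test_stream_determinism(self):
        cfg = small_config()
        p, _ = generate_cohort(cfg)[0]
        a1 = generate_accel_stream(p, cfg)
        a2 = generate_accel_stream(p, cfg)
        assert np.array_equal(a1.az_g, a2.az_g)


class TestHeartRateStream:
    def test_periodic_spacing_and_physiological_range(self):
        cfg = small_config()
        p, _ = generate_cohort(cfg)[0]
        accel = generate_accel_stream(p, cfg)
        hs = generate_hr_stream(p, accel, cfg)
        assert np.allclose(np.diff(hs.t_s), cfg.hr_interval_s)
        assert hs.hr_bpm.min() >= 30 and hs.hr_bpm.max() <= 220

    def test_empty_accel_gives_empty_hr(self):
        from frailscreen.streams import AccelStream

        cfg = small_config()
        p = manual_participant()
        empty = AccelStream(np.empty(0), np.empty(0), np.empty(0), np.empty(0), 25.0)
        hs = generate_hr_stream(p, empty, cfg)
        assert hs.n_samples == 0

    def test_noise_free_single_exertion_recovery_is_exact(self):
        """One exertion episode, zero noise, true HRR 25 -> measured peak
        minus the next sample equals 25."""
        budgets = {c: ActivityBudget(walk_min=30, moderate_min=0, exertion_min=120)
                   for c in ("robust", "prefrail", "frail")}
        cfg = small_config(activity_budget=budgets, duration_days=1 / 12).zero_noise()
        p = manual_participant(hrr_bpm=25.0)
        accel = generate_accel_stream(p, cfg)
        hs = generate_hr_stream(p, accel, cfg)
        ex = [b for b in accel.schedule if b.kind == "exertion"]
        assert len(ex) == 1
        in_run = (hs.t_s >= ex[0].t_start_s) & (hs.t_s < ex[0].t_end_s)
        peak_idx = np.where(in_run)[0][np.argmax(hs.hr_bpm[in_run])]
        assert hs.hr_bpm[peak_idx] - hs.hr_bpm[peak_idx + 1] == pytest.approx(25.0, abs=1e-9)

    def test_no_exertion_hr_fluctuates_about_resting(self):
        budgets = {c: ActivityBudget(0, 30, 0) for c in ("robust", "prefrail", "frail")}
        cfg = small_config(activity_budget=budgets)
        p = manual_participant()
        accel = generate_accel_stream(p, cfg)
        hs = generate_hr_stream(p, accel, cfg)
        assert abs(np.mean(hs.hr_bpm) - p.resting_hr_bpm) < 3.0
        # and the analyzer finds no recovery episodes
        bouts = gait.segment_bouts(gait.detect_steps(accel))
        epochs = energy.classify_epochs(
            energy.epoch_energy(accel), energy.walking_reference(accel, bouts, 0.03)
        )
        assert hrr.detect_episodes(hs, epochs) == []

    def test_class_hrr_difference_recovered(self):
        """50 robust (true HRR ~25) vs 50 frail (~10), HR noise sd 4:
        estimated class difference lands at 15 +/- 2 bpm."""
        from frailscreen.pipeline import hrr_recovery_simulation

        res = hrr_recovery_simulation(seed=42)
        assert res.screener_auc > 0.9
        # difference check via a second pass over the same simulated design
        cfg_budgets = {c: ActivityBudget(80, 60, 240) for c in ("robust", "prefrail", "frail")}
        cfg = CohortConfig(n_participants=100, frailty_mix=(0.5, 0.0, 0.5),
                           hr_noise_bpm=4.0, activity_budget=cfg_budgets,
                           accel_rate_hz=25.0, duration_days=0.25, seed=42)
        from frailscreen.pipeline import analyze_participant

        means = {"robust": [], "frail": []}
        for p, a in generate_cohort(cfg):
            ph = analyze_participant(p, a, cfg).participant_hrr
            if not ph.missing:
                means[p.frailty_class].append(ph.mean_hrr_bpm)
        diff = np.mean(means["robust"]) - np.mean(means["frail"])
        assert diff == pytest.approx(15.0, abs=2.0)
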