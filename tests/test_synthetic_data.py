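"""Generator contracts: determinism, degenerate limits, known expectations."""

import numpy as np
import pytest

from axenic.estimation_stats import bca_ci, mean_difference
from axenic.sleep_activity import remove_dead_flies, summarize_day_night
from axenic.synthetic_data import (
    ArenaSimConfig,
    CourtshipSimConfig,
    DamsSimConfig,
    PupationSimConfig,
    simulate_courtship,
    simulate_dams,
    simulate_pupation_days,
    simulate_trajectories,
)
from axenic.trajectory_metrics import wafo_metric

SEED = 1234


class TestSimulateDams:
    def test_absorbing_sleep_state_all_zero(self):
        cfg = DamsSimConfig(n_flies_per_group=3, n_days=1, seed=SEED,
                            sleep_entry_prob=1.0, sleep_exit_prob=0.0)
        for s in simulate_dams(cfg):
            assert (s.counts == 0).all()

    def test_poisson_mean_recovered_when_never_asleep(self):
        lam = 1.7
        cfg = DamsSimConfig(n_flies_per_group=2, n_days=7, seed=SEED,
                            day_rate=lam, night_rate=lam,
                            sleep_entry_prob=0.0, sleep_exit_prob=0.5)
        for s in simulate_dams(cfg):  # >= 10^4 minutes per fly
            assert s.counts.mean() == pytest.approx(lam, abs=4 * np.sqrt(lam / s.n_minutes))

    def test_determinism_same_seed(self):
        cfg = DamsSimConfig(n_flies_per_group=2, n_days=1, seed=SEED)
        a = simulate_dams(cfg)
        b = simulate_dams(cfg)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.counts, s2.counts)

    def test_adding_flies_preserves_earlier_streams(self):
        small = simulate_dams(DamsSimConfig(n_flies_per_group=2, n_days=1, seed=SEED))
        large = simulate_dams(DamsSimConfig(n_flies_per_group=4, n_days=1, seed=SEED))
        by_id = {s.fly_id: s for s in large}
        for s in small:
            np.testing.assert_array_equal(s.counts, by_id[s.fly_id].counts)

    def test_dead_fraction_produces_removable_flies(self):
        cfg = DamsSimConfig(n_flies_per_group=40, n_days=3, seed=SEED,
                            dead_fraction=0.25, group_labels=("CV",))
        series = simulate_dams(cfg)
        _, removed = remove_dead_flies(series)
        assert 2 <= len(removed) <= 20  # ~25% of 40

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            DamsSimConfig(sleep_entry_prob=1.5)

    def test_zero_flies_rejected(self):
        with pytest.raises(ValueError, match="at least one fly"):
            DamsSimConfig(n_flies_per_group=0)

    def test_sleep_monotone_in_entry_probability(self):
        # lower sleep-entry probability -> less sleep (3-point grid)
        sleep_means = []
        for entry in (0.12, 0.05, 0.01):
            cfg = DamsSimConfig(n_flies_per_group=50, n_days=2, seed=SEED,
                                group_labels=("CV",), sleep_entry_prob=entry)
            summ = [summarize_day_night(s) for s in simulate_dams(cfg)]
            sleep_means.append(np.mean([s.day_sleep + s.night_sleep for s in summ]))
        assert sleep_means[0] > sleep_means[1] > sleep_means[2]

    def test_pipeline_recovers_known_rate_difference(self):
        """CI coverage of an injected day-rate difference through the full
        monitor -> day/night summary -> mean-difference + BCa chain."""
        delta = 0.3
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = DamsSimConfig(
                n_flies_per_group=60, n_days=2, seed=SEED + rep,
                day_rate={"CV": 1.0, "GF": 1.0 + delta},
                night_rate={"CV": 1.0, "GF": 1.0 + delta},
                sleep_entry_prob=0.0, sleep_exit_prob=0.5,
            )
            summ = [summarize_day_night(s) for s in simulate_dams(cfg)]
            x = [s.day_activity for s in summ if s.group == "GF"]
            y = [s.day_activity for s in summ if s.group == "CV"]
            lo, hi = bca_ci(x, y, mean_difference, n_boot=1000, seed=SEED + rep)
            covered += lo <= delta <= hi
        assert covered / n_rep >= 0.90


class TestSimulateTrajectories:
    def test_zero_speed_stays_at_start(self):
        cfg = ArenaSimConfig(n_flies_per_group=3, duration_s=10, seed=SEED,
                             speed_mean_mm_s=0.0, group_labels=("CV",))
        for tr in simulate_trajectories(cfg):
            assert np.ptp(tr.x) == 0.0 and np.ptp(tr.y) == 0.0

    def test_positions_inside_arena(self):
        cfg = ArenaSimConfig(n_flies_per_group=10, duration_s=60, seed=SEED,
                             wall_bias=2.0, group_labels=("CV",))
        for tr in simulate_trajectories(cfg):
            assert (np.hypot(tr.x, tr.y) <= tr.arena_radius + 1e-9).all()

    def test_isotropic_walk_matches_uniform_disc_expectation(self):
        # E[r] for a uniform disc of radius R is 2R/3
        cfg = ArenaSimConfig(n_flies_per_group=60, duration_s=600, seed=SEED,
                             wall_bias=0.0, group_labels=("CV",))
        wafos = [wafo_metric(tr) for tr in simulate_trajectories(cfg)]
        assert np.mean(wafos) == pytest.approx(2 * cfg.arena_radius_mm / 3, rel=0.05)

    def test_wall_bias_monotone_on_grid(self):
        means = []
        for bias in (0.0, 0.25, 0.75):
            cfg = ArenaSimConfig(n_flies_per_group=50, duration_s=300, seed=SEED,
                                 wall_bias=bias, group_labels=("CV",))
            means.append(np.mean([wafo_metric(t) for t in simulate_trajectories(cfg)]))
        assert means[0] < means[1] < means[2]

    def test_determinism(self):
        cfg = ArenaSimConfig(n_flies_per_group=2, duration_s=20, seed=SEED)
        a = simulate_trajectories(cfg)
        b = simulate_trajectories(cfg)
        for t1, t2 in zip(a, b):
            np.testing.assert_array_equal(t1.x, t2.x)
            np.testing.assert_array_equal(t1.y, t2.y)

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError, match="dt_s"):
            ArenaSimConfig(dt_s=0.0)


class TestSimulateCourtship:
    def test_full_preference(self):
        cfg = CourtshipSimConfig(n_trials=20, preference_p=1.0, seed=SEED)
        for tr in simulate_courtship(cfg):
            assert tr.t_target_b == 0.0
            assert tr.t_target_a == tr.total_courtship_s

    def test_symmetric_preference_median_half(self):
        from axenic.courtship_choice import preference

        cfg = CourtshipSimConfig(n_trials=300, preference_p=0.5, seed=SEED,
                                 bout_rate=100 / 3600)
        prefs = [preference(t) for t in simulate_courtship(cfg)]
        prefs = [p for p in prefs if p is not None]
        assert np.median(prefs) == pytest.approx(0.5, abs=0.05)

    def test_zero_bout_rate_all_silent(self):
        cfg = CourtshipSimConfig(n_trials=10, bout_rate=0.0, seed=SEED)
        assert all(t.total_courtship_s == 0.0 for t in simulate_courtship(cfg))

    def test_invalid_preference_rejected(self):
        with pytest.raises(ValueError, match="preference_p"):
            CourtshipSimConfig(preference_p=1.2)

    def test_some_trials_fall_under_inclusion_threshold(self):
        cfg = CourtshipSimConfig(n_trials=200, seed=SEED)
        totals = [t.total_courtship_s for t in simulate_courtship(cfg)]
        assert any(t < 60.0 for t in totals)
        assert any(t >= 60.0 for t in totals)

    def test_determinism(self):
        cfg = CourtshipSimConfig(n_trials=5, seed=SEED)
        a = simulate_courtship(cfg)
        b = simulate_courtship(cfg)
        assert [(t.t_target_a, t.t_target_b) for t in a] == \
               [(t.t_target_a, t.t_target_b) for t in b]


class TestSimulatePupation:
    def test_delay_recovered(self):
        cfg = PupationSimConfig(n_ctrl=4000, n_exp=4000, delay_days=1.33, seed=SEED)
        days = simulate_pupation_days(cfg)
        diff = days["GF"].mean() - days["CV"].mean()
        assert diff == pytest.approx(1.33, abs=0.1)
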