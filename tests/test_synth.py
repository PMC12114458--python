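"""Synthetic cytometer: determinism, dose response, and population shape."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from cytocide import (AcquisitionMeta, KillCurve, SyntheticConfig,
                      simulate_experiment, simulate_sample,
                      simulate_stained_sample, true_mbc)


class TestKillCurve:
    def test_hill_closed_form(self):
        # at c = 8*c50 with hill=4, floor=0: s = 1 / (1 + 8^4)
        kc = KillCurve(c50=1.0, hill=4.0, floor=0.0)
        assert kc.survival(8.0) == pytest.approx(1.0 / (1.0 + 8.0 ** 4))

    def test_survival_boundary_conditions(self):
        kc = KillCurve(c50=2.0, hill=3.0, floor=0.05)
        assert kc.survival(0.0) == 1.0
        assert kc.survival(1e9) == pytest.approx(0.05, abs=1e-6)

    def test_survival_monotone_nonincreasing(self):
        kc = KillCurve(c50=1.7, hill=2.5)
        grid = np.linspace(0, 20, 200)
        values = [kc.survival(c) for c in grid]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestSimulateSample:
    def test_seed_repeat_gives_identical_events(self, cfg):
        a = simulate_sample(cfg, role="growth_control")
        b = simulate_sample(cfg, role="growth_control")
        np.testing.assert_array_equal(a.events, b.events)

    def test_negative_control_poisson_mean(self):
        # nc_event_rate=2/s over ~42.86 s -> mean ~85.7 debris events;
        # check the seed-average against the Poisson mean within 3 SE
        rate, duration = 2.0, 25 * 60 / 35
        mean_expected = rate * duration
        counts = []
        for seed in range(200):
            cfg = SyntheticConfig(seed=seed, nc_event_rate=rate)
            counts.append(simulate_sample(cfg, role="negative_control").n_events)
        se = np.sqrt(mean_expected / len(counts))
        assert abs(np.mean(counts) - mean_expected) < 3 * se

    def test_treated_survivor_counts_match_hill_oracle(self):
        # c = 8*c50, hill=4: surviving fraction 1/(1+8^4) ~ 2.4e-4, so the
        # treated sample keeps essentially no intact cells
        cfg = SyntheticConfig(seed=2, n0_events=2000, growth_factor=10,
                              kill=KillCurve(c50=1.25, hill=4.0),
                              ladder=(10.0, 5.0, 2.5, 1.25, 0.625),
                              doublet_fraction=0.0)
        surviving = cfg.kill.survival(10.0)
        assert surviving == pytest.approx(1.0 / (1.0 + 8 ** 4))
        counts = []
        for seed in range(50):
            t = simulate_sample(replace(cfg, seed=seed), concentration=10.0)
            # intact survivors are the high-FSC events (debris/damaged sit low)
            counts.append(int((t.channel("FSC-H") > 10 ** 4.0).sum()))
        expected = cfg.n0_events * cfg.growth_factor * surviving
        assert np.mean(counts) == pytest.approx(expected, abs=3 * np.sqrt(expected / 50) + 1)

    def test_zero_dose_indistinguishable_from_growth_control(self):
        # survival(0)=1: treated at c=0 has the same intact-cell distribution
        cfg = SyntheticConfig(seed=7, ladder=(2.0, 1.0, 0.5, 0.25),
                              doublet_fraction=0.0)
        kc = cfg.kill
        assert kc.survival(0.0) == 1.0
        fsc_treated, fsc_control = [], []
        for seed in range(50):
            c = replace(cfg, seed=seed, kill=KillCurve(c50=1e9, hill=4.0))
            t = simulate_sample(c, concentration=0.25)  # ~zero effect dose
            g = simulate_sample(c, role="growth_control")
            fsc_treated.append(t.channel("FSC-H")[t.channel("FSC-H") > 10 ** 3.8])
            fsc_control.append(g.channel("FSC-H")[g.channel("FSC-H") > 10 ** 3.8])
        ks = stats.ks_2samp(np.concatenate(fsc_treated),
                            np.concatenate(fsc_control))
        assert ks.pvalue > 0.01

    def test_concentration_not_in_ladder_rejected(self, cfg):
        with pytest.raises(ValueError, match="not in ladder"):
            simulate_sample(cfg, concentration=3.33)

    def test_concentration_role_consistency(self, cfg):
        with pytest.raises(ValueError, match="concentration"):
            simulate_sample(cfg, concentration=10.0, role="growth_control")
        with pytest.raises(ValueError, match="concentration"):
            simulate_sample(cfg, role="treated")

    def test_event_totals_scale_with_sampled_volume(self):
        # doubling the volume doubles the duration at fixed flow rate and
        # should double expected totals for both cells and debris
        totals = {}
        for vol in (25.0, 50.0):
            acq = AcquisitionMeta(volume_ul=vol)
            counts = [
                simulate_sample(
                    SyntheticConfig(seed=s, acquisition=acq, n0_events=200,
                                    growth_factor=10),
                    role="growth_control").n_events
                for s in range(40)
            ]
            totals[vol] = np.mean(counts)
        assert totals[50.0] / totals[25.0] == pytest.approx(2.0, rel=0.05)

    def test_singlet_area_height_ratio_unimodal_without_doublets(self, cfg):
        t = simulate_sample(replace(cfg, doublet_fraction=0.0),
                            role="growth_control")
        ssc_h = t.channel("SSC-H")
        ratio = t.channel("SSC-A")[ssc_h > 0] / ssc_h[ssc_h > 0]
        # tight unimodal cloud around the singlet gain of 1
        assert np.median(ratio) == pytest.approx(1.0, abs=0.02)
        assert np.quantile(ratio, 0.99) < 1.2


class TestSimulateExperiment:
    def test_table_count(self, cfg):
        tables, _ = simulate_experiment(cfg)
        # growth control + negative control + unstained + one per ladder step
        assert len(tables) == 3 + len(cfg.ladder)

    def test_experiment_deterministic(self, cfg):
        t1, truth1 = simulate_experiment(cfg)
        t2, truth2 = simulate_experiment(cfg)
        assert truth1 == truth2
        for key in t1:
            np.testing.assert_array_equal(t1[key].events, t2[key].events)

    def test_true_mbc_matches_brute_force_scan(self):
        for c50, hill in [(2.0, 4.0), (0.7, 6.0), (40.0, 4.0), (0.01, 8.0)]:
            cfg = SyntheticConfig(kill=KillCurve(c50=c50, hill=hill))
            # independent brute force: lowest c whose survival < 0.1 such
            # that every higher ladder c also kills (Hill is monotone)
            killed = [c for c in cfg.ladder if cfg.kill.survival(c) < 0.1]
            expected = min(killed) if len(killed) and max(cfg.ladder) in killed else None
            assert true_mbc(cfg) == expected

    def test_mean_surviving_events_monotone_in_concentration(self):
        # survival monotonicity should show in intact-event counts
        sums = None
        for seed in range(100):
            cfg = SyntheticConfig(seed=seed, n0_events=150, growth_factor=10,
                                  doublet_fraction=0.0)
            counts = [
                (simulate_sample(cfg, concentration=c).channel("FSC-H")
                 > 10 ** 4.0).sum()
                for c in cfg.ladder
            ]
            sums = np.array(counts) if sums is None else sums + counts
        means = sums / 100
        assert all(a <= b + 3 * np.sqrt(max(b, 1.0) / 100)
                   for a, b in zip(means, means[1:]))


class TestStainedSamples:
    def test_pure_live_has_no_red_population(self, cfg):
        cfg = replace(cfg, spillover=((1.0, 0.0), (0.0, 1.0)))
        t = simulate_stained_sample(cfg, (1.0, 0.0, 0.0, 0.0), n_events=3000)
        # no events at the dead-population red location (log10 ~3.8)
        assert int((t.channel("FL3-H") > 10 ** 3.3).sum()) == 0

    def test_spillover_then_inverse_recovers_intensities(self, cfg):
        spill = np.array([[0.95, 0.05], [0.10, 0.90]])
        mixed = replace(cfg, spillover=tuple(map(tuple, spill)))
        clean = replace(cfg, spillover=((1.0, 0.0), (0.0, 1.0)))
        tm = simulate_stained_sample(mixed, (0.4, 0.4, 0.1, 0.1))
        tc = simulate_stained_sample(clean, (0.4, 0.4, 0.1, 0.1))
        fl = np.column_stack([tm.channel("FL1-H"), tm.channel("FL3-H")])
        unmixed = fl @ np.linalg.inv(spill)
        expected = np.column_stack([tc.channel("FL1-H"), tc.channel("FL3-H")])
        np.testing.assert_allclose(unmixed, expected, rtol=1e-9)

    def test_invalid_fractions_rejected(self, cfg):
        with pytest.raises(ValueError, match="fractions"):
            simulate_stained_sample(cfg, (0.5, 0.5, 0.5, -0.5))
        with pytest.raises(ValueError, match="fractions"):
            simulate_stained_sample(cfg, (0.2, 0.2, 0.2, 0.2))


class TestConfigValidation:
    def test_ladder_must_be_two_fold_descending(self):
        with pytest.raises(ValueError, match="two-fold"):
            SyntheticConfig(ladder=(10.0, 6.0, 3.0))
        with pytest.raises(ValueError, match="two-fold|>= 2"):
            SyntheticConfig(ladder=(10.0,))

    def test_doublet_fraction_bounds(self):
        with pytest.raises(ValueError, match="doublet_fraction"):
            SyntheticConfig(doublet_fraction=0.3)
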