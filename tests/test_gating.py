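"""Gating: transform, threshold, doublet exclusion, back-gated density gate."""

from dataclasses import replace

import numpy as np
import pytest

from cytocide import (EventTable, Gate, GatingConfig, SyntheticConfig,
                      apply_event_threshold, apply_gate, build_bacteria_gate,
                      exclude_doublets, simulate_sample, transform_log)


def _table(fsc, ssc=None, channels=("FSC-H", "SSC-H")):
    fsc = np.asarray(fsc, dtype=float)
    ssc = fsc.copy() if ssc is None else np.asarray(ssc, dtype=float)
    return EventTable(np.column_stack([fsc, ssc]), list(channels))


class TestTransformLog:
    @pytest.mark.parametrize("value,expected", [(1000.0, 3.0), (0.0, 0.0),
                                                (1.0, 0.0), (10.0, 1.0),
                                                (100.0, 2.0)])
    def test_log10_with_floor(self, value, expected):
        t = transform_log(_table([value]), ["FSC-H"], floor=1.0)
        assert t.channel("FSC-H")[0] == pytest.approx(expected)

    def test_untouched_channels_preserved(self):
        t = transform_log(_table([100.0], [7.0]), ["FSC-H"])
        assert t.channel("SSC-H")[0] == 7.0

    def test_missing_channel_errors(self):
        with pytest.raises((KeyError, ValueError)):
            transform_log(_table([1.0]), ["FL1-H"])


class TestEventThreshold:
    def test_threshold_inclusive_at_cut(self):
        t = apply_event_threshold(_table([500.0, 1000.0, 1500.0]),
                                  GatingConfig(fsc_h_threshold=1000.0))
        assert t.n_events == 2
        assert set(t.channel("FSC-H")) == {1000.0, 1500.0}

    def test_empty_table_passes_through(self):
        t = apply_event_threshold(_table([]), GatingConfig())
        assert t.n_events == 0

    def test_zero_threshold_retains_all(self):
        t = apply_event_threshold(_table([1.0, 2.0, 3.0]),
                                  GatingConfig(fsc_h_threshold=0.0))
        assert t.n_events == 3


class TestDoubletExclusion:
    def _crafted(self, n_singlets=2000, n_doublets=200, seed=0):
        """Hand-built ground truth: singlet area ~ height, doublets use the
        generator's gains (area x2, height x1.3)."""
        rng = np.random.default_rng(seed)
        h = 10 ** rng.normal(4.0, 0.15, size=n_singlets)
        a = h * np.exp(rng.normal(0, 0.05, size=n_singlets))
        h1 = 10 ** rng.normal(4.0, 0.15, size=n_doublets)
        h2 = 10 ** rng.normal(4.0, 0.15, size=n_doublets)
        a1 = h1 * np.exp(rng.normal(0, 0.05, size=n_doublets))
        a2 = h2 * np.exp(rng.normal(0, 0.05, size=n_doublets))
        hd = 1.3 * 0.5 * (h1 + h2)
        ad = 2.0 * 0.5 * (a1 + a2)
        heights = np.concatenate([h, hd])
        areas = np.concatenate([a, ad])
        is_doublet = np.arange(len(heights)) >= n_singlets
        table = EventTable(np.column_stack([areas, heights]),
                           ["SSC-A", "SSC-H"])
        return table, is_doublet

    def test_planted_doublets_excluded_singlets_kept(self):
        table, is_doublet = self._crafted()
        result = exclude_doublets(table, GatingConfig())
        kept_heights = result.table.channel("SSC-H")
        # recover which originals were kept by exact height match
        kept = np.isin(table.channel("SSC-H"), kept_heights)
        doublets_removed = (~kept & is_doublet).sum() / is_doublet.sum()
        singlets_lost = (~kept & ~is_doublet).sum() / (~is_doublet).sum()
        assert doublets_removed >= 0.90
        assert singlets_lost <= 0.02

    def test_identical_ratios_exclude_nothing(self):
        # MAD = 0 degenerates to excluding nothing
        table = _table([2.0, 4.0, 8.0], [1.0, 2.0, 4.0],
                       channels=("SSC-A", "SSC-H"))
        result = exclude_doublets(table, GatingConfig())
        assert result.n_excluded == 0
        assert result.table.n_events == 3

    def test_single_event_table(self):
        table = _table([2.0], [1.0], channels=("SSC-A", "SSC-H"))
        result = exclude_doublets(table, GatingConfig())
        assert result.n_excluded == 0

    def test_zero_height_counted_separately(self):
        table = _table([2.0, 3.0, 5.0], [1.0, 0.0, 2.5],
                       channels=("SSC-A", "SSC-H"))
        result = exclude_doublets(table, GatingConfig())
        assert result.n_zero_height == 1
        assert result.table.n_events == 2


def _processed_control(cfg, gating_cfg, role="growth_control"):
    t = apply_event_threshold(simulate_sample(cfg, role=role), gating_cfg)
    return exclude_doublets(t, gating_cfg).table


class TestBacteriaGate:
    def test_gate_captures_intact_population(self, cfg, gating_cfg):
        control = _processed_control(cfg, gating_cfg)
        unstained = simulate_sample(cfg, role="unstained")
        gate = build_bacteria_gate(control, unstained, gating_cfg)
        intact = control.select(control.channel("FL1-H") > 10 ** 3.0)
        _, n_in = apply_gate(intact, gate)
        assert n_in / intact.n_events >= 0.98 * gating_cfg.density_mass

    def test_negative_control_outside_gate(self, cfg, gating_cfg):
        control = _processed_control(cfg, gating_cfg)
        gate = build_bacteria_gate(control, simulate_sample(cfg, role="unstained"),
                                   gating_cfg)
        nc = simulate_sample(cfg, role="negative_control")
        _, n_in = apply_gate(nc, gate)
        assert n_in == 0

    def test_full_density_mass_covers_every_positive_event(self, cfg):
        gcfg = GatingConfig(density_mass=1.0)
        control = _processed_control(cfg, gcfg)
        unstained = simulate_sample(cfg, role="unstained")
        gate = build_bacteria_gate(control, unstained, gcfg)
        cut = np.quantile(unstained.channel("FL1-H"), gcfg.syto9_cut_quantile)
        positives = control.select(control.channel("FL1-H") > cut)
        _, n_in = apply_gate(positives, gate)
        assert n_in == positives.n_events

    def test_gate_deterministic(self, cfg, gating_cfg):
        control = _processed_control(cfg, gating_cfg)
        unstained = simulate_sample(cfg, role="unstained")
        g1 = build_bacteria_gate(control, unstained, gating_cfg)
        g2 = build_bacteria_gate(control, unstained, gating_cfg)
        assert g1 == g2

    def test_density_mass_monotone_in_gate_area(self, cfg):
        control = _processed_control(cfg, GatingConfig())
        unstained = simulate_sample(cfg, role="unstained")
        areas = [
            build_bacteria_gate(control, unstained,
                                GatingConfig(density_mass=m)).area
            for m in (0.5, 0.8, 0.9, 0.98, 0.999)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(areas, areas[1:]))

    def test_too_few_positive_events_errors(self, gating_cfg):
        sparse = SyntheticConfig(seed=1, n0_events=2, growth_factor=1.0)
        control = simulate_sample(sparse, role="growth_control")
        with pytest.raises(ValueError, match="larger"):
            build_bacteria_gate(control, None, gating_cfg)


def _ray_cast(poly, x, y):
    """Independent even-odd ray-casting point-in-polygon (boundary-agnostic)."""
    inside = np.zeros(len(x), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xcross, np.inf))
    return inside


class TestApplyGate:
    unit_square = Gate(kind="polygon", channels=("FSC-H", "SSC-H"),
                       vertices=((0, 0), (1, 0), (1, 1), (0, 1)),
                       transform_tag="linear")

    def test_interior_point_inside(self):
        assert self.unit_square.contains([0.5], [0.5])[0]

    def test_vertex_counts_as_inside(self):
        assert self.unit_square.contains([0.0], [0.0])[0]
        assert self.unit_square.contains([1.0], [0.5])[0]

    def test_membership_matches_ray_casting_oracle(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(0.3, 0.6, size=(3, 2))
        extra = rng.normal(0.7, 0.6, size=(2, 2))
        from scipy.spatial import ConvexHull
        cloud = np.vstack([pts, extra])
        hull = ConvexHull(cloud)
        poly = cloud[hull.vertices]
        gate = Gate(kind="polygon", channels=("FSC-H", "SSC-H"),
                    vertices=tuple(map(tuple, poly)), transform_tag="linear")
        x = rng.uniform(-1.5, 2.0, size=10_000)
        y = rng.uniform(-1.5, 2.0, size=10_000)
        got = gate.contains(x, y)
        expected = _ray_cast(poly, x, y)
        # random continuous points never sit exactly on the boundary, so the
        # two conventions must agree everywhere
        np.testing.assert_array_equal(got, expected)

    def test_polygon_must_be_simple(self):
        with pytest.raises(ValueError, match="simple"):
            Gate(kind="polygon", channels=("FSC-H", "SSC-H"),
                 vertices=((0, 0), (1, 1), (1, 0), (0, 1)))

    def test_gate_serialization_roundtrip(self, tmp_path):
        path = self.unit_square.save(tmp_path / "gate.json")
        assert Gate.load(path) == self.unit_square


class TestPipelineOrderInvariant:
    def test_each_step_only_removes_events(self, cfg, gating_cfg):
        raw = simulate_sample(cfg, role="growth_control")
        t1 = apply_event_threshold(raw, gating_cfg)
        t2 = exclude_doublets(t1, gating_cfg).table
        gate = build_bacteria_gate(t2, simulate_sample(cfg, role="unstained"),
                                   gating_cfg)
        t3, n_in = apply_gate(t2, gate)
        assert raw.n_events >= t1.n_events >= t2.n_events >= t3.n_events
        assert t3.n_events == n_in
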