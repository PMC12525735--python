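"""Default configuration, intake equations, Monte Carlo engine."""

import numpy as np
import pytest

import milkcal as mc
from milkcal.distributions import DistributionSpec


class TestDefaultConfig:
    def test_seven_contiguous_groups(self, default_groups):
        assert len(default_groups) == 7
        bounds = [(g.age_start_months, g.age_end_months) for g in default_groups]
        assert bounds[0][0] == 0 and bounds[-1][1] == 24
        for (_, end), (start, _) in zip(bounds, bounds[1:]):
            assert end == start

    def test_family_assignments(self, default_groups):
        for g in default_groups:
            assert g.feeds.family == "triangular"
            assert g.volume.family == "pert"
            assert g.weight.family == "uniform"
            assert g.density.family in ("normal", "pert")
        by_label = {g.label: g for g in default_groups}
        # normal densities only where pooled heterogeneity was low
        assert by_label["3–6"].density.family == "normal"
        assert by_label["6–9"].density.family == "normal"
        assert sum(g.density.family == "pert" for g in default_groups) == 5

    def test_first_group_parameters(self, group_by_label):
        g = group_by_label["0–1"]
        assert (g.feeds.a, g.feeds.m, g.feeds.b) == (8, 11, 14)
        assert (g.volume.a, g.volume.m, g.volume.b) == (30, 70, 110)
        assert (g.density.a, g.density.m, g.density.b) == (62.10, 63.70, 65.31)
        assert (g.weight.a, g.weight.b) == (3.2, 3.3)

    def test_normal_density_parameters(self, group_by_label):
        d36 = group_by_label["3–6"].density
        assert (d36.mu, d36.sigma) == (61.66, 0.76)
        d69 = group_by_label["6–9"].density
        assert (d69.mu, d69.sigma) == (61.74, 0.79)

    def test_wrong_family_rejected(self, group_by_label):
        g = group_by_label["0–1"]
        with pytest.raises(ValueError, match="feeds"):
            mc.AgeGroupConfig(
                label="bad", age_start_months=0, age_end_months=1,
                feeds=g.volume, volume=g.volume, density=g.density, weight=g.weight,
            )


class TestIntakeEquations:
    @pytest.mark.parametrize(
        "v,d,w,expected",
        [
            (70, 63.70, 3.25, 13.719),
            (100, 100, 1, 100.0),
            (210, 90.43, 11.1, 17.108),
        ],
    )
    def test_per_feed(self, v, d, w, expected):
        assert mc.intake_per_feed(v, d, w) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize(
        "f,pf,expected", [(11, 13.719, 150.9), (1, 42.0, 42.0), (3, 17.108, 51.32)]
    )
    def test_per_day(self, f, pf, expected):
        assert mc.intake_per_day(f, pf) == pytest.approx(expected, abs=5e-2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mc.intake_per_feed(-70, 63.7, 3.25)
        with pytest.raises(ValueError):
            mc.intake_per_feed(70, 63.7, 0)
        with pytest.raises(ValueError):
            mc.intake_per_day(0, 10)


def _point_mass_config(f=6.0, v=150.0, d=62.0, w=7.0):
    # near-degenerate specs collapse each input to (almost) a point
    eps = 1e-9
    return mc.AgeGroupConfig(
        label="point", age_start_months=0, age_end_months=1,
        feeds=mc.make_spec("triangular", {"a": f - eps, "m": f, "b": f + eps}),
        volume=mc.make_spec("pert", {"a": v - eps, "m": v, "b": v + eps}),
        density=mc.make_spec("pert", {"a": d - eps, "m": d, "b": d + eps}),
        weight=mc.make_spec("uniform", {"a": w - eps, "b": w + eps}),
    )


class TestSimulateGroup:
    def test_point_mass_reduces_to_arithmetic(self):
        f, v, d, w = 6.0, 150.0, 62.0, 7.0
        draws = mc.simulate_group(_point_mass_config(f, v, d, w), n_iter=200, seed=1)
        expected = f * v * (d / 100) / w
        np.testing.assert_allclose(draws.per_day, expected, rtol=1e-6)
        np.testing.assert_allclose(draws.per_feed, expected / f, rtol=1e-6)

    def test_per_day_is_feeds_times_per_feed(self, group_by_label):
        draws = mc.simulate_group(group_by_label["9–12"], n_iter=2000, seed=3)
        np.testing.assert_allclose(draws.per_day, draws.feeds * draws.per_feed, rtol=1e-12)

    def test_outcome_bounds_for_bounded_inputs(self, group_by_label):
        """per_day stays inside the algebraic envelope of the input supports."""
        for label in ("0–1", "9–12", "18–24"):  # PERT-density groups
            g = group_by_label[label]
            draws = mc.simulate_group(g, n_iter=5000, seed=5)
            lo = g.feeds.a * g.volume.a * (g.density.a / 100) / g.weight.b
            hi = g.feeds.b * g.volume.b * (g.density.b / 100) / g.weight.a
            assert draws.per_day.min() >= lo
            assert draws.per_day.max() <= hi
            assert np.all(draws.per_day > 0)

    def test_deterministic_given_seed(self, group_by_label):
        a = mc.simulate_group(group_by_label["0–1"], 1000, seed=77)
        b = mc.simulate_group(group_by_label["0–1"], 1000, seed=77)
        np.testing.assert_array_equal(a.per_day, b.per_day)
        c = mc.simulate_group(group_by_label["0–1"], 1000, seed=78)
        assert not np.array_equal(a.per_day, c.per_day)

    def test_mean_close_to_reference(self, group_by_label):
        draws = mc.simulate_group(group_by_label["0–1"], 5000, seed=202)
        assert draws.per_day.mean() == pytest.approx(150.80, rel=0.02)
        draws = mc.simulate_group(group_by_label["18–24"], 5000, seed=202)
        assert draws.per_feed.mean() == pytest.approx(17.11, rel=0.02)


class TestExpectedIntake:
    @pytest.mark.parametrize(
        "label,per_day",
        [("9–12", 84.30), ("0–1", 150.94)],
    )
    def test_closed_form_values(self, group_by_label, label, per_day):
        _, ed = mc.expected_intake(group_by_label[label])
        assert ed == pytest.approx(per_day, abs=0.05)

    def test_point_mass_equals_arithmetic(self):
        f, v, d, w = 6.0, 150.0, 62.0, 7.0
        ef, ed = mc.expected_intake(_point_mass_config(f, v, d, w))
        assert ed == pytest.approx(f * v * (d / 100) / w, rel=1e-6)
        assert ef == pytest.approx(v * (d / 100) / w, rel=1e-6)

    def test_weight_scaling_inverse(self, group_by_label):
        """Scaling both weight bounds by c divides expected intake by c."""
        g = group_by_label["3–6"]
        c = 1.7
        scaled = mc.AgeGroupConfig(
            label=g.label, age_start_months=g.age_start_months,
            age_end_months=g.age_end_months, feeds=g.feeds, volume=g.volume,
            density=g.density,
            weight=mc.make_spec("uniform", {"a": g.weight.a * c, "b": g.weight.b * c}),
        )
        _, base = mc.expected_intake(g)
        _, got = mc.expected_intake(scaled)
        assert got == pytest.approx(base / c, rel=1e-12)


class TestRunAll:
    def test_defaults_shape(self):
        results = mc.run_all(n_iter_per_group=50, master_seed=9)
        assert len(results) == 7
        assert all(r.n_iter == 50 for r in results)
        assert sum(r.n_iter for r in results) == 350

    def test_group_order_invariance(self, default_groups):
        forward = mc.run_all(default_groups, 500, master_seed=11)
        backward = mc.run_all(list(reversed(default_groups)), 500, master_seed=11)
        back = {r.group_label: r for r in backward}
        for r in forward:
            np.testing.assert_array_equal(r.per_day, back[r.group_label].per_day)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mc.run_all([], 10, 1)


class TestConfigIO:
    @pytest.mark.parametrize("ext", ["yaml", "json"])
    def test_round_trip(self, tmp_path, default_groups, ext):
        path = tmp_path / f"cfg.{ext}"
        mc.save_config(default_groups, path)
        loaded = mc.load_config(path)
        assert loaded == default_groups

    def test_invalid_field_diagnosed(self, tmp_path, default_groups):
        path = tmp_path / "cfg.json"
        mc.save_config(default_groups, path)
        text = path.read_text().replace('"a": 8.0,', '"a": 80.0,', 1)  # feeds min > max
        path.write_text(text)
        with pytest.raises(Exception, match="a"):
            mc.load_config(path)

    def test_draws_frame_layout(self, default_groups):
        results = mc.run_all(default_groups[:2], 10, 1)
        frame = mc.draws_frame(results)
        assert len(frame) == 20
        assert list(frame.columns) == [
            "group", "iteration", "feeds", "volume_ml", "density_kcal_dl",
            "weight_kg", "kcal_kg_feed", "kcal_kg_day",
        ]
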