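"""Volumes, centres of mass, distance matrices, ratios and trend fits."""

import itertools

import numpy as np
import pytest

import otomorph as om
from otomorph.grids import LabeledVolume
from otomorph.morphometry import (
    UM3_PER_UL,
    analyze_stage,
    fit_trend,
    parse_gestational_week,
)
from otomorph.phantoms import VESTIBULAR_ORGANS, make_blob_volume


def grid_volume(labels, spacing=1.0, origin=0.0):
    return LabeledVolume(
        labels=np.asarray(labels, dtype=np.int32), spacing_um=spacing, origin_um=origin
    )


class TestLabelVolume:
    def test_block_volume_exact(self):
        vol = grid_volume(np.ones((10, 10, 10)), spacing=10.0)
        assert om.label_volume(vol, 1) == 1e6
        assert om.label_volume(vol, 1) / UM3_PER_UL == pytest.approx(1e-3)

    def test_equals_count_times_voxel_volume_exactly(self):
        rng = np.random.default_rng(0)
        vol = grid_volume(rng.integers(0, 3, (12, 9, 7)), spacing=3.7)
        for lab in (1, 2):
            count = int(np.count_nonzero(vol.labels == lab))
            assert om.label_volume(vol, lab) == count * 3.7**3

    def test_ball_volume_within_5pct(self):
        vol = make_blob_volume({"b": (0.0, 0.0, 0.0)}, {"b": 100.0}, 5.0)
        assert om.label_volume(vol, 1) == pytest.approx(4 / 3 * np.pi * 100**3, rel=0.05)

    def test_absent_label_raises(self):
        vol = grid_volume(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="not present"):
            om.label_volume(vol, 9)

    def test_invariant_under_axis_permutation_and_relabel(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, (8, 6, 4))
        v1 = om.label_volume(grid_volume(labels, 2.0), 1)
        v2 = om.label_volume(grid_volume(labels.transpose(2, 0, 1), 2.0), 1)
        v3 = om.label_volume(grid_volume(labels * 5, 2.0), 5)
        assert v1 == v2 == v3


class TestCenterOfMass:
    def test_single_voxel(self):
        labels = np.zeros((5, 5, 5))
        labels[2, 3, 4] = 1
        vol = grid_volume(labels, spacing=10.0)
        assert np.allclose(om.center_of_mass(vol, 1), [20.0, 30.0, 40.0])

    def test_two_voxel_midpoint(self):
        labels = np.zeros((3, 3, 3))
        labels[0, 0, 0] = 1
        labels[1, 0, 0] = 1
        vol = grid_volume(labels, spacing=10.0)
        assert np.allclose(om.center_of_mass(vol, 1), [5.0, 0.0, 0.0])

    def test_respects_origin(self):
        labels = np.zeros((3, 3, 3))
        labels[1, 1, 1] = 1
        vol = grid_volume(labels, spacing=10.0, origin=(-100.0, 0.0, 50.0))
        assert np.allclose(om.center_of_mass(vol, 1), [-90.0, 10.0, 60.0])


class TestPairwiseDistances:
    def test_three_four_five(self):
        vol = make_blob_volume(
            {"a": (0.0, 0.0, 0.0), "b": (3000.0, 4000.0, 0.0)},
            {"a": 100.0, "b": 100.0}, 10.0,
        )
        dm = om.pairwise_distances(vol, [1, 2])
        assert dm.matrix[0, 1] == pytest.approx(5000.0, abs=5.0)

    def test_matches_phantom_centers_within_half_voxel(self, default_spec):
        vest = om.make_vestibular_phantom(default_spec)
        dm = om.pairwise_distances(vest, [2, 3, 4, 5, 6])
        names = list(VESTIBULAR_ORGANS)
        for i, j in itertools.combinations(range(5), 2):
            true = np.linalg.norm(
                np.subtract(
                    default_spec.blob_centers_um[names[i]],
                    default_spec.blob_centers_um[names[j]],
                )
            )
            assert abs(dm.matrix[i, j] - true) < 0.5 * default_spec.voxel_spacing_um

    def test_symmetry_zero_diagonal(self, default_spec):
        vest = om.make_vestibular_phantom(default_spec)
        dm = om.pairwise_distances(vest, [2, 3, 4, 5, 6])
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)

    def test_absent_label_listed_in_error(self, default_spec):
        vest = om.make_vestibular_phantom(default_spec)
        with pytest.raises(ValueError, match="9"):
            om.pairwise_distances(vest, [2, 9])


class TestVolumeLengthRatio:
    def test_unit_example(self):
        assert om.volume_length_ratio(1e9, 1e4) == pytest.approx(0.1)

    def test_linear_in_volume(self):
        assert om.volume_length_ratio(2e9, 1e4) == 2 * om.volume_length_ratio(1e9, 1e4)

    def test_cylinder_ratio_is_cross_section_area(self):
        """For a straight tube the ratio equals pi r^2 expressed in μl/mm."""
        vol, gt = om.make_cylinder_phantom(5000.0, 100.0, 10.0)
        measured = om.label_volume(vol, 1)
        ratio = om.volume_length_ratio(measured, gt.length_um)
        expected = np.pi * 100.0**2 * 1e3 / UM3_PER_UL  # μl per mm
        assert ratio == pytest.approx(expected, rel=0.03)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            om.volume_length_ratio(1e9, 0.0)


class TestFitTrend:
    def test_exact_line(self):
        fit = fit_trend([(1, 1), (2, 2), (3, 3)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_line_r2_zero_by_convention(self):
        fit = fit_trend([(1, 5), (2, 5), (3, 5)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_seeded_noise_recovers_slope(self):
        rng = np.random.default_rng(42)
        weeks = np.arange(11, 27, 2).astype(float)
        y = 100.0 * weeks + 500.0 + rng.normal(0, 10.0, size=len(weeks))
        fit = fit_trend(list(zip(weeks, y)))
        assert 90.0 <= fit.slope <= 110.0

    def test_identical_weeks_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_trend([(3, 1), (3, 2)])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(10, 40, 12)
        y = rng.normal(size=12)
        fit = fit_trend(list(zip(x, y)))
        X = np.stack([x, np.ones_like(x)], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0])
        assert fit.intercept == pytest.approx(beta[1])


class TestParseWeek:
    @pytest.mark.parametrize("label,week", [("GW19", 19.0), ("gw 11.5", 11.5), ("week36", 36.0)])
    def test_parses(self, label, week):
        assert parse_gestational_week(label) == week

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            parse_gestational_week("apex")


def _stage_series(n_stages=3):
    """Scaled-down inner-ear phantoms with a linear growth schedule."""
    stages = []
    for i in range(n_stages):
        week = 11 + 4 * i
        scale = 0.55 + 0.15 * i
        spec = om.PhantomSpec(
            n_turns=1.5,
            base_radius_um=900.0 * scale,
            apex_radius_um=350.0 * scale,
            pitch_um=300.0 * scale,
            tube_radius_base_um=90.0,
            tube_radius_apex_um=55.0,
            voxel_spacing_um=10.0,
            blob_centers_um={
                k: tuple(np.asarray(v) * scale)
                for k, v in om.phantoms.DEFAULT_BLOB_CENTERS_UM.items()
            },
            blob_radii_um={k: v * 0.7 for k, v in om.phantoms.DEFAULT_BLOB_RADII_UM.items()},
        )
        vol, _ = om.make_inner_ear_phantom(spec)
        stages.append((f"GW{week}", vol))
    return stages


class TestGrowthReport:
    @pytest.fixture(scope="class")
    def series(self):
        return _stage_series(3)

    def test_scheduled_growth_gives_monotone_length(self, series):
        table, trends = om.growth_report(series, 1, [2, 3, 4, 5, 6])
        lengths = table["duct_length_um"].to_numpy()
        assert np.all(np.diff(lengths) > 0)
        assert len(table) == 3
        slope = trends.set_index("quantity").loc["duct_length_um", "slope_per_week"]
        assert slope > 0

    def test_single_stage_has_no_trends(self, series):
        table, trends = om.growth_report(series[:1], 1, [2, 3, 4, 5, 6])
        assert len(table) == 1
        assert trends.empty

    def test_missing_label_names_stage_and_label(self, series):
        stage, vol = series[0]
        broken = LabeledVolume(
            labels=np.where(vol.labels == 6, 0, vol.labels),
            spacing_um=vol.spacing_um,
            origin_um=vol.origin_um,
            label_names=vol.label_names,
        )
        with pytest.raises(ValueError, match="GW11"):
            om.growth_report([(stage, broken)], 1, [2, 3, 4, 5, 6])

    def test_report_fields_consistent(self, series):
        rep = analyze_stage(series[0][0], series[0][1], 1, [2, 3, 4, 5, 6])
        assert rep.volume_length_ratio_ul_per_mm == pytest.approx(
            rep.duct_volume_ul / rep.duct_length_mm
        )
        assert rep.distances is not None
        assert len(rep.distances.names) == 5
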