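import math

import numpy as np
import pytest

import nephroflow as nf
from nephroflow import synthdata as sd
from nephroflow.io import ImageSeries
from nephroflow.tubule import SeedAnnotation, TubulePath, trace_tubule, tubule_volume

from conftest import seeds_from_phantom


def make_path(radii, spacing=1.0, length=None):
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    s = np.arange(n) * spacing if length is None else np.linspace(0, length, n)
    pts = np.column_stack([s, np.zeros(n)])
    return TubulePath(points_um=pts, s_um=s, radius_um=radii)


class TestVolume:
    def test_uniform_cylinder(self):
        path = make_path(np.full(101, 10.0))
        expected = math.pi * 10.0**2 * 100.0
        assert tubule_volume(path) == pytest.approx(expected, rel=1e-12)
        assert path.cylinder_volume_um3 == pytest.approx(expected, rel=1e-12)

    def test_unit_case(self):
        r = 0.5641895835477563  # area exactly 1 µm²
        path = make_path([r, r], spacing=1.0)
        assert tubule_volume(path) == pytest.approx(1.0, rel=1e-9)

    def test_taper_against_numeric_integration(self):
        n = 61
        radii = np.linspace(10.0, 5.0, n)
        path = make_path(radii, length=60.0)
        s_fine = np.linspace(0, 60.0, 600_001)
        r_fine = np.interp(s_fine, path.s_um, radii)
        oracle = np.trapezoid(math.pi * r_fine**2, s_fine)
        assert tubule_volume(path) == pytest.approx(oracle, rel=5e-3)

    def test_resampling_invariance(self):
        def vol(spacing):
            s = np.arange(0, 60.0 + 1e-9, spacing)
            radii = 10.0 - s / 12.0  # taper 10 -> 5
            pts = np.column_stack([s, np.zeros_like(s)])
            return tubule_volume(TubulePath(points_um=pts, s_um=s, radius_um=radii))

        assert vol(0.25) == pytest.approx(vol(1.0), rel=5e-3)

    def test_nonpositive_radius_error(self):
        path = make_path([10.0, -1.0, 10.0])
        path.radius_ok[:] = True
        with pytest.raises(ValueError, match="non-positive"):
            tubule_volume(path)

    def test_length_is_sum_of_segments(self, clean_path):
        seg = np.linalg.norm(np.diff(clean_path.points_um, axis=0), axis=1)
        assert clean_path.length_um == pytest.approx(seg.sum(), abs=1e-6)

    def test_rigid_motion_invariance(self):
        radii = np.linspace(8, 10, 61)
        base = make_path(radii, length=60.0)
        theta = 0.73
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = TubulePath(points_um=base.points_um @ rot.T + [12.3, -4.5],
                           s_um=base.s_um, radius_um=radii)
        assert moved.length_um == pytest.approx(base.length_um, abs=1e-9)
        assert tubule_volume(moved) == pytest.approx(tubule_volume(base), rel=1e-12)


class TestTrace:
    def test_diameter_recovery_noise_free(self, clean_path, clean_phantom,
                                          clean_series):
        # true diameter 20 µm, tolerance one in-plane pixel
        assert abs(clean_path.mean_diameter_um - 20.0) <= clean_phantom.pixel_size_um

    def test_length_and_inclusion_flag(self):
        ph = sd.straight_nephron(length_um=45.0, radius_um=8, sngfr_nl_min=2.0,
                                 noise_model=None)
        series, _ = sd.generate_filling_series(ph)
        path = trace_tubule(series, seeds_from_phantom(ph, every=5))
        assert path.length_um == pytest.approx(45.0, abs=1.5)
        assert path.meets_length_criterion

    def test_short_tubule_flagged_not_included(self):
        ph = sd.straight_nephron(length_um=30.0, radius_um=8, sngfr_nl_min=2.0,
                                 noise_model=None, allow_short=True)
        series, _ = sd.generate_filling_series(ph)
        path = trace_tubule(series, seeds_from_phantom(ph, every=5))
        assert not path.meets_length_criterion

    def test_offset_seeds_snap_to_centerline(self, clean_phantom, clean_series):
        series, _ = clean_series
        seeds = nf.SeedAnnotation(
            points_px=(clean_phantom.centerline_um[::10] + [0.0, 3.0])
            / clean_phantom.pixel_size_um - 0.5
        )
        path = trace_tubule(series, seeds)
        true_y = clean_phantom.centerline_um[0, 1]
        rms = float(np.sqrt(np.mean((path.points_um[:, 1] - true_y) ** 2)))
        assert rms < 0.5

    def test_diameter_recovery_sweep_default_snr(self):
        # property: <5% mean-diameter error across radii 5..15 at default noise
        rng = np.random.default_rng(11)
        errors = []
        for i in range(50):
            r = float(rng.uniform(5.0, 15.0))
            ph = sd.straight_nephron(length_um=70, radius_um=r, sngfr_nl_min=3.0,
                                     seed=int(rng.integers(2**31)))
            series, _ = sd.generate_filling_series(ph)
            path = trace_tubule(series, seeds_from_phantom(ph))
            errors.append(abs(path.mean_diameter_um - 2 * r) / (2 * r))
        assert float(np.median(errors)) < 0.05

    def test_too_few_seeds_rejected(self):
        with pytest.raises(ValueError, match="two points"):
            SeedAnnotation(points_px=[[5.0, 5.0]])

    def test_out_of_bounds_seeds_rejected(self, clean_series):
        series, _ = clean_series
        seeds = SeedAnnotation(points_px=[[10.0, 10.0], [1e5, 1e5]])
        with pytest.raises(ValueError, match="bounds"):
            trace_tubule(series, seeds)

    def test_self_intersecting_path_error(self):
        img = np.full((3, 100, 100), 10.0)
        series = ImageSeries(data=img, pixel_size_um=1.0, frame_interval_s=1 / 6)
        crossing = SeedAnnotation(
            points_px=[[10, 10], [80, 80], [80, 10], [10, 80]]
        )
        with pytest.raises(ValueError, match="self-intersects at"):
            trace_tubule(series, crossing)

    def test_flat_image_flags_unreliable_radii(self):
        img = np.full((3, 60, 60), 10.0)
        series = ImageSeries(data=img, pixel_size_um=1.0, frame_interval_s=1 / 6)
        path = trace_tubule(series, SeedAnnotation(points_px=[[5, 30], [55, 30]]))
        assert not path.radius_ok.any()
        assert math.isnan(path.mean_diameter_um)

    def test_roi_json_roundtrip(self, tmp_path):
        seeds = SeedAnnotation(points_px=[[1.5, 2.5], [10.0, 12.0]],
                               image="demo.tif", made_by="tester")
        f = tmp_path / "roi.json"
        seeds.to_json(f)
        back = SeedAnnotation.from_json(f)
        np.testing.assert_array_equal(back.points_px, seeds.points_px)
        assert back.image == "demo.tif"

    def test_path_csv_export(self, tmp_path, clean_path):
        f = tmp_path / "path.csv"
        clean_path.to_csv(f)
        import pandas as pd

        df = pd.read_csv(f)
        assert list(df.columns) == ["s_um", "x_um", "y_um", "radius_um", "radius_ok"]
        assert len(df) == len(clean_path.points_um)


class TestTraceRotationInvariance:
    def test_rotated_phantom_same_geometry(self):
        def traced(angle_deg):
            theta = math.radians(angle_deg)
            rot = np.array([[math.cos(theta), -math.sin(theta)],
                            [math.sin(theta), math.cos(theta)]])
            n = 81
            base = np.column_stack([np.linspace(0, 80, n), np.zeros(n)])
            center = base @ rot.T + [45.0, 45.0]
            ph = sd.NephronPhantom(
                centerline_um=center, radius_um=8.0, true_sngfr_nl_min=3.0,
                noise_model=None, fov_shape_px=(360, 360),
            )
            series, _ = sd.generate_filling_series(ph)
            return trace_tubule(series, seeds_from_phantom(ph))

        p0, p35 = traced(0.0), traced(35.0)
        assert p35.length_um == pytest.approx(p0.length_um, abs=1.0)
        assert p35.mean_diameter_um == pytest.approx(p0.mean_diameter_um, abs=0.3)
        assert p35.volume_um3 == pytest.approx(p0.volume_um3, rel=0.05)
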