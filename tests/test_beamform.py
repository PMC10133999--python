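import math
import warnings

import numpy as np
import pytest

from patdas import (
    ImageGrid,
    Phantom,
    ReconImage,
    ScanGeometry,
    Sinogram,
    ValidationError,
    das_reconstruct,
    delay_to_sample,
    detector_positions,
    fbp_weighting_term,
    forward_pressure,
    normalize_image,
)


def brute_force_das(sinogram, grid, interpolation="linear"):
    """Independent triple-loop delay-and-sum used as oracle."""
    geometry = sinogram.geometry
    det = detector_positions(geometry)
    out = np.zeros((grid.ny, grid.nx))
    for i in range(grid.ny):
        y = ((grid.ny - 1) / 2 - i) * grid.pixel_size
        for j in range(grid.nx):
            x = (j - (grid.nx - 1) / 2) * grid.pixel_size
            acc = 0.0
            for k in range(geometry.n_positions):
                d = math.hypot(x - det[k][0], y - det[k][1])
                idx = (d / geometry.speed_of_sound - geometry.time_offset) * \
                    geometry.sampling_frequency
                if idx < 0 or idx > geometry.n_samples - 1:
                    continue
                if interpolation == "nearest":
                    acc += sinogram.data[k, round(idx)]
                else:
                    i0 = math.floor(idx)
                    f = idx - i0
                    v0 = sinogram.data[k, i0]
                    v1 = sinogram.data[k, i0 + 1] if i0 + 1 <= geometry.n_samples - 1 else 0.0
                    acc += (1 - f) * v0 + f * v1
            out[i, j] = acc
    return out


class TestDetectorPositions:
    def test_four_positions_on_axes(self):
        g = ScanGeometry(radius=41e-3, n_positions=4, angle_step=90.0,
                         speed_of_sound=1500.0, sampling_frequency=25e6, n_samples=10)
        pos = detector_positions(g)
        np.testing.assert_allclose(
            pos, [[41e-3, 0], [0, 41e-3], [-41e-3, 0], [0, -41e-3]], atol=1e-17
        )

    def test_all_positions_on_circle(self, small_geometry):
        pos = detector_positions(small_geometry)
        np.testing.assert_allclose(np.hypot(pos[:, 0], pos[:, 1]),
                                   small_geometry.radius, rtol=1e-12)

    def test_last_of_800_positions_at_359_55_degrees(self, sim_geometry):
        pos = detector_positions(sim_geometry)
        angle = math.degrees(math.atan2(pos[-1, 1], pos[-1, 0])) % 360
        assert angle == pytest.approx(359.55, abs=1e-9)


class TestDelayToSample:
    @pytest.mark.parametrize(
        "distance, expected",
        [(15e-3, 250.0), (0.0, 0.0), (41e-3, 683.3333333333334)],
    )
    def test_known_delays(self, sim_geometry, distance, expected):
        assert delay_to_sample(distance, sim_geometry) == pytest.approx(expected)

    def test_time_offset_shifts_index(self):
        g = ScanGeometry(radius=41e-3, n_positions=1, angle_step=0.0,
                         speed_of_sound=1500.0, sampling_frequency=25e6,
                         n_samples=100, time_offset=4e-6)
        assert delay_to_sample(15e-3, g) == pytest.approx(150.0)


class TestDasReconstruct:
    def test_zero_sinogram_gives_zero_image(self, small_geometry):
        sino = Sinogram(np.zeros((16, 1200)), small_geometry)
        grid = ImageGrid(nx=11, ny=11, pixel_size=1e-3)
        assert not das_reconstruct(sino, grid).values.any()

    def test_single_detector_arc_hand_example(self):
        # one detector at (41, 0) mm, unit impulse at sample 250 (15 mm);
        # the pixel 15 mm away receives exactly 1, a pixel 20 mm away nothing
        g = ScanGeometry(radius=41e-3, n_positions=1, angle_step=0.0,
                         speed_of_sound=1500.0, sampling_frequency=25e6,
                         n_samples=500)
        data = np.zeros((1, 500))
        data[0, 250] = 1.0
        grid = ImageGrid(nx=53, ny=1, pixel_size=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            img = das_reconstruct(Sinogram(data, g), grid).values
        x_mm = grid.x_coords * 1e3
        assert img[0, np.argmin(abs(x_mm - 26))] == pytest.approx(1.0)  # 15 mm away
        assert img[0, np.argmin(abs(x_mm - 21))] == 0.0  # 20 mm away

    def test_linearity_in_sinogram(self, random_sinogram):
        grid = ImageGrid(nx=9, ny=9, pixel_size=1e-3)
        one = das_reconstruct(random_sinogram, grid).values
        doubled = Sinogram(2 * random_sinogram.data, random_sinogram.geometry)
        np.testing.assert_array_equal(das_reconstruct(doubled, grid).values, 2 * one)

    @pytest.mark.parametrize("interpolation", ["linear", "nearest"])
    def test_matches_brute_force_oracle(self, interpolation):
        g = ScanGeometry(radius=41e-3, n_positions=8, angle_step=45.0,
                         speed_of_sound=1500.0, sampling_frequency=25e6,
                         n_samples=800)
        rng = np.random.default_rng(7)
        sino = Sinogram(rng.standard_normal((8, 800)), g)
        grid = ImageGrid(nx=10, ny=10, pixel_size=1e-3)
        fast = das_reconstruct(sino, grid, interpolation=interpolation).values
        slow = brute_force_das(sino, grid, interpolation)
        # 1e-10 relative to the image magnitude (pixels where the detector
        # sum nearly cancels have no meaningful relative scale of their own)
        np.testing.assert_allclose(fast, slow, rtol=1e-10,
                                   atol=1e-10 * np.abs(slow).max())

    def test_detector_contributions_decompose(self, small_geometry):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((16, 1200))
        grid = ImageGrid(nx=7, ny=7, pixel_size=1e-3)
        full = das_reconstruct(Sinogram(data, small_geometry), grid).values
        partial = np.zeros_like(full)
        for k in range(16):
            solo = np.zeros_like(data)
            solo[k] = data[k]
            partial += das_reconstruct(Sinogram(solo, small_geometry), grid).values
        np.testing.assert_allclose(partial, full, rtol=1e-10, atol=1e-12)

    def test_point_source_localization_within_one_pixel(self):
        g = ScanGeometry(radius=41e-3, n_positions=200, angle_step=1.8,
                         speed_of_sound=1500.0, sampling_frequency=25e6,
                         n_samples=1500)
        cx, cy = 4.3e-3, -2.7e-3
        sino = forward_pressure(Phantom(((cx, cy, 0.05e-3, 1.0),)), g)
        img = das_reconstruct(sino)
        i, j = np.unravel_index(np.argmax(np.abs(img.values)), img.values.shape)
        true_j = cx / 1e-4 + (250 - 1) / 2
        true_i = (250 - 1) / 2 - cy / 1e-4
        assert math.hypot(i - true_i, j - true_j) <= 1.0

    def test_rotating_sinogram_rows_rotates_image(self):
        g = ScanGeometry(radius=41e-3, n_positions=8, angle_step=45.0,
                         speed_of_sound=1500.0, sampling_frequency=25e6,
                         n_samples=1200)
        ph = Phantom(((5e-3, 1e-3, 0.8e-3, 1.0), (-2e-3, -6e-3, 0.5e-3, 0.7)))
        sino = forward_pressure(ph, g)
        grid = ImageGrid(nx=41, ny=41, pixel_size=0.5e-3)
        base = das_reconstruct(sino, grid).values
        shifted = Sinogram(np.roll(sino.data, 2, axis=0), g)  # 2 x 45 = 90 deg
        turned = das_reconstruct(shifted, grid).values
        diff = np.abs(turned - np.rot90(base, 1)).max() / np.abs(base).max()
        assert diff < 1e-6

    def test_grid_beyond_scan_radius_warns(self, small_geometry):
        sino = Sinogram(np.zeros((16, 1200)), small_geometry)
        grid = ImageGrid(nx=1000, ny=1000, pixel_size=1e-4)
        with pytest.warns(UserWarning, match="scan radius"):
            das_reconstruct(sino, grid)


class TestFbpWeightingTerm:
    def test_constant_trace_gives_twice_pressure(self, small_geometry):
        sino = Sinogram(np.full((16, 1200), 3.5), small_geometry)
        np.testing.assert_allclose(fbp_weighting_term(sino).data, 7.0)

    def test_linear_ramp_through_origin_cancels(self):
        g = ScanGeometry(radius=41e-3, n_positions=2, angle_step=10.0,
                         speed_of_sound=1500.0, sampling_frequency=25e6,
                         n_samples=100, time_offset=0.0)
        alpha = 3e6
        p = alpha * g.sample_times
        sino = Sinogram(np.tile(p, (2, 1)), g)
        b = fbp_weighting_term(sino).data
        np.testing.assert_allclose(b[:, 1:-1], 0.0, atol=1e-9)

    def test_first_sample_at_time_zero_is_twice_pressure(self):
        g = ScanGeometry(radius=41e-3, n_positions=1, angle_step=0.0,
                         speed_of_sound=1500.0, sampling_frequency=25e6,
                         n_samples=50, time_offset=0.0)
        rng = np.random.default_rng(3)
        sino = Sinogram(rng.standard_normal((1, 50)), g)
        b = fbp_weighting_term(sino).data
        assert b[0, 0] == pytest.approx(2 * sino.data[0, 0])

    def test_derivative_scale_reproduces_literal_ct_form(self, random_sinogram):
        c = random_sinogram.geometry.speed_of_sound
        t = random_sinogram.geometry.sample_times
        dpdt = np.gradient(random_sinogram.data, t, axis=1)
        expected = 2 * random_sinogram.data - 2 * c * t[None, :] * dpdt
        got = fbp_weighting_term(random_sinogram, derivative_scale=c).data
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_too_few_samples_rejected(self):
        g = ScanGeometry(radius=41e-3, n_positions=1, angle_step=0.0,
                         speed_of_sound=1500.0, sampling_frequency=25e6,
                         n_samples=2)
        with pytest.raises(ValidationError):
            fbp_weighting_term(Sinogram(np.zeros((1, 2)), g))


class TestNormalizeImage:
    def test_scales_by_max_absolute_value(self):
        grid = ImageGrid(nx=2, ny=1, pixel_size=1e-3)
        img = normalize_image(ReconImage(np.array([[2.0, -4.0]]), grid))
        np.testing.assert_array_equal(img.values, [[0.5, -1.0]])
        assert img.normalized

    def test_idempotent(self):
        grid = ImageGrid(nx=3, ny=1, pixel_size=1e-3)
        img = ReconImage(np.array([[0.1, -0.7, 0.3]]), grid)
        once = normalize_image(img)
        twice = normalize_image(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_zero_image_rejected(self):
        grid = ImageGrid(nx=3, ny=1, pixel_size=1e-3)
        with pytest.raises(ValidationError):
            normalize_image(ReconImage(np.zeros((1, 3)), grid))
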