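import itertools

import numpy as np
import pytest

from aortaflex import phantom, segmentation
from aortaflex.segmentation import (
    Contour,
    PolarMap,
    SegmentationParams,
    contour_area,
    enhance_edges,
    find_contour,
    polygon_area,
    segment_series,
    to_polar,
)
from conftest import disk_image


class TestEnhanceEdges:
    def test_disk_boundary_argmax_every_angle(self):
        img = disk_image(size=64, radius=15.0)
        edges = enhance_edges(img)
        polar = to_polar(edges, ((64 - 1) / 2.0,) * 2, n_angles=90, n_radii=28,
                         radial_step=1.0)
        argmax_r = polar.radii[np.argmax(polar.samples, axis=1)]
        assert np.all(np.abs(argmax_r - 15.0) <= 1.0)

    def test_constant_image_zero_map(self):
        assert np.all(enhance_edges(np.full((32, 32), 3.7)) == 0.0)

    def test_gradient_fallback_same_contract(self):
        img = disk_image(size=64, radius=15.0)
        edges = enhance_edges(img, method="gradient")
        polar = to_polar(edges, ((64 - 1) / 2.0,) * 2, n_angles=90, n_radii=28,
                         radial_step=1.0)
        argmax_r = polar.radii[np.argmax(polar.samples, axis=1)]
        assert np.all(np.abs(argmax_r - 15.0) <= 1.0)

    def test_noisy_disk_argmax_mostly_on_boundary(self):
        # Monte-Carlo: noise sd = 10 % of contrast; >= 90 % of angles within 2 px
        hits, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            img = disk_image(size=64, radius=15.0) + rng.normal(0, 0.08, (64, 64))
            edges = enhance_edges(img)
            polar = to_polar(edges, ((64 - 1) / 2.0,) * 2, n_angles=90,
                             n_radii=28, radial_step=1.0)
            argmax_r = polar.radii[np.argmax(polar.samples, axis=1)]
            hits += int(np.sum(np.abs(argmax_r - 15.0) <= 2.0))
            total += argmax_r.size
        assert hits / total >= 0.90

    def test_nonfinite_rejected(self):
        img = np.ones((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            enhance_edges(img)


class TestToPolar:
    def test_concentric_rings_constant_per_angle(self):
        size = 65
        c = (size - 1) / 2.0
        yy, xx = np.indices((size, size), dtype=float)
        rr = np.hypot(xx - c, yy - c)
        img = np.sin(rr / 3.0)
        polar = to_polar(img, (c, c), n_angles=60, n_radii=25, radial_step=1.0)
        spread = polar.samples.max(axis=0) - polar.samples.min(axis=0)
        assert spread.max() < 0.05  # rotational symmetry up to interpolation

    def test_shifted_center_geometry(self):
        img = disk_image(size=64, radius=15.0)
        c = (64 - 1) / 2.0
        polar = to_polar(img, (c + 2.0, c), n_angles=120, n_radii=30, radial_step=1.0)
        # boundary radius per angle = last radius still inside the disk
        boundary = np.array([polar.radii[row > 0.5][-1] for row in polar.samples])
        assert boundary.max() - boundary.min() > 2.0  # angle-dependent now
        assert np.all(np.abs(boundary - 15.0) <= 2.0 + 1.0)  # max shift = offset

    def test_round_trip_rms(self):
        # polar -> cartesian round trip on a smooth image
        from scipy.interpolate import RegularGridInterpolator

        size = 65
        c = (size - 1) / 2.0
        yy, xx = np.indices((size, size), dtype=float)
        img = np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * 9.0**2))
        polar = to_polar(img, (c, c), n_angles=360, n_radii=56, radial_step=0.5)
        ang = np.concatenate([polar.angles, [2 * np.pi]])
        samp = np.vstack([polar.samples, polar.samples[:1]])  # wrap angle
        interp = RegularGridInterpolator((ang, polar.radii), samp,
                                         bounds_error=False, fill_value=None)
        rr = np.hypot(xx - c, yy - c)
        th = np.mod(np.arctan2(yy - c, xx - c), 2 * np.pi)
        inside = (rr >= polar.radii[0]) & (rr <= polar.radii[-1])
        recon = interp(np.column_stack([th[inside], rr[inside]]))
        rms = np.sqrt(np.mean((recon - img[inside]) ** 2))
        assert rms < 0.02 * (img.max() - img.min())

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError, match="center"):
            to_polar(np.zeros((16, 16)), (20.0, 5.0))

    def test_out_of_image_flagged(self):
        polar = to_polar(np.ones((16, 16)), (14.0, 8.0), n_angles=8, n_radii=10,
                         radial_step=1.0)
        assert polar.out_of_image.any()


def _peak_energy(n_angles: int, n_radii: int, peak_idx, strength=1.0, width=1.0):
    """Polar energy map with a Gaussian radial peak per angle."""
    r = np.arange(n_radii)
    peaks = np.broadcast_to(np.asarray(peak_idx, dtype=float), (n_angles,))
    s = np.broadcast_to(np.asarray(strength, dtype=float), (n_angles,))
    return s[:, None] * np.exp(-((r[None, :] - peaks[:, None]) ** 2) / (2 * width**2))


def _polar_from_energy(energy: np.ndarray, radial_step: float = 1.0) -> PolarMap:
    n_ang, n_rad = energy.shape
    return PolarMap(
        samples=energy,
        angles=np.arange(n_ang) * 2 * np.pi / n_ang,
        radii=(np.arange(n_rad) + 1.0) * radial_step,
        center_xy=(0.0, 0.0),
        out_of_image=np.zeros_like(energy, dtype=bool),
    )


class TestFindContour:
    def test_noiseless_disk_recovery(self):
        img = disk_image(size=80, radius=20.0)
        c = (80 - 1) / 2.0
        edges = enhance_edges(img)
        polar = to_polar(edges, (c, c), n_angles=180, n_radii=64, radial_step=0.5)
        contour = find_contour(polar, smoothness=2)
        assert np.all(np.abs(contour.radii_px - 20.0) <= 0.5)
        assert abs(contour.area_mm2 - np.pi * 400.0) / (np.pi * 400.0) < 0.02

    def test_locks_onto_stronger_inner_edge(self):
        energy = (_peak_energy(36, 30, 10, strength=1.0)
                  + _peak_energy(36, 30, 20, strength=0.5))
        contour = find_contour(_polar_from_energy(energy), smoothness=2, refine=False)
        assert np.all(contour.radii_px == 11.0)  # index 10 -> radius 11

    def test_single_angle_degenerates_to_argmax(self):
        rng = np.random.default_rng(0)
        energy = rng.random((1, 12))
        contour = find_contour(_polar_from_energy(energy), smoothness=None, refine=False)
        assert contour.radii_px[0] == np.argmax(energy[0]) + 1.0

    def test_smoothness_none_is_columnwise_argmax(self):
        rng = np.random.default_rng(1)
        energy = rng.random((9, 14))
        contour = find_contour(_polar_from_energy(energy), smoothness=None, refine=False)
        assert np.array_equal(contour.radii_px, np.argmax(energy, axis=1) + 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_dp_equals_bruteforce_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_ang, n_rad, sm = 6, 8, 1
        energy = rng.random((n_ang, n_rad))
        contour = find_contour(_polar_from_energy(energy), smoothness=sm, refine=False)
        dp_cost = energy[np.arange(n_ang), (contour.radii_px - 1.0).astype(int)].sum()
        best = -np.inf
        for path in itertools.product(range(n_rad), repeat=n_ang):
            jumps = [abs(path[i] - path[(i + 1) % n_ang]) for i in range(n_ang)]
            if max(jumps) <= sm:
                best = max(best, sum(energy[i, r] for i, r in enumerate(path)))
        assert dp_cost == pytest.approx(best, abs=1e-12)

    def test_closure_constraint_holds(self):
        rng = np.random.default_rng(2)
        energy = rng.random((24, 16))
        contour = find_contour(_polar_from_energy(energy), smoothness=2, refine=False)
        idx = (contour.radii_px - 1.0).astype(int)
        wrapped = np.abs(np.diff(np.append(idx, idx[0])))
        assert wrapped.max() <= 2

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            find_contour(_polar_from_energy(np.empty((0, 0))))


class TestContourArea:
    def test_square_exact(self):
        x = np.array([0.0, 10.0, 10.0, 0.0])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        assert polygon_area(x, y) == pytest.approx(100.0)

    def test_360gon_approximates_circle(self):
        r = 11.28
        angles = np.arange(360) * 2 * np.pi / 360
        contour = Contour(angles=angles, radii_px=np.full(360, r),
                          center_xy=(0.0, 0.0), pixel_mm=1.0)
        exact = np.pi * r**2  # 399.87; inscribed 360-gon is slightly smaller
        assert contour_area(contour) == pytest.approx(exact, rel=1e-4)
        assert contour_area(contour) < exact

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="3 vertices"):
            polygon_area(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestSegmentSeries:
    def test_recovers_truth_areas(self, noisy_cine):
        cine, truth, cfg = noisy_cine
        result = segment_series(cine, cfg.center_xy)
        rel = np.abs(result.areas_mm2() - truth.areas_mm2) / truth.areas_mm2
        assert rel.max() < 0.02

    def test_seed_offset_robustness(self, small_cine):
        cine, truth, cfg = small_cine
        r0 = np.sqrt(truth.areas_mm2[0] / np.pi) / cine.pixel_mm
        seed = (cfg.center_xy[0] + 0.3 * r0, cfg.center_xy[1])
        result = segment_series(cine, seed)
        rel = np.abs(result.areas_mm2() - truth.areas_mm2) / truth.areas_mm2
        assert rel.max() < 0.02

    def test_constant_cine_temporal_consistency(self):
        spec = phantom.WaveformSpec(a_min=420.0, a_max=420.0)
        cfg = phantom.PhantomConfig(image_size=96, pixel_mm=1.0, n_frames=5, seed=2)
        cine, _ = phantom.render_cine(spec, cfg)
        result = segment_series(cine, cfg.center_xy)
        base = result.contours[0].radii_px
        for contour in result.contours[1:]:
            rms = np.sqrt(np.mean((contour.radii_px - base) ** 2))
            assert rms < 0.5

    def test_determinism(self, noisy_cine):
        cine, _, cfg = noisy_cine
        a = segment_series(cine, cfg.center_xy)
        b = segment_series(cine, cfg.center_xy)
        for ca, cb in zip(a.contours, b.contours):
            assert np.array_equal(ca.radii_px, cb.radii_px)

    def test_rotation_equivariance(self, rest_waveform):
        cfg = phantom.PhantomConfig(image_size=96, pixel_mm=1.0, n_frames=3,
                                    ellipticity=0.85, seed=4)
        cine, _ = phantom.render_cine(rest_waveform, cfg)
        rotated = type(cine)(
            frames=np.rot90(cine.frames, axes=(1, 2)).copy(),
            pixel_mm=cine.pixel_mm, frame_times=cine.frame_times,
        )
        a = segment_series(cine, cfg.center_xy).areas_mm2()
        b = segment_series(rotated, cfg.center_xy).areas_mm2()
        assert np.all(np.abs(a - b) / a < 0.005)

    def test_monotone_degradation_with_noise(self, rest_waveform):
        mean_err = []
        for noise in (0.0, 0.05, 0.15):
            errs = []
            for seed in range(6):
                cfg = phantom.PhantomConfig(image_size=112, pixel_mm=0.8, n_frames=3,
                                            noise_sd=noise, seed=100 + seed)
                cine, truth = phantom.render_cine(rest_waveform, cfg)
                est = segment_series(cine, cfg.center_xy).areas_mm2()
                errs.append(np.mean(np.abs(est - truth.areas_mm2) / truth.areas_mm2))
            mean_err.append(np.mean(errs))
        assert mean_err[0] <= mean_err[1] + 1e-4
        assert mean_err[1] <= mean_err[2] + 1e-4

    def test_blank_series_aborts_with_frame_index(self):
        from aortaflex.io import CineSeries

        blank = CineSeries(frames=np.zeros((3, 48, 48)), pixel_mm=1.0,
                           frame_times=np.array([0.0, 30.0, 60.0]))
        with pytest.raises(RuntimeError, match="frame 0"):
            segment_series(blank, (24.0, 24.0))

    def test_params_recorded_in_provenance(self, small_cine):
        cine, _, cfg = small_cine
        result = segment_series(cine, cfg.center_xy, SegmentationParams(n_angles=90))
        assert result.provenance["params"]["n_angles"] == 90
        assert tuple(result.provenance["seed_point_xy"]) == cfg.center_xy
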