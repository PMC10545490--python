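"""ΔF/F, beat segmentation, activation mapping, isochrones, velocity."""

import numpy as np
import pytest

from cardiopair.calcium import (
    ActivationMap,
    CalciumMovie,
    NoBeatsError,
    VelocityUndefinedError,
    activation_map,
    delta_f_over_f,
    estimate_velocity,
    isochrones,
    segment_beats,
)
from cardiopair.synthetic import CalciumSpec, gen_calcium_movie


@pytest.fixture(scope="module")
def clean_movie(small_tissue):
    cs = CalciumSpec(geometry=small_tissue, velocity=15.0, noise_sd=0.0,
                     n_beats=2, seed=1)
    movie, truth = gen_calcium_movie(cs)
    return cs, movie, truth


def run_pipeline(movie, roi_mask, **dff_kw):
    dff = delta_f_over_f(movie, **dff_kw)
    beats = segment_beats(dff)
    amap = activation_map(dff, window=beats.windows[0])
    return beats, amap, estimate_velocity(amap, roi_mask=roi_mask)


class TestDeltaFOverF:
    def test_constant_trace_maps_to_zero(self, small_tissue):
        mask = small_tissue.mask(40.0)
        frames = np.full((50, *mask.shape), 80.0, dtype=np.float32)
        movie = CalciumMovie(frames, 1.0, 40.0, mask)
        dff = delta_f_over_f(movie)
        assert np.allclose(dff.frames[:, mask], 0.0, atol=1e-6)

    def test_noise_free_max_equals_amplitude(self, clean_movie):
        # tolerance covers frame-grid sampling of the transient peak and
        # the small upward bias of the 10th-percentile baseline when the
        # diastolic interval is short relative to the decay constant
        cs, movie, _ = clean_movie
        dff = delta_f_over_f(movie)
        peaks = np.nanmax(dff.frames[:, dff.tissue_mask], axis=0)
        assert np.nanmax(peaks) == pytest.approx(cs.amplitude, abs=0.005)

    def test_nonpositive_baseline_pixels_invalidated(self, small_tissue):
        mask = small_tissue.mask(40.0)
        frames = np.full((50, *mask.shape), 10.0, dtype=np.float32)
        rr, cc = np.nonzero(mask)
        frames[:, rr[0], cc[0]] = 0.0
        movie = CalciumMovie(frames, 1.0, 40.0, mask)
        dff = delta_f_over_f(movie)
        assert not dff.tissue_mask[rr[0], cc[0]]
        assert dff.tissue_mask.sum() == mask.sum() - 1


class TestBeatSegmentation:
    def test_one_hz_five_beats(self, small_tissue):
        cs = CalciumSpec(geometry=small_tissue, pacing_rate=1.0, n_beats=5,
                         noise_sd=0.0, px_size=40.0, frame_interval=2.0, seed=2)
        movie, _ = gen_calcium_movie(cs)
        beats = segment_beats(delta_f_over_f(movie))
        assert len(beats.onsets) == 5
        # within one frame interval of 1 Hz: period 1000 ± 2 ms
        assert beats.frequency_hz == pytest.approx(1.0, abs=1.0 / 998 - 1.0 / 1000 + 1e-4)

    def test_two_hz_movie_measured_at_two_hz(self, small_tissue):
        cs = CalciumSpec(geometry=small_tissue, pacing_rate=2.0, n_beats=6,
                         noise_sd=0.0, px_size=40.0, frame_interval=2.0, seed=2)
        movie, _ = gen_calcium_movie(cs)
        beats = segment_beats(delta_f_over_f(movie), pacing_rate=2.0)
        assert beats.frequency_hz == pytest.approx(2.0, abs=0.02)

    def test_flat_movie_raises_no_beats(self, small_tissue):
        mask = small_tissue.mask(40.0)
        frames = np.full((100, *mask.shape), 5.0, dtype=np.float32)
        movie = CalciumMovie(frames, 1.0, 40.0, mask)
        with pytest.raises(NoBeatsError):
            segment_beats(delta_f_over_f(movie))


class TestActivationMap:
    def test_map_matches_truth_within_half_frame(self, clean_movie):
        """Noise-free planar wave: activation equals truth up to a constant
        offset (the 50%-upstroke delay), with spread ≤ frame_interval/2."""
        cs, movie, truth = clean_movie
        dff = delta_f_over_f(movie)
        beats = segment_beats(dff)
        amap = activation_map(dff, window=beats.windows[0])
        both = amap.defined & np.isfinite(truth["activation_ms"])
        err = amap.times[both] - truth["activation_ms"][both]
        assert np.max(np.abs(err - np.median(err))) <= cs.frame_interval / 2 + 1e-9

    def test_simultaneous_activation_gives_constant_map(self, small_tissue):
        mask = small_tissue.mask(40.0)
        t = np.arange(300)
        g = np.exp(-t / 150.0) - np.exp(-t / 10.0)
        frames = np.zeros((300, *mask.shape), dtype=np.float32)
        frames[:, mask] = 100.0 * (1 + 0.5 * g[:, None] / g.max())
        frames[:, ~mask] = 1.0
        movie = CalciumMovie(frames, 1.0, 40.0, mask)
        amap = activation_map(delta_f_over_f(movie))
        vals = amap.times[amap.defined]
        assert np.ptp(vals) <= 1.0
        with pytest.raises(VelocityUndefinedError):
            estimate_velocity(amap, min_pixels=10)

    def test_pixel_without_transient_is_undefined(self, small_tissue):
        mask = small_tissue.mask(40.0)
        t = np.arange(300)
        g = (np.exp(-t / 150.0) - np.exp(-t / 10.0))
        g /= g.max()
        frames = np.zeros((300, *mask.shape), dtype=np.float32)
        frames[:, mask] = 100.0 * (1 + 0.5 * g[:, None])
        rr, cc = np.nonzero(mask)
        frames[:, rr[0], cc[0]] = 100.0  # dead pixel: no transient
        movie = CalciumMovie(frames, 1.0, 40.0, mask)
        amap = activation_map(delta_f_over_f(movie), amplitude_min=0.1)
        assert not amap.defined[rr[0], cc[0]]


class TestIsochrones:
    def test_planar_wave_contours_equispaced(self):
        """At 20 cm/s a 10 ms spacing puts contours 2 mm apart."""
        px = 20.0  # μm
        ny, nx = 40, 200
        v_um_ms = 200.0  # 20 cm/s
        x_um = np.arange(nx) * px
        times = np.tile(x_um / v_um_ms, (ny, 1))
        amap = ActivationMap(times=times, px_size=px, frame_interval=1.0)
        iso = isochrones(amap, 10.0)
        mean_cols = []
        for lv in iso.levels[1:-1]:
            pts = np.vstack(iso.contours[lv])
            mean_cols.append(pts[:, 1].mean())
        sep_um = np.diff(mean_cols) * px
        assert np.allclose(sep_um, 2000.0, atol=px)

    def test_point_source_contours_are_arcs(self):
        px = 20.0
        yy, xx = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
        r_um = np.hypot(yy - 30, xx - 30) * px
        amap = ActivationMap(times=r_um / 100.0, px_size=px, frame_interval=1.0)
        iso = isochrones(amap, 2.0)
        lv = iso.levels[3]
        pts = np.vstack(iso.contours[lv])
        radii = np.hypot(pts[:, 0] - 30, pts[:, 1] - 30) * px
        assert radii.std() / radii.mean() < 0.05


class TestVelocity:
    def test_closed_form_plane_exact(self):
        px = 20.0
        nx, ny = 120, 40
        x_um = np.arange(nx) * px
        times = np.tile(x_um / 100.0, (ny, 1))  # 10 cm/s
        amap = ActivationMap(times=times, px_size=px, frame_interval=1.0)
        est = estimate_velocity(amap)
        assert est.velocity_cm_s == pytest.approx(10.0, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        # uniform time offset leaves the gradient (and velocity) unchanged
        est2 = estimate_velocity(
            ActivationMap(times=times + 5.0, px_size=px, frame_interval=1.0)
        )
        assert est2.velocity_cm_s == pytest.approx(est.velocity_cm_s, rel=1e-12)

    def test_local_poly_agrees_on_plane(self):
        px = 20.0
        times = np.tile(np.arange(120) * px / 100.0, (40, 1))
        amap = ActivationMap(times=times, px_size=px, frame_interval=1.0)
        est = estimate_velocity(amap, method="local_poly")
        assert est.velocity_cm_s == pytest.approx(10.0, rel=1e-6)

    def test_small_roi_rejected(self):
        times = np.zeros((4, 4)) + np.arange(4)[None, :]
        amap = ActivationMap(times=times, px_size=20.0, frame_interval=1.0)
        with pytest.raises(ValueError, match="defined pixels"):
            estimate_velocity(amap, min_pixels=50)

    def test_generator_velocity_sweep_linearity(self, small_tissue):
        """Estimated vs true speed over 5–25 cm/s: slope ≈ 1, intercept ≈ 0."""
        roi = small_tissue.neck_roi_mask(20.0)
        true_v = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        est_v = []
        for v in true_v:
            cs = CalciumSpec(geometry=small_tissue, velocity=v, noise_sd=0.0,
                             n_beats=1, seed=1)
            movie, _ = gen_calcium_movie(cs)
            est_v.append(run_pipeline(movie, roi)[2].velocity_cm_s)
        slope, intercept = np.polyfit(true_v, est_v, 1)
        assert 0.95 <= slope <= 1.05
        assert abs(intercept) <= 0.5

    def test_noisy_recovery_within_five_percent(self, small_tissue):
        """SNR 10 (noise_sd = amplitude·baseline/10) end-to-end recovery."""
        cs = CalciumSpec(geometry=small_tissue, velocity=20.0, noise_sd=5.0,
                         n_beats=2, seed=4)
        movie, _ = gen_calcium_movie(cs)
        _, _, est = run_pipeline(
            movie, small_tissue.neck_roi_mask(cs.px_size),
            spatial_sigma_px=1.0, savgol=(11, 3),
        )
        assert est.velocity_cm_s == pytest.approx(20.0, rel=0.05)

    def test_velocity_invariant_to_intensity_scaling(self, clean_movie):
        cs, movie, _ = clean_movie
        roi = cs.geometry.neck_roi_mask(cs.px_size)
        ref = run_pipeline(movie, roi)[2]
        scaled = CalciumMovie(movie.frames * 3.7, movie.frame_interval,
                              movie.px_size, movie.tissue_mask,
                              movie.pacing_rate, movie.stim_site_px)
        est = run_pipeline(scaled, roi)[2]
        assert est.velocity_cm_s == pytest.approx(ref.velocity_cm_s, rel=1e-6)
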