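"""Optical mapping of paced calcium waves.

From a time-lapse fluorescence movie of a paced tissue: ΔF/F
normalization, beat segmentation from the tissue-mean trace, per-pixel
activation-time maps (fractional-upstroke criterion), isochrone contours,
and wavefront propagation velocity from the spatial gradient of
activation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy import ndimage as ndi
from skimage import measure as skmeasure

__all__ = [
    "CalciumMovie",
    "ActivationMap",
    "BeatSegmentation",
    "VelocityEstimate",
    "Isochrones",
    "delta_f_over_f",
    "segment_beats",
    "activation_map",
    "isochrones",
    "estimate_velocity",
    "NoBeatsError",
    "VelocityUndefinedError",
]


class NoBeatsError(RuntimeError):
    """No calcium transients detected in the record."""


class VelocityUndefinedError(RuntimeError):
    """Activation-time gradient below tolerance (simultaneous activation)."""


@dataclass
class CalciumMovie:
    """A calcium movie with acquisition and stimulation metadata.

    ``frames`` is a (T, Y, X) raster; ``frame_interval`` is in ms and
    ``px_size`` in μm/px.  ``tissue_mask`` restricts every analysis to
    tissue-covered pixels.
    """

    frames: np.ndarray
    frame_interval: float
    px_size: float
    tissue_mask: np.ndarray
    pacing_rate: float = 1.0
    stim_site_px: tuple[int, int] | None = None
    provenance: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frames.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not self.tissue_mask.any():
            raise ValueError("tissue_mask is empty")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def mean_trace(self) -> np.ndarray:
        return self.frames[:, self.tissue_mask].mean(axis=1)


@dataclass
class BeatSegmentation:
    """Beat onsets (frame indices), per-beat windows, measured frequency."""

    onsets: np.ndarray                     # frame indices of upstroke peaks
    windows: list[tuple[int, int]]         # [start, stop) frame indices
    frequency_hz: float
    frame_interval: float


@dataclass
class ActivationMap:
    """Per-pixel activation times (ms from beat-window start); NaN = undefined."""

    times: np.ndarray
    px_size: float
    frame_interval: float
    beat_index: int = 0
    window: tuple[int, int] | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.times)


@dataclass
class VelocityEstimate:
    velocity_cm_s: float
    method: str
    r_squared: float
    n_pixels: int
    direction_deg: float | None = None


@dataclass
class Isochrones:
    levels: np.ndarray                     # ms
    contours: dict[float, list[np.ndarray]]
    labels: np.ndarray                     # floor(t / spacing); -1 undefined
    spacing_ms: float


# ---------------------------------------------------------------------------

def delta_f_over_f(
    movie: CalciumMovie,
    baseline_percentile: float = 10.0,
    spatial_sigma_px: float = 0.0,
    savgol: tuple[int, int] | None = None,
) -> CalciumMovie:
    """Normalize a movie to ΔF/F = (F − F₀)/F₀ per pixel.

    F₀ is the ``baseline_percentile``-th percentile of each pixel's trace.
    Optional spatial Gaussian and temporal Savitzky–Golay filtering are
    applied before normalization and recorded in provenance.  Pixels with
    F₀ ≤ 0 are marked invalid (removed from the tissue mask).
    """
    frames = movie.frames.astype(float, copy=True)
    if spatial_sigma_px > 0:
        frames = ndi.gaussian_filter(frames, (0.0, spatial_sigma_px, spatial_sigma_px))
    if savgol is not None:
        window, order = savgol
        frames = savgol_filter(frames, window, order, axis=0)
    f0 = np.percentile(frames, baseline_percentile, axis=0)
    valid = f0 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (frames - f0[None]) / f0[None]
    dff[:, ~valid] = np.nan
    mask = movie.tissue_mask & valid
    if not mask.any():
        raise ValueError("no valid pixels after ΔF/F normalization")
    prov = dict(movie.provenance)
    prov["dff"] = {
        "baseline_percentile": baseline_percentile,
        "spatial_sigma_px": spatial_sigma_px,
        "savgol": savgol,
    }
    return CalciumMovie(
        frames=dff, frame_interval=movie.frame_interval, px_size=movie.px_size,
        tissue_mask=mask, pacing_rate=movie.pacing_rate,
        stim_site_px=movie.stim_site_px, provenance=prov,
        warnings=list(movie.warnings),
    )


def segment_beats(
    movie: CalciumMovie, pacing_rate: float | None = None
) -> BeatSegmentation:
    """Find paced beats on the tissue-mean trace.

    Beat onsets are peaks of dF/dt separated by at least half the pacing
    period; the measured frequency is the reciprocal of the median
    inter-beat interval.
    """
    rate = movie.pacing_rate if pacing_rate is None else pacing_rate
    trace = movie.mean_trace()
    if np.ptp(trace) < 1e-12:
        raise NoBeatsError("flat tissue-mean trace; no beats detected")
    dtr = np.gradient(trace)
    if dtr.max() <= 0:
        raise NoBeatsError("no rising phase in tissue-mean trace")
    period_frames = 1000.0 / rate / movie.frame_interval
    peaks, _ = find_peaks(
        dtr,
        distance=max(1, int(0.5 * period_frames)),
        height=0.5 * dtr.max(),
    )
    if peaks.size == 0:
        raise NoBeatsError("no beats detected in tissue-mean trace")
    if peaks.size >= 2:
        frequency = 1000.0 / (np.median(np.diff(peaks)) * movie.frame_interval)
    else:
        frequency = float("nan")
    pre = int(round(0.05 * period_frames))
    windows: list[tuple[int, int]] = []
    for k, p in enumerate(peaks):
        start = max(0, int(p) - pre)
        stop = (
            max(0, int(peaks[k + 1]) - pre)
            if k + 1 < peaks.size
            else min(movie.n_frames, start + int(round(period_frames)))
        )
        windows.append((start, stop))
    return BeatSegmentation(peaks, windows, float(frequency), movie.frame_interval)


def activation_map(
    movie: CalciumMovie,
    window: tuple[int, int] | None = None,
    beat_index: int = 0,
    amplitude_min: float = 0.1,
    fraction: float = 0.5,
    method: str = "fractional",
) -> ActivationMap:
    """Per-pixel activation time within one beat window of a ΔF/F movie.

    ``fractional`` (default): activation is the linearly interpolated
    crossing of ``fraction`` of the pixel's beat peak on the upstroke.
    ``dvdt``: time of maximal dF/dt.  Pixels whose beat peak falls below
    ``amplitude_min`` ΔF/F are undefined (NaN).
    """
    w0, w1 = (0, movie.n_frames) if window is None else window
    mask = movie.tissue_mask
    traces = movie.frames[w0:w1, mask]          # (Tw, N)
    tw = traces.shape[0]
    if tw < 2:
        raise ValueError("beat window shorter than 2 frames")
    base = np.nanmin(traces, axis=0)
    peak = np.nanmax(traces, axis=0)
    ipk = np.nanargmax(traces, axis=0)
    ok = (peak - base >= 0) & (peak >= amplitude_min)

    t_act = np.full(traces.shape[1], np.nan)
    if method == "fractional":
        thr = base + fraction * (peak - base)
        below = traces < thr[None, :]
        before_peak = np.arange(tw)[:, None] < ipk[None, :]
        cand = below & before_peak
        has_cross = cand.any(axis=0)
        # last below-threshold frame before the peak
        i0 = tw - 1 - np.argmax(cand[::-1], axis=0)
        i0 = np.clip(i0, 0, tw - 2)
        y0 = np.take_along_axis(traces, i0[None, :], axis=0)[0]
        y1 = np.take_along_axis(traces, (i0 + 1)[None, :], axis=0)[0]
        dy = y1 - y0
        frac = np.where(np.abs(dy) > 1e-30, (thr - y0) / np.where(dy == 0, 1, dy), 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        t = (i0 + frac) * movie.frame_interval
        sel = ok & has_cross
        t_act[sel] = t[sel]
        # pixel already above threshold at window start: activation at start
        sel_pre = ok & ~has_cross & (traces[0] >= thr)
        t_act[sel_pre] = 0.0
    elif method == "dvdt":
        d = np.gradient(traces, axis=0)
        t_act[ok] = np.argmax(d, axis=0)[ok] * movie.frame_interval
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.isfinite(t_act).any():
        raise ValueError("all pixels undefined in activation map")
    times = np.full(mask.shape, np.nan)
    times[mask] = t_act
    return ActivationMap(
        times=times, px_size=movie.px_size,
        frame_interval=movie.frame_interval,
        beat_index=beat_index, window=(w0, w1),
    )


def isochrones(amap: ActivationMap, spacing_ms: float) -> Isochrones:
    """Level curves of activation time at multiples of ``spacing_ms``."""
    t = amap.times
    finite = np.isfinite(t)
    if not finite.any():
        raise ValueError("activation map has no defined pixels")
    tmax = np.nanmax(t)
    levels = np.arange(0.0, tmax + spacing_ms, spacing_ms)
    filled = np.where(finite, t, tmax + 10 * spacing_ms)
    contours: dict[float, list[np.ndarray]] = {}
    for lv in levels:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            contours[float(lv)] = skmeasure.find_contours(filled, lv)
    labels = np.where(finite, np.floor(t / spacing_ms), -1.0)
    return Isochrones(levels, contours, labels, spacing_ms)


def _plane_fit(t: np.ndarray, x_um: np.ndarray, y_um: np.ndarray):
    A = np.column_stack([np.ones_like(x_um), x_um, y_um])
    coef, *_ = np.linalg.lstsq(A, t, rcond=None)
    resid = t - A @ coef
    ss_tot = np.sum((t - t.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return coef, float(r2)


def estimate_velocity(
    amap: ActivationMap,
    roi_mask: np.ndarray | None = None,
    method: str = "plane",
    min_pixels: int = 50,
    window_px: int = 15,
) -> VelocityEstimate:
    """Wavefront speed from the spatial gradient of activation time.

    ``plane`` fits t(x, y) = a + bx + cy over the ROI by least squares;
    speed = 1/‖(b, c)‖ converted to cm/s.  ``local_poly`` fits windowed
    quadratic surfaces and reports the median of local speeds (for curved
    fronts).
    """
    sel = amap.defined
    if roi_mask is not None:
        sel = sel & roi_mask
    rows, cols = np.nonzero(sel)
    if rows.size < min_pixels:
        raise ValueError(
            f"only {rows.size} defined pixels in ROI (need >= {min_pixels})"
        )
    t = amap.times[rows, cols]
    x_um = cols * amap.px_size
    y_um = rows * amap.px_size

    if method == "plane":
        coef, r2 = _plane_fit(t, x_um, y_um)
        grad = float(np.hypot(coef[1], coef[2]))  # ms/μm
        if grad < 1e-12:
            raise VelocityUndefinedError("activation-time gradient is zero")
        v_cm_s = (1.0 / grad) * 0.1  # μm/ms → cm/s
        direction = float(np.degrees(np.arctan2(coef[2], coef[1])))
        return VelocityEstimate(v_cm_s, "plane", r2, rows.size, direction)

    if method == "local_poly":
        speeds: list[float] = []
        r2s: list[float] = []
        half = window_px // 2
        r_centers = range(rows.min() + half, rows.max() - half + 1, half)
        c_centers = range(cols.min() + half, cols.max() - half + 1, half)
        for rc in r_centers:
            for cc in c_centers:
                win = sel[rc - half: rc + half + 1, cc - half: cc + half + 1]
                if win.sum() < 0.8 * window_px**2:
                    continue
                wr, wc = np.nonzero(win)
                wt = amap.times[rc - half + wr, cc - half + wc]
                wx = (cc - half + wc) * amap.px_size
                wy = (rc - half + wr) * amap.px_size
                A = np.column_stack([
                    np.ones_like(wx), wx, wy, wx**2, wx * wy, wy**2,
                ])
                coef, *_ = np.linalg.lstsq(A, wt, rcond=None)
                xc, yc = cc * amap.px_size, rc * amap.px_size
                gx = coef[1] + 2 * coef[3] * xc + coef[4] * yc
                gy = coef[2] + coef[4] * xc + 2 * coef[5] * yc
                g = float(np.hypot(gx, gy))
                if g < 1e-12:
                    continue
                speeds.append((1.0 / g) * 0.1)
                ss_tot = np.sum((wt - wt.mean()) ** 2)
                resid = wt - A @ coef
                r2s.append(
                    1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
                )
        if not speeds:
            raise VelocityUndefinedError("no valid local windows for velocity")
        return VelocityEstimate(
            float(np.median(speeds)), "local_poly",
            float(np.median(r2s)), rows.size, None,
        )

    raise ValueError(f"unknown method {method!r}")
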