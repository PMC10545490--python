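"""Synthetic paced calcium-wave movies with ground-truth activation times.

A point stimulus at the tissue base launches a wave that propagates at a
fixed speed; each pixel activates at t = (geodesic distance within the
tissue mask from the stimulation site) / velocity, so the wave wraps
correctly from the base into the neck.  The fluorescence transient is a
double-exponential upstroke/decay normalized to peak 1, repeating at the
pacing rate.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from skimage.graph import MCP_Geometric

from ..calcium import CalciumMovie
from .specs import CalciumSpec

__all__ = ["gen_calcium_movie", "geodesic_distance_map", "transient"]

_CHUNK_FRAMES = 256


def geodesic_distance_map(
    mask: np.ndarray, source_px: tuple[int, int], px_size: float
) -> np.ndarray:
    """Geodesic (within-mask) distance in μm from ``source_px``.

    Uses 8-connected minimum-cost paths; pixels outside the mask are inf.
    """
    costs = np.where(mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs)
    cum, _ = mcp.find_costs([source_px])
    return cum * px_size


def transient(tau_ms: np.ndarray, tau_up: float, tau_down: float) -> np.ndarray:
    """Double-exponential calcium transient normalized to peak 1.

    g(τ) = (e^(−τ/τ_down) − e^(−τ/τ_up)) / norm for τ ≥ 0, else 0.
    """
    t_pk = tau_up * tau_down / (tau_down - tau_up) * np.log(tau_down / tau_up)
    norm = np.exp(-t_pk / tau_down) - np.exp(-t_pk / tau_up)
    tau = np.asarray(tau_ms, dtype=float)
    g = np.where(
        tau >= 0,
        (np.exp(-np.clip(tau, 0, None) / tau_down)
         - np.exp(-np.clip(tau, 0, None) / tau_up)) / norm,
        0.0,
    )
    return g


def gen_calcium_movie(
    cspec: CalciumSpec, *, rng: np.random.Generator | None = None
) -> tuple[CalciumMovie, dict[str, Any]]:
    """Simulate a paced calcium movie; returns (movie, ground truth).

    Ground truth holds the activation-time map of one beat (ms, NaN
    outside the tissue), the geodesic distance map (μm), and the spec.
    """
    rng = np.random.default_rng(cspec.seed) if rng is None else rng
    geo = cspec.geometry
    px = cspec.px_size
    mask = geo.mask(px)
    stim = geo.stimulation_px(px)
    if not mask[stim]:
        raise ValueError("stimulation site falls outside the tissue mask")

    dist_um = geodesic_distance_map(mask, stim, px)
    v_um_ms = cspec.velocity * 10.0  # cm/s → μm/ms
    t_act = dist_um / v_um_ms        # ms; inf outside mask

    T = cspec.n_frames
    if T * cspec.frame_interval < cspec.beat_period_ms:
        raise ValueError("movie duration must cover at least one full beat")
    warns: list[str] = []
    if cspec.tau_up < cspec.frame_interval:
        warns.append(
            f"frame interval {cspec.frame_interval} ms exceeds upstroke "
            f"time constant {cspec.tau_up} ms; upstroke under-resolved"
        )

    t_act_in = t_act[mask]
    n_px = t_act_in.size
    period = cspec.beat_period_ms
    frames = np.zeros((T, *mask.shape), dtype=np.float32)
    times = np.arange(T) * cspec.frame_interval
    block = np.empty((min(_CHUNK_FRAMES, T), n_px), dtype=float)
    for s in range(0, T, _CHUNK_FRAMES):
        e = min(s + _CHUNK_FRAMES, T)
        tau = times[s:e, None] - t_act_in[None, :]
        g = transient(np.mod(tau, period), cspec.tau_up, cspec.tau_down)
        g = np.where(tau >= 0, g, 0.0)
        # tail of the previous beat (only once a full period has elapsed)
        tail = transient(np.mod(tau, period) + period, cspec.tau_up, cspec.tau_down)
        g = g + np.where(tau >= period, tail, 0.0)
        block = cspec.baseline * (1.0 + cspec.amplitude * g)
        frames[s:e][:, mask] = block.astype(np.float32)
    if cspec.noise_sd > 0:
        frames += rng.normal(0.0, cspec.noise_sd, frames.shape).astype(np.float32)

    movie = CalciumMovie(
        frames=frames,
        frame_interval=cspec.frame_interval,
        px_size=px,
        tissue_mask=mask,
        pacing_rate=cspec.pacing_rate,
        stim_site_px=stim,
        provenance={"synthetic": True, "seed": cspec.seed,
                    "velocity_cm_s": cspec.velocity},
        warnings=warns,
    )
    truth = {
        "activation_ms": np.where(mask, t_act, np.nan),
        "distance_um": dist_um,
        "spec": cspec,
    }
    return movie, truth
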