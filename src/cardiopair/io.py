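"""TIFF / YAML / JSON input-output.

Images and movies are exchanged as multi-page TIFF with axes recorded in
metadata ('CYX' for multichannel images, 'TYX' for movies); ground truth
and calibration travel in JSON/YAML sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .calcium import CalciumMovie

__all__ = [
    "write_channels_tiff",
    "read_channels_tiff",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_json_sidecar",
    "read_json_sidecar",
    "read_config",
]


def write_channels_tiff(
    path: str | Path, channels: dict[str, np.ndarray], px_size: float
) -> None:
    """Write a multichannel image as a CYX TIFF stack."""
    names = sorted(channels)
    stack = np.stack([channels[n] for n in names]).astype(np.float32)
    meta = {"axes": "CYX", "channels": names, "px_size_um": px_size}
    tifffile.imwrite(Path(path), stack, metadata=meta,
                     photometric="minisblack")


def read_channels_tiff(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    with tifffile.TiffFile(Path(path)) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = meta.get("channels", [f"ch{i}" for i in range(stack.shape[0])])
    px = float(meta.get("px_size_um", 1.0))
    return {n: stack[i] for i, n in enumerate(names)}, px


def write_movie_tiff(path: str | Path, movie: CalciumMovie) -> None:
    """Write a calcium movie as a TYX TIFF with timing/masking metadata."""
    meta = {
        "axes": "TYX",
        "frame_interval_ms": movie.frame_interval,
        "px_size_um": movie.px_size,
        "pacing_rate_hz": movie.pacing_rate,
        "stim_site_px": list(movie.stim_site_px) if movie.stim_site_px else None,
    }
    tifffile.imwrite(Path(path), movie.frames.astype(np.float32), metadata=meta)
    mask_path = Path(path).with_suffix(".mask.tif")
    tifffile.imwrite(mask_path, movie.tissue_mask.astype(np.uint8))


def read_movie_tiff(path: str | Path) -> CalciumMovie:
    with tifffile.TiffFile(Path(path)) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    mask_path = Path(path).with_suffix(".mask.tif")
    if mask_path.exists():
        mask = tifffile.imread(mask_path).astype(bool)
    else:
        mask = np.ones(frames.shape[1:], dtype=bool)
    stim = meta.get("stim_site_px")
    return CalciumMovie(
        frames=frames,
        frame_interval=float(meta.get("frame_interval_ms", 1.0)),
        px_size=float(meta.get("px_size_um", 1.0)),
        tissue_mask=mask,
        pacing_rate=float(meta.get("pacing_rate_hz", 1.0)),
        stim_site_px=tuple(stim) if stim else None,
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        return super().default(o)


def write_json_sidecar(path: str | Path, payload: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder))


def read_json_sidecar(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML calibration/configuration file."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
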