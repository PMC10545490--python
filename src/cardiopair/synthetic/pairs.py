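"""Synthetic cell-pair images, fibril fields, and plate mosaics.

Coordinates: physical x (μm) runs along image columns with x = 0 at the
pattern centre; y runs along rows with y = 0 at the pattern mid-height.
Fibril angles are measured in degrees counter-clockwise from +x (with y
pointing up, i.e. against the row direction) and are π-periodic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import transform as sktransform

from ..geometry import PlateLayout
from .specs import KAPPA_CAP, SyntheticSpec

__all__ = [
    "CellPairSample",
    "FibrilField",
    "PlateSample",
    "gen_cell_pair_image",
    "gen_fibril_field",
    "gen_plate",
    "sample_fibril_angles",
]

CHANNELS = ("nuclei", "actinin", "junction", "factin")

#: fibrils per μm² of cell area in rendered structural channels
FIBRIL_DENSITY = 0.08
#: fibril segment length range, μm
FIBRIL_LENGTH_UM = (6.0, 16.0)

#: QC failure taxonomy used by plate simulation
FAILURE_VARIANTS = ("single_cell", "three_nuclei", "binucleate_close")


# ---------------------------------------------------------------------------
# angle sampling

def sample_fibril_angles(
    rng: np.random.Generator,
    n: int,
    director_deg: float,
    kappa: float,
    zdisc_fraction: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` π-periodic fibril angles about a director.

    Fibrils are apolar, so angles live on [0°, 180°); concentration is
    expressed through a von Mises distribution on the doubled angle
    (kappa = 0 gives the uniform distribution, kappa above ``KAPPA_CAP``
    collapses to the director exactly).  A ``zdisc_fraction`` of the draws
    uses the short axis (director + 90°) as centre instead — the α-actinin
    Z-disc mode.

    Returns ``(angles_deg, is_zdisc)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    is_z = rng.random(n) < zdisc_fraction
    centers = np.where(is_z, director_deg + 90.0, director_deg)
    if kappa >= KAPPA_CAP:
        phi = np.zeros(n)
    else:
        phi = rng.vonmises(0.0, kappa, size=n)  # doubled-angle deviation
    angles = np.mod(centers + np.degrees(phi) / 2.0, 180.0)
    return angles, is_z


@dataclass
class FibrilField:
    """Rendered fibril image with per-fibril ground truth."""

    image: np.ndarray
    angles_deg: np.ndarray           # (n_fibrils,)
    is_zdisc: np.ndarray             # (n_fibrils,) bool
    segments_px: np.ndarray          # (n_fibrils, 2, 2) endpoints (row, col)
    director_deg: float
    px_size: float


def gen_fibril_field(
    spec: SyntheticSpec,
    director_deg: float = 0.0,
    n_fibrils: int = 200,
    *,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
    mask: np.ndarray | None = None,
    zdisc_fraction: float | None = None,
) -> FibrilField:
    """Render line-segment fibrils with known angles.

    Segment centres are uniform over ``mask`` (or the full raster); angles
    come from :func:`sample_fibril_angles` with concentration
    ``spec.fibril_kappa``.  The image is lightly blurred (σ = 1 px) so the
    lines have a finite ridge width for tubeness filtering.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if shape is None:
        h = int(round((spec.geometry.width + 2 * spec.margin) / spec.px_size))
        w = int(round((spec.geometry.length + 2 * spec.margin) / spec.px_size))
        shape = (h, w)
    zfrac = spec.zdisc_fraction if zdisc_fraction is None else zdisc_fraction
    angles, is_z = sample_fibril_angles(
        rng, n_fibrils, director_deg, spec.fibril_kappa, zfrac
    )
    if mask is not None and mask.any():
        rows, cols = np.nonzero(mask)
        pick = rng.integers(0, rows.size, size=n_fibrils)
        centers = np.column_stack([rows[pick], cols[pick]]).astype(float)
    else:
        centers = np.column_stack([
            rng.uniform(0, shape[0], n_fibrils),
            rng.uniform(0, shape[1], n_fibrils),
        ])
    half_px = rng.uniform(*FIBRIL_LENGTH_UM, size=n_fibrils) / 2.0 / spec.px_size

    image = np.zeros(shape, dtype=float)
    segments = np.empty((n_fibrils, 2, 2))
    th = np.radians(angles)
    # +x along columns, angle CCW with y up => row step is -sin
    drc = np.column_stack([-np.sin(th), np.cos(th)])
    for i in range(n_fibrils):
        p0 = centers[i] - half_px[i] * drc[i]
        p1 = centers[i] + half_px[i] * drc[i]
        segments[i, 0], segments[i, 1] = p0, p1
        rr, cc = skdraw.line(
            int(round(p0[0])), int(round(p0[1])),
            int(round(p1[0])), int(round(p1[1])),
        )
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        image[rr[ok], cc[ok]] = 1.0
    image = ndi.gaussian_filter(image, 1.0)
    return FibrilField(image, angles, is_z, segments, director_deg, spec.px_size)


# ---------------------------------------------------------------------------
# cell pair images

@dataclass
class CellPairSample:
    """One rendered cell pair (or QC-failure configuration) with truth."""

    channels: dict[str, np.ndarray]
    cell_mask: np.ndarray
    nuclei_mask: np.ndarray          # boolean union of nuclei
    band_mask: np.ndarray            # junction band region (±3σ within cell)
    truth: dict[str, Any]
    spec: SyntheticSpec

    @property
    def px_size(self) -> float:
        return self.spec.px_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_mask.shape


def _ellipse_mask(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    major_px: float,
    minor_px: float,
    angle_deg: float,
) -> np.ndarray:
    """Filled rotated ellipse; angle CCW from +x (y up)."""
    # draw.ellipse's rotation is CCW in math (y-up) convention
    rr, cc = skdraw.ellipse(
        center_px[0], center_px[1], minor_px, major_px,
        shape=shape, rotation=np.radians(angle_deg),
    )
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def gen_cell_pair_image(
    spec: SyntheticSpec,
    variant: str = "pair",
    *,
    rng: np.random.Generator | None = None,
) -> CellPairSample:
    """Render a four-channel cell-pair image with ground truth.

    ``variant`` selects the configuration: ``"pair"`` (a valid QC-passing
    pair), or one of the QC failure modes — ``"empty"`` (no cell),
    ``"single_cell"`` (one cell on half the island), ``"three_nuclei"``,
    ``"binucleate_close"`` (two nuclei 40 μm apart with long-axis
    filaments spanning both, i.e. a likely binucleated single cell).
    ``"binucleate_close_nospan"`` renders close nuclei *without* spanning
    filaments (should pass the exclusion rule's conjunction).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    geo = spec.geometry
    px = spec.px_size
    h = int(round((geo.width + 2 * spec.margin) / px))
    w = int(round((geo.length + 2 * spec.margin) / px))
    shape = (h, w)
    # physical coordinates of pixel centres
    x = (np.arange(w) + 0.5) * px - (spec.margin + geo.length / 2.0)
    y = (np.arange(h) + 0.5) * px - (spec.margin + geo.width / 2.0)
    xx, yy = np.meshgrid(x, y)

    in_pattern = (np.abs(xx) <= geo.length / 2) & (np.abs(yy) <= geo.width / 2)
    if variant == "empty":
        cell_mask = np.zeros(shape, dtype=bool)
    elif variant == "single_cell":
        cell_mask = in_pattern & (xx >= 0)
    else:
        cell_mask = in_pattern

    # --- nuclei -----------------------------------------------------------
    x_nuc = spec.nuclear_offset_frac * geo.length / 2.0
    if variant == "empty":
        nuc_centers: list[tuple[float, float]] = []
    elif variant == "single_cell":
        nuc_centers = [(x_nuc, 0.0)]
    elif variant == "three_nuclei":
        nuc_centers = [(-x_nuc, 0.0), (0.0, 0.0), (x_nuc, 0.0)]
    elif variant in ("binucleate_close", "binucleate_close_nospan"):
        nuc_centers = [(-20.0, 0.0), (20.0, 0.0)]
    elif variant == "pair":
        nuc_centers = [(-x_nuc, 0.0), (x_nuc, 0.0)]
    else:
        raise ValueError(f"unknown variant {variant!r}")

    major_px = spec.nuclear_length / 2.0 / px
    minor_px = major_px / spec.nuclear_aspect
    nuclei_mask = np.zeros(shape, dtype=bool)
    for cx, cy in nuc_centers:
        r0 = (cy + spec.margin + geo.width / 2.0) / px - 0.5
        c0 = (cx + spec.margin + geo.length / 2.0) / px - 0.5
        nuclei_mask |= _ellipse_mask(
            shape, (r0, c0), major_px, minor_px, spec.nuclear_angle
        )
    nuclei = ndi.gaussian_filter(nuclei_mask.astype(float), 1.0)

    # --- structural channels ---------------------------------------------
    cell_area_um2 = float(cell_mask.sum()) * px * px
    n_fib = max(1, int(round(cell_area_um2 * FIBRIL_DENSITY)))
    if cell_mask.any():
        if variant == "binucleate_close_nospan":
            # transverse-only fibrils: nothing within ±15° of the long axis
            act = gen_fibril_field(
                spec, 90.0, n_fib, rng=rng, shape=shape, mask=cell_mask,
                zdisc_fraction=0.0,
            )
            fac = gen_fibril_field(
                spec.with_(fibril_kappa=max(spec.fibril_kappa, 8.0)),
                90.0, n_fib, rng=rng, shape=shape, mask=cell_mask,
                zdisc_fraction=0.0,
            )
        else:
            act = gen_fibril_field(
                spec, 0.0, n_fib, rng=rng, shape=shape, mask=cell_mask,
            )
            fac = gen_fibril_field(
                spec, 0.0, n_fib, rng=rng, shape=shape, mask=cell_mask,
                zdisc_fraction=0.0,
            )
        actinin, factin = act.image.copy(), fac.image.copy()
        truth_angles = {"actinin": act.angles_deg, "factin": fac.angles_deg,
                        "actinin_is_zdisc": act.is_zdisc}
    else:
        actinin = np.zeros(shape)
        factin = np.zeros(shape)
        truth_angles = {"actinin": np.empty(0), "factin": np.empty(0),
                        "actinin_is_zdisc": np.empty(0, dtype=bool)}

    if variant == "binucleate_close":
        # explicit horizontal filaments spanning both nuclei
        span_px = 45.0 / px
        c_mid = (spec.margin + geo.length / 2.0) / px
        extra = np.zeros(shape)
        for dy in (-2.0, 0.0, 2.0):
            r = int(round((dy + spec.margin + geo.width / 2.0) / px))
            rr, cc = skdraw.line(
                r, int(round(c_mid - span_px)), r, int(round(c_mid + span_px))
            )
            extra[rr, cc] = 1.0
        extra = ndi.gaussian_filter(extra, 1.0)
        factin += extra
        actinin += 0.5 * extra

    # --- junction-protein mixture ----------------------------------------
    junction = np.zeros(shape)
    band_center = spec.band_offset
    band_mask = cell_mask & (np.abs(xx - band_center) <= 3 * spec.junction_band_sigma)
    components: dict[str, np.ndarray] = {}
    if cell_mask.any():
        band = np.exp(-((xx - band_center) ** 2) / (2 * spec.junction_band_sigma ** 2))
        components["junctional"] = band * cell_mask
        components["diffuse"] = cell_mask.astype(float)
    if nuclei_mask.any():
        dist_out = ndi.distance_transform_edt(~nuclei_mask) * px
        ring = (dist_out <= spec.perinuclear_ring_width) & ~nuclei_mask
        components["perinuclear"] = ring.astype(float)
    weights = {
        "junctional": spec.junctional_weight,
        "diffuse": spec.diffuse_weight,
        "perinuclear": spec.perinuclear_weight,
    }
    for name, comp in components.items():
        total = comp.sum()
        if weights[name] > 0 and total > 0:
            junction += weights[name] * comp / total
    if cell_mask.any() and junction.sum() > 0:
        junction /= junction[cell_mask].mean()  # mean cell signal = 1

    channels = {
        "nuclei": nuclei / nuclei.max() if nuclei.max() > 0 else nuclei,
        "actinin": actinin / actinin.max() if actinin.max() > 0 else actinin,
        "junction": junction,
        "factin": factin / factin.max() if factin.max() > 0 else factin,
    }
    if spec.noise_sd > 0:
        for name in CHANNELS:
            channels[name] = channels[name] + rng.normal(
                0.0, spec.noise_sd, shape
            )

    truth: dict[str, Any] = {
        "variant": variant,
        "weights": weights,
        "band_center_um": band_center,
        "band_sigma_um": spec.junction_band_sigma,
        "nuclei_centers_um": nuc_centers,
        "pattern_center_px": (
            (spec.margin + geo.width / 2.0) / px - 0.5,
            (spec.margin + geo.length / 2.0) / px - 0.5,
        ),
        "angles_deg": truth_angles,
        "accept": variant == "pair" or variant == "binucleate_close_nospan",
    }
    return CellPairSample(channels, cell_mask, nuclei_mask, band_mask, truth, spec)


def gen_unpatterned_cells(
    n_cells: int,
    mean_area_um2: float = 1600.0,
    area_cv: float = 0.25,
    px_size: float = 0.5,
    mean_aspect: float = 7.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[dict[str, float]]]:
    """Render isolated unpatterned cells of a set mean area.

    Cells are ellipses with lognormal area variation about
    ``mean_area_um2`` (defaults emulate single hiPSC-CMs of ~1,600 μm²,
    aspect ~7:1) laid out on a grid with clear separation.  Returns the
    binary image and per-cell truth (area μm², aspect, angle).
    """
    rng = np.random.default_rng(seed)
    n_cols = int(math.ceil(math.sqrt(n_cells)))
    n_rows = int(math.ceil(n_cells / n_cols))
    sigma = math.sqrt(math.log(1 + area_cv**2))
    areas = mean_area_um2 * np.exp(
        rng.normal(-sigma**2 / 2, sigma, n_cells)
    )
    aspects = np.clip(rng.normal(mean_aspect, 1.0, n_cells), 2.0, None)
    angles = rng.uniform(0, 180, n_cells)
    # tile large enough for the longest cell
    tile_um = 2.2 * math.sqrt(areas.max() * aspects.max() / math.pi)
    tile_px = int(round(tile_um / px_size))
    img = np.zeros((n_rows * tile_px, n_cols * tile_px), dtype=bool)
    truth = []
    for i in range(n_cells):
        r, c = divmod(i, n_cols)
        # ellipse area = π a b with a = aspect·b
        b = math.sqrt(areas[i] / (math.pi * aspects[i])) / px_size
        a = aspects[i] * b
        center = ((r + 0.5) * tile_px, (c + 0.5) * tile_px)
        img |= _ellipse_mask(img.shape, center, a, b, angles[i])
        truth.append({
            "area_um2": float(areas[i]),
            "aspect": float(aspects[i]),
            "angle_deg": float(angles[i]),
        })
    return img, truth


# ---------------------------------------------------------------------------
# plate mosaics

@dataclass
class PlateSample:
    """Mosaic of islands with per-island ground truth."""

    channels: dict[str, np.ndarray]
    px_size: float
    layout: PlateLayout
    n_islands: int
    islands: list[dict[str, Any]] = field(default_factory=list)
    spec: SyntheticSpec | None = None

    @property
    def truth_accepted(self) -> set[int]:
        return {i["index"] for i in self.islands if i["accept"]}


def gen_plate(
    n_islands: int,
    occupancy: float,
    pair_fraction: float,
    spec: SyntheticSpec,
    *,
    seed: int | None = None,
    angle_deg: float = 0.0,
) -> PlateSample:
    """Lay islands on a grid; occupy each independently with ``occupancy``.

    Occupied islands hold a valid pair with probability ``pair_fraction``
    and otherwise one of the QC failure configurations (single cell, three
    nuclei, or a close-nuclei binucleate with spanning filaments), chosen
    uniformly.  ``angle_deg`` rotates the finished mosaic (about its
    centre, expanding the canvas) to emulate plate misalignment; truth
    centres are transformed accordingly.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    if not 0.0 <= pair_fraction <= 1.0:
        raise ValueError("pair_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    geo = spec.geometry
    px = spec.px_size
    gap = 20.0  # μm between island crops
    pitch_x = geo.length + 2 * spec.margin + gap
    pitch_y = geo.width + 2 * spec.margin + gap
    n_cols = int(math.ceil(math.sqrt(n_islands)))
    n_rows = int(math.ceil(n_islands / n_cols))
    crop_h = int(round((geo.width + 2 * spec.margin) / px))
    crop_w = int(round((geo.length + 2 * spec.margin) / px))
    H = int(round(n_rows * pitch_y / px))
    W = int(round(n_cols * pitch_x / px))
    channels = {name: np.zeros((H, W)) for name in CHANNELS}

    origin = (
        (gap / 2 + spec.margin + geo.length / 2.0),
        (gap / 2 + spec.margin + geo.width / 2.0),
    )
    layout = PlateLayout(
        n_rows=n_rows, n_cols=n_cols, pitch_x=pitch_x, pitch_y=pitch_y,
        origin=origin, angle_deg=angle_deg,
    )

    islands: list[dict[str, Any]] = []
    for idx in range(n_islands):
        r, c = divmod(idx, n_cols)
        occupied = rng.random() < occupancy
        if not occupied:
            variant = "empty"
        elif rng.random() < pair_fraction:
            variant = "pair"
        else:
            variant = FAILURE_VARIANTS[rng.integers(0, len(FAILURE_VARIANTS))]
        sample = gen_cell_pair_image(
            spec.with_(seed=int(rng.integers(0, 2**31 - 1))), variant
        )
        r0 = int(round((gap / 2 + r * pitch_y) / px))
        c0 = int(round((gap / 2 + c * pitch_x) / px))
        for name in CHANNELS:
            tile = sample.channels[name]
            channels[name][r0:r0 + crop_h, c0:c0 + crop_w] = tile[:crop_h, :crop_w]
        cx = origin[0] + c * pitch_x
        cy = origin[1] + r * pitch_y
        islands.append({
            "index": idx,
            "grid_rc": (r, c),
            "center_um": (cx, cy),
            "variant": variant,
            "occupied": occupied,
            "accept": variant == "pair",
            "nuclei_centers_um": sample.truth["nuclei_centers_um"],
        })

    if angle_deg != 0.0:
        c_in = (np.array([H, W]) - 1) / 2.0
        rotated = {}
        for name in CHANNELS:
            rotated[name] = sktransform.rotate(
                channels[name], angle_deg, resize=True, order=1,
                preserve_range=True,
            )
        new_shape = next(iter(rotated.values())).shape
        c_out = (np.array(new_shape) - 1) / 2.0
        # skimage rotates the image CCW on screen: pixel content at
        # (row, col) maps to R(-a) about the centre in (row, col) space.
        a = np.radians(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        for isl in islands:
            cx, cy = isl["center_um"]
            rc = np.array([cy / px - 0.5, cx / px - 0.5])
            rc_new = rot @ (rc - c_in) + c_out
            isl["center_um"] = (
                (rc_new[1] + 0.5) * px, (rc_new[0] + 0.5) * px
            )
        channels = rotated

    return PlateSample(channels, px, layout, n_islands, islands, spec)
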