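"""Fibril orientation analysis: skeletonization, orientational order,
Z-disc presence, and nuclear morphometry.

The orientational order parameter (OOP) summarizes the angular
distribution of fibrillar structures: 0 for an isotropic field, 1 for
perfect alignment.  It is the largest eigenvalue of the mean orientation
tensor ⟨2 n nᵀ − I⟩ over unit direction vectors n = (cos θ, sin θ), with
fibril angles treated as π-periodic (fibrils are apolar).

Z-disc presence is the fraction of sarcomeric α-actinin skeleton oriented
within a tolerance of the cell's short axis — transverse Z-discs being
the signature of assembled sarcomeres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph

__all__ = [
    "OrientationField",
    "OOPResult",
    "ZDiscResult",
    "NuclearMorphology",
    "skeletonize_fibrils",
    "compute_oop",
    "z_disc_presence",
    "nuclear_morphology",
    "angular_distance_deg",
]


@dataclass
class OrientationField:
    """Skeleton pixels with local fibril angles.

    Angles are degrees on [0°, 180°), counter-clockwise from +x (image
    columns, y up).
    """

    coords: np.ndarray        # (N, 2) of (row, col)
    angles_deg: np.ndarray    # (N,)
    channel: str = ""
    long_axis_deg: float = 0.0
    shape: tuple[int, int] | None = None

    @property
    def n_pixels(self) -> int:
        return self.angles_deg.size


@dataclass
class OOPResult:
    oop: float
    director_deg: float
    n_pixels: int


@dataclass
class ZDiscResult:
    presence: float
    tolerance_deg: float
    n_pixels: int


@dataclass
class NuclearMorphology:
    aspect_ratio: float
    alignment_deg: float       # [0°, 90°] between nuclear major axis and cell long axis
    centroid: tuple[float, float]   # (row, col)
    area_px: int = 0
    orientation_deg: float = 0.0


def angular_distance_deg(a: np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """π-periodic angular distance in degrees, in [0°, 90°]."""
    d = np.mod(np.asarray(a, dtype=float) - b, 180.0)
    return np.minimum(d, 180.0 - d)


# ---------------------------------------------------------------------------

def skeletonize_fibrils(
    image: np.ndarray,
    px_size: float = 0.5,
    tubeness_scale_um: float = 0.8,
    smoothing_um: float = 1.5,
    channel: str = "",
    long_axis_deg: float = 0.0,
) -> OrientationField:
    """Extract 1-px fibril skeletons with per-pixel orientations.

    Pipeline: Hessian ridge (tubeness) enhancement at the fibril diameter
    scale → Otsu threshold → morphological skeletonization → local
    orientation from the smoothed structure tensor of the enhanced image.
    An image with no ridge response returns an empty field with a warning.
    """
    img = np.asarray(image, dtype=float)
    scale_px = max(tubeness_scale_um / px_size, 0.5)
    enhanced = skfilters.sato(img, sigmas=[scale_px], black_ridges=False)
    if enhanced.max() <= 0:
        warnings.warn("no ridge response; returning empty orientation field")
        return OrientationField(
            np.empty((0, 2), dtype=int), np.empty(0), channel,
            long_axis_deg, img.shape,
        )
    thr = skfilters.threshold_otsu(enhanced)
    binary = enhanced > thr
    if not binary.any():
        warnings.warn("no pixels above threshold; returning empty field")
        return OrientationField(
            np.empty((0, 2), dtype=int), np.empty(0), channel,
            long_axis_deg, img.shape,
        )
    skel = skmorph.skeletonize(binary)

    # structure tensor of the enhanced image (g_row is along -y)
    sigma = max(smoothing_um / px_size, 0.5)
    g_row = ndi.gaussian_filter(enhanced, 1.0, order=(1, 0))
    g_col = ndi.gaussian_filter(enhanced, 1.0, order=(0, 1))
    gx, gy = g_col, -g_row           # math convention, y up
    jxx = ndi.gaussian_filter(gx * gx, sigma)
    jxy = ndi.gaussian_filter(gx * gy, sigma)
    jyy = ndi.gaussian_filter(gy * gy, sigma)
    # dominant gradient orientation; fibril runs perpendicular to it
    theta_grad = 0.5 * np.arctan2(2 * jxy, jxx - jyy)
    theta_fibril = np.mod(np.degrees(theta_grad) + 90.0, 180.0)

    rows, cols = np.nonzero(skel)
    return OrientationField(
        coords=np.column_stack([rows, cols]),
        angles_deg=theta_fibril[rows, cols],
        channel=channel,
        long_axis_deg=long_axis_deg,
        shape=img.shape,
    )


def compute_oop(
    field: OrientationField | np.ndarray,
    weights: np.ndarray | None = None,
) -> OOPResult:
    """Orientational order parameter of an angle set.

    Builds the mean orientation tensor T = ⟨2 n nᵀ − I⟩ and returns its
    largest eigenvalue (the OOP) and the corresponding eigenvector angle
    (the director).  Accepts an :class:`OrientationField` or a raw array
    of angles in degrees.
    """
    angles = field.angles_deg if isinstance(field, OrientationField) else np.asarray(field, dtype=float)
    if angles.size < 2:
        raise ValueError("need at least 2 orientation samples for OOP")
    th = np.radians(angles)
    n = np.column_stack([np.cos(th), np.sin(th)])
    outer = 2.0 * np.einsum("ni,nj->nij", n, n) - np.eye(2)[None]
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        tensor = np.einsum("n,nij->ij", w, outer) / w.sum()
    else:
        tensor = outer.mean(axis=0)
    evals, evecs = np.linalg.eigh(tensor)
    oop = float(evals[-1])
    director = float(np.mod(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])), 180.0))
    return OOPResult(oop=oop, director_deg=director, n_pixels=angles.size)


def z_disc_presence(
    field: OrientationField | np.ndarray,
    long_axis_deg: float = 0.0,
    tolerance_deg: float = 15.0,
) -> ZDiscResult:
    """Fraction of skeleton oriented within ``tolerance_deg`` of the short axis."""
    angles = field.angles_deg if isinstance(field, OrientationField) else np.asarray(field, dtype=float)
    if angles.size == 0:
        raise ValueError("empty orientation field")
    short_axis = long_axis_deg + 90.0
    within = angular_distance_deg(angles, short_axis) <= tolerance_deg
    return ZDiscResult(
        presence=float(within.mean()),
        tolerance_deg=tolerance_deg,
        n_pixels=angles.size,
    )


def nuclear_morphology(
    nuclei_mask: np.ndarray,
    long_axis_deg: float = 0.0,
    min_area_px: int = 10,
) -> list[NuclearMorphology]:
    """Ellipse morphometrics of each nucleus from second-order moments.

    ``nuclei_mask`` may be boolean (components are labelled) or an integer
    label image.  Components smaller than ``min_area_px`` are skipped.
    Aspect ratio is major/minor axis length; alignment is the π-periodic
    angle between the nuclear major axis and the cell long axis, folded to
    [0°, 90°].  A circular nucleus (undefined orientation) reports
    alignment 0.
    """
    labels = (
        skmeasure.label(nuclei_mask)
        if nuclei_mask.dtype == bool
        else np.asarray(nuclei_mask)
    )
    out: list[NuclearMorphology] = []
    for prop in skmeasure.regionprops(labels):
        if prop.area < min_area_px:
            continue
        minor = prop.axis_minor_length
        major = prop.axis_major_length
        if minor <= 0:
            continue
        aspect = major / minor
        # convert skimage's row-axis-referenced orientation to the math
        # convention (degrees CCW from +x with y up): θ = 90° + orientation
        theta = np.mod(90.0 + np.degrees(prop.orientation), 180.0)
        if prop.eccentricity < 0.05:
            alignment = 0.0
            theta = 0.0
        else:
            alignment = float(angular_distance_deg(np.array([theta]), long_axis_deg)[0])
        out.append(
            NuclearMorphology(
                aspect_ratio=float(aspect),
                alignment_deg=alignment,
                centroid=tuple(prop.centroid),
                area_px=int(prop.area),
                orientation_deg=float(theta),
            )
        )
    return out
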