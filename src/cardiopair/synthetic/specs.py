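"""Parameterizations of the synthetic generators.

A spec is the complete stated world of one simulated sample: geometry,
phenotype mixture, optics, noise, and the seed.  Specs are immutable;
regenerating from an identical spec yields bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

from ..geometry import PatternGeometry, TissueGeometry

__all__ = ["SyntheticSpec", "CalciumSpec"]

#: cap above which the angular concentration is treated as a delta function
KAPPA_CAP = 1e6


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameterization of one synthetic cell-pair image.

    The junction-protein channel is a three-component mixture whose
    nonnegative weights sum to 1:

    * ``junctional`` — a Gaussian band of width ``junction_band_sigma``
      across the short axis, centred at the junction plane (the pattern
      midline, offset by ``band_offset``);
    * ``diffuse`` — uniform over the cell mask;
    * ``perinuclear`` — thin annuli hugging each nucleus.

    Fibril channels draw per-fibril angles from a π-periodic von Mises
    distribution of concentration ``fibril_kappa`` about a director;
    ``zdisc_fraction`` is the fraction of α-actinin fibrils oriented about
    the short axis instead (transverse Z-discs).
    """

    geometry: PatternGeometry = field(default_factory=PatternGeometry)
    px_size: float = 0.5            # μm / pixel
    junctional_weight: float = 1.0
    diffuse_weight: float = 0.0
    perinuclear_weight: float = 0.0
    junction_band_sigma: float = 5.0  # μm
    band_offset: float = 0.0          # μm, junction band centre from pattern midline
    fibril_kappa: float = 4.0         # angular concentration (0 = isotropic)
    zdisc_fraction: float = 0.7       # α-actinin fibrils about the short axis
    nuclear_aspect: float = 2.0       # major/minor axis ratio, ≥ 1
    nuclear_angle: float = 0.0        # degrees from the long axis
    nuclear_length: float = 18.0      # μm, nuclear major axis
    nuclear_offset_frac: float = 0.55  # nucleus centre, fraction of L/2 from junction
    perinuclear_ring_width: float = 2.0  # μm
    margin: float = 10.0              # μm of background around the pattern
    noise_sd: float = 0.02            # additive Gaussian, units of mean cell signal
    seed: int = 0

    def __post_init__(self) -> None:
        w = (self.junctional_weight, self.diffuse_weight, self.perinuclear_weight)
        if any(x < 0 for x in w):
            raise ValueError(f"mixture weights must be nonnegative, got {w}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(w)!r}")
        if self.px_size <= 0:
            raise ValueError("px_size must be > 0")
        if self.fibril_kappa < 0:
            raise ValueError("fibril_kappa must be >= 0")
        if not 0.0 <= self.zdisc_fraction <= 1.0:
            raise ValueError("zdisc_fraction must be in [0, 1]")
        if self.nuclear_aspect < 1.0:
            raise ValueError("nuclear_aspect must be >= 1")

    def with_(self, **kwargs: Any) -> "SyntheticSpec":
        """Return a copy with fields replaced (validation re-run)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CalciumSpec:
    """Ground-truth parameterization of one paced calcium movie.

    A planar wave leaves the stimulation site and travels at ``velocity``
    through the tissue; each pixel's fluorescence is
    ``baseline · (1 + amplitude · g(t − t_act))`` with a double-exponential
    transient g normalized to peak 1 and beats repeating at
    ``pacing_rate``.  ``t_act`` is geodesic distance within the tissue mask
    divided by velocity.
    """

    geometry: TissueGeometry = field(default_factory=TissueGeometry)
    velocity: float = 15.0        # cm/s
    pacing_rate: float = 1.0      # Hz
    frame_interval: float = 1.0   # ms
    px_size: float = 20.0         # μm / pixel
    tau_up: float = 10.0          # ms, transient upstroke time constant
    tau_down: float = 150.0       # ms, transient decay time constant
    amplitude: float = 0.5        # peak ΔF/F
    baseline: float = 100.0       # intensity units
    noise_sd: float = 5.0         # intensity units (SNR 10 at defaults)
    n_beats: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not self.tau_up < self.tau_down:
            raise ValueError("require tau_up < tau_down")
        if self.pacing_rate <= 0:
            raise ValueError("pacing_rate must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")

    @property
    def beat_period_ms(self) -> float:
        return 1000.0 / self.pacing_rate

    @property
    def duration_ms(self) -> float:
        return self.n_beats * self.beat_period_ms

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms / self.frame_interval))

    def with_(self, **kwargs: Any) -> "CalciumSpec":
        return replace(self, **kwargs)
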