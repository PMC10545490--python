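"""Shared fixtures: noise-free generator specs and small, fast geometries."""

from __future__ import annotations

import numpy as np
import pytest

from cardiopair.geometry import TissueGeometry
from cardiopair.registration import CellPairROI, to_canonical_frame
from cardiopair.synthetic import SyntheticSpec, gen_cell_pair_image


@pytest.fixture(scope="session")
def clean_spec() -> SyntheticSpec:
    """Noise-free cell-pair spec with default stamp geometry."""
    return SyntheticSpec(seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_tissue() -> TissueGeometry:
    """Scaled-down base+neck tissue to keep movie simulations fast."""
    return TissueGeometry(
        base_width=1200.0, base_length=1200.0,
        neck_width=500.0, neck_length=1500.0,
    )


def make_standardized(spec: SyntheticSpec, variant: str = "pair"):
    """Generate → wrap as ROI → canonical frame (the standard route)."""
    sample = gen_cell_pair_image(spec, variant)
    roi = CellPairROI(
        channels=sample.channels, px_size=spec.px_size,
        geometry=spec.geometry,
    )
    return to_canonical_frame(roi)


@pytest.fixture(scope="session")
def standardized_pair(clean_spec):
    return make_standardized(clean_spec)
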