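"""Shared fixtures: noise-free configs and hand-built cells/records."""

import numpy as np
import pytest

from ctsfna.images import CellRecord
from ctsfna.simulate import CellSpec, SmearSimConfig


@pytest.fixture
def noisefree_config():
    """A small noise-free field: rendering is then exactly reproducible."""
    return SmearSimConfig(
        field_width=128.0,
        field_height=128.0,
        pixel_size=0.5,
        noise_sd=0.0,
        poisson_noise=False,
        background=100.0,
        seed=0,
    )


def make_cell(
    center=(64.0, 64.0),
    major=12.0,
    minor=6.0,
    orientation=0.0,
    irregularity=0.0,
    cytoplasm_scale=1.6,
    red=1000.0,
    blue=3000.0,
    truth_class="malignant",
):
    return CellSpec(
        center=center,
        nuclear_major_axis=major,
        nuclear_minor_axis=minor,
        orientation=orientation,
        irregularity_amplitude=irregularity,
        cytoplasm_scale=cytoplasm_scale,
        red_level=red,
        blue_level=blue,
        truth_class=truth_class,
    )


def make_record(
    cell_id=1,
    centroid=(0.0, 0.0),
    major=8.0,
    minor=6.0,
    circularity=0.95,
    nc_ratio=0.6,
    median_red=500.0,
    red_positive=True,
):
    return CellRecord(
        cell_id=cell_id,
        centroid=centroid,
        major_axis=major,
        minor_axis=minor,
        circularity=circularity,
        nc_ratio=nc_ratio,
        median_red=median_red,
        red_positive=red_positive,
        enlarged=major >= 10.0,
        irregular=circularity < 0.8,
    )


def raster_ellipse(major_um, minor_um, angle=0.0, pixel_size=0.5, pad=3):
    """Analytically rasterized ellipse mask (pixel-center inclusion test)."""
    a, b = major_um / 2 / pixel_size, minor_um / 2 / pixel_size
    n = int(np.ceil(max(a, b))) + pad
    rr, cc = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1), indexing="ij")
    xr = np.cos(angle) * cc + np.sin(angle) * rr
    yr = -np.sin(angle) * cc + np.cos(angle) * rr
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
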