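"""Segmentation and per-cell feature extraction for two-channel smears.

Nuclei are segmented from the blue (Hoechst) channel by smoothed Otsu
thresholding with a distance-transform watershed to split touching nuclei.
Red-positive cytoplasm is thresholded against a robust (median/MAD)
background estimate.  Each nucleus is measured by its moment-fit ellipse
(major/minor axis in micrometres) and circularity 4*pi*A/P^2; cytoplasm is
the red-positive ring around the nucleus, assigned to the nearest nucleus,
from which the median red intensity and the N/C ratio are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import clear_border, watershed


class InputError(ValueError):
    """Raised for malformed image or parameter input."""


class MeasurementError(ValueError):
    """Raised when a measurement is requested on an empty mask."""


@dataclass
class SmearImage:
    """Two-channel raster with physical calibration.

    Pixel (r, c) sits at physical (x, y) = (c, r) * ``pixel_size`` (um),
    origin at the top-left pixel center.
    """

    red: np.ndarray
    blue: np.ndarray
    pixel_size: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.blue = np.asarray(self.blue)
        if self.red.shape != self.blue.shape:
            raise InputError("red and blue channels must have the same shape")
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be positive")


@dataclass
class CellRecord:
    """One segmented cell with the features the diagnostic criteria consume."""

    cell_id: int
    centroid: tuple[float, float]  # (x, y) um
    major_axis: float  # um
    minor_axis: float  # um
    circularity: float
    nc_ratio: float
    median_red: float
    red_positive: bool
    enlarged: bool
    irregular: bool
    nucleus_area_um2: float = 0.0
    cytoplasm_area_um2: float = 0.0
    nucleus_mask: tuple = field(default=(), repr=False)
    cytoplasm_mask: tuple = field(default=(), repr=False)


@dataclass
class RoiBox:
    """One scored tile from the low-power scan (pixel coordinates)."""

    origin: tuple[int, int]  # (row, col)
    width: int
    height: int
    score: float


def segment_nuclei(
    image: SmearImage,
    *,
    sigma: float = 1.0,
    threshold: float | None = None,
    min_nucleus_diameter_um: float = 4.0,
    split_min_distance_um: float = 2.5,
    exclude_border: bool = True,
) -> np.ndarray:
    """Label nuclei in the blue channel.

    Global Otsu threshold (overridable) on the Gaussian-smoothed blue
    channel; touching nuclei split by distance-transform watershed;
    components smaller than a ``min_nucleus_diameter_um`` disc removed.
    Nuclei clipped by the image border are discarded by default (their
    truncated shapes would be mismeasured).  Returns an integer label
    image (background 0).
    """
    blue = image.blue.astype(np.float64)
    labels = np.zeros(blue.shape, dtype=np.int32)
    if blue.size == 0 or np.ptp(blue) == 0:
        return labels
    smoothed = gaussian(blue, sigma=sigma, preserve_range=True)
    thr = threshold_otsu(smoothed) if threshold is None else threshold
    binary = smoothed > thr
    min_area_px = max(
        1, int(round(np.pi * (min_nucleus_diameter_um / 2.0) ** 2 / image.pixel_size**2))
    )
    binary = _drop_small(binary, min_area_px)
    if not binary.any():
        return labels

    distance = ndi.distance_transform_edt(binary)
    distance_s = gaussian(distance, sigma=1.0, preserve_range=True)
    min_dist_px = max(1, int(round(split_min_distance_um / image.pixel_size)))
    peaks = peak_local_max(
        distance_s, min_distance=min_dist_px, labels=binary, exclude_border=False
    )
    if len(peaks) == 0:
        labels, _ = ndi.label(binary)
        labels = labels.astype(np.int32)
        return clear_border(labels) if exclude_border else labels
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance_s, markers, mask=binary).astype(np.int32)
    if exclude_border:
        labels = clear_border(labels)
    # drop undersized fragments and relabel sequentially
    counts = np.bincount(labels.ravel())
    keep = np.nonzero(counts >= min_area_px)[0]
    keep = keep[keep > 0]
    remap = np.zeros(len(counts), dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def _drop_small(binary: np.ndarray, min_area_px: int) -> np.ndarray:
    lab, n = ndi.label(binary)
    if n == 0:
        return binary
    counts = np.bincount(lab.ravel())
    good = counts >= min_area_px
    good[0] = False
    return good[lab]


def measure_nucleus(
    mask: np.ndarray, pixel_size: float
) -> tuple[float, float, float]:
    """(major axis um, minor axis um, circularity) of one nucleus mask.

    Axes come from the best-fit ellipse of the mask's second central
    moments; circularity is 4*pi*area/perimeter^2 (Crofton perimeter,
    robust to pixelation), clipped to <= 1.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise MeasurementError("empty nucleus mask")
    props = regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length * pixel_size
    minor = props.axis_minor_length * pixel_size
    perim = props.perimeter_crofton
    if perim <= 0:
        circ = 1.0
    else:
        circ = min(1.0, 4.0 * np.pi * props.area / perim**2)
    return float(major), float(minor), float(circ)


def segment_red(
    image: SmearImage, *, k: float = 3.0, exclude: np.ndarray | None = None
) -> np.ndarray:
    """Boolean mask of red-positive pixels.

    Background is the median of the red channel (over ``~exclude`` if an
    exclusion mask of known-cell pixels is given); spread is 1.4826 * MAD
    with a small epsilon floor so a perfectly constant channel yields an
    empty mask.  A pixel is positive when red >= background + k * spread.
    """
    red = image.red.astype(np.float64)
    sample = red if exclude is None else red[~exclude.astype(bool)]
    if sample.size == 0:
        sample = red
    med = float(np.median(sample))
    mad = float(np.median(np.abs(sample - med))) * 1.4826
    spread = max(mad, 1e-6)
    return red >= med + k * spread


def assemble_cells(
    nuclei: np.ndarray,
    red_mask: np.ndarray,
    image: SmearImage,
    *,
    ring_um: float = 5.0,
    min_cyto_diameter_um: float = 2.0,
    enlargement_um: float = 10.0,
    circularity_irregular: float = 0.8,
    keep_masks: bool = False,
) -> list[CellRecord]:
    """Build per-cell records from nucleus labels and the red-positive mask.

    The cytoplasm of each cell is the set of red-positive pixels within a
    ``ring_um``-wide ring around its nucleus, each pixel assigned to its
    nearest nucleus, so shared red blobs are partitioned without double
    counting.  ``red_positive`` requires at least a ``min_cyto_diameter_um``
    disc worth of cytoplasm area.
    """
    ps = image.pixel_size
    nuclei = np.asarray(nuclei)
    n_labels = int(nuclei.max())
    if n_labels == 0:
        return []
    dist, (ir, ic) = ndi.distance_transform_edt(nuclei == 0, return_indices=True)
    nearest = nuclei[ir, ic]
    ring_px = ring_um / ps
    ring = (dist > 0) & (dist <= ring_px)
    cyto_ok = np.asarray(red_mask).astype(bool) & ring
    min_cyto_area = np.pi * (min_cyto_diameter_um / 2.0) ** 2
    red = image.red.astype(np.float64)

    records: list[CellRecord] = []
    for lab in range(1, n_labels + 1):
        nuc_mask = nuclei == lab
        if not nuc_mask.any():
            continue
        major, minor, circ = measure_nucleus(nuc_mask, ps)
        rows, cols = np.nonzero(nuc_mask)
        centroid = (float(cols.mean() * ps), float(rows.mean() * ps))
        cyt = cyto_ok & (nearest == lab)
        cyt_area = float(cyt.sum()) * ps**2
        nuc_area = float(nuc_mask.sum()) * ps**2
        if cyt.any():
            median_red = float(np.median(red[cyt]))
        else:
            median_red = 0.0
        red_positive = cyt_area >= min_cyto_area
        records.append(
            CellRecord(
                cell_id=lab,
                centroid=centroid,
                major_axis=major,
                minor_axis=minor,
                circularity=circ,
                nc_ratio=nuc_area / (nuc_area + cyt_area),
                median_red=median_red,
                red_positive=red_positive,
                enlarged=major >= enlargement_um,
                irregular=circ < circularity_irregular,
                nucleus_area_um2=nuc_area,
                cytoplasm_area_um2=cyt_area,
                nucleus_mask=np.nonzero(nuc_mask) if keep_masks else (),
                cytoplasm_mask=np.nonzero(cyt) if keep_masks else (),
            )
        )
    return records


def scan_low_power(
    image: SmearImage, box_size: int, n_top: int
) -> list[RoiBox]:
    """Tile the image and rank tiles by mean red intensity.

    Returns the top ``n_top`` tiles, score-descending; ties broken by
    row-major tile order.  Edge tiles may be smaller than ``box_size``.
    """
    if n_top <= 0:
        raise InputError("n_top must be positive")
    if box_size <= 0 or box_size > max(image.red.shape):
        raise InputError("box_size must be positive and fit in the image")
    rows, cols = image.red.shape
    boxes: list[RoiBox] = []
    for r0 in range(0, rows, box_size):
        for c0 in range(0, cols, box_size):
            tile = image.red[r0 : r0 + box_size, c0 : c0 + box_size]
            boxes.append(
                RoiBox(
                    origin=(r0, c0),
                    width=tile.shape[1],
                    height=tile.shape[0],
                    score=float(tile.mean()),
                )
            )
    order = np.argsort([-b.score for b in boxes], kind="stable")
    return [boxes[i] for i in order[: min(n_top, len(boxes))]]


# ---------------------------------------------------------------------------
# File I/O


def write_smear(image: SmearImage, path: str | Path) -> None:
    """Write a two-page TIFF (red, blue) with a sidecar JSON for pixel size."""
    path = Path(path)
    stack = np.stack([image.red, image.blue])
    tifffile.imwrite(path, stack, metadata={"axes": "CYX"})
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"pixel_size_um": image.pixel_size, "slide_id": image.slide_id})
    )


def read_smear(path: str | Path, pixel_size: float | None = None) -> SmearImage:
    """Read a two-page TIFF written by :func:`write_smear`.

    Pixel size comes from the sidecar JSON unless given explicitly.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise InputError(f"expected a 2-channel stack in {path}")
    slide_id = ""
    if pixel_size is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise InputError(f"no pixel size given and no sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta["pixel_size_um"])
        slide_id = meta.get("slide_id", "")
    return SmearImage(red=stack[0], blue=stack[1], pixel_size=pixel_size, slide_id=slide_id)


def cells_to_frame(cells: list[CellRecord], slide_id: str = "") -> pd.DataFrame:
    """Flatten cell records to a table (masks omitted)."""
    rows = []
    for c in cells:
        rows.append(
            {
                "slide_id": slide_id,
                "cell_id": c.cell_id,
                "x_um": c.centroid[0],
                "y_um": c.centroid[1],
                "major_axis_um": c.major_axis,
                "minor_axis_um": c.minor_axis,
                "circularity": c.circularity,
                "nc_ratio": c.nc_ratio,
                "median_red": c.median_red,
                "red_positive": c.red_positive,
                "enlarged": c.enlarged,
                "irregular": c.irregular,
                "nucleus_area_um2": c.nucleus_area_um2,
                "cytoplasm_area_um2": c.cytoplasm_area_um2,
            }
        )
    return pd.DataFrame(rows)


def frame_to_cells(frame: pd.DataFrame) -> list[CellRecord]:
    """Rebuild cell records from a table written by :func:`cells_to_frame`."""
    return [
        CellRecord(
            cell_id=int(r.cell_id),
            centroid=(float(r.x_um), float(r.y_um)),
            major_axis=float(r.major_axis_um),
            minor_axis=float(r.minor_axis_um),
            circularity=float(r.circularity),
            nc_ratio=float(r.nc_ratio),
            median_red=float(r.median_red),
            red_positive=bool(r.red_positive),
            enlarged=bool(r.enlarged),
            irregular=bool(r.irregular),
            nucleus_area_um2=float(r.nucleus_area_um2),
            cytoplasm_area_um2=float(r.cytoplasm_area_um2),
        )
        for r in frame.itertuples()
    ]
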