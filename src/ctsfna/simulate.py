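"""Synthetic two-channel smear-image generator with full ground truth.

Emulates fine-needle-aspirate smears of malignant, benign and normal breast
tissue as they appear under a red cytoplasmic stain (oxidative-stress probe)
plus a blue nuclear stain (Hoechst): malignant cells form tight aggregates
of enlarged (major axis predominantly >= 10 um), often irregular nuclei with
strong red cytoplasm; benign epithelium forms aggregates of small regular
nuclei with weak red cytoplasm; normal epithelium carries no red signal.

Cell positions follow a Neyman-Scott (parent-offspring) clustered point
process plus uniformly scattered singletons.  Nuclei are ellipses with an
optional smooth radial boundary perturbation (harmonics k=3..6) modelling
nuclear irregularity; the red cytoplasm is the nucleus ellipse dilated by a
per-cell factor, minus the nucleus.  The camera model is additive Gaussian
read noise on top of optional Poisson shot noise, written as 16-bit unsigned
counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd

TRUTH_CLASSES = ("malignant", "benign_epithelial", "normal_epithelial", "stromal")

#: fixed per-slide seed stride for cohort substreams (kept < 2**31 by modulo)
SLIDE_SEED_STRIDE = 10007


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class CellSpec:
    """One simulated cell: geometry, intensity and ground-truth class.

    Lengths are in micrometres, angles in radians, intensities in arbitrary
    camera units.
    """

    center: tuple[float, float]  # (x, y) um
    nuclear_major_axis: float
    nuclear_minor_axis: float
    orientation: float
    irregularity_amplitude: float
    cytoplasm_scale: float
    red_level: float
    blue_level: float
    truth_class: str

    def __post_init__(self) -> None:
        if self.nuclear_minor_axis > self.nuclear_major_axis + 1e-9:
            raise ConfigurationError("minor axis exceeds major axis")
        if self.truth_class not in TRUTH_CLASSES:
            raise ConfigurationError(f"unknown truth_class {self.truth_class!r}")
        if self.red_level < 0 or self.blue_level <= 0:
            raise ConfigurationError("red_level must be >= 0 and blue_level > 0")
        if self.irregularity_amplitude < 0 or self.cytoplasm_scale < 1:
            raise ConfigurationError(
                "irregularity_amplitude >= 0 and cytoplasm_scale >= 1 required"
            )


# Per-class defaults.  Major-axis distributions are lognormal; the malignant
# median (13 um, sigma_log 0.15) puts ~96% of malignant nuclei above the
# 10-um enlargement threshold while benign/normal medians (~7 um) stay
# almost entirely below it, reproducing the bimodal separation the
# threshold was derived from.  Red intensities give malignant cytoplasm a
# strong contrast over the weakly stained benign epithelium; normal
# epithelium and stroma are unstained.
DEFAULT_SIZE_PARAMS: dict[str, tuple[float, float]] = {
    "malignant": (13.0, 0.15),
    "benign_epithelial": (7.0, 0.12),
    "normal_epithelial": (7.0, 0.10),
    "stromal": (6.0, 0.15),
}
DEFAULT_RED_PARAMS: dict[str, tuple[float, float]] = {
    "malignant": (1500.0, 300.0),
    "benign_epithelial": (350.0, 120.0),
    "normal_epithelial": (0.0, 0.0),
    "stromal": (0.0, 0.0),
}
DEFAULT_IRREGULARITY: dict[str, tuple[float, float]] = {
    "malignant": (0.20, 0.08),
    "benign_epithelial": (0.02, 0.02),
    "normal_epithelial": (0.02, 0.02),
    "stromal": (0.03, 0.03),
}
# benign/normal nuclei are rounder than malignant ones
DEFAULT_AXIS_RATIO: dict[str, tuple[float, float]] = {
    "malignant": (0.55, 0.85),
    "benign_epithelial": (0.75, 0.95),
    "normal_epithelial": (0.75, 0.95),
    "stromal": (0.45, 0.75),
}


@dataclass
class SmearSimConfig:
    """Parameters of one simulated smear field.

    ``field_width``/``field_height`` are in micrometres; the raster is
    ``round(height / pixel_size) x round(width / pixel_size)`` pixels.
    ``cells_per_cluster`` is ``(mean, dispersion)``: dispersion 0 gives a
    fixed count, otherwise counts are negative-binomial with variance
    ``mean + dispersion * mean**2``.  ``dilution_factor`` multiplies every
    red level, modelling reagent dilution by excess mounting liquid.
    """

    field_width: float = 256.0
    field_height: float = 256.0
    pixel_size: float = 0.5
    n_clusters: int = 3
    cluster_radius: float = 12.0
    cells_per_cluster: tuple[float, float] = (12.0, 0.1)
    n_scattered: int = 10
    #: hard-core minimum center-to-center distance (um): nuclei in a smear
    #: monolayer touch but do not interpenetrate
    min_separation: float = 6.5
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"malignant": 0.8, "stromal": 0.2}
    )
    size_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_PARAMS)
    )
    red_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RED_PARAMS)
    )
    irregularity_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_IRREGULARITY)
    )
    axis_ratio_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AXIS_RATIO)
    )
    cytoplasm_scale_range: tuple[float, float] = (1.4, 1.8)
    blue_level: tuple[float, float] = (3000.0, 400.0)
    dilution_factor: float = 1.0
    background: float = 100.0
    noise_sd: float = 10.0
    poisson_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.field_width <= 0 or self.field_height <= 0:
            raise ConfigurationError("field dimensions must be positive")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if not self.class_mix:
            raise ConfigurationError("class_mix must not be empty")
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError(f"class_mix proportions sum to {total}, not 1")
        for cls in self.class_mix:
            if cls not in TRUTH_CLASSES:
                raise ConfigurationError(f"unknown class {cls!r} in class_mix")
        if not 0.0 <= self.dilution_factor <= 1.0:
            raise ConfigurationError("dilution_factor must lie in [0, 1]")
        if self.n_clusters < 0 or self.n_scattered < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.cluster_radius <= 0:
            raise ConfigurationError("cluster_radius must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered raster."""
        return (
            int(round(self.field_height / self.pixel_size)),
            int(round(self.field_width / self.pixel_size)),
        )


@dataclass
class GroundTruth:
    """Exact per-cell annotation attached to a rendered smear.

    ``nucleus_masks``/``cytoplasm_masks`` hold per-cell pixel index arrays
    ``(rows, cols)`` into the rendered raster.  ``slide_truth`` is malignant
    iff at least one malignant cell was generated.
    """

    cells: list[CellSpec]
    nucleus_masks: list[tuple[np.ndarray, np.ndarray]]
    cytoplasm_masks: list[tuple[np.ndarray, np.ndarray]]
    slide_truth: str
    intended_category: int

    def to_json(self) -> str:
        """Serialize cells + run-length masks to a JSON string."""
        records = []
        for spec, nuc, cyt in zip(self.cells, self.nucleus_masks, self.cytoplasm_masks):
            rec = asdict(spec)
            rec["nucleus_rle"] = _rle_encode(nuc)
            rec["cytoplasm_rle"] = _rle_encode(cyt)
            records.append(rec)
        return json.dumps(
            {
                "slide_truth": self.slide_truth,
                "intended_category": self.intended_category,
                "cells": records,
            },
            sort_keys=True,
        )


def _rle_encode(index_pair: tuple[np.ndarray, np.ndarray]) -> list[list[int]]:
    """Row-wise run-length encoding of a pixel index set: [row, start, length]."""
    rows, cols = index_pair
    if rows.size == 0:
        return []
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    runs: list[list[int]] = []
    r0, c0, length = int(rows[0]), int(cols[0]), 1
    for r, c in zip(rows[1:], cols[1:]):
        if r == r0 and c == c0 + length:
            length += 1
        else:
            runs.append([r0, c0, length])
            r0, c0, length = int(r), int(c), 1
    runs.append([r0, c0, length])
    return runs


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean < 0:
        raise ConfigurationError("cells_per_cluster mean must be >= 0")
    if dispersion <= 0:
        return int(round(mean))
    if mean == 0:
        return 0
    # negative binomial with variance mean + dispersion * mean**2
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _draw_cell(
    rng: np.random.Generator, center: tuple[float, float], cls: str, config: SmearSimConfig
) -> CellSpec:
    med, sig = config.size_params[cls]
    major = float(rng.lognormal(np.log(med), sig))
    lo, hi = config.axis_ratio_params[cls]
    minor = major * float(rng.uniform(lo, hi))
    orientation = float(rng.uniform(0.0, np.pi))
    imean, isd = config.irregularity_params[cls]
    irregularity = max(0.0, float(rng.normal(imean, isd)))
    cscale = float(rng.uniform(*config.cytoplasm_scale_range))
    rmean, rsd = config.red_params[cls]
    red = max(0.0, float(rng.normal(rmean, rsd))) if rmean > 0 or rsd > 0 else 0.0
    bmean, bsd = config.blue_level
    blue = max(bmean * 0.25, float(rng.normal(bmean, bsd)))
    return CellSpec(
        center=center,
        nuclear_major_axis=major,
        nuclear_minor_axis=minor,
        orientation=orientation,
        irregularity_amplitude=irregularity,
        cytoplasm_scale=cscale,
        red_level=red,
        blue_level=blue,
        truth_class=cls,
    )


def sample_cells(config: SmearSimConfig) -> list[CellSpec]:
    """Draw a clustered cell scene from ``config``.

    Cluster centers are uniform in the field; offspring are displaced by an
    isotropic Gaussian of sd ``cluster_radius``; ``n_scattered`` singletons
    are uniform.  Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    W, H = config.field_width, config.field_height

    cells: list[CellSpec] = []
    placed: list[tuple[float, float]] = []

    def admit(draw) -> tuple[float, float]:
        # Matern-style hard core: retry draws that land closer than
        # min_separation to an already-placed center; after max_tries the
        # last draw is accepted (dense clusters stay dense).
        for _ in range(20):
            x, y = draw()
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= config.min_separation**2
                for px, py in placed
            ):
                break
        placed.append((x, y))
        return x, y

    for _ in range(config.n_clusters):
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        count = _draw_count(rng, *config.cells_per_cluster)
        for _ in range(count):
            x, y = admit(
                lambda: (
                    float(np.clip(cx + rng.normal(0, config.cluster_radius), 0, W)),
                    float(np.clip(cy + rng.normal(0, config.cluster_radius), 0, H)),
                )
            )
            cls = classes[int(rng.choice(len(classes), p=probs))]
            cells.append(_draw_cell(rng, (x, y), cls, config))
    for _ in range(config.n_scattered):
        x, y = admit(
            lambda: (float(rng.uniform(0, W)), float(rng.uniform(0, H)))
        )
        cls = classes[int(rng.choice(len(classes), p=probs))]
        cells.append(_draw_cell(rng, (x, y), cls, config))
    return cells


def _boundary_harmonics(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalized amplitudes and phases for harmonics k = 3..6."""
    amps = rng.uniform(0.3, 1.0, size=4)
    amps = amps / np.linalg.norm(amps)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    return amps, phases


def _rasterize_cell(
    cell: CellSpec,
    harmonics: tuple[np.ndarray, np.ndarray],
    shape: tuple[int, int],
    pixel_size: float,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Pixel index sets (nucleus, cytoplasm) for one cell, clipped to the field.

    A pixel (r, c) sits at physical (x, y) = (c, r) * pixel_size.  The
    nucleus boundary in the ellipse frame is rho(theta) = 1 + amp * f(theta)
    with f a unit-normalized sum of cos(k theta + phi_k), k = 3..6; the
    cytoplasm boundary is the same curve scaled by ``cytoplasm_scale``.
    """
    a = cell.nuclear_major_axis / 2.0
    b = cell.nuclear_minor_axis / 2.0
    amp = cell.irregularity_amplitude
    cs = cell.cytoplasm_scale
    margin = cs * a * (1.0 + 2.0 * amp) + pixel_size
    cx, cy = cell.center

    r0 = max(0, int(np.floor((cy - margin) / pixel_size)))
    r1 = min(shape[0] - 1, int(np.ceil((cy + margin) / pixel_size)))
    c0 = max(0, int(np.floor((cx - margin) / pixel_size)))
    c1 = min(shape[1] - 1, int(np.ceil((cx + margin) / pixel_size)))
    if r1 < r0 or c1 < c0:
        empty = (np.array([], dtype=np.intp), np.array([], dtype=np.intp))
        return empty, empty

    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    dx = cc * pixel_size - cx
    dy = rr * pixel_size - cy
    cosb, sinb = np.cos(cell.orientation), np.sin(cell.orientation)
    xr = (cosb * dx + sinb * dy) / a
    yr = (-sinb * dx + cosb * dy) / b
    rho = np.hypot(xr, yr)
    if amp > 0:
        theta = np.arctan2(yr, xr)
        amps, phases = harmonics
        f = np.zeros_like(theta)
        for k, (ak, pk) in enumerate(zip(amps, phases), start=3):
            f += ak * np.cos(k * theta + pk)
        boundary = 1.0 + amp * f
    else:
        boundary = 1.0
    inside_nuc = rho <= boundary
    inside_cyt = (rho <= cs * boundary) & ~inside_nuc
    nuc = (rr[inside_nuc].astype(np.intp), cc[inside_nuc].astype(np.intp))
    cyt = (rr[inside_cyt].astype(np.intp), cc[inside_cyt].astype(np.intp))
    return nuc, cyt


def infer_intended_category(cells: Sequence[CellSpec]) -> int:
    """Category the generation parameters aim at (truth channel, not a call)."""
    red_cells = [c for c in cells if c.red_level > 0]
    big_or_malignant = [
        c
        for c in red_cells
        if c.nuclear_major_axis >= 10.0 or c.truth_class == "malignant"
    ]
    if len(red_cells) >= 5:
        return 4 if big_or_malignant else 3
    if red_cells:
        return 2
    return 1


def render_smear(
    cells: Sequence[CellSpec], config: SmearSimConfig
) -> tuple["SmearImage", GroundTruth]:
    """Rasterize a cell scene into a two-channel 16-bit smear image.

    Blue channel: nuclei at each cell's ``blue_level``.  Red channel:
    cytoplasmic annuli at ``red_level * dilution_factor``.  Overlapping
    cells combine by maximum so uniform intensities stay flat.  Identical
    (cells, config) give identical output.
    """
    from ctsfna.images import SmearImage  # local import to avoid a cycle

    config.validate()
    shape = config.shape
    red = np.zeros(shape, dtype=np.float64)
    blue = np.zeros(shape, dtype=np.float64)
    nucleus_masks = []
    cytoplasm_masks = []
    for idx, cell in enumerate(cells):
        # per-cell boundary shape drawn from a stream keyed by (seed, index)
        cell_rng = np.random.default_rng([config.seed, idx, 17])
        harmonics = _boundary_harmonics(cell_rng)
        nuc, cyt = _rasterize_cell(cell, harmonics, shape, config.pixel_size)
        nucleus_masks.append(nuc)
        cytoplasm_masks.append(cyt)
        if nuc[0].size:
            np.maximum.at(blue, nuc, cell.blue_level)
        if cyt[0].size and cell.red_level > 0:
            np.maximum.at(red, cyt, cell.red_level * config.dilution_factor)

    noise_rng = np.random.default_rng([config.seed, 0xBEEF])
    channels = []
    for raw in (red, blue):
        img = raw + config.background
        if config.poisson_noise:
            img = noise_rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if config.noise_sd > 0:
            img = img + noise_rng.normal(0.0, config.noise_sd, size=img.shape)
        channels.append(np.clip(np.round(img), 0, 65535).astype(np.uint16))
    red_u16, blue_u16 = channels

    truth = GroundTruth(
        cells=list(cells),
        nucleus_masks=nucleus_masks,
        cytoplasm_masks=cytoplasm_masks,
        slide_truth="malignant"
        if any(c.truth_class == "malignant" for c in cells)
        else ("normal" if all(c.red_level == 0 for c in cells) else "benign"),
        intended_category=infer_intended_category(cells),
    )
    image = SmearImage(red=red_u16, blue=blue_u16, pixel_size=config.pixel_size)
    return image, truth


# ---------------------------------------------------------------------------
# Cohort generation


def _slide_config(base: SmearSimConfig, truth: str, slide_seed: int) -> SmearSimConfig:
    """Per-slide configuration for one cohort slide of the given truth class."""
    if truth == "malignant":
        return replace(
            base,
            class_mix={"malignant": 0.8, "stromal": 0.2},
            n_clusters=3,
            cells_per_cluster=(12.0, 0.1),
            n_scattered=10,
            seed=slide_seed,
        )
    if truth == "benign":
        return replace(
            base,
            class_mix={"benign_epithelial": 0.85, "stromal": 0.15},
            n_clusters=3,
            cells_per_cluster=(10.0, 0.1),
            n_scattered=10,
            seed=slide_seed,
        )
    if truth == "normal":
        return replace(
            base,
            class_mix={"normal_epithelial": 0.8, "stromal": 0.2},
            n_clusters=2,
            cells_per_cluster=(6.0, 0.1),
            n_scattered=15,
            seed=slide_seed,
        )
    raise ConfigurationError(f"unknown slide truth {truth!r}")


def _ensure_malignant_cluster(
    cells: list[CellSpec], config: SmearSimConfig, slide_seed: int
) -> list[CellSpec]:
    """Guarantee at least one generated cluster holds >= 5 red malignant cells.

    Cohort malignant slides model aspirates of carcinoma, which in this
    regime always shed at least one qualifying aggregate; without the
    guarantee a rare class-mix draw could produce a malignant slide with no
    malignant aggregate at all.
    """
    # cluster cells precede scattered ones; group offspring by proximity is
    # unnecessary: re-class the first cluster's first five members if needed
    rng = np.random.default_rng([slide_seed, 0xC0FFEE])
    per_cluster = int(round(config.cells_per_cluster[0]))
    n_cluster_cells = len(cells) - config.n_scattered
    if n_cluster_cells <= 0 or per_cluster == 0:
        return cells
    # count red malignant cells per generated cluster block
    blocks: list[list[int]] = []
    i = 0
    while i < n_cluster_cells:
        blocks.append(list(range(i, min(i + per_cluster, n_cluster_cells))))
        i += per_cluster
    for block in blocks:
        n_mal = sum(
            1 for j in block if cells[j].truth_class == "malignant" and cells[j].red_level > 0
        )
        if n_mal >= 5:
            return cells
    # convert the first block's leading members to malignant
    block = max(blocks, key=len)
    for j in block[:5]:
        cells[j] = _draw_cell(rng, cells[j].center, "malignant", config)
    return cells


def generate_cohort(
    n_malignant: int,
    n_benign: int,
    n_normal: int,
    base_config: SmearSimConfig | None = None,
    seed: int = 0,
    render: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Generate one smear per slide for a cohort of the given composition.

    Returns ``(cohort_table, slides)`` where the table has one row per slide
    (slide_id, truth_class, intended_category, seed) and ``slides`` is a
    list of ``(SmearImage, GroundTruth)`` pairs (or ``(cells, config)``
    pairs when ``render=False``).  Per-slide substreams are derived from
    ``seed`` by a fixed stride so each slide is independently reproducible.
    """
    if n_malignant < 0 or n_benign < 0 or n_normal < 0:
        raise ConfigurationError("cohort counts must be non-negative")
    if n_malignant + n_benign + n_normal == 0:
        raise ConfigurationError("empty cohort requested")
    base = base_config if base_config is not None else SmearSimConfig()

    truths = (
        ["malignant"] * n_malignant + ["benign"] * n_benign + ["normal"] * n_normal
    )
    rows = []
    slides = []
    for i, truth in enumerate(truths):
        slide_seed = (seed + SLIDE_SEED_STRIDE * (i + 1)) % (2**31)
        cfg = _slide_config(base, truth, slide_seed)
        cells = sample_cells(cfg)
        if truth == "malignant":
            cells = _ensure_malignant_cluster(cells, cfg, slide_seed)
        if truth == "normal":
            # normal epithelium is unstained by construction
            cells = [replace(c, red_level=0.0) for c in cells]
        if render:
            image, truth_obj = render_smear(cells, cfg)
            image.slide_id = f"S{i + 1:03d}"
            slides.append((image, truth_obj))
            intended = truth_obj.intended_category
        else:
            slides.append((cells, cfg))
            intended = infer_intended_category(cells)
        rows.append(
            {
                "slide_id": f"S{i + 1:03d}",
                "truth_class": truth,
                "intended_category": intended,
                "seed": slide_seed,
            }
        )
    return pd.DataFrame(rows), slides
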