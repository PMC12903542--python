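"""Four-category diagnostic flow chart for red-stained smears.

A slide is category 4 (positive, malignant) when it holds an aggregate of
at least ``min_aggregate`` (default 5) red-positive cells of which at least
one nucleus is enlarged (major axis >= 10 um, inclusive) or irregular in
shape; category 3 when qualifying aggregates exist but all their members
are small and regular; category 2 when red-positive cells exist without
any qualifying aggregate; category 1 when no red-stained epithelial cell
is seen.  Only category 4 maps to a positive (malignant) call.

Aggregation is operationalized as single-linkage connected components over
red-positive cell centroids with link distance ``link_distance_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from ctsfna.images import CellRecord, InputError


@dataclass
class CtsThresholds:
    """Decision thresholds of the flow chart.

    ``min_aggregate`` (cells) and ``enlargement_um`` (um) are the published
    criteria; ``circularity_irregular`` operationalizes "irregular in
    shape" (no numeric definition is published), ``link_distance_um`` turns
    visual aggregation into single-linkage clustering, and ``nc_high`` with
    ``require_high_nc`` optionally adds the high-N/C requirement to the
    positive rule (off by default; the decision rule is the enlarged-OR-
    irregular disjunction).
    """

    min_aggregate: int = 5
    enlargement_um: float = 10.0
    circularity_irregular: float = 0.8
    nc_high: float = 0.5
    link_distance_um: float = 25.0
    require_high_nc: bool = False

    def __post_init__(self) -> None:
        if self.min_aggregate < 2:
            raise InputError("min_aggregate must be >= 2")
        if self.enlargement_um <= 0 or self.link_distance_um <= 0:
            raise InputError("length thresholds must be positive")
        if not 0 < self.circularity_irregular <= 1:
            raise InputError("circularity_irregular must lie in (0, 1]")
        if not 0 < self.nc_high <= 1:
            raise InputError("nc_high must lie in (0, 1]")


@dataclass
class CellCluster:
    """A single-linkage aggregate of red-positive cells."""

    member_ids: list[int]
    size: int
    max_major_axis: float
    any_irregular: bool
    max_nc: float


@dataclass
class CtsCategory:
    """Flow-chart output: category value 1-4 plus the rule that fired."""

    value: int
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4):
            raise InputError(f"category value must be 1-4, got {self.value}")


def _is_enlarged(cell: CellRecord, thresholds: CtsThresholds) -> bool:
    return cell.major_axis >= thresholds.enlargement_um


def _is_irregular(cell: CellRecord, thresholds: CtsThresholds) -> bool:
    return cell.circularity < thresholds.circularity_irregular


def cluster_red_cells(
    cells: list[CellRecord], thresholds: CtsThresholds | None = None
) -> list[CellCluster]:
    """Single-linkage clusters over red-positive cells.

    Two red-positive cells link when their centroid distance is at most
    ``link_distance_um``; non-red cells never cluster; every red-positive
    cell lands in exactly one cluster (singletons included).
    """
    thresholds = thresholds or CtsThresholds()
    red = [c for c in cells if c.red_positive]
    if not red:
        return []
    pts = np.array([c.centroid for c in red])
    if len(red) == 1:
        adjacency = csr_matrix((1, 1))
    else:
        dmat = squareform(pdist(pts)) <= thresholds.link_distance_um
        np.fill_diagonal(dmat, False)
        adjacency = csr_matrix(dmat)
    n_comp, labels = connected_components(adjacency, directed=False)
    clusters = []
    for comp in range(n_comp):
        members = [red[i] for i in np.nonzero(labels == comp)[0]]
        clusters.append(
            CellCluster(
                member_ids=[m.cell_id for m in members],
                size=len(members),
                max_major_axis=max(m.major_axis for m in members),
                any_irregular=any(_is_irregular(m, thresholds) for m in members),
                max_nc=max(m.nc_ratio for m in members),
            )
        )
    return clusters


def categorize_slide(
    cells: list[CellRecord],
    clusters: list[CellCluster] | None = None,
    thresholds: CtsThresholds | None = None,
) -> CtsCategory:
    """Assign the slide category from its cells and clusters.

    Enlarged/irregular are re-evaluated from the raw measurements against
    ``thresholds`` (so jittered thresholds apply), not from cached flags.
    The slide takes the maximum category supported by any cluster
    (worst-lesion-wins).
    """
    thresholds = thresholds or CtsThresholds()
    if clusters is None:
        clusters = cluster_red_cells(cells, thresholds)
    by_id = {c.cell_id: c for c in cells}

    aggregates = [cl for cl in clusters if cl.size >= thresholds.min_aggregate]
    for cl in aggregates:
        members = [by_id[i] for i in cl.member_ids]
        atypical = [
            m
            for m in members
            if _is_enlarged(m, thresholds) or _is_irregular(m, thresholds)
        ]
        if atypical and (not thresholds.require_high_nc or cl.max_nc >= thresholds.nc_high):
            return CtsCategory(
                4,
                f"aggregate of {cl.size} red cells with "
                f"{len(atypical)} enlarged/irregular member(s)",
            )
    if aggregates:
        return CtsCategory(
            3,
            f"aggregate(s) of >= {thresholds.min_aggregate} red cells, "
            "all small and regular",
        )
    if any(c.red_positive for c in cells):
        n_red = sum(1 for c in cells if c.red_positive)
        return CtsCategory(2, f"{n_red} red cell(s) without a qualifying aggregate")
    return CtsCategory(1, "no red-stained epithelial cells")


def category_to_call(category: CtsCategory | int) -> str:
    """Map category to the binary diagnosis: 4 -> positive, 1-3 -> negative."""
    value = category.value if isinstance(category, CtsCategory) else int(category)
    if value not in (1, 2, 3, 4):
        raise InputError(f"category value must be 1-4, got {value}")
    return "positive" if value == 4 else "negative"
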