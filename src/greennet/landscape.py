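"""Landscape-level composition and configuration metrics.

Composition is summarised by Shannon's diversity of the class-area
proportions, ``SHDI = -sum(P_k ln P_k)``, and its evenness normalisation
``SHEI = SHDI / ln(n)``.  Configuration is summarised by the landscape
shape index ``LSI = 0.25 E / sqrt(A)``, the mean Euclidean
nearest-neighbour distance between same-class patches (ENN, shortest
edge-cell center to edge-cell center), and connectance (CONNECT, the
percentage of same-class patch pairs lying within a user-chosen threshold
distance).

The connectance threshold has no universal default and is a required,
recorded parameter of every report: silent defaults would fabricate
comparability between runs.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .grid import GridRaster
from .patches import (
    PatchMap,
    delineate_patches,
    edge_density,
    mean_patch_fractal_dimension,
    mean_patch_size,
    patch_density,
    total_edge_length,
)
from .report import MetricsReport

__all__ = [
    "shannon_diversity",
    "shannon_evenness",
    "landscape_shape_index",
    "euclidean_nearest_neighbor",
    "connectance",
    "landscape_report",
    "class_report",
]


def _class_proportions(
    raster: GridRaster,
    classes: list[int] | None = None,
    include_background: bool = True,
    background: int = 0,
) -> np.ndarray:
    """Area proportions P_k of the included classes (nonzero only)."""
    if classes is None:
        classes = raster.classes()
        if not include_background:
            classes = [c for c in classes if c != background]
    counts = np.array(
        [np.count_nonzero(raster.values == c) for c in classes], dtype=float
    )
    total = counts.sum()
    if total == 0:
        raise ValueError("no cells in the included classes: proportions undefined")
    p = counts / total
    return p[p > 0]


def shannon_diversity(
    raster: GridRaster,
    classes: list[int] | None = None,
    include_background: bool = True,
    background: int = 0,
) -> float:
    """SHDI = -sum(P_k ln P_k) over class-area proportions; 0 for one class."""
    p = _class_proportions(raster, classes, include_background, background)
    return float(-(p * np.log(p)).sum())


def shannon_evenness(
    raster: GridRaster,
    classes: list[int] | None = None,
    include_background: bool = True,
    background: int = 0,
) -> float:
    """SHEI = SHDI / ln(n), in [0, 1]; 1 iff all proportions are equal."""
    p = _class_proportions(raster, classes, include_background, background)
    n = p.size
    if n < 2:
        raise ValueError("evenness undefined for a single patch type (ln 1 = 0)")
    return float(-(p * np.log(p)).sum() / np.log(n))


def landscape_shape_index(pm: PatchMap, include_boundary: bool = False) -> float:
    """LSI = 0.25 E / sqrt(A); rises as patches dis-aggregate."""
    a = pm.parent.landscape_area_m2
    if a == 0:
        raise ValueError("landscape area is zero")
    e = total_edge_length(pm.parent, None, include_boundary)
    return 0.25 * e / np.sqrt(a)


def _pairwise_min_distances(pm: PatchMap, class_code: int):
    """Min edge-cell center-to-center distance between each patch pair of a class."""
    patches = pm.patches_of(class_code)
    k = len(patches)
    mat = np.full((k, k), np.inf)
    cells = [pm.edge_cell_centers(p.id) for p in patches]
    for i in range(k):
        for j in range(i + 1, k):
            d = float(cdist(cells[i], cells[j]).min())
            mat[i, j] = mat[j, i] = d
    return patches, mat


def euclidean_nearest_neighbor(
    pm: PatchMap, class_code: int | None = None
) -> tuple[float, dict[int, float]]:
    """ENN: per patch, the shortest same-class edge-cell center distance.

    Returns the unweighted mean over patches and the per-patch distances
    (patch id -> metres).  With ``class_code=None`` every class with at
    least two patches contributes; patches of singleton classes have no
    neighbour and are left out of the mean.
    """
    class_codes = [class_code] if class_code is not None else list(pm.classes)
    per_patch: dict[int, float] = {}
    for c in class_codes:
        patches, mat = _pairwise_min_distances(pm, c)
        if len(patches) < 2:
            if class_code is not None:
                raise ValueError(
                    f"class {c} has {len(patches)} patch(es): ENN undefined"
                )
            continue
        mins = mat.min(axis=1)
        for p, d in zip(patches, mins):
            per_patch[p.id] = float(d)
    if not per_patch:
        raise ValueError("no class has >= 2 patches: ENN undefined")
    return float(np.mean(list(per_patch.values()))), per_patch


def connectance(pm: PatchMap, threshold_m: float) -> float:
    """CONNECT: percent of same-class patch pairs within ``threshold_m``.

    Pair distance is the same edge-cell center-to-center minimum as ENN;
    the result is non-decreasing in the threshold.
    """
    total_pairs = 0
    joined = 0
    for c in pm.classes:
        patches, mat = _pairwise_min_distances(pm, c)
        k = len(patches)
        total_pairs += k * (k - 1) // 2
        iu = np.triu_indices(k, 1)
        joined += int(np.count_nonzero(mat[iu] <= threshold_m))
    if total_pairs == 0:
        raise ValueError("no class has >= 2 patches: CONNECT undefined")
    return 100.0 * joined / total_pairs


_LANDSCAPE_METRICS = ("PD", "ED", "MPS", "LSI", "SHDI", "SHEI", "MPFD", "ENN", "CONNECT")


def landscape_report(
    raster: GridRaster,
    connect_threshold_m: float,
    connectivity: int = 8,
    include_boundary: bool = False,
    background: int = 0,
    include_background_in_diversity: bool = True,
    classes: list[int] | None = None,
    raster_id: str = "",
) -> MetricsReport:
    """Full landscape-level report: PD, ED, MPS, LSI, SHDI, SHEI, MPFD, ENN, CONNECT.

    ``classes`` restricts patch delineation (default: all non-background,
    non-nodata codes); diversity proportions include the background class
    unless switched off.  All parameters are echoed into the report's
    provenance.
    """
    pm = delineate_patches(raster, connectivity, classes, background)
    report = MetricsReport(
        level="landscape",
        provenance={
            "raster_id": raster_id,
            "cell_size_m": raster.cell_size,
            "shape": list(raster.shape),
            "connectivity": connectivity,
            "connect_threshold_m": connect_threshold_m,
            "include_boundary": include_boundary,
            "background": background,
            "include_background_in_diversity": include_background_in_diversity,
            "classes": list(pm.classes),
        },
    )
    report.add("PD", patch_density(pm), "n/100ha")
    report.add("ED", edge_density(pm, None, include_boundary), "m/ha")
    report.add("MPS", mean_patch_size(pm, "landscape"), "ha")
    report.add("LSI", landscape_shape_index(pm, include_boundary), "")
    report.add(
        "SHDI",
        shannon_diversity(raster, None, include_background_in_diversity, background),
        "",
    )
    report.add(
        "SHEI",
        shannon_evenness(raster, None, include_background_in_diversity, background),
        "",
    )
    report.add("MPFD", mean_patch_fractal_dimension(pm), "")
    enn_mean, _ = euclidean_nearest_neighbor(pm)
    report.add("ENN", enn_mean, "m")
    report.add("CONNECT", connectance(pm, connect_threshold_m), "%")
    return report


def class_report(
    raster: GridRaster,
    class_code: int,
    connectivity: int = 8,
    include_boundary: bool = False,
    background: int = 0,
    raster_id: str = "",
) -> MetricsReport:
    """Class-level report: CA, PD, ED, MPS, MPFD for one class."""
    from .patches import total_class_area

    pm = delineate_patches(raster, connectivity, None, background)
    report = MetricsReport(
        level="class",
        class_label=str(class_code),
        provenance={
            "raster_id": raster_id,
            "cell_size_m": raster.cell_size,
            "connectivity": connectivity,
            "include_boundary": include_boundary,
            "background": background,
            "class": class_code,
        },
    )
    report.add("CA", total_class_area(pm, class_code), "ha")
    report.add("PD", patch_density(pm, class_code), "n/100ha")
    report.add("ED", edge_density(pm, class_code, include_boundary), "m/ha")
    report.add("MPS", mean_patch_size(pm, "class", class_code), "ha")
    report.add("MPFD", mean_patch_fractal_dimension(pm, class_code), "")
    return report
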