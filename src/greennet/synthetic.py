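"""Synthetic landscapes and networks with controlled structure.

The original Nanchang GIS layers are not publicly deposited, so every
pipeline stage is exercised on synthetic stand-ins:

* a *random-cluster* neutral landscape generator — plant a chosen number of
  seed cells per class and grow clusters by uniform random accretion of
  4-adjacent cells until each class reaches its target area proportion.
  The seeds-per-class count is a direct fragmentation dial: more seeds
  means more, smaller patches, which is exactly what the fragmentation
  metrics (PD, MPS) probe;
* a random spatial network generator — uniform node placement, candidate
  links from a Delaunay proximity triangulation, random thinning to the
  target link count ``floor(beta * v)``;
* fixed reference networks carrying the published node/corridor counts of
  the two Nanchang districts (Changbei: v=44, l=56, d=100.45 km; Changnan:
  v=74, l=109, d=197.15 km).  Their geometry is arbitrary but frozen —
  only v, l and d are faithful, so geometry-dependent quantities (e.g.
  density without a district area) carry no claim.

Every generator is a pure function of its spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay

from .grid import GridRaster
from .network import EcoNetwork, Link

__all__ = [
    "LandscapeSpec",
    "NetworkSpec",
    "generate_landscape",
    "generate_network",
    "reference_networks",
    "REFERENCE_COUNTS",
    "toy_single_patch",
    "toy_bridging_plan",
]

# Published district counts: (nodes v, corridors l, total corridor length d km).
REFERENCE_COUNTS = {
    "Changbei": (44, 56, 100.45),
    "Changnan": (74, 109, 197.15),
}


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for a random-cluster categorical landscape.

    ``proportions`` maps class code -> target area fraction; the remainder
    of the grid is background.  ``clumping`` is the number of seed cells
    per class: 1 grows a single connected patch, larger values fragment
    the class into more, smaller patches.
    """

    rows: int = 50
    cols: int = 50
    cell_size: float = 10.0
    proportions: dict[int, float] = field(default_factory=lambda: {1: 0.3})
    clumping: int = 3
    background: int = 0
    nodata: int = -9999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 4:
            raise ValueError("grid must have at least 4 cells")
        if self.clumping < 1:
            raise ValueError("clumping (seeds per class) must be >= 1")
        total = sum(self.proportions.values())
        if any(p < 0 for p in self.proportions.values()) or total > 1:
            raise ValueError(
                f"class proportions must be >= 0 and sum <= 1 (got {total})"
            )
        if self.background in self.proportions:
            raise ValueError("background cannot have a target proportion")


def generate_landscape(spec: LandscapeSpec) -> GridRaster:
    """Grow a random-cluster landscape; bit-identical for identical specs.

    Each class's achieved cell count equals ``round(p * rows * cols)``
    (within one cell of target).  If a growing cluster is walled in before
    reaching its target, a fresh seed is planted on free ground, so targets
    are met whenever free cells remain.
    """
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.rows, spec.cols
    ncells = nrows * ncols
    targets = {c: int(round(p * ncells)) for c, p in sorted(spec.proportions.items())}

    claim = np.full((nrows, ncols), -1, dtype=np.int64)  # -1 = unclaimed
    remaining = dict(targets)
    frontiers: dict[int, list[tuple[int, int]]] = {c: [] for c in targets}

    def neighbors(r: int, c: int):
        if r > 0:
            yield r - 1, c
        if r < nrows - 1:
            yield r + 1, c
        if c > 0:
            yield r, c - 1
        if c < ncols - 1:
            yield r, c + 1

    def claim_cell(cls: int, r: int, c: int) -> None:
        claim[r, c] = cls
        remaining[cls] -= 1
        for nr, nc in neighbors(r, c):
            if claim[nr, nc] == -1:
                frontiers[cls].append((nr, nc))

    def plant_seed(cls: int) -> bool:
        free = np.flatnonzero(claim.ravel() == -1)
        if free.size == 0:
            return False
        idx = int(rng.choice(free))
        claim_cell(cls, idx // ncols, idx % ncols)
        return True

    for cls, tgt in targets.items():
        for _ in range(min(spec.clumping, tgt)):
            if remaining[cls] > 0:
                plant_seed(cls)

    needy = [c for c in targets if remaining[c] > 0]
    while needy:
        cls = needy[int(rng.integers(len(needy)))]
        grown = False
        frontier = frontiers[cls]
        while frontier:
            i = int(rng.integers(len(frontier)))
            frontier[i], frontier[-1] = frontier[-1], frontier[i]
            r, c = frontier.pop()
            if claim[r, c] == -1:
                claim_cell(cls, r, c)
                grown = True
                break
        if not grown and not plant_seed(cls):
            break  # grid exhausted
        needy = [c for c in targets if remaining[c] > 0]

    values = np.where(claim == -1, spec.background, claim)
    return GridRaster(
        values=values.astype(np.int64),
        cell_size=spec.cell_size,
        nodata=spec.nodata,
    )


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for a random spatial network.

    ``target_beta`` is the desired mean links per node; the realised link
    count is ``floor(target_beta * v)``.
    """

    v: int = 30
    extent_km: tuple[float, float] = (10.0, 10.0)
    target_beta: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v < 3:
            raise ValueError("need at least 3 nodes")
        if not (0 < self.target_beta < 3):
            raise ValueError("target_beta must lie in (0, 3)")
        if min(self.extent_km) <= 0:
            raise ValueError("extent must be positive")


def generate_network(spec: NetworkSpec) -> EcoNetwork:
    """Random planar-ish network: Delaunay candidates thinned to the target.

    Link lengths are node-to-node chords in km; no duplicate links or
    self-loops can arise (candidates are triangulation edges).
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.extent_km
    coords = rng.uniform((0, 0), (w * 1000.0, h * 1000.0), size=(spec.v, 2))
    tri = Delaunay(coords)
    candidates = sorted(
        {
            tuple(sorted(pair))
            for simplex in tri.simplices
            for pair in combinations(simplex.tolist(), 2)
        }
    )
    n_links = int(np.floor(spec.target_beta * spec.v + 1e-9))
    if n_links > len(candidates):
        raise ValueError(
            f"target of {n_links} links exceeds the {len(candidates)} candidate "
            f"triangulation edges; target_beta={spec.target_beta} is infeasible "
            f"for v={spec.v}"
        )
    chosen = rng.choice(len(candidates), size=n_links, replace=False)
    nodes = {i: (float(x), float(y)) for i, (x, y) in enumerate(coords)}
    links = []
    for k in sorted(chosen.tolist()):
        a, b = candidates[k]
        d_km = float(np.hypot(*(coords[a] - coords[b]))) / 1000.0
        links.append(Link(source=a, target=b, length_km=d_km))
    return EcoNetwork(nodes=nodes, links=links)


def _fixed_network(name: str, v: int, n_links: int, d_km: float) -> EcoNetwork:
    """Frozen-geometry network with exactly v nodes, l links, total length d."""
    base = generate_network(
        NetworkSpec(v=v, extent_km=(10.0, 10.0), target_beta=n_links / v + 1e-9, seed=7)
    )
    assert base.l == n_links
    factor = d_km / base.total_length_km
    nodes = {i: (x * factor, y * factor) for i, (x, y) in base.nodes.items()}
    links = [
        Link(source=lk.source, target=lk.target, length_km=lk.length_km * factor)
        for lk in base.links
    ]
    return EcoNetwork(nodes=nodes, links=links, name=name)


def reference_networks() -> dict[str, EcoNetwork]:
    """The two district networks with published v, l and d; geometry frozen."""
    return {
        name: _fixed_network(name, v, n_links, d_km)
        for name, (v, n_links, d_km) in REFERENCE_COUNTS.items()
    }


# -- hand-authored toy rasters --------------------------------------------


def toy_single_patch() -> GridRaster:
    """10x10 background grid with one 3x3 green patch (10 m cells).

    Anchors: E = 120 m boundary-excluded, ED = 120 m/ha, LSI = 0.30,
    MPFD = 1.0.
    """
    values = np.zeros((10, 10), dtype=np.int64)
    values[3:6, 3:6] = 1
    return GridRaster(values=values, cell_size=10.0)


def toy_bridging_plan() -> tuple[GridRaster, list[tuple[tuple[float, float], tuple[float, float]]]]:
    """Two 1-cell green patches 50 m apart plus the corridor chord joining them.

    A 40 m-wide corridor along the chord merges the two patches into one
    under 8-connectivity.
    """
    values = np.zeros((10, 10), dtype=np.int64)
    values[5, 2] = 1  # center (25, 45)
    values[5, 7] = 1  # center (75, 45), 50 m away
    raster = GridRaster(values=values, cell_size=10.0)
    corridor = [((25.0, 45.0), (75.0, 45.0))]
    return raster, corridor
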