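"""Independent brute-force oracles for the raster metrics.

Deliberately naive implementations (BFS flood fill, exhaustive face and
pair enumeration) kept free of any code from the package under test.
"""

from __future__ import annotations

import math
from collections import deque


def flood_fill_patches(values, class_code, connectivity=8, nodata=-9999):
    """All connected components of a class as lists of (row, col) sets."""
    nrows, ncols = len(values), len(values[0])
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = set()
    patches = []
    for r in range(nrows):
        for c in range(ncols):
            if values[r][c] != class_code or (r, c) in seen:
                continue
            comp = set()
            q = deque([(r, c)])
            seen.add((r, c))
            while q:
                cr, cc = q.popleft()
                comp.add((cr, cc))
                for dr, dc in offsets:
                    nr, nc = cr + dr, cc + dc
                    if (
                        0 <= nr < nrows
                        and 0 <= nc < ncols
                        and (nr, nc) not in seen
                        and values[nr][nc] == class_code
                    ):
                        seen.add((nr, nc))
                        q.append((nr, nc))
            patches.append(comp)
    return patches


def patch_perimeter_cells(cells, cell_size):
    """Perimeter (m) of a cell set: every face not shared within the set."""
    faces = 0
    for r, c in cells:
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if (nr, nc) not in cells:
                faces += 1
    return faces * cell_size


def total_edge_oracle(values, cell_size, nodata=-9999, class_code=None,
                      include_boundary=False):
    """Summed edge length (m) by exhaustive face enumeration."""
    nrows, ncols = len(values), len(values[0])

    def code(r, c):
        if 0 <= r < nrows and 0 <= c < ncols:
            return values[r][c]
        return None  # off-grid

    faces = 0
    for r in range(nrows):
        for c in range(ncols):
            a = code(r, c)
            if a == nodata:
                continue
            for nr, nc in ((r, c + 1), (r + 1, c)):  # each interior face once
                b = code(nr, nc)
                if b is None:
                    continue
                if b == nodata:
                    if include_boundary and (class_code is None or a == class_code):
                        faces += 1
                    continue
                if a != b:
                    if class_code is None or class_code in (a, b):
                        faces += 1
            # nodata side of the face seen from the valid cell
            for nr, nc in ((r, c - 1), (r - 1, c)):
                b = code(nr, nc)
                if b == nodata and include_boundary and (
                    class_code is None or a == class_code
                ):
                    faces += 1
            if include_boundary and (class_code is None or a == class_code):
                faces += sum(
                    1
                    for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                    if code(nr, nc) is None
                )
    return faces * cell_size


def edge_cells(cells, nrows, ncols):
    out = set()
    for r, c in cells:
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if (nr, nc) not in cells:
                out.add((r, c))
                break
    return out


def _cell_center(r, c, nrows, cell_size, origin=(0.0, 0.0)):
    x = origin[0] + (c + 0.5) * cell_size
    y = origin[1] + (nrows - r - 0.5) * cell_size
    return x, y


def min_patch_distance(cells_a, cells_b, nrows, ncols, cell_size):
    """Min edge-cell center-to-center distance between two patches (m)."""
    ea = edge_cells(cells_a, nrows, ncols)
    eb = edge_cells(cells_b, nrows, ncols)
    best = math.inf
    for ra, ca in ea:
        xa, ya = _cell_center(ra, ca, nrows, cell_size)
        for rb, cb in eb:
            xb, yb = _cell_center(rb, cb, nrows, cell_size)
            best = min(best, math.hypot(xb - xa, yb - ya))
    return best


def enn_oracle(values, cell_size, classes, connectivity=8):
    """Mean nearest same-class patch distance over all patches with a neighbour."""
    nrows, ncols = len(values), len(values[0])
    dists = []
    for cls in classes:
        patches = flood_fill_patches(values, cls, connectivity)
        if len(patches) < 2:
            continue
        for i, pa in enumerate(patches):
            best = min(
                min_patch_distance(pa, pb, nrows, ncols, cell_size)
                for j, pb in enumerate(patches)
                if j != i
            )
            dists.append(best)
    if not dists:
        raise ValueError("no class with >= 2 patches")
    return sum(dists) / len(dists)


def connect_oracle(values, cell_size, classes, threshold, connectivity=8):
    """Percent of same-class patch pairs within the threshold distance."""
    nrows, ncols = len(values), len(values[0])
    pairs = 0
    joined = 0
    for cls in classes:
        patches = flood_fill_patches(values, cls, connectivity)
        for i in range(len(patches)):
            for j in range(i + 1, len(patches)):
                pairs += 1
                d = min_patch_distance(
                    patches[i], patches[j], nrows, ncols, cell_size
                )
                if d <= threshold:
                    joined += 1
    if pairs == 0:
        raise ValueError("no class with >= 2 patches")
    return 100.0 * joined / pairs
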