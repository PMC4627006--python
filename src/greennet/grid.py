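"""Categorical raster container, ESRI ASCII grid I/O and class remapping.

The raster model is deliberately minimal: a rectangular grid of integer
land-cover codes with a square cell size in metres, a nodata code and a
lower-left origin.  Row 0 of ``values`` is the northernmost row, matching
the ESRI ASCII grid convention.  All distances in the package are computed
between cell centers, located at ``origin + (index + 0.5) * cell_size``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "GridRaster",
    "ClassScheme",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_class_scheme",
    "reclassify",
]

DEFAULT_NODATA = -9999


class GridFormatError(ValueError):
    """Raised when an ESRI ASCII grid file cannot be parsed."""


@dataclass(frozen=True)
class GridRaster:
    """A rectangular grid of integer land-cover codes.

    Parameters
    ----------
    values
        2-D integer array of class codes; row 0 is the northernmost row.
    cell_size
        Side length of the square cells, in metres.
    nodata
        Integer code marking cells outside the landscape.  Nodata cells are
        excluded from the landscape area, from patch delineation and from
        diversity proportions.
    origin
        ``(x, y)`` of the lower-left corner of the grid, in metres.
    """

    values: np.ndarray
    cell_size: float = 10.0
    nodata: int = DEFAULT_NODATA
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"raster values must be integers, got dtype {arr.dtype}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        object.__setattr__(self, "values", arr.astype(np.int64, copy=False))

    # -- derived geometry ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return self.values != self.nodata

    @property
    def landscape_area_m2(self) -> float:
        """Total landscape area A: non-nodata cell count times cell area (m^2)."""
        return float(np.count_nonzero(self.valid_mask)) * self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` coordinate arrays of all cell centers, in metres."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        x = x0 + (cols + 0.5) * self.cell_size
        # row 0 is northernmost: its center sits (nrows - 0.5) cells above y0
        y = y0 + (nrows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def classes(self) -> list[int]:
        """Sorted distinct class codes present, excluding nodata."""
        vals = np.unique(self.values)
        return [int(v) for v in vals if v != self.nodata]

    def equals(self, other: "GridRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
            and self.cell_size == other.cell_size
            and self.nodata == other.nodata
            and self.origin == other.origin
        )


@dataclass(frozen=True)
class ClassScheme:
    """Total mapping of source land-use codes to analysis class codes.

    By convention target code 0 is the non-green background; green classes
    use positive codes (e.g. 1 = natural green, 2 = cultivated green).
    """

    mapping: Mapping[int, int]
    class_names: Mapping[int, str] = field(default_factory=dict)

    def __call__(self, code: int) -> int:
        return self.mapping[code]


# -- ESRI ASCII grid ------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> GridRaster:
    """Read an ESRI ASCII grid (.asc) into a :class:`GridRaster`.

    The header must carry ncols/nrows/xllcorner/yllcorner/cellsize; a
    NODATA_value line is optional (default -9999).  Cell values must be
    integers (integral floats such as ``3.0`` are accepted).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise GridFormatError(
                    f"{path}: malformed header line {i + 1}: {line!r}"
                ) from None
            body_start = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path}: header missing {', '.join(missing)}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = int(header.get("nodata_value", DEFAULT_NODATA))

    flat: list[int] = []
    for i, line in enumerate(lines[body_start:], start=body_start):
        for tok in line.split():
            try:
                val = float(tok)
            except ValueError:
                raise GridFormatError(
                    f"{path}: non-numeric cell value {tok!r} on line {i + 1}"
                ) from None
            if val != int(val):
                raise TypeError(
                    f"{path}: non-integer cell value {tok!r} on line {i + 1}"
                )
            flat.append(int(val))
    if len(flat) != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} cell values, found {len(flat)}"
        )
    values = np.array(flat, dtype=np.int64).reshape(nrows, ncols)
    return GridRaster(
        values=values,
        cell_size=header["cellsize"],
        nodata=nodata,
        origin=(header["xllcorner"], header["yllcorner"]),
    )


def write_ascii_grid(raster: GridRaster, path: str | Path) -> None:
    """Write a :class:`GridRaster` as an ESRI ASCII grid, re-readable to equality."""
    nrows, ncols = raster.values.shape
    x0, y0 = raster.origin
    cs = raster.cell_size
    cs_str = f"{int(cs)}" if float(cs).is_integer() else repr(float(cs))
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0}\n")
        fh.write(f"yllcorner {y0}\n")
        fh.write(f"cellsize {cs_str}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for row in raster.values:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_class_scheme(path: str | Path) -> ClassScheme:
    """Read a two-column CSV ``source_code,target_code`` into a ClassScheme.

    A header row is skipped if its first field is not an integer.
    """
    mapping: dict[int, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                src = int(row[0])
            except ValueError:
                continue  # header line
            mapping[src] = int(row[1])
    if not mapping:
        raise ValueError(f"{path}: no code mappings found")
    return ClassScheme(mapping=mapping)


def reclassify(raster: GridRaster, scheme: ClassScheme) -> GridRaster:
    """Remap class codes pointwise; nodata and geometry are preserved.

    Every code present in the raster (other than nodata) must appear in
    ``scheme.mapping``.
    """
    present = set(raster.classes())
    unmapped = sorted(present - set(int(k) for k in scheme.mapping))
    if unmapped:
        raise ValueError(f"unmapped class codes in raster: {unmapped}")
    out = raster.values.copy()
    for src, dst in scheme.mapping.items():
        if int(dst) == raster.nodata:
            raise ValueError(
                f"target code {dst} collides with the nodata code {raster.nodata}"
            )
        out[raster.values == int(src)] = int(dst)
    out[~raster.valid_mask] = raster.nodata
    return GridRaster(
        values=out,
        cell_size=raster.cell_size,
        nodata=raster.nodata,
        origin=raster.origin,
    )
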