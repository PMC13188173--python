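"""Aligned raster grids, ESRI ASCII I/O, occurrence tables.

All analysis surfaces live on one rectangular grid. ``RasterGrid`` stores a
2-D value array with a boolean nodata mask and the usual ESRI ASCII geometry
(lower-left corner, square cells). Row 0 is the northernmost row, matching
the on-disk row order of the ``.asc`` format.

``EnvStack`` bundles aligned covariate layers, each labelled with one of the
four driver groups (climate, soil, terrain, anthropogenic), and exposes the
pixel table: one row per cell that is unmasked in *every* layer (union-nodata
rule), one column per covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("climate", "soil", "terrain", "anthropogenic")

DEFAULT_NODATA = -9999.0

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class GridFormatError(ValueError):
    """Malformed ESRI ASCII grid or occurrence file."""


class AlignmentError(ValueError):
    """Layers do not share (or cannot be mapped onto) one grid geometry."""


@dataclass
class RasterGrid:
    """One aligned 2-D surface with nodata mask and grid geometry.

    Parameters
    ----------
    values
        2-D float array; entries under the mask are ignored by all statistics.
    mask
        Boolean array, same shape, ``True`` where the cell is nodata.
    origin_x, origin_y
        Map coordinates of the lower-left corner (ESRI ``xllcorner`` /
        ``yllcorner``).
    cell_size
        Square cell edge length in map units; must be positive.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 2-D array")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def geometry(self) -> tuple[int, int, float, float, float]:
        return (self.nrows, self.ncols, self.origin_x, self.origin_y, self.cell_size)

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol
            for a, b in zip(self.geometry()[2:], other.geometry()[2:])
        )

    def unmasked(self) -> np.ndarray:
        """Values at valid cells, as a flat array."""
        return self.values[~self.mask]

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of cell centres (row 0 = north)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y + (self.nrows - 1 - np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col) with half-open cell intervals.

        A point exactly on an interior cell edge belongs to the cell to the
        east (x edges) / north (y edges) of that edge. Points outside the
        grid get row/col = -1.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        j = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        row = self.nrows - 1 - j
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def with_values(self, values: np.ndarray, name: str | None = None,
                    mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid on the same geometry."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            mask=self.mask.copy() if mask is None else mask,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            name=self.name if name is None else name,
        )


def read_ascii_grid(path, name: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid (six-line header, row-major values)."""
    header: dict[str, float] = {}
    nodata = DEFAULT_NODATA
    with open(path) as fh:
        lines = fh.readlines()
    idx = 0
    for idx, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"{path}: bad header line {idx + 1}: {line.strip()!r}"
                ) from exc
            if key == "nodata_value":
                nodata = val
            else:
                header[key] = val
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path}: header missing {', '.join(missing)}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[idx:], start=idx + 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != ncols:
            raise GridFormatError(
                f"{path}: line {lineno} has {len(parts)} values, expected ncols={ncols}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise GridFormatError(f"{path}: non-numeric value on line {lineno}") from exc
    if len(rows) != nrows:
        raise GridFormatError(
            f"{path}: found {len(rows)} data rows, expected nrows={nrows}"
        )
    values = np.array(rows, dtype=float)
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    import os

    return RasterGrid(
        values=values,
        mask=mask,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        name=name or os.path.splitext(os.path.basename(str(path)))[0],
    )


def write_ascii_grid(grid: RasterGrid, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write an ESRI ASCII grid; masked cells become ``nodata``."""
    out = np.where(grid.mask, nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


@dataclass
class OccurrenceSet:
    """Occurrence records of one species (longitude/latitude or map units)."""

    species: str
    points: np.ndarray  # (n, 2) array of (x, y)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return len(self.points)

    def cell_indices(self, grid: RasterGrid) -> np.ndarray:
        """(row, col) per point, dropping points off-grid or on nodata.

        The number of dropped points is logged, as these records carry no
        usable environmental information.
        """
        row, col = grid.point_to_cell(self.points[:, 0], self.points[:, 1])
        ok = row >= 0
        inside = np.flatnonzero(ok)
        keep = inside[~grid.mask[row[inside], col[inside]]]
        n_dropped = len(self.points) - len(keep)
        if n_dropped:
            logger.warning(
                "%s: %d of %d occurrence points off-grid or on nodata; excluded",
                self.species, n_dropped, len(self.points),
            )
        return np.column_stack([row[keep], col[keep]])


def read_occurrences_csv(path) -> list[OccurrenceSet]:
    """Read a ``species,longitude,latitude`` CSV into per-species sets."""
    df = pd.read_csv(path, dtype={"species": str})
    required = ["species", "longitude", "latitude"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GridFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("longitude", "latitude"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 0-based indexing
            line = int(bad.idxmax()) + 2
            raise GridFormatError(
                f"{path}: non-numeric {col} {df[col][bad].iloc[0]!r} on line {line}"
            )
        df[col] = coerced
    sets = []
    for species in df["species"].drop_duplicates():
        sub = df[df["species"] == species]
        sets.append(OccurrenceSet(species=species,
                                  points=sub[["longitude", "latitude"]].to_numpy()))
    return sets


def write_occurrences_csv(sets: Iterable[OccurrenceSet], path) -> None:
    frames = [
        pd.DataFrame({
            "species": s.species,
            "longitude": s.points[:, 0],
            "latitude": s.points[:, 1],
        })
        for s in sets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


class EnvStack:
    """Named, group-labelled collection of aligned covariate layers.

    Parameters
    ----------
    layers
        Ordered mapping name -> RasterGrid; all layers must share geometry.
    groups
        Mapping name -> one of ``climate | soil | terrain | anthropogenic``.
    """

    def __init__(self, layers: Mapping[str, RasterGrid], groups: Mapping[str, str]):
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        self.layers: dict[str, RasterGrid] = dict(layers)
        ref = next(iter(self.layers.values()))
        for name, grid in self.layers.items():
            if not grid.same_geometry(ref):
                raise AlignmentError(f"layer {name!r} not aligned with {ref.name!r}")
        unknown = {g for g in groups.values()} - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        missing = set(self.layers) - set(groups)
        if missing:
            raise ValueError(f"layers without group label: {sorted(missing)}")
        self.groups: dict[str, str] = {n: groups[n] for n in self.layers}
        self._pixel_table: pd.DataFrame | None = None

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    @property
    def mask(self) -> np.ndarray:
        """Union nodata: masked anywhere -> masked in the pixel table."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for grid in self.layers.values():
            m |= grid.mask
        return m

    @property
    def pixel_table(self) -> pd.DataFrame:
        """Covariate table of jointly unmasked pixels.

        The index is the flat cell id (row * ncols + col) so rows can be
        mapped back onto the grid.
        """
        if self._pixel_table is None:
            keep = ~self.mask
            flat = np.flatnonzero(keep.ravel())
            data = {n: g.values.ravel()[flat] for n, g in self.layers.items()}
            self._pixel_table = pd.DataFrame(data, index=flat)
        return self._pixel_table

    def group_members(self, group: str) -> list[str]:
        return [n for n, g in self.groups.items() if g == group]

    def subset(self, names: Sequence[str]) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names},
                        {n: self.groups[n] for n in names})

    def cells_to_table(self, cells: np.ndarray) -> pd.DataFrame:
        """Covariate rows for (row, col) cells (e.g. presence cells)."""
        r, c = cells[:, 0], cells[:, 1]
        return pd.DataFrame({n: g.values[r, c] for n, g in self.layers.items()})

    def grid_from_flat(self, flat_ids: np.ndarray, values: np.ndarray,
                       name: str = "") -> RasterGrid:
        """Scatter per-pixel-table values back onto the grid geometry."""
        out = np.full(self.grid.shape, np.nan).ravel()
        out[flat_ids] = values
        out = out.reshape(self.grid.shape)
        return self.grid.with_values(out, name=name, mask=~np.isfinite(out))


def align_stack(layers: Mapping[str, RasterGrid], target: RasterGrid,
                groups: Mapping[str, str], method: str = "nearest") -> EnvStack:
    """Resample layers onto ``target``'s geometry by nearest neighbour.

    Each target cell centre is mapped into the source grid; the nearest
    source cell's value is assigned. Categorical layers (e.g. aspect
    classes) survive this unharmed, which is why only nearest is offered.
    """
    if method != "nearest":
        raise ValueError(f"unsupported resampling method {method!r}")
    out: dict[str, RasterGrid] = {}
    rows, cols = np.mgrid[0:target.nrows, 0:target.ncols]
    cx, cy = target.cell_center(rows.ravel(), cols.ravel())
    for name, src in layers.items():
        if src.same_geometry(target):
            out[name] = src.with_values(src.values.copy(), name=name)
            continue
        # nearest source cell of each target centre
        sc = np.clip(np.round((cx - src.origin_x) / src.cell_size - 0.5).astype(int),
                     0, src.ncols - 1)
        j = np.clip(np.round((cy - src.origin_y) / src.cell_size - 0.5).astype(int),
                    0, src.nrows - 1)
        sr = src.nrows - 1 - j
        # refuse grids that do not overlap the target at all
        x0, x1 = src.origin_x, src.origin_x + src.ncols * src.cell_size
        y0, y1 = src.origin_y, src.origin_y + src.nrows * src.cell_size
        if cx.max() < x0 or cx.min() > x1 or cy.max() < y0 or cy.min() > y1:
            raise AlignmentError(f"layer {name!r} extent disjoint from target")
        vals = src.values[sr, sc].reshape(target.shape)
        msk = src.mask[sr, sc].reshape(target.shape)
        out[name] = RasterGrid(values=np.where(msk, np.nan, vals), mask=msk,
                               origin_x=target.origin_x, origin_y=target.origin_y,
                               cell_size=target.cell_size, name=name)
    return EnvStack(out, groups)
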