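"""Core data containers: the observation matrix and its addressing.

The central object is :class:`CoreMatrix`, an M × N array whose columns are
serialized observations (spectra or real-space density maps) and whose rows
address a fixed measurement coordinate (a wavelength, or a voxel of a shared
grid).  Experimental conditions — time, temperature, pH, pump wavelength —
live in a :class:`MetadataTable` that is kept strictly apart from the matrix
values: the factorization only ever sees the core data, and the metadata is
used afterwards to interpret the per-observation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MetadataTable",
    "SpectralSeries",
    "MapGrid",
    "MapSeries",
    "CoreMatrix",
    "serialize_map",
    "deserialize_map",
    "assemble_matrix",
    "disassemble",
    "difference_series",
    "SERIAL_ORDERS",
]

#: Supported serialization orders for flattening a 3-D map into a row vector.
#: "first_axis_fastest" walks nx fastest (Fortran order); "last_axis_fastest"
#: walks nz fastest (C order).  Either is fine as long as it is applied
#: consistently and recorded, so every artifact carries the tag.
SERIAL_ORDERS = ("first_axis_fastest", "last_axis_fastest")

_ORDER_CHAR = {"first_axis_fastest": "F", "last_axis_fastest": "C"}


class DimensionalityError(ValueError):
    """Shapes of maps, grids, or masks are inconsistent."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable information."""


@dataclass
class MetadataTable:
    """Per-observation experimental conditions, one row per matrix column.

    Parameters are stored as named numeric vectors of common length N.
    At most one parameter may be designated the ordering axis (typically
    time) used when coefficients are plotted as trajectories.
    """

    table: pd.DataFrame
    ordering_axis: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(self.table)
        numeric = self.table.select_dtypes(include=[np.number])
        if not np.all(np.isfinite(numeric.to_numpy(dtype=float))) and numeric.size:
            raise ValueError("metadata parameter values must be finite")
        if self.ordering_axis is not None and self.ordering_axis not in self.table.columns:
            raise KeyError(f"ordering axis {self.ordering_axis!r} not a metadata parameter")

    @property
    def n_observations(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return [str(x) for x in self.table.index]

    def axis_values(self, name: str | None = None) -> np.ndarray:
        """Values of a metadata parameter (defaults to the ordering axis)."""
        name = name if name is not None else self.ordering_axis
        if name is None:
            raise KeyError("no ordering axis designated and no parameter named")
        return self.table[name].to_numpy(dtype=float)

    def take(self, indices) -> "MetadataTable":
        return MetadataTable(self.table.iloc[list(indices)].copy(), self.ordering_axis)


@dataclass
class SpectralSeries:
    """N absorption (or difference-absorption) spectra on one wavelength grid."""

    wavelengths: np.ndarray  # nm, strictly ascending, length M
    absorbance: np.ndarray  # M x N, AU
    metadata: MetadataTable

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if self.absorbance.ndim != 2:
            raise DimensionalityError("absorbance must be an M x N matrix")
        m, n = self.absorbance.shape
        if m != self.wavelengths.size:
            raise DimensionalityError("absorbance rows must match the wavelength grid")
        if m < 2 or n < 2:
            raise DegenerateInputError("need at least 2 wavelengths and 2 observations")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("missing/non-finite absorbance values are rejected, not imputed")
        if self.metadata.n_observations != n:
            raise DimensionalityError("one metadata row per observation is required")

    @property
    def n_observations(self) -> int:
        return self.absorbance.shape[1]


@dataclass(frozen=True)
class MapGrid:
    """Geometry of a real-space map: dimensions, voxel spacing, origin."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # Angstrom per voxel along each axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    serial_order: str = "first_axis_fastest"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(d < 1 for d in self.shape):
            raise DimensionalityError("grid must be 3-D with all dimensions >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.serial_order not in SERIAL_ORDERS:
            raise ValueError(f"serial_order must be one of {SERIAL_ORDERS}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def cell(self) -> tuple[float, float, float]:
        """Orthorhombic cell edge lengths implied by shape × spacing."""
        return tuple(d * s for d, s in zip(self.shape, self.spacing))


@dataclass
class MapSeries:
    """N density maps on one shared grid, optionally masked to a region."""

    grid: MapGrid
    maps: np.ndarray  # N x nx x ny x nz
    metadata: MetadataTable
    mask: np.ndarray | None = None  # boolean, grid shape

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4 or self.maps.shape[1:] != self.grid.shape:
            raise DimensionalityError("maps must be N x (grid shape)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("missing/non-finite density values are rejected")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise DimensionalityError("mask shape must match the grid")
            if not self.mask.any():
                raise DegenerateInputError("mask selects no voxels")
        if self.metadata.n_observations != self.maps.shape[0]:
            raise DimensionalityError("one metadata row per map is required")

    @property
    def n_observations(self) -> int:
        return self.maps.shape[0]


@dataclass
class RowAddressing:
    """How matrix rows map back to physical coordinates.

    Exactly one of ``wavelengths`` (spectral rows) or ``grid`` (voxel rows,
    with optional mask and recorded serialization order) is set, so every
    column can be erected back into its source spectrum or 3-D map.
    """

    wavelengths: np.ndarray | None = None
    grid: MapGrid | None = None
    mask: np.ndarray | None = None

    @property
    def kind(self) -> str:
        return "spectral" if self.wavelengths is not None else "map"


@dataclass
class CoreMatrix:
    """The M × N data matrix A together with its row addressing and metadata.

    Columns are observations in no particular order; the ``provenance`` note
    records whether they are raw data, differences against a reference
    column, or a low-rank reconstitution.
    """

    matrix: np.ndarray
    addressing: RowAddressing
    metadata: MetadataTable
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DimensionalityError("core matrix must be 2-D")
        if self.metadata.n_observations != self.matrix.shape[1]:
            raise DimensionalityError("one metadata row per column is required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def column(self, j: int) -> np.ndarray:
        return self.matrix[:, j]


def serialize_map(
    map3d: np.ndarray,
    grid: MapGrid,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Flatten a 3-D map into a 1-D density vector under the grid's order tag.

    If a mask is given only the selected voxels are kept (in serialization
    order).  The operation is exactly reversible via :func:`deserialize_map`
    given the same grid and mask.
    """
    map3d = np.asarray(map3d, dtype=float)
    if map3d.shape != grid.shape:
        raise DimensionalityError(f"map shape {map3d.shape} != grid shape {grid.shape}")
    order = _ORDER_CHAR[grid.serial_order]
    flat = map3d.ravel(order=order)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise DimensionalityError("mask shape must match the grid")
        sel = mask.ravel(order=order)
        if not sel.any():
            raise DegenerateInputError("mask selects no voxels")
        flat = flat[sel]
    return flat


def deserialize_map(
    vector: np.ndarray,
    grid: MapGrid,
    mask: np.ndarray | None = None,
    fill: float = 0.0,
) -> np.ndarray:
    """Erect a 3-D map from a serialized density vector (inverse of serialize).

    Voxels outside the mask, if any, are set to ``fill``.
    """
    vector = np.asarray(vector, dtype=float)
    order = _ORDER_CHAR[grid.serial_order]
    if mask is None:
        if vector.size != grid.n_voxels:
            raise DimensionalityError("vector length must equal the voxel count")
        return vector.reshape(grid.shape, order=order)
    mask = np.asarray(mask, dtype=bool)
    sel = mask.ravel(order=order)
    if vector.size != int(sel.sum()):
        raise DimensionalityError("vector length must equal the masked voxel count")
    flat = np.full(grid.n_voxels, fill, dtype=float)
    flat[sel] = vector
    return flat.reshape(grid.shape, order=order)


def assemble_matrix(series: SpectralSeries | MapSeries) -> CoreMatrix:
    """Fill the columns of the data matrix A from a spectral or map series."""
    if isinstance(series, SpectralSeries):
        addressing = RowAddressing(wavelengths=series.wavelengths.copy())
        return CoreMatrix(series.absorbance.copy(), addressing, series.metadata, "raw")
    if isinstance(series, MapSeries):
        cols = [serialize_map(m, series.grid, series.mask) for m in series.maps]
        addressing = RowAddressing(
            grid=series.grid,
            mask=None if series.mask is None else series.mask.copy(),
        )
        return CoreMatrix(np.column_stack(cols), addressing, series.metadata, "raw")
    raise TypeError(f"cannot assemble a core matrix from {type(series).__name__}")


def disassemble(matrix: CoreMatrix) -> SpectralSeries | MapSeries:
    """Reverse :func:`assemble_matrix`, reconstructing every observation."""
    addr = matrix.addressing
    if addr.kind == "spectral":
        return SpectralSeries(addr.wavelengths.copy(), matrix.matrix.copy(), matrix.metadata)
    maps = np.stack(
        [deserialize_map(matrix.matrix[:, j], addr.grid, addr.mask)
         for j in range(matrix.shape[1])]
    )
    return MapSeries(addr.grid, maps, matrix.metadata, mask=None if addr.mask is None else addr.mask.copy())


def difference_series(
    matrix: CoreMatrix,
    reference: int,
    scale: str = "none",
) -> CoreMatrix:
    """Subtract a reference column from every column of the matrix.

    With ``scale="lstsq"`` each column first determines a single scalar k by
    least squares (k = a_j·ref / ref·ref) so that the subtracted reference
    best matches that column; ``scale="none"`` subtracts the reference as-is.
    The reference column itself becomes exactly zero.
    """
    n = matrix.shape[1]
    if not -n <= reference < n:
        raise IndexError(f"reference column {reference} out of range for N={n}")
    reference = reference % n
    if scale not in ("none", "lstsq"):
        raise ValueError("scale must be 'none' or 'lstsq'")
    ref = matrix.matrix[:, reference]
    a = matrix.matrix
    if scale == "lstsq":
        denom = float(ref @ ref)
        if denom == 0.0:
            k = np.ones(n)
        else:
            k = (a.T @ ref) / denom
        out = a - np.outer(ref, k)
    else:
        out = a - ref[:, None]
    out[:, reference] = 0.0  # exact zero for the reference itself
    prov = f"difference vs column {reference} (scale={scale})"
    return CoreMatrix(out, matrix.addressing, matrix.metadata, prov)
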