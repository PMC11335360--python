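"""File input/output: spectra as delimited text, maps as CCP4/MRC, archives as HDF5.

Conventions
-----------
* Spectral series: CSV/TSV with the wavelength grid in the first column and
  one observation per remaining column; the per-observation metadata lives in
  a separate CSV keyed by observation label (column header).
* Map series: one CCP4/MRC file (mode-2 float) per observation, orthorhombic
  cell derived from grid shape × voxel spacing; a mask is a second map of
  0/1 values on the same grid.
* Core-matrix archive: a single HDF5 container with named datasets for the
  matrix, the row addressing (wavelengths or grid + mask + serialization
  order), the metadata table, and the provenance note, so an analysis can be
  replayed without the original source files.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import h5py
import numpy as np
import pandas as pd

from .core_data import (
    CoreMatrix,
    MapGrid,
    MapSeries,
    MetadataTable,
    RowAddressing,
    SpectralSeries,
)

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "read_map",
    "write_map",
    "read_map_series",
    "write_map_series",
    "save_core_matrix",
    "load_core_matrix",
    "save_basis",
    "load_basis",
    "export_components",
]


def write_spectra_csv(path, series: SpectralSeries, sep: str = ",") -> None:
    df = pd.DataFrame(series.absorbance, columns=series.metadata.labels)
    df.insert(0, "wavelength_nm", series.wavelengths)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_spectra_csv(path, metadata: MetadataTable | None = None, sep: str = ",") -> SpectralSeries:
    """Read a wavelength × observation table; first column is the grid."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    wavelengths = df.iloc[:, 0].to_numpy(dtype=float)
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    if metadata is None:
        metadata = MetadataTable(pd.DataFrame(index=list(df.columns[1:])))
    return SpectralSeries(wavelengths, data, metadata)


def write_metadata_csv(path, metadata: MetadataTable) -> None:
    df = metadata.table.copy()
    df.index.name = "label"
    header = f"# ordering_axis={metadata.ordering_axis or ''}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh)


def read_metadata_csv(path) -> MetadataTable:
    with open(path) as fh:
        first = fh.readline()
        ordering = None
        if first.startswith("# ordering_axis="):
            ordering = first.split("=", 1)[1].strip() or None
            df = pd.read_csv(fh, index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, index_col=0)
    return MetadataTable(df, ordering_axis=ordering)


def _grid_to_cell(grid: MapGrid) -> gemmi.UnitCell:
    a, b, c = grid.cell
    return gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0)


def write_map(path, map3d: np.ndarray, grid: MapGrid) -> None:
    """Write one 3-D density map as a CCP4 mode-2 (float32) file."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(map3d, dtype=np.float32))
    m.grid.unit_cell = _grid_to_cell(grid)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_map(path, serial_order: str = "first_axis_fastest") -> tuple[np.ndarray, MapGrid]:
    """Read a CCP4/MRC map; returns the density array and its grid geometry."""
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True).astype(float)
    cell = m.grid.unit_cell
    shape = arr.shape
    spacing = tuple(c / d for c, d in zip((cell.a, cell.b, cell.c), shape))
    grid = MapGrid(tuple(shape), spacing, serial_order=serial_order)
    return arr, grid


def write_map_series(directory, series: MapSeries, stem: str = "map") -> list[Path]:
    """Write every observation as <stem>_<j>.ccp4 plus the mask if present."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for j in range(series.n_observations):
        p = directory / f"{stem}_{j:04d}.ccp4"
        write_map(p, series.maps[j], series.grid)
        paths.append(p)
    if series.mask is not None:
        write_map(directory / f"{stem}_mask.ccp4", series.mask.astype(float), series.grid)
    return paths


def read_map_series(paths, metadata: MetadataTable, mask_path=None,
                    serial_order: str = "first_axis_fastest") -> MapSeries:
    maps, grid = [], None
    for p in paths:
        arr, g = read_map(p, serial_order)
        if grid is None:
            grid = g
        elif g.shape != grid.shape:
            raise ValueError(f"inconsistent grid in {p}: {g.shape} != {grid.shape}")
        maps.append(arr)
    mask = None
    if mask_path is not None:
        mask_arr, g = read_map(mask_path, serial_order)
        mask = mask_arr > 0.5
    return MapSeries(grid, np.stack(maps), metadata, mask=mask)


def save_core_matrix(path, matrix: CoreMatrix) -> None:
    """Archive a core matrix with addressing, metadata, and provenance in HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=matrix.matrix)
        f.attrs["provenance"] = matrix.provenance
        addr = matrix.addressing
        f.attrs["addressing_kind"] = addr.kind
        if addr.kind == "spectral":
            f.create_dataset("wavelengths", data=addr.wavelengths)
        else:
            g = addr.grid
            f.attrs["grid_shape"] = g.shape
            f.attrs["grid_spacing"] = g.spacing
            f.attrs["grid_origin"] = g.origin
            f.attrs["serial_order"] = g.serial_order
            if addr.mask is not None:
                f.create_dataset("mask", data=addr.mask.astype(np.uint8))
        _write_metadata(f, matrix.metadata)


def load_core_matrix(path) -> CoreMatrix:
    with h5py.File(path, "r") as f:
        mat = f["matrix"][...]
        prov = f.attrs["provenance"]
        kind = f.attrs["addressing_kind"]
        if kind == "spectral":
            addr = RowAddressing(wavelengths=f["wavelengths"][...])
        else:
            grid = MapGrid(
                tuple(int(x) for x in f.attrs["grid_shape"]),
                tuple(float(x) for x in f.attrs["grid_spacing"]),
                tuple(float(x) for x in f.attrs["grid_origin"]),
                str(f.attrs["serial_order"]),
            )
            mask = f["mask"][...].astype(bool) if "mask" in f else None
            addr = RowAddressing(grid=grid, mask=mask)
        meta = _read_metadata(f)
    return CoreMatrix(mat, addr, meta, str(prov))


def _write_addressing(f: h5py.File, addr: RowAddressing) -> None:
    f.attrs["addressing_kind"] = addr.kind if (addr.wavelengths is not None or addr.grid is not None) else "none"
    if addr.wavelengths is not None:
        f.create_dataset("wavelengths", data=addr.wavelengths)
    elif addr.grid is not None:
        g = addr.grid
        f.attrs["grid_shape"] = g.shape
        f.attrs["grid_spacing"] = g.spacing
        f.attrs["grid_origin"] = g.origin
        f.attrs["serial_order"] = g.serial_order
        if addr.mask is not None:
            f.create_dataset("mask", data=addr.mask.astype(np.uint8))


def _read_addressing(f: h5py.File) -> RowAddressing:
    kind = str(f.attrs.get("addressing_kind", "none"))
    if kind == "spectral":
        return RowAddressing(wavelengths=f["wavelengths"][...])
    if kind == "map":
        grid = MapGrid(
            tuple(int(x) for x in f.attrs["grid_shape"]),
            tuple(float(x) for x in f.attrs["grid_spacing"]),
            tuple(float(x) for x in f.attrs["grid_origin"]),
            str(f.attrs["serial_order"]),
        )
        mask = f["mask"][...].astype(bool) if "mask" in f else None
        return RowAddressing(grid=grid, mask=mask)
    return RowAddressing()


def _write_metadata(f: h5py.File, meta: MetadataTable) -> None:
    # to_dict yields native Python scalars, so json round-trips floats exactly
    # (pandas' own to_json truncates to at most 15 significant digits)
    d = meta.table.to_dict(orient="split")
    f.attrs["metadata_json"] = json.dumps(d)
    f.attrs["ordering_axis"] = meta.ordering_axis or ""


def _read_metadata(f: h5py.File) -> MetadataTable:
    d = json.loads(str(f.attrs["metadata_json"]))
    table = pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])
    ordering = str(f.attrs["ordering_axis"]) or None
    return MetadataTable(table, ordering_axis=ordering)


def save_basis(path, basis) -> None:
    """Archive a singular-triplet set or rotated basis in one HDF5 file."""
    from .rotation import RotatedBasis
    from .svd_engine import SingularTriplets

    with h5py.File(path, "w") as f:
        _write_addressing(f, basis.addressing)
        _write_metadata(f, basis.metadata)
        if isinstance(basis, SingularTriplets):
            f.attrs["basis_kind"] = "triplets"
            f.create_dataset("u", data=basis.u)
            f.create_dataset("w", data=basis.w)
            f.create_dataset("v", data=basis.v)
            f.attrs["rank"] = basis.rank
            f.attrs["sign_convention"] = basis.sign_convention
        elif isinstance(basis, RotatedBasis):
            f.attrs["basis_kind"] = "rotated"
            f.create_dataset("r", data=basis.r)
            f.create_dataset("f", data=basis.f)
            f.attrs["history_json"] = basis.history.to_json()
        else:
            raise TypeError(f"cannot archive {type(basis).__name__}")


def load_basis(path):
    from .rotation import RotatedBasis, RotationPlan
    from .svd_engine import SingularTriplets

    with h5py.File(path, "r") as f:
        addr = _read_addressing(f)
        meta = _read_metadata(f)
        kind = str(f.attrs["basis_kind"])
        if kind == "triplets":
            return SingularTriplets(f["u"][...], f["w"][...], f["v"][...],
                                    rank=int(f.attrs["rank"]), addressing=addr,
                                    metadata=meta,
                                    sign_convention=str(f.attrs["sign_convention"]))
        return RotatedBasis(f["r"][...], f["f"][...], addr, meta,
                            RotationPlan.from_json(str(f.attrs["history_json"])))


def export_components(directory, components: np.ndarray, addressing: RowAddressing,
                      stem: str = "component") -> list[Path]:
    """Export basis components as spectrum CSVs or CCP4 maps per the addressing."""
    from .core_data import deserialize_map

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    if addressing.kind == "spectral" and addressing.wavelengths is not None:
        df = pd.DataFrame(components,
                          columns=[f"{stem}_{k + 1}" for k in range(components.shape[1])])
        df.insert(0, "wavelength_nm", addressing.wavelengths)
        p = directory / f"{stem}s.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    elif addressing.grid is not None:
        for k in range(components.shape[1]):
            map3d = deserialize_map(components[:, k], addressing.grid, addressing.mask)
            p = directory / f"{stem}_{k + 1}.ccp4"
            write_map(p, map3d, addressing.grid)
            paths.append(p)
    else:
        p = directory / f"{stem}s.csv"
        pd.DataFrame(components).to_csv(p, index=False)
        paths.append(p)
    return paths
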