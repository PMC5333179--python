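"""Labeled voxel volumes with per-label optical and fluorescent materials.

A :class:`VoxelGrid` stores one 8-bit material label per voxel plus a table
mapping label -> :class:`OpticalMaterial`.  Label 0 is reserved for background
(vacuum by default, so rays traverse extracellular space unattenuated unless a
background material is assigned explicitly).  The grid exposes the per-voxel
total absorption ``mu_a = sigma_a_base + mu_a^f`` and extinction
``sigma_t = sigma_s + mu_a`` needed by the tracker, and a per-wavelength
majorant table for woodcock (null-collision) sampling.

Coordinate convention: the voxel ``(i, j, k)`` occupies the half-open box
``[origin + (i,j,k)*spacing, origin + (i+1,j+1,k+1)*spacing)``; world units
are micrometres, coefficients mm^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import DEFAULT_GRID, DyeSolution, Spectrum, WavelengthGrid

__all__ = [
    "OpticalMaterial",
    "VoxelGrid",
    "MajorantTable",
    "VACUUM",
    "water_baseline_material",
    "build_majorant",
    "total_absorption",
    "total_extinction",
    "read_volume",
    "write_volume",
]

#: micrometres per millimetre; coefficients are mm^-1, positions um
UM_PER_MM = 1000.0

#: default flat pure-water extinction baseline, mm^-1
WATER_EXTINCTION_MM = 1e-3


@dataclass
class OpticalMaterial:
    """Optical properties of one voxel label.

    sigma_s and sigma_a_base are spectra in mm^-1; ``g`` is the
    Henyey-Greenstein anisotropy; ``dye`` optionally adds the fluorescence
    absorption mu_a^f of a dye solution.
    """

    sigma_s: Spectrum
    sigma_a_base: Spectrum
    g: float = 0.9
    dye: DyeSolution | None = None

    def __post_init__(self):
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.sigma_s.grid.n != self.sigma_a_base.grid.n:
            raise ValueError("sigma_s and sigma_a_base must share a grid")

    @property
    def grid_wl(self) -> WavelengthGrid:
        return self.sigma_s.grid

    def mu_a_f(self) -> np.ndarray:
        if self.dye is None:
            return np.zeros(self.grid_wl.n)
        return self.dye.mu_a_f()

    def mu_a(self) -> np.ndarray:
        """Total absorption per wavelength bin: sigma_a_base + mu_a^f."""
        return self.sigma_a_base.values + self.mu_a_f()

    def sigma_t(self) -> np.ndarray:
        return self.sigma_s.values + self.mu_a()


def _vacuum(grid_wl: WavelengthGrid) -> OpticalMaterial:
    zero = Spectrum.constant(0.0, grid_wl)
    return OpticalMaterial(sigma_s=zero, sigma_a_base=zero, g=0.0, dye=None)


VACUUM = _vacuum(DEFAULT_GRID)


def water_baseline_material(multiplier: float,
                            baseline: Spectrum | float = WATER_EXTINCTION_MM,
                            scattering_fraction: float = 0.5,
                            g: float = 0.9,
                            grid_wl: WavelengthGrid = DEFAULT_GRID
                            ) -> OpticalMaterial:
    """Material whose extinction is ``multiplier`` times a pure-water baseline.

    The baseline is a flat constant by default (mm^-1) and can be overridden
    with a tabulated spectrum.  ``scattering_fraction`` splits the extinction
    between sigma_s and sigma_a_base.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if not 0.0 <= scattering_fraction <= 1.0:
        raise ValueError("scattering_fraction must lie in [0, 1]")
    if isinstance(baseline, Spectrum):
        ext = multiplier * baseline.values
        grid_wl = baseline.grid
    else:
        ext = np.full(grid_wl.n, multiplier * float(baseline))
    return OpticalMaterial(
        sigma_s=Spectrum(grid_wl, scattering_fraction * ext),
        sigma_a_base=Spectrum(grid_wl, (1.0 - scattering_fraction) * ext),
        g=g)


@dataclass
class MajorantTable:
    """Per-wavelength upper bound on sigma_t over all voxels."""

    grid_wl: WavelengthGrid
    mu_bar: np.ndarray

    def __call__(self, lam_index: int) -> float:
        return float(self.mu_bar[lam_index])


@dataclass
class VoxelGrid:
    """Labeled voxel volume: geometry + label array + material table."""

    labels: np.ndarray                       # (nx, ny, nz) uint8
    spacing: float                           # um, cubic voxels
    origin: np.ndarray = None                # um, corner of voxel (0,0,0)
    materials: dict = field(default_factory=dict)   # label -> OpticalMaterial
    grid_wl: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        present = set(np.unique(self.labels).tolist())
        missing = present - {0} - set(self.materials)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no material entry")
        if 0 not in self.materials:
            self.materials = {0: _vacuum(self.grid_wl), **self.materials}
        self._tables = None

    # -- derived geometry ---------------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent_min(self) -> np.ndarray:
        return self.origin

    @property
    def extent_max(self) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(self.dims)

    def voxel_at(self, point: np.ndarray) -> tuple[int, int, int] | None:
        """Voxel index containing a world point, or None if outside."""
        f = (np.asarray(point) - self.origin) / self.spacing
        idx = np.floor(f).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.dims)):
            return None
        return tuple(idx)

    # -- material coefficient tables ---------------------------------------
    def _build_tables(self):
        max_label = max(self.materials)
        n = self.grid_wl.n
        sig_t = np.zeros((max_label + 1, n))
        sig_s = np.zeros((max_label + 1, n))
        mu_a = np.zeros((max_label + 1, n))
        mu_af = np.zeros((max_label + 1, n))
        g = np.zeros(max_label + 1)
        for lab, mat in self.materials.items():
            mu_af[lab] = mat.mu_a_f()
            mu_a[lab] = mat.mu_a()
            sig_s[lab] = mat.sigma_s.values
            sig_t[lab] = sig_s[lab] + mu_a[lab]
            g[lab] = mat.g
        self._tables = dict(sigma_t=sig_t, sigma_s=sig_s, mu_a=mu_a,
                            mu_a_f=mu_af, g=g)

    @property
    def tables(self) -> dict:
        """Per-label coefficient arrays of shape (n_labels, n_lambda), mm^-1."""
        if self._tables is None:
            self._build_tables()
        return self._tables

    @property
    def is_homogeneous(self) -> bool:
        return len(np.unique(self.labels)) == 1

    def label_of(self, ijk) -> int:
        i, j, k = ijk
        nx, ny, nz = self.dims
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            raise IndexError(f"voxel index {ijk} outside grid {self.dims}")
        return int(self.labels[i, j, k])


def total_absorption(grid: VoxelGrid, voxel_index, lam: float) -> float:
    """mu_a(voxel, lambda) = sigma_a_base + mu_a^f, mm^-1."""
    lab = grid.label_of(voxel_index)
    return float(grid.tables["mu_a"][lab, grid.grid_wl.index(lam)])


def total_extinction(grid: VoxelGrid, voxel_index, lam: float) -> float:
    """sigma_t(voxel, lambda) = sigma_s + mu_a, mm^-1."""
    lab = grid.label_of(voxel_index)
    return float(grid.tables["sigma_t"][lab, grid.grid_wl.index(lam)])


def build_majorant(grid: VoxelGrid) -> MajorantTable:
    """Pointwise max of sigma_t over the material table, per wavelength."""
    present = np.unique(grid.labels)
    mu_bar = grid.tables["sigma_t"][present].max(axis=0)
    return MajorantTable(grid_wl=grid.grid_wl, mu_bar=mu_bar)


# -- raw + sidecar I/O ------------------------------------------------------

def write_volume(grid: VoxelGrid, path: str | Path,
                 nrrd_header: bool = False) -> None:
    """Write labels as little-endian uint8 raw + a JSON metadata sidecar.

    ``path`` is the raw-file path; the sidecar is ``path + '.json'``.  With
    ``nrrd_header=True`` a detached NRRD text header (.nhdr) referencing the
    raw file is written alongside.
    """
    path = Path(path)
    grid.labels.astype("<u1").tofile(path)
    meta = {
        "dims": list(grid.dims),
        "spacing_um": grid.spacing,
        "origin_um": grid.origin.tolist(),
        "dtype": "uint8",
        "order": "C",
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1))
    if nrrd_header:
        nx, ny, nz = grid.dims
        hdr = (
            "NRRD0004\n"
            "type: uint8\n"
            "dimension: 3\n"
            f"sizes: {nz} {ny} {nx}\n"
            f"spacings: {grid.spacing} {grid.spacing} {grid.spacing}\n"
            "encoding: raw\n"
            "endian: little\n"
            f"data file: {path.name}\n"
        )
        path.with_suffix(".nhdr").write_text(hdr)


def read_volume(path: str | Path, materials: dict | None = None,
                grid_wl: WavelengthGrid = DEFAULT_GRID) -> VoxelGrid:
    """Read a raw+sidecar volume written by :func:`write_volume`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    dims = tuple(meta["dims"])
    expected = dims[0] * dims[1] * dims[2]
    data = np.fromfile(path, dtype="<u1")
    if data.size != expected:
        raise ValueError(
            f"raw file has {data.size} bytes but dims {dims} imply {expected}")
    return VoxelGrid(labels=data.reshape(dims),
                     spacing=float(meta["spacing_um"]),
                     origin=np.asarray(meta["origin_um"], dtype=float),
                     materials=materials or {}, grid_wl=grid_wl)
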