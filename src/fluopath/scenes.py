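"""Standard validation scenes: homogeneous dye blocks under epifluorescence.

The emission-profile and excitation-scan validations render a homogeneous
16^3-voxel block of dye solution at 0.4 mol/L, illuminated by a monochromatic
diffuse panel and viewed from the same side (epi geometry).  At this
concentration the fluorescence absorption coefficient at the excitation peak
reaches 1.75/um (AF350) to 14.6/um (AF633), so the block is given
sub-wavelength voxel spacing (0.5 nm): the worst-case joint excitation plus
reabsorption optical depth across the block is then ~0.2 and the recorded
SPD stays in the optically thin regime, where it is proportional to the
emission spectrum.  Thicker blocks exhibit the physical inner-filter red
shift of the apparent emission peak.

The block material adds a flat, wavelength-independent scattering coefficient
so that camera paths interact at every emission wavelength (including those
outside the dye's reabsorption band); its value keeps the block at a fraction
of a scattering mean free path.  Fluorescence emission is treated as
isotropic here (g = 0).
"""

from __future__ import annotations

import numpy as np

from .render import Camera, LightSource, Scene
from .spectra import (DEFAULT_GRID, DyeSolution, Fluorophore, Spectrum,
                      dye_preset)
from .volume import OpticalMaterial, VoxelGrid, water_baseline_material

__all__ = ["dye_block_scene", "extinction_series_scene",
           "DYE_BLOCK_CONCENTRATION"]

#: dye concentration of the validation blocks, mol/L
DYE_BLOCK_CONCENTRATION = 0.4

#: voxel spacing of the validation blocks, um (sub-wavelength; see module doc)
DYE_BLOCK_SPACING_UM = 0.0005

#: flat scattering coefficient of the validation blocks, mm^-1
DYE_BLOCK_SIGMA_S = 20000.0

#: non-fluorescent background absorption, mm^-1
DYE_BLOCK_SIGMA_A = 0.01


def _epi_geometry(half_extent: float, resolution):
    """Camera and light placement above a block of given half extent."""
    cam_z = 12.0 * half_extent
    camera = Camera(position=(0.0, 0.0, cam_z), look_at=(0.0, 0.0, 0.0),
                    up=(0.0, 1.0, 0.0), vfov_deg=14.0, resolution=resolution)
    light_z = 7.0 * half_extent
    return camera, light_z


def dye_block_scene(dye: str | Fluorophore,
                    illumination_nm: float | None = None,
                    resolution=(32, 32), n_voxels: int = 16,
                    spacing_um: float = DYE_BLOCK_SPACING_UM,
                    concentration: float = DYE_BLOCK_CONCENTRATION,
                    sigma_s_mm: float = DYE_BLOCK_SIGMA_S,
                    g: float = 0.0) -> Scene:
    """Homogeneous dye block under monochromatic epi-illumination.

    ``illumination_nm`` defaults to the dye's excitation maximum.  Pass a
    Fluorophore for custom spectra, or a preset name ("AF488", ...).
    """
    fluo = dye_preset(dye) if isinstance(dye, str) else dye
    if illumination_nm is None:
        illumination_nm = fluo.lambda_x_peak
    grid_wl = fluo.f_x.grid
    half = 0.5 * n_voxels * spacing_um
    material = OpticalMaterial(
        sigma_s=Spectrum.constant(sigma_s_mm, grid_wl),
        sigma_a_base=Spectrum.constant(DYE_BLOCK_SIGMA_A, grid_wl),
        g=g,
        dye=DyeSolution(fluo, concentration))
    labels = np.ones((n_voxels,) * 3, dtype=np.uint8)
    grid = VoxelGrid(labels=labels, spacing=spacing_um,
                     origin=np.full(3, -half), materials={1: material},
                     grid_wl=grid_wl)
    camera, light_z = _epi_geometry(half, resolution)
    light = LightSource.monochromatic_panel(
        center=(0.0, 0.0, light_z), size=6.0 * half, normal=(0, 0, -1.0),
        lam=illumination_nm, grid=grid_wl)
    return Scene(camera, light, grid)


def extinction_series_scene(multiplier: float, dye: str = "AF488",
                            resolution=(32, 32), n_voxels: int = 16,
                            spacing_um: float = 250.0,
                            concentration: float = 1e-6) -> Scene:
    """Dilute dye block whose medium has ``multiplier`` times the pure-water
    extinction (the low/medium/high scattering triplet).

    The water-baseline medium carries the transport (half scattering, half
    absorption) and the dye is dilute.  The default block is millimetre
    scale, so the x10/x100/x1000 extinctions span the optically thin to
    optically thick range and the recorded brightness responds to the
    multiplier through attenuation (empirically: decreasing).
    """
    fluo = dye_preset(dye)
    base = water_baseline_material(multiplier, g=0.0)
    material = OpticalMaterial(
        sigma_s=base.sigma_s, sigma_a_base=base.sigma_a_base, g=0.0,
        dye=DyeSolution(fluo, concentration))
    half = 0.5 * n_voxels * spacing_um
    labels = np.ones((n_voxels,) * 3, dtype=np.uint8)
    grid = VoxelGrid(labels=labels, spacing=spacing_um,
                     origin=np.full(3, -half), materials={1: material},
                     grid_wl=base.grid_wl)
    camera, light_z = _epi_geometry(half, resolution)
    light = LightSource.monochromatic_panel(
        center=(0.0, 0.0, light_z), size=6.0 * half, normal=(0, 0, -1.0),
        lam=fluo.lambda_x_peak, grid=base.grid_wl)
    return Scene(camera, light, grid)
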