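import numpy as np
import pytest

from fluopath.spectra import DEFAULT_GRID, DyeSolution, dye_preset
from fluopath.volume import OpticalMaterial, Spectrum, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def af488():
    return dye_preset("AF488")


@pytest.fixture(scope="session")
def all_presets():
    return {name: dye_preset(name)
            for name in ("AF350", "AF488", "AF568", "AF633")}


def make_material(sigma_s=0.0, sigma_a=0.0, g=0.0, dye=None,
                  concentration=0.0):
    grid_wl = DEFAULT_GRID
    return OpticalMaterial(
        sigma_s=Spectrum.constant(sigma_s, grid_wl),
        sigma_a_base=Spectrum.constant(sigma_a, grid_wl),
        g=g,
        dye=DyeSolution(dye, concentration) if dye is not None else None)


def homogeneous_grid(n=8, spacing=1.0, origin=(0.0, 0.0, 0.0), **mat_kwargs):
    """Cubic single-material grid (label 1 everywhere)."""
    labels = np.ones((n, n, n), dtype=np.uint8)
    return VoxelGrid(labels=labels, spacing=spacing,
                     origin=np.asarray(origin, float),
                     materials={1: make_material(**mat_kwargs)})
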