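import math

import numpy as np
import pytest
from scipy import integrate, stats

from conftest import homogeneous_grid, make_material
from fluopath.render import (Camera, LightSource, RenderConfig, Scene,
                             _BareScene, _propagate_batch,
                             _ratio_tracking_batch, _trace_batch,
                             classify_event, direct_light_at_emission,
                             phase_eval, phase_sample, render,
                             sample_free_path_woodcock, spectral_to_rgb,
                             trace_path, transmittance)
from fluopath.scenes import dye_block_scene, extinction_series_scene
from fluopath.spectra import (DEFAULT_GRID, DyeSolution,
                              make_gaussian_fluorophore)
from fluopath.volume import MajorantTable, VoxelGrid, build_majorant

MM = 1e-3   # mm^-1 -> um^-1


def slab_grid(labels_1d, materials, spacing=1.0, width=5):
    """Grid whose material varies along x only (ray tests run along +x)."""
    nx = len(labels_1d)
    labels = np.tile(np.asarray(labels_1d, np.uint8)[:, None, None],
                     (1, width, width))
    return VoxelGrid(labels=labels, spacing=spacing, materials=materials)


class TestWoodcock:
    def test_vacuum_grid_always_escapes(self, rng):
        grid = VoxelGrid(labels=np.zeros((8, 8, 8), np.uint8), spacing=1.0,
                         materials={})
        m = build_majorant(grid)
        for _ in range(10):
            assert sample_free_path_woodcock(
                grid, m, (-5.0, 4.0, 4.0), (1.0, 0.0, 0.0), 500.0, rng) \
                is None

    def test_scalar_sampler_returns_points_inside_grid(self, rng):
        grid = homogeneous_grid(n=10, sigma_s=500.0)
        m = build_majorant(grid)
        hits = 0
        for _ in range(200):
            p = sample_free_path_woodcock(grid, m, (-5.0, 5.0, 5.0),
                                          (1.0, 0.0, 0.0), 500.0, rng)
            if p is not None:
                hits += 1
                assert 0.0 <= p[0] <= 10.0
        assert hits > 150     # optical depth 5: most paths collide

    def test_zero_majorant_over_nonzero_medium_rejected(self, rng):
        grid = homogeneous_grid(n=4, sigma_s=10.0)
        bad = MajorantTable(grid.grid_wl, np.zeros(grid.grid_wl.n))
        with pytest.raises(ValueError, match="majorant"):
            sample_free_path_woodcock(grid, bad, (-1.0, 2.0, 2.0),
                                      (1.0, 0.0, 0.0), 500.0, rng)

    def test_homogeneous_free_path_is_exponential(self, rng):
        # sigma_t = 1/um along the ray; an off-ray material with 3x the
        # extinction inflates the majorant so null collisions are exercised
        mats = {1: make_material(sigma_s=1000.0),
                2: make_material(sigma_s=3000.0)}
        labels = np.ones((10, 10, 10), np.uint8)
        labels[9, 9, 9] = 2
        grid = VoxelGrid(labels=labels, spacing=1.0, materials=mats)
        scene = _BareScene(grid)
        assert scene.mu_bar[grid.grid_wl.index(500.0)] == pytest.approx(
            3000.0 * MM)
        n = 100_000
        pos = np.tile([-5.0, 0.55, 0.55], (n, 1))
        dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
        li = np.full(n, grid.grid_wl.index(500.0))
        coll, p, _ = _propagate_batch(scene, pos, dirs, li, rng)
        depths = p[coll][:, 0]          # entry plane is x = 0
        sig, L = 1.0, 10.0

        def cdf(t):
            return (1 - np.exp(-sig * t)) / (1 - np.exp(-sig * L))

        assert stats.kstest(depths, cdf).pvalue > 0.01

    def test_two_slab_collision_depths_follow_piecewise_law(self, rng):
        mats = {1: make_material(sigma_s=500.0),
                2: make_material(sigma_s=2000.0)}
        grid = slab_grid([1] * 5 + [2] * 5, mats)
        scene = _BareScene(grid)
        n = 100_000
        pos = np.tile([-3.0, 2.5, 2.5], (n, 1))
        dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
        li = np.full(n, grid.grid_wl.index(500.0))
        coll, p, _ = _propagate_batch(scene, pos, dirs, li, rng)
        depths = p[coll][:, 0]
        s1, s2, d1, L = 0.5, 2.0, 5.0, 10.0
        total = 1 - math.exp(-s1 * d1 - s2 * (L - d1))

        def cdf(t):
            t = np.asarray(t)
            f = np.where(t < d1, 1 - np.exp(-s1 * t),
                         1 - np.exp(-s1 * d1 - s2 * (np.maximum(t, d1) - d1)))
            return f / total

        assert stats.kstest(depths, cdf).pvalue > 0.01


class TestClassifyEvent:
    def test_dyeless_material_never_fluoresces(self, rng):
        mat = make_material(sigma_s=0.5, sigma_a=0.5)
        events = {classify_event(mat, 500.0, rng) for _ in range(500)}
        assert "fluorescence" not in events

    def test_pure_fluorescent_absorber_always_fluoresces(self, rng, af488):
        mat = make_material(sigma_s=0.0, sigma_a=0.0, dye=af488,
                            concentration=0.4)
        events = {classify_event(mat, 495.0, rng) for _ in range(200)}
        assert events == {"fluorescence"}

    def test_branch_frequencies_match_probabilities(self, rng, af488):
        # sigma_s/sigma_t = 0.7 and mu_a^f/mu_a = 0.5 at 495 nm
        c = 0.15 * 10.0 / (math.log(10.0) * 73000.0)
        mat = make_material(sigma_s=0.7, sigma_a=0.15, dye=af488,
                            concentration=c)
        assert mat.mu_a_f()[DEFAULT_GRID.index(495)] == pytest.approx(0.15)
        n = 100_000
        counts = {"elastic_scatter": 0, "fluorescence": 0,
                  "absorb_terminate": 0}
        for _ in range(n):
            counts[classify_event(mat, 495.0, rng)] += 1
        for name, p in (("elastic_scatter", 0.7), ("fluorescence", 0.15),
                        ("absorb_terminate", 0.15)):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[name] / n - p) < 3 * se

    def test_collision_in_vacuum_rejected(self, rng):
        with pytest.raises(ValueError):
            classify_event(make_material(), 500.0, rng)


class TestPhaseFunction:
    def test_isotropic_density_is_quarter_pi(self):
        assert phase_eval(0.0, 0.3) == pytest.approx(1 / (4 * math.pi))
        assert phase_eval(0.0, -0.9) == pytest.approx(1 / (4 * math.pi))

    @pytest.mark.parametrize("g", [-0.5, 0.0, 0.3, 0.9])
    def test_normalization_by_quadrature(self, g):
        val, _ = integrate.quad(
            lambda c: 2 * math.pi * phase_eval(g, c), -1.0, 1.0,
            epsabs=1e-10)
        assert abs(val - 1.0) < 1e-6

    def test_mean_cosine_equals_g(self, rng):
        g = 0.9
        n = 100_000
        cosines = np.array([phase_sample(g, rng)[2] for _ in range(2000)])
        # large-sample check through the inverse-CDF formula directly
        from fluopath.render import _hg_cos
        big = _hg_cos(g, rng.random(n))
        se = big.std() / math.sqrt(n)
        assert abs(big.mean() - g) < 3 * se
        assert abs(cosines.mean() - g) < 3 * cosines.std() / math.sqrt(2000)

    def test_invalid_anisotropy_rejected(self, rng):
        with pytest.raises(ValueError):
            phase_eval(1.0, 0.5)
        with pytest.raises(ValueError):
            phase_sample(-1.0, rng)


class TestTransmittance:
    def test_vacuum_is_unity(self):
        grid = VoxelGrid(labels=np.zeros((4, 4, 4), np.uint8), spacing=1.0,
                         materials={})
        assert transmittance(grid, (-1, 2, 2), (5, 2, 2), 500.0) == 1.0

    def test_homogeneous_closed_form(self):
        # sigma_t = 1 mm^-1 over a 1 mm chord
        grid = homogeneous_grid(n=10, spacing=100.0, sigma_s=0.6,
                                sigma_a=0.4)
        tau = transmittance(grid, (-100, 500, 500), (1100, 500, 500), 500.0)
        assert tau == pytest.approx(math.exp(-1.0))

    def test_ratio_tracking_mean_matches_beer_lambert(self, rng):
        # heterogeneous in label only (uniform sigma_t), majorant inflated
        mats = {1: make_material(sigma_s=1.0), 2: make_material(sigma_s=2.0)}
        grid = slab_grid([1] * 10, mats, spacing=100.0, width=10)
        grid.labels[0, 0, 0] = 2            # inflates the majorant to 2
        grid._tables = None
        scene = _BareScene(grid)
        n = 100_000
        a = np.tile([-50.0, 550.0, 550.0], (n, 1))
        b = np.tile([1050.0, 550.0, 550.0], (n, 1))
        li = np.full(n, grid.grid_wl.index(500.0))
        tau = _ratio_tracking_batch(scene, a, b, li, rng)
        assert abs(tau.mean() - math.exp(-1.0)) / math.exp(-1.0) < 0.005

    def test_opaque_occluder_blocks(self, rng):
        mats = {1: make_material(sigma_s=0.001),
                2: make_material(sigma_s=50000.0)}
        grid = slab_grid([1, 1, 2, 2, 1, 1], mats, spacing=5.0, width=6)
        tau = transmittance(grid, (-1, 15, 15), (31, 15, 15), 500.0, rng)
        assert tau < 1e-6


class TestDirectLight:
    def _vacuum_grid(self):
        return VoxelGrid(labels=np.zeros((4, 4, 4), np.uint8), spacing=1.0,
                         materials={})

    def test_inverse_square_falloff(self, rng):
        grid = self._vacuum_grid()
        light = LightSource.monochromatic_panel(
            center=(2, 2, 100.0), size=0.1, normal=(0, 0, -1), lam=495.0)
        near = direct_light_at_emission((2.0, 2.0, 50.0), light, 495.0,
                                        grid, rng)
        far = direct_light_at_emission((2.0, 2.0, 0.0), light, 495.0,
                                       grid, rng)
        assert near / far == pytest.approx((100.0 / 50.0) ** 2, rel=0.01)

    def test_fully_occluded_gives_zero(self, rng):
        mats = {1: make_material(sigma_s=100000.0)}
        labels = np.zeros((8, 8, 8), np.uint8)
        labels[:, :, 4] = 1          # opaque wall at z in [4, 5)
        grid = VoxelGrid(labels=labels, spacing=1.0, materials=mats)
        light = LightSource.monochromatic_panel(
            center=(4, 4, 20.0), size=1.0, normal=(0, 0, -1), lam=495.0)
        got = direct_light_at_emission((4.0, 4.0, 1.0), light, 495.0,
                                       grid, rng)
        assert got == 0.0

    def test_homogeneous_attenuation_factor(self, rng):
        grid = homogeneous_grid(n=10, spacing=100.0, sigma_s=1.0)  # 1 mm^-1
        light = LightSource.monochromatic_panel(
            center=(500, 500, 2000.0), size=0.5, normal=(0, 0, -1),
            lam=495.0)
        # event at the bottom of the grid: the light path crosses 1 mm
        inside = direct_light_at_emission((500.0, 500.0, 0.0), light, 495.0,
                                          grid, rng)
        vac = direct_light_at_emission((500.0, 500.0, 0.0), light, 495.0,
                                       self._vacuum_grid(), rng)
        # vacuum grid has different geometry shadowing nothing; compare the
        # attenuation ratio analytically instead
        assert inside / vac == pytest.approx(math.exp(-1.0), rel=1e-6)


class TestEstimator:
    def test_dye_free_scene_renders_identically_zero(self):
        scene = dye_block_scene("AF488", concentration=0.0,
                                resolution=(8, 8))
        img = render(scene, RenderConfig(spp=4, spectral_samples=4, seed=0))
        assert np.all(img.values == 0.0)

    def test_out_of_band_illumination_renders_identically_zero(self):
        scene = dye_block_scene("AF488", illumination_nm=700.0,
                                resolution=(8, 8))
        img = render(scene, RenderConfig(spp=4, spectral_samples=4, seed=0))
        assert np.all(img.values == 0.0)

    def test_same_seed_is_bit_identical(self):
        cfg = RenderConfig(spp=8, spectral_samples=8, seed=42)
        a = render(dye_block_scene("AF488", resolution=(8, 8)), cfg)
        b = render(dye_block_scene("AF488", resolution=(8, 8)), cfg)
        assert np.array_equal(a.values, b.values)

    def test_stokes_zero_below_source_line_for_disjoint_bands(self):
        fluo = make_gaussian_fluorophore("toy", 400.0, 600.0, 30.0, 30.0,
                                         0.9, 73000.0, 500.0)
        scene = dye_block_scene(fluo, resolution=(8, 8))
        img = render(scene, RenderConfig(spp=8, spectral_samples=16, seed=1))
        assert img.values.sum() > 0
        cut = scene.grid_wl.index(520.0)   # well below the emission band
        assert np.all(img.values[:, :, :cut] == 0.0)

    def test_single_inelastic_event_per_path(self, rng):
        scene = dye_block_scene("AF633", resolution=(4, 4))
        cfg = RenderConfig(spp=1, spectral_samples=1, seed=0,
                           method="analog")
        n = 2000
        li = np.full(n, scene.grid_wl.index(647.0))
        pos = np.tile(scene.camera.position, (n, 1))
        dirs = scene.camera.rays(rng.integers(0, 4, n).astype(float),
                                 rng.integers(0, 4, n).astype(float),
                                 rng.random(n), rng.random(n))
        instrument = {"fluor_events": np.zeros(n)}
        _trace_batch(scene, cfg, pos, dirs, li, rng,
                     lambda p, l, v: None, np.arange(n),
                     instrument=instrument)
        assert instrument["fluor_events"].max() <= 1

    def test_analog_and_nee_agree_on_overlapping_bands(self):
        def total(method, seed):
            cfg = RenderConfig(spp=16, spectral_samples=16, seed=seed,
                               method=method)
            img = render(dye_block_scene("AF633", resolution=(8, 8)), cfg)
            return img.values.sum()

        nee = np.array([total("nee", s) for s in range(4)])
        ana = np.array([total("analog", s) for s in range(4)])
        se = math.sqrt(nee.var(ddof=1) / 4 + ana.var(ddof=1) / 4)
        assert abs(nee.mean() - ana.mean()) < 3 * se

    def test_trace_path_zero_when_no_dye(self, rng):
        scene = dye_block_scene("AF488", concentration=0.0,
                                resolution=(4, 4))
        cfg = RenderConfig(spp=1, spectral_samples=1)
        assert trace_path((2, 2), 519.0, scene, cfg, rng) == 0.0

    def test_invalid_sampling_config_rejected(self):
        with pytest.raises(ValueError):
            RenderConfig(spp=0)
        with pytest.raises(ValueError):
            RenderConfig(method="bidirectional")

    def test_brightness_ordered_across_extinction_triplet(self):
        totals = []
        for mult in (10.0, 100.0, 1000.0):
            scene = extinction_series_scene(mult, resolution=(8, 8))
            img = render(scene, RenderConfig(spp=16, spectral_samples=32,
                                             seed=2))
            totals.append(img.values.sum())
        assert totals == sorted(totals) or totals == sorted(totals,
                                                            reverse=True)


class TestRgbConversion:
    def _image(self, lam=None):
        from fluopath.render import SpectralImage
        img = SpectralImage((4, 4), DEFAULT_GRID)
        if lam is not None:
            img.values[:, :, DEFAULT_GRID.index(lam)] = 1.0
        return img

    def test_all_zero_image_is_black(self):
        rgb = spectral_to_rgb(self._image(), exposure=1.0)
        assert np.all(rgb == 0.0)

    def test_monochromatic_550nm_is_green_dominant(self):
        rgb = spectral_to_rgb(self._image(550.0))
        assert np.all(rgb[:, :, 1] >= rgb[:, :, 0])
        assert np.all(rgb[:, :, 1] >= rgb[:, :, 2])

    def test_flat_spectrum_is_roughly_neutral(self):
        from fluopath.render import SpectralImage
        img = SpectralImage((2, 2), DEFAULT_GRID)
        img.values[:] = 1.0
        rgb = spectral_to_rgb(img)
        lin = rgb[0, 0]
        assert lin.max() > 0
        assert lin.max() / max(lin.min(), 1e-9) < 1.5

    def test_monotone_in_radiance(self):
        img = self._image(550.0)
        bright = spectral_to_rgb(img, exposure=1.0)
        img.values *= 0.25
        dim = spectral_to_rgb(img, exposure=1.0)
        assert np.all(bright[:, :, 1] >= dim[:, :, 1])
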