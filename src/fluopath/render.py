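"""Spectral Monte Carlo path tracing of fluorescent participating media.

The renderer estimates the camera-side path integral of a fluorescent volume:
rays leave the camera at an emission wavelength ``lambda_m``, undergo
woodcock-tracked free flights and Henyey-Greenstein elastic scattering, and a
path contributes only if it contains exactly one inelastic (fluorescence)
vertex, where the wavelength maps back to an excitation wavelength
``lambda_x`` and the light source is sampled directly (next-event
estimation).  The fluorescence vertex couples the walk to the source through
the photon absorption probability ``p_x(lambda_x) = phi mu_a^f/mu_a`` and
the emission probability mass ``p_m(lambda_m)``.

Two estimators are provided.  The default (``method="nee"``) gathers the
fluorescence source term at *every* real collision with the collision
estimator (contribution ``epsilon/sigma_t``) and continues the walk
elastically with probability ``sigma_s/sigma_t``; this is unbiased and keeps
the variance bounded even when the excitation and emission bands barely
overlap.  The analog mode (``method="analog"``) instead classifies each
collision stochastically (elastic / fluorescent / terminal absorption, the
event taxonomy of the model) and terminates at the single fluorescence
vertex; it is unbiased only where the dye's excitation spectrum is nonzero
across the emission band and its variance grows as ``1/f_x(lambda_m)``.
Both agree in expectation on overlapping-band dyes.

Positions are micrometres; coefficient tables are converted to um^-1 once
per scene.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra import Spectrum, WavelengthGrid, emission_pdf
from .volume import MajorantTable, VoxelGrid, build_majorant

__all__ = [
    "Camera",
    "LightSource",
    "PathState",
    "RenderConfig",
    "Scene",
    "SpectralImage",
    "phase_eval",
    "phase_sample",
    "sample_free_path_woodcock",
    "classify_event",
    "transmittance",
    "direct_light_at_emission",
    "trace_path",
    "render",
    "spectral_to_rgb",
]

MM_PER_UM = 1e-3   # coefficients are stored in mm^-1; engine works in um


def _unit(v):
    return v / np.linalg.norm(v)


@dataclass
class Camera:
    """Pinhole camera; film plane holds the x_0 sample locations."""

    position: np.ndarray
    look_at: np.ndarray
    up: np.ndarray = (0.0, 1.0, 0.0)
    vfov_deg: float = 40.0
    resolution: tuple = (32, 32)       # (width, height) pixels

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        self.look_at = np.asarray(self.look_at, float)
        self.up = np.asarray(self.up, float)
        if self.vfov_deg <= 0 or self.vfov_deg >= 180:
            raise ValueError("vertical field of view must be in (0, 180)")
        w, h = self.resolution
        if w < 1 or h < 1:
            raise ValueError("film resolution must be positive")

    def rays(self, px, py, jitter_x, jitter_y):
        """Directions through film positions (px + jx, py + jy), vectorized."""
        w, h = self.resolution
        fwd = _unit(self.look_at - self.position)
        right = _unit(np.cross(fwd, self.up))
        up = np.cross(right, fwd)
        tan_half = math.tan(math.radians(self.vfov_deg) / 2.0)
        aspect = w / h
        sx = ((px + jitter_x) / w * 2.0 - 1.0) * tan_half * aspect
        sy = (1.0 - (py + jitter_y) / h * 2.0) * tan_half
        d = (fwd[None, :] + sx[:, None] * right[None, :]
             + sy[:, None] * up[None, :])
        return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class LightSource:
    """Rectangular diffuse panel with a spectral (or monochromatic) emission.

    The panel spans ``corner + s*edge_u + t*edge_v`` for s, t in [0, 1] and
    emits from the face whose normal is ``cross(edge_u, edge_v)``.
    """

    corner: np.ndarray
    edge_u: np.ndarray
    edge_v: np.ndarray
    emission: Spectrum

    def __post_init__(self):
        self.corner = np.asarray(self.corner, float)
        self.edge_u = np.asarray(self.edge_u, float)
        self.edge_v = np.asarray(self.edge_v, float)
        n = np.cross(self.edge_u, self.edge_v)
        self.area = float(np.linalg.norm(n))
        if self.area <= 0:
            raise ValueError("light panel must have positive area")
        self.normal = n / self.area

    @classmethod
    def monochromatic_panel(cls, center, size, normal, lam, radiance=1.0,
                            grid: WavelengthGrid | None = None
                            ) -> "LightSource":
        """Square panel emitting a single wavelength line toward ``normal``."""
        from .spectra import DEFAULT_GRID
        grid = grid or DEFAULT_GRID
        normal = _unit(np.asarray(normal, float))
        a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else \
            np.array([0.0, 1.0, 0.0])
        u = _unit(np.cross(normal, a)) * size
        v = np.cross(normal, _unit(u)) * size
        # order edges so cross(u, v) points along +normal
        if np.cross(u, v) @ normal < 0:
            u, v = v, u
        corner = np.asarray(center, float) - 0.5 * u - 0.5 * v
        return cls(corner=corner, edge_u=u, edge_v=v,
                   emission=Spectrum.line(lam, radiance, grid))

    @property
    def line_index(self) -> int | None:
        """Grid index of a monochromatic line, or None for broadband."""
        nz = np.nonzero(self.emission.values)[0]
        return int(nz[0]) if len(nz) == 1 else None


@dataclass
class PathState:
    """Instrumented state of a single camera-side walk."""

    vertices: list
    direction: np.ndarray
    lambda_index: int
    throughput: float = 1.0
    fluorescence_visibility: bool = False
    bounces: int = 0
    wavelength_changes: int = 0


@dataclass
class RenderConfig:
    """Sampling parameters of one render.

    The estimator averages a double sum: ``spectral_samples`` emission
    wavelengths per pixel (stratified over the dye-informed sampling pdf),
    each traced with ``spp`` paths, for ``spp * spectral_samples`` paths per
    pixel in total.
    """

    spp: int = 64                    # paths per spectral sample (N)
    spectral_samples: int = 64       # emission wavelengths per pixel (N_lambda)
    max_bounces: int = 32
    seed: int = 0
    rr_start_depth: int = 1 << 30    # Russian roulette off by default
    rr_survival: float = 0.8
    method: str = "nee"              # "nee" | "analog"
    pixel_jitter: bool = True
    max_batch: int = 1 << 20         # paths traced per vectorized batch

    def __post_init__(self):
        if self.spp < 1 or self.spectral_samples < 1 or self.max_bounces < 1:
            raise ValueError("sampling parameters must be positive")
        if not 0.0 < self.rr_survival <= 1.0:
            raise ValueError("rr_survival must lie in (0, 1]")
        if self.method not in ("nee", "analog"):
            raise ValueError("method must be 'nee' or 'analog'")

    @property
    def paths_per_pixel(self) -> int:
        return self.spp * self.spectral_samples


class Scene:
    """Camera + light + annotated voxel grid, with cached engine tables."""

    def __init__(self, camera: Camera, light: LightSource, grid: VoxelGrid):
        self.camera = camera
        self.light = light
        self.grid = grid
        self.majorant: MajorantTable = build_majorant(grid)
        t = grid.tables
        # engine tables in um^-1
        self.sigma_t = t["sigma_t"] * MM_PER_UM
        self.sigma_s = t["sigma_s"] * MM_PER_UM
        self.mu_a = t["mu_a"] * MM_PER_UM
        self.mu_a_f = t["mu_a_f"] * MM_PER_UM
        self.g = t["g"]
        self.mu_bar = self.majorant.mu_bar * MM_PER_UM
        n_lab, n_lam = self.sigma_t.shape
        self.phi = np.zeros(n_lab)
        self.p_m = np.zeros((n_lab, n_lam))
        for lab, mat in grid.materials.items():
            if mat.dye is not None and mat.dye.concentration > 0:
                self.phi[lab] = mat.dye.fluorophore.phi
                self.p_m[lab] = emission_pdf(mat.dye.fluorophore,
                                             grid.grid_wl).values

    @property
    def grid_wl(self) -> WavelengthGrid:
        return self.grid.grid_wl

    def emission_sampling_pdf(self, uniform_floor: float = 0.2) -> np.ndarray:
        """Discrete pdf over wavelength bins used to place spectral samples:
        a mixture of the dyes' emission pdfs with a uniform floor."""
        n = self.grid_wl.n
        dye_rows = self.p_m[self.phi > 0]
        if len(dye_rows) == 0:
            return np.full(n, 1.0 / n)
        mix = dye_rows.mean(axis=0)
        q = (1.0 - uniform_floor) * mix + uniform_floor / n
        return q / q.sum()


class SpectralImage:
    """Per-pixel radiance accumulator over the wavelength grid."""

    def __init__(self, resolution, grid_wl: WavelengthGrid):
        w, h = resolution
        self.grid_wl = grid_wl
        self.values = np.zeros((h, w, grid_wl.n))
        self.counts = np.zeros((h, w), dtype=np.int64)

    @property
    def resolution(self):
        h, w, _ = self.values.shape
        return (w, h)

    def integrated(self) -> np.ndarray:
        """Per-pixel spectrally integrated radiance (H, W)."""
        return self.values.sum(axis=2)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.values.astype("<f8").tofile(path)
        meta = {"shape": list(self.values.shape),
                "grid": [self.grid_wl.lambda_min, self.grid_wl.lambda_max,
                         self.grid_wl.delta_lambda],
                "counts": self.counts.tolist(), "dtype": "float64"}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SpectralImage":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        h, w, n = meta["shape"]
        gmin, gmax, dl = meta["grid"]
        img = cls((w, h), WavelengthGrid(gmin, gmax, dl))
        img.values = np.fromfile(path, dtype="<f8").reshape(h, w, n)
        img.counts = np.asarray(meta["counts"], dtype=np.int64)
        return img


# -- phase function ---------------------------------------------------------

def phase_eval(g: float, cos_theta) -> np.ndarray:
    """Henyey-Greenstein phase density over solid angle (integrates to 1)."""
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    c = np.asarray(cos_theta, dtype=float)
    denom = (1.0 + g * g - 2.0 * g * c) ** 1.5
    return (1.0 - g * g) / (4.0 * np.pi * denom)


def _hg_cos(g: float, u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-6:
        return 1.0 - 2.0 * u
    s = (1.0 - g * g) / (1.0 + g - 2.0 * g * u)
    return (1.0 + g * g - s * s) / (2.0 * g)


def phase_sample(g: float, rng) -> np.ndarray:
    """Sample one direction from HG about the +z axis (importance weight 1)."""
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    c = float(_hg_cos(g, rng.random()))
    phi = 2.0 * np.pi * rng.random()
    s = math.sqrt(max(0.0, 1.0 - c * c))
    return np.array([s * math.cos(phi), s * math.sin(phi), c])


def _rotate_about(dirs: np.ndarray, cos_t: np.ndarray, phi: np.ndarray
                  ) -> np.ndarray:
    """New unit vectors at angle arccos(cos_t), azimuth phi, about dirs."""
    d = dirs
    a = np.where(np.abs(d[:, 0:1]) < 0.9,
                 np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
    u = np.cross(d, a)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    s = np.sqrt(np.clip(1.0 - cos_t * cos_t, 0.0, None))
    out = (cos_t[:, None] * d
           + (s * np.cos(phi))[:, None] * u
           + (s * np.sin(phi))[:, None] * v)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


# -- geometric helpers ------------------------------------------------------

def _ray_box(origins, dirs, lo, hi):
    """Slab intersection; returns (t_enter >= 0, t_exit), t_enter > t_exit
    when the ray misses the box."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t0 = (lo[None, :] - origins) * inv
        t1 = (hi[None, :] - origins) * inv
    # rays parallel to an axis and outside the slab never enter it
    par = dirs == 0.0
    inside = (origins >= lo[None, :]) & (origins <= hi[None, :])
    t0 = np.where(par, np.where(inside, -np.inf, np.inf), t0)
    t1 = np.where(par, np.where(inside, np.inf, -np.inf), t1)
    tmin = np.minimum(t0, t1).max(axis=1)
    tmax = np.maximum(t0, t1).min(axis=1)
    return np.maximum(tmin, 0.0), tmax


def _labels_at(grid: VoxelGrid, pts: np.ndarray) -> np.ndarray:
    """Material labels at world points (points outside the grid -> 0)."""
    f = (pts - grid.origin[None, :]) / grid.spacing
    idx = np.floor(f).astype(np.int64)
    dims = np.asarray(grid.dims)
    ok = np.all((idx >= 0) & (idx < dims[None, :]), axis=1)
    out = np.zeros(len(pts), dtype=np.int64)
    if ok.any():
        ii = idx[ok]
        out[ok] = grid.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


# -- woodcock tracking ------------------------------------------------------

def _propagate_batch(scene: Scene, pos, dirs, lam_idx, rng):
    """Woodcock free-flight for a batch of rays.

    Returns (collided, position, label): collided is False for rays that
    escape the volume.
    """
    n = len(pos)
    lo = scene.grid.extent_min
    hi = scene.grid.extent_max
    t_enter, t_exit = _ray_box(pos, dirs, lo, hi)
    mu = scene.mu_bar[lam_idx]
    alive = (t_exit > t_enter) & (mu > 0)
    t = t_enter.copy()
    collided = np.zeros(n, dtype=bool)
    labels = np.zeros(n, dtype=np.int64)
    out_pos = pos.copy()
    idx = np.nonzero(alive)[0]
    while len(idx):
        step = -np.log(rng.random(len(idx))) / mu[idx]
        t[idx] = t[idx] + step
        esc = t[idx] > t_exit[idx]
        idx = idx[~esc]
        if not len(idx):
            break
        p = pos[idx] + dirs[idx] * t[idx, None]
        lab = _labels_at(scene.grid, p)
        sig = scene.sigma_t[lab, lam_idx[idx]]
        hit = rng.random(len(idx)) < sig / mu[idx]
        hidx = idx[hit]
        collided[hidx] = True
        labels[hidx] = lab[hit]
        out_pos[hidx] = p[hit]
        idx = idx[~hit]
    return collided, out_pos, labels


def sample_free_path_woodcock(grid: VoxelGrid, majorant: MajorantTable,
                              origin, direction, lam: float, rng):
    """Sample one real collision (or escape) of a ray at wavelength ``lam``.

    Returns the collision position as an array, or None on escape.  Tentative
    collisions are spaced exponentially at the majorant rate and accepted
    with probability sigma_t/mu_bar (null-collision tracking).
    """
    scene_like = _BareScene(grid, majorant)
    li = grid.grid_wl.index(lam)
    pos = np.asarray(origin, float)[None, :]
    d = _unit(np.asarray(direction, float))[None, :]
    t_enter, t_exit = _ray_box(pos, d, grid.extent_min, grid.extent_max)
    if t_exit[0] > t_enter[0] and scene_like.mu_bar[li] <= 0:
        # a nonzero medium with a zero majorant is an invalid table
        present = np.unique(grid.labels)
        if np.any(grid.tables["sigma_t"][present, li] > 0):
            raise ValueError("zero majorant over a nonzero medium")
    coll, p, _ = _propagate_batch(scene_like, pos, d,
                                  np.array([li]), rng)
    return p[0] if coll[0] else None


class _BareScene:
    """Minimal Scene interface for the scalar tracking helpers."""

    def __init__(self, grid: VoxelGrid, majorant: MajorantTable | None = None):
        self.grid = grid
        m = majorant or build_majorant(grid)
        self.mu_bar = m.mu_bar * MM_PER_UM
        self.sigma_t = grid.tables["sigma_t"] * MM_PER_UM


def classify_event(material, lam: float, rng) -> str:
    """Stochastic event taxonomy at a real collision.

    Scatter with probability sigma_s/sigma_t; otherwise the photon is
    absorbed, and the absorption is fluorescent with probability
    mu_a^f/mu_a (possible only at dye-bearing voxels) and terminal
    otherwise.
    """
    li = material.grid_wl.index(lam)
    sig_s = float(material.sigma_s.values[li])
    mu_a = float(material.mu_a()[li])
    mu_af = float(material.mu_a_f()[li])
    sig_t = sig_s + mu_a
    if sig_t <= 0:
        raise ValueError("classify_event requires a collision in a voxel "
                         "with sigma_t > 0")
    p_s = sig_s / sig_t
    p_f = mu_af / mu_a if mu_a > 0 else 0.0
    if not (0.0 <= p_s <= 1.0 and 0.0 <= p_f <= 1.0):
        raise ValueError("event probabilities outside [0, 1]")
    u = rng.random()
    if u < p_s:
        return "elastic_scatter"
    if rng.random() < p_f:
        return "fluorescence"
    return "absorb_terminate"


# -- transmittance ----------------------------------------------------------

def _ratio_tracking_batch(scene: Scene, a, b, lam_idx, rng) -> np.ndarray:
    """Unbiased ratio-tracking estimate of exp(-integral sigma_t) along the
    segments a -> b at per-segment wavelength bins."""
    n = len(a)
    seg = b - a
    seg_len = np.linalg.norm(seg, axis=1)
    d = seg / np.maximum(seg_len, 1e-300)[:, None]
    t_enter, t_exit = _ray_box(a, d, scene.grid.extent_min,
                               scene.grid.extent_max)
    t_exit = np.minimum(t_exit, seg_len)
    mu = scene.mu_bar[lam_idx]
    tau = np.ones(n)
    idx = np.nonzero((t_exit > t_enter) & (mu > 0))[0]
    t = t_enter.copy()
    while len(idx):
        t[idx] = t[idx] - np.log(rng.random(len(idx))) / mu[idx]
        done = t[idx] > t_exit[idx]
        idx = idx[~done]
        if not len(idx):
            break
        p = a[idx] + d[idx] * t[idx, None]
        lab = _labels_at(scene.grid, p)
        sig = scene.sigma_t[lab, lam_idx[idx]]
        tau[idx] *= 1.0 - sig / mu[idx]
        dead = tau[idx] <= 0.0
        idx = idx[~dead]
    return tau


def transmittance(grid: VoxelGrid, a, b, lam: float, rng=None) -> float:
    """Transmittance exp(-integral sigma_t ds) between two points.

    Closed form (Beer-Lambert over the chord inside the grid) when the grid
    is homogeneous; otherwise an unbiased ratio-tracking estimate, which
    requires ``rng``.
    """
    li = grid.grid_wl.index(lam)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if grid.is_homogeneous:
        lab = int(grid.labels.flat[0])
        sig = grid.tables["sigma_t"][lab, li] * MM_PER_UM
        seg = b - a
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0 or sig == 0:
            return 1.0
        d = (seg / seg_len)[None, :]
        t0, t1 = _ray_box(a[None, :], d, grid.extent_min, grid.extent_max)
        chord = max(0.0, min(float(t1[0]), seg_len) - float(t0[0]))
        return math.exp(-sig * chord)
    if rng is None:
        raise ValueError("heterogeneous transmittance needs an rng")
    scene_like = _BareScene(grid)
    return float(_ratio_tracking_batch(scene_like, a[None, :], b[None, :],
                                       np.array([li]), rng)[0])


# -- light connection -------------------------------------------------------

def _light_contrib_batch(scene: Scene, pos, dirs, labels, lam_m_idx, rng,
                         sigma_div):
    """Direct-light fluorescence gather at a batch of collision vertices.

    ``sigma_div`` is the per-vertex divisor of the collision estimator
    (sigma_t for the NEE gather; mu_a^f(lambda_m) for the analog weight).
    Returns per-vertex radiance contributions.
    """
    n = len(pos)
    light = scene.light
    u1 = rng.random(n)[:, None]
    u2 = rng.random(n)[:, None]
    xl = light.corner[None, :] + u1 * light.edge_u[None, :] \
        + u2 * light.edge_v[None, :]
    vec = xl - pos
    r = np.linalg.norm(vec, axis=1)
    ldir = vec / np.maximum(r, 1e-300)[:, None]        # event -> light
    cos_l = np.maximum(0.0, -(ldir @ light.normal))    # light-side cosine
    geom = cos_l / np.maximum(r * r, 1e-300)

    # excitation wavelength: monochromatic line, or sampled ~ L_e * f_x
    line = light.line_index
    if line is not None:
        lam_x_idx = np.full(n, line, dtype=np.int64)
        le_over_p = np.full(n, float(light.emission.values[line]))
    else:
        lam_x_idx = np.zeros(n, dtype=np.int64)
        le_over_p = np.zeros(n)
        for lab in np.unique(labels):
            m = labels == lab
            mat = scene.grid.materials[int(lab)]
            if mat.dye is None:
                continue
            w = light.emission.values * mat.dye.fluorophore.f_x.values
            tot = w.sum()
            if tot <= 0:
                continue
            pdf = w / tot
            cdf = np.cumsum(pdf)
            sel = np.searchsorted(cdf, rng.random(int(m.sum())), side="right")
            sel = np.minimum(sel, len(pdf) - 1)
            lam_x_idx[m] = sel
            le_over_p[m] = light.emission.values[sel] / pdf[sel]

    mu_af_x = scene.mu_a_f[labels, lam_x_idx]
    tau = _ratio_tracking_batch(scene, pos, xl, lam_x_idx, rng)
    cos_t = np.einsum("ij,ij->i", dirs, ldir)
    fp = phase_eval_batch(scene.g[labels], cos_t)
    contrib = (scene.phi[labels] * scene.p_m[labels, lam_m_idx]
               * mu_af_x * fp * le_over_p * geom * light.area * tau
               / np.maximum(sigma_div, 1e-300))
    return contrib


def phase_eval_batch(g: np.ndarray, cos_theta: np.ndarray) -> np.ndarray:
    g = np.asarray(g, float)
    denom = (1.0 + g * g - 2.0 * g * cos_theta) ** 1.5
    return (1.0 - g * g) / (4.0 * np.pi * denom)


def direct_light_at_emission(event_position, light: LightSource,
                             lam_x: float, grid: VoxelGrid, rng,
                             incoming_direction=None, g: float = 0.0
                             ) -> float:
    """Single-sample direct-light term at a fluorescence vertex:
    ``L_e * G * tau(lambda_x) * f_p / p(x_n)`` with x_n uniform on the panel.
    """
    pos = np.asarray(event_position, float)
    u1, u2 = rng.random(), rng.random()
    xl = light.corner + u1 * light.edge_u + u2 * light.edge_v
    vec = xl - pos
    r = float(np.linalg.norm(vec))
    ldir = vec / r
    cos_l = max(0.0, float(-(ldir @ light.normal)))
    if cos_l == 0.0:
        return 0.0
    geom = cos_l / (r * r)
    li = grid.grid_wl.index(lam_x)
    le = float(light.emission.values[li])
    tau = transmittance(grid, pos, xl, lam_x,
                        rng if not grid.is_homogeneous else None)
    if incoming_direction is None:
        fp = 1.0 / (4.0 * math.pi)
    else:
        fp = float(phase_eval(g, float(np.dot(_unit(np.asarray(
            incoming_direction, float)), ldir))))
    return le * geom * tau * fp * light.area


# -- the estimator ----------------------------------------------------------

def _trace_batch(scene: Scene, config: RenderConfig, pos, dirs, lam_idx,
                 rng, accumulate, path_ids, instrument=None):
    """Trace a batch of camera paths; contributions are handed to
    ``accumulate(path_ids, lam_idx, values)``."""
    n = len(pos)
    weight = np.ones(n)
    active = np.ones(n, dtype=bool)
    analog = config.method == "analog"
    for depth in range(config.max_bounces):
        idx = np.nonzero(active)[0]
        if not len(idx):
            break
        coll, cpos, clab = _propagate_batch(scene, pos[idx], dirs[idx],
                                            lam_idx[idx], rng)
        esc = idx[~coll]
        active[esc] = False
        hit = idx[coll]
        if not len(hit):
            break
        pos[hit] = cpos[coll]
        labels = clab[coll]
        li = lam_idx[hit]
        sig_t = scene.sigma_t[labels, li]
        sig_s = scene.sigma_s[labels, li]
        mu_a = scene.mu_a[labels, li]
        mu_af = scene.mu_a_f[labels, li]

        if analog:
            u = rng.random(len(hit))
            p_scatter = sig_s / sig_t
            scat = u < p_scatter
            absorbed = ~scat
            with np.errstate(invalid="ignore", divide="ignore"):
                p_f = np.where(mu_a > 0, mu_af / mu_a, 0.0)
            fluor = absorbed & (rng.random(len(hit)) < p_f)
            fl = np.nonzero(fluor)[0]
            if len(fl):
                c = _light_contrib_batch(
                    scene, pos[hit[fl]], dirs[hit[fl]], labels[fl],
                    li[fl], rng, sigma_div=mu_af[fl])
                _check_finite(c)
                accumulate(path_ids[hit[fl]], li[fl], weight[hit[fl]] * c)
                if instrument is not None:
                    instrument["fluor_events"][path_ids[hit[fl]]] += 1
            active[hit[absorbed]] = False
            cont = np.nonzero(scat)[0]
        else:
            # NEE gather of the fluorescence source term at every collision
            # in a dye-bearing voxel (the mu_a^f(lambda_x) factor inside the
            # gather vanishes when the source cannot excite the dye)
            gather = np.nonzero(scene.phi[labels] > 0)[0]
            if len(gather):
                c = _light_contrib_batch(
                    scene, pos[hit[gather]], dirs[hit[gather]],
                    labels[gather], li[gather], rng,
                    sigma_div=sig_t[gather])
                _check_finite(c)
                accumulate(path_ids[hit[gather]], li[gather],
                           weight[hit[gather]] * c)
                if instrument is not None:
                    instrument["fluor_events"][path_ids[hit[gather]]] += 1
            # continue elastically with albedo probability
            cont = np.nonzero(rng.random(len(hit)) < sig_s / sig_t)[0]
            dead = np.setdiff1d(np.arange(len(hit)), cont,
                                assume_unique=False)
            active[hit[dead]] = False

        if len(cont):
            ci = hit[cont]
            if depth + 1 >= config.rr_start_depth:
                live = rng.random(len(ci)) < config.rr_survival
                active[ci[~live]] = False
                ci = ci[live]
                weight[ci] /= config.rr_survival
            if len(ci):
                cos_t = _hg_cos_batch(scene.g[_labels_at(scene.grid,
                                                         pos[ci])],
                                      rng.random(len(ci)))
                phi = 2.0 * np.pi * rng.random(len(ci))
                dirs[ci] = _rotate_about(dirs[ci], cos_t, phi)
        else:
            pass
    # paths exceeding max_bounces are terminated with V_f unset


def _hg_cos_batch(g: np.ndarray, u: np.ndarray) -> np.ndarray:
    g = np.asarray(g, float)
    iso = np.abs(g) < 1e-6
    gs = np.where(iso, 0.5, g)
    s = (1.0 - gs * gs) / (1.0 + gs - 2.0 * gs * u)
    c = (1.0 + gs * gs - s * s) / (2.0 * gs)
    return np.where(iso, 1.0 - 2.0 * u, np.clip(c, -1.0, 1.0))


def _check_finite(c):
    if np.any(~np.isfinite(c)) or np.any(c < 0):
        raise FloatingPointError("non-finite or negative path contribution")


def trace_path(pixel, lam_m: float, scene: Scene, config: RenderConfig,
               rng) -> float:
    """Radiance sample for one pixel at one emission wavelength."""
    li = scene.grid_wl.index(lam_m)
    px = np.array([float(pixel[0])])
    py = np.array([float(pixel[1])])
    if config.pixel_jitter:
        jx, jy = rng.random(1), rng.random(1)
    else:
        jx = jy = np.full(1, 0.5)
    d = scene.camera.rays(px, py, jx, jy)
    pos = np.repeat(scene.camera.position[None, :], 1, axis=0)
    out = np.zeros(1)

    def accumulate(pids, lidx, vals):
        np.add.at(out, pids, vals)

    _trace_batch(scene, config, pos, d, np.array([li]), rng, accumulate,
                 np.zeros(1, dtype=np.int64))
    return float(out[0])


def render(scene: Scene, config: RenderConfig) -> SpectralImage:
    """Estimate the spectral image: per pixel, ``spp`` paths with emission
    wavelengths stratified over the dye-informed spectral sampling pdf.

    The accumulator at bin lambda estimates the per-bin radiance
    L(pixel, lambda); deterministic per seed.
    """
    w, h = scene.camera.resolution
    npx = w * h
    per_px = config.paths_per_pixel
    n_paths = npx * per_px
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    image = SpectralImage((w, h), scene.grid_wl)

    q = scene.emission_sampling_pdf()
    cdf = np.cumsum(q)
    cdf /= cdf[-1]

    flat = np.zeros((npx, scene.grid_wl.n))
    norm = 1.0 / (q * per_px)

    def accumulate(pids, lidx, vals):
        np.add.at(flat, (pids, lidx), vals * norm[lidx])

    # spectral sample s of a pixel occupies stratum s of the sampling pdf
    strata_of_path = (np.arange(per_px) // config.spp).astype(float)
    for start in range(0, n_paths, config.max_batch):
        stop = min(start + config.max_batch, n_paths)
        pidx = np.arange(start, stop)
        pix = pidx // per_px
        strata = strata_of_path[pidx % per_px]
        u = (strata + rng.random(len(pidx))) / config.spectral_samples
        lam_idx = np.minimum(np.searchsorted(cdf, u, side="right"),
                             len(q) - 1)
        px = (pix % w).astype(float)
        py = (pix // w).astype(float)
        if config.pixel_jitter:
            jx, jy = rng.random(len(pidx)), rng.random(len(pidx))
        else:
            jx = jy = np.full(len(pidx), 0.5)
        dirs = scene.camera.rays(px, py, jx, jy)
        pos = np.repeat(scene.camera.position[None, :], len(pidx), axis=0)
        _trace_batch(scene, config, pos, dirs, lam_idx, rng, accumulate, pix)

    image.values = flat.reshape(h, w, scene.grid_wl.n)
    image.counts[:] = per_px
    return image


# -- display conversion -----------------------------------------------------

def _cie_g(x, mu, s1, s2):
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def _cie_xyz_bar(lam: np.ndarray):
    """Multi-lobe Gaussian fits of the CIE 1931 2-degree observer."""
    x = (1.056 * _cie_g(lam, 599.8, 37.9, 31.0)
         + 0.362 * _cie_g(lam, 442.0, 16.0, 26.7)
         - 0.065 * _cie_g(lam, 501.1, 20.4, 26.2))
    y = (0.821 * _cie_g(lam, 568.8, 46.9, 40.5)
         + 0.286 * _cie_g(lam, 530.9, 16.3, 31.1))
    z = (1.217 * _cie_g(lam, 437.0, 11.8, 36.0)
         + 0.681 * _cie_g(lam, 459.0, 26.0, 13.8))
    return x, y, z


_XYZ_TO_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


def spectral_to_rgb(image: SpectralImage, exposure: float | None = None
                    ) -> np.ndarray:
    """CIE 1931 integration -> linear sRGB -> gamma; returns (H, W, 3) in
    [0, 1].  ``exposure`` rescales so that value maps to 1; default is the
    image maximum luminance."""
    lam = image.grid_wl.wavelengths
    xb, yb, zb = _cie_xyz_bar(lam)
    X = image.values @ xb
    Y = image.values @ yb
    Z = image.values @ zb
    if exposure is None:
        exposure = float(Y.max()) or 1.0
    xyz = np.stack([X, Y, Z], axis=-1) / exposure
    rgb = np.einsum("ij,hwj->hwi", _XYZ_TO_SRGB, xyz)
    rgb = np.clip(rgb, 0.0, 1.0)
    srgb = np.where(rgb <= 0.0031308, 12.92 * rgb,
                    1.055 * rgb ** (1.0 / 2.4) - 0.055)
    return np.clip(srgb, 0.0, 1.0)
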