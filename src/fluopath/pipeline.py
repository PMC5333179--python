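"""End-to-end pipeline: generate -> voxelize -> annotate -> render -> measure.

The pipeline is driven by a single TOML configuration with explicit units
(um, nm, mol/L, mm^-1) and one master seed; each stage derives its own
sub-seed so that re-running an identical configuration reproduces identical
artifacts.  Every run writes a manifest (configuration hash, seeds, stage
artifact paths) so any stage can be re-run standalone from prior artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import measure_spd, validation_report
from .render import (Camera, LightSource, RenderConfig, Scene, render,
                     spectral_to_rgb)
from .spectra import DEFAULT_GRID, DyeSolution, Spectrum, dye_preset, list_presets
from .tissuegen import (Block, MorphologyParams, check_watertight,
                        clip_to_block, morphology_to_mesh, place_population,
                        transform_morphology, voxelize_solid)
from .volume import OpticalMaterial, VoxelGrid, write_volume

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "build_scene"]

log = logging.getLogger("fluopath.pipeline")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config``)."""

    raw: dict
    path: Path | None = None

    def __post_init__(self):
        c = self.raw
        for section in ("tissue", "materials", "camera", "light", "sampling"):
            if section not in c:
                raise ValueError(f"config is missing the [{section}] section")
        for lab, m in c["materials"].items():
            if "dye" in m and m["dye"] is not None:
                name = m["dye"]
                key = str(name).upper().replace(" ", "")
                if key.replace("ALEXA", "AF").replace(".", "") not in \
                        [p for p in list_presets()]:
                    raise ValueError(
                        f"unknown dye name {name!r} for material {lab}; "
                        f"available presets: {list_presets()}")
        t = c["tissue"]
        Block(tuple(t["block"][0]), tuple(t["block"][1]))
        if t.get("n", 1) < 1 or t.get("spacing_um", 1.0) <= 0:
            raise ValueError("tissue.n and tissue.spacing_um must be positive")

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return PipelineConfig(raw=raw, path=Path(path))


def _material_from_config(m: dict) -> OpticalMaterial:
    grid_wl = DEFAULT_GRID
    dye = None
    if m.get("dye"):
        fluo = dye_preset(m["dye"], grid_wl)
        dye = DyeSolution(fluo, float(m.get("concentration", 0.0)))
    return OpticalMaterial(
        sigma_s=Spectrum.constant(float(m.get("sigma_s_mm", 0.0)), grid_wl),
        sigma_a_base=Spectrum.constant(float(m.get("sigma_a_mm", 0.0)),
                                       grid_wl),
        g=float(m.get("g", 0.9)),
        dye=dye)


def build_scene(config: PipelineConfig, grid: VoxelGrid) -> Scene:
    cam = config.raw["camera"]
    light = config.raw["light"]
    camera = Camera(position=cam["position"], look_at=cam["look_at"],
                    up=cam.get("up", (0.0, 1.0, 0.0)),
                    vfov_deg=float(cam.get("vfov_deg", 40.0)),
                    resolution=tuple(cam.get("resolution", (32, 32))))
    source = LightSource.monochromatic_panel(
        center=light["center"], size=float(light["size"]),
        normal=light["normal"], lam=float(light["wavelength_nm"]),
        radiance=float(light.get("radiance", 1.0)), grid=grid.grid_wl)
    return Scene(camera, source, grid)


def _tissue_stage(config: PipelineConfig, seed: int) -> VoxelGrid:
    t = config.raw["tissue"]
    block = Block(tuple(t["block"][0]), tuple(t["block"][1]))
    spacing = float(t["spacing_um"])
    mp_kwargs = {k: t[k] for k in
                 ("n_stems", "branch_prob", "mean_segment_len", "taper",
                  "max_depth", "extent", "soma_radius") if k in t}
    params = MorphologyParams(**mp_kwargs)
    cells = place_population(int(t.get("n", 1)), block, seed, params)
    label_cycle = [int(k) for k in config.raw["materials"]] or [1]
    dims = np.maximum(1, np.round(block.size / spacing).astype(int))
    labels = np.zeros(tuple(dims), dtype=np.uint8)
    for i, (morph, T) in enumerate(cells):
        placed = transform_morphology(morph, T)
        mesh = morphology_to_mesh(placed)
        ok, bad = check_watertight(mesh)
        if not ok:
            raise RuntimeError(
                f"stage tissue: morphology {i} produced a non-watertight "
                f"mesh ({len(bad)} bad edges)")
        clipped = clip_to_block(mesh, block)
        if len(clipped.faces) == 0:
            continue
        occ = voxelize_solid(clipped, spacing, block)
        labels[occ] = label_cycle[i % len(label_cycle)]   # later cells win
    materials = {int(k): _material_from_config(m)
                 for k, m in config.raw["materials"].items()}
    return VoxelGrid(labels=labels, spacing=spacing,
                     origin=np.asarray(block.lo, float),
                     materials=materials)


def run_pipeline(config: PipelineConfig | str | Path,
                 out_dir: str | Path | None = None) -> dict:
    """Execute all stages in order and write artifacts plus a manifest.

    Returns the manifest dict.  Any stage failure aborts with the stage name
    in the exception message.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    c = config.raw
    out = Path(out_dir or c.get("output", {}).get("dir", "fluopath_out"))
    out.mkdir(parents=True, exist_ok=True)
    master = int(c.get("sampling", {}).get("seed", 0))
    seeds = {"tissue": master % (2**31), "render": (master + 1) % (2**31)}
    manifest = {"config_digest": config.digest, "seeds": seeds,
                "version": __version__, "artifacts": {}}

    def stage(name, fn, *args):
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            result = fn(*args)
        except Exception as e:
            raise RuntimeError(f"stage {name} failed: {e}") from e
        log.info("stage %s: done in %.2f s", name, time.time() - t0)
        return result

    grid = stage("tissue+voxelize", _tissue_stage, config, seeds["tissue"])
    vol_path = out / "volume.raw"
    write_volume(grid, vol_path, nrrd_header=True)
    manifest["artifacts"]["volume"] = str(vol_path)

    scene = stage("annotate", build_scene, config, grid)
    s = c["sampling"]
    rc = RenderConfig(spp=int(s.get("spp", 16)),
                      spectral_samples=int(s.get("spectral_samples", 16)),
                      max_bounces=int(s.get("max_bounces", 32)),
                      seed=seeds["render"],
                      method=s.get("method", "nee"))
    image = stage("render", render, scene, rc)
    img_path = out / "image.spectral"
    image.save(img_path)
    manifest["artifacts"]["spectral_image"] = str(img_path)

    rgb = spectral_to_rgb(image)
    try:
        from PIL import Image as PILImage
        png_path = out / "preview.png"
        PILImage.fromarray((rgb * 255).astype(np.uint8)).save(png_path)
        manifest["artifacts"]["preview"] = str(png_path)
    except Exception:           # preview is best-effort
        pass

    spd = stage("measure", measure_spd, image)
    written = validation_report({"full_image": spd}, out, plot=False)
    manifest["artifacts"]["spd_csv"] = str(written["spds"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
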