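"""SPD measurement and spectral validation of rendered fluorescence images.

Two validation procedures are provided, mirroring standard spectroscopic
practice for fluorescent solutions:

* emission-profile validation — the spectral power distribution (SPD)
  measured from a rendered image, peak-normalized, should match the dye's
  intrinsic emission spectrum;
* excitation-wavelength scan — rendering the same block under a series of
  monochromatic illumination lines, the SPD amplitude of each run (relative
  to the run at the excitation maximum) should follow the amplitude of the
  dye's excitation spectrum at the illumination line.

SPDs are always measured from the raw spectral accumulators, never from the
RGB conversion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .render import RenderConfig, Scene, SpectralImage, render
from .spectra import Spectrum

__all__ = [
    "MeasuredSPD",
    "ExcitationScanResult",
    "measure_spd",
    "peak_wavelength",
    "profile_similarity",
    "excitation_scan",
    "validation_report",
]


@dataclass
class MeasuredSPD:
    """Mean radiance per wavelength over a pixel region of a spectral image."""

    spectrum: Spectrum
    region: tuple                  # (x0, y0, x1, y1), half-open
    normalization: str = "none"    # none | peak

    def normalized(self) -> "MeasuredSPD":
        peak = self.spectrum.values.max()
        if peak <= 0:
            raise ValueError("cannot peak-normalize an all-zero SPD")
        return MeasuredSPD(Spectrum(self.spectrum.grid,
                                    self.spectrum.values / peak),
                           self.region, "peak")


@dataclass
class ExcitationScanResult:
    """Relative SPD amplitudes of an illumination-wavelength scan.

    ``amplitudes[i]`` is the SPD maximum of run ``i`` divided by that of the
    reference run (the dye's excitation-maximum line); ``integrals`` holds
    the same normalization for spectrally integrated SPDs.
    """

    wavelengths: np.ndarray
    amplitudes: np.ndarray
    integrals: np.ndarray
    spds: list

    @property
    def argmax_wavelength(self) -> float:
        """Illumination wavelength with the maximal integrated SPD."""
        return float(self.wavelengths[int(np.argmax(self.integrals))])


def measure_spd(image: SpectralImage, region: tuple | None = None
                ) -> MeasuredSPD:
    """Per-wavelength mean radiance over a pixel rectangle.

    ``region`` is (x0, y0, x1, y1), half-open in pixels; default full image.
    """
    w, h = image.resolution
    if region is None:
        region = (0, 0, w, h)
    x0, y0, x1, y1 = region
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"empty or out-of-bounds region {region} "
                         f"for a {w}x{h} image")
    vals = image.values[y0:y1, x0:x1].mean(axis=(0, 1))
    return MeasuredSPD(Spectrum(image.grid_wl, vals), region)


def peak_wavelength(spd: MeasuredSPD | Spectrum) -> float:
    """Grid wavelength of the SPD maximum; ties break toward the smaller
    wavelength."""
    s = spd.spectrum if isinstance(spd, MeasuredSPD) else spd
    if s.values.max() <= 0:
        raise ValueError("peak of an all-zero SPD is undefined")
    return float(s.grid.wavelengths[int(np.argmax(s.values))])


def profile_similarity(spd: MeasuredSPD | Spectrum,
                       reference: Spectrum) -> float:
    """Pearson correlation of peak-normalized profiles over the union
    support of the two spectra."""
    a = (spd.spectrum if isinstance(spd, MeasuredSPD) else spd).values
    b = reference.values
    if a.max() <= 0 or b.max() <= 0:
        raise ValueError("profile similarity needs nonzero spectra")
    mask = (a > 0) | (b > 0)
    an = a[mask] / a.max()
    bn = b[mask] / b.max()
    if an.std() == 0 or bn.std() == 0:
        raise ValueError("zero-variance profile")
    return float(np.corrcoef(an, bn)[0, 1])


def excitation_scan(scene_template, wavelengths, config: RenderConfig,
                    reference_nm: float | None = None,
                    region: tuple | None = None) -> ExcitationScanResult:
    """Render the same scene once per illumination line and compare SPDs.

    ``scene_template`` is a callable ``lambda illumination_nm: Scene`` (the
    same block re-lit at each line).  Amplitudes are normalized to the run
    at ``reference_nm`` (default: the scanned wavelength with the largest
    response; the conventional choice is the dye's excitation maximum,
    which should coincide).
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    spds = []
    for lam in wavelengths:
        scene = scene_template(float(lam))
        img = render(scene, config)
        spds.append(measure_spd(img, region))
    amps = np.array([s.spectrum.values.max() for s in spds])
    ints = np.array([s.spectrum.values.sum() for s in spds])
    if reference_nm is not None:
        ref = int(np.nonzero(wavelengths == reference_nm)[0][0])
    else:
        ref = int(np.argmax(amps))
    if amps[ref] <= 0:
        raise ValueError("reference run recorded no radiance")
    return ExcitationScanResult(wavelengths=wavelengths,
                                amplitudes=amps / amps[ref],
                                integrals=ints / ints[ref],
                                spds=spds)


def validation_report(results: dict, out_dir: str | Path,
                      plot: bool = True) -> dict:
    """Write SPD curves and scan amplitudes as CSV (and PNG plots).

    ``results`` maps a name to either a :class:`MeasuredSPD` (written to
    ``spds.csv``) or an :class:`ExcitationScanResult` (written to
    ``scan_<name>.csv``).  Returns the mapping of written file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    spd_items = {k: v for k, v in results.items()
                 if isinstance(v, MeasuredSPD)}
    scan_items = {k: v for k, v in results.items()
                  if isinstance(v, ExcitationScanResult)}

    spd_path = out_dir / "spds.csv"
    with open(spd_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["wavelength_nm"] + list(spd_items))
        if spd_items:
            grid = next(iter(spd_items.values())).spectrum.grid
            cols = [v.spectrum.values for v in spd_items.values()]
            for i, lam in enumerate(grid.wavelengths):
                w.writerow([f"{lam:g}"] + [repr(float(c[i])) for c in cols])
    written["spds"] = spd_path

    for name, scan in scan_items.items():
        p = out_dir / f"scan_{name}.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["illumination_nm", "relative_amplitude",
                        "relative_integral"])
            for lam, a, s in zip(scan.wavelengths, scan.amplitudes,
                                 scan.integrals):
                w.writerow([f"{lam:g}", repr(float(a)), repr(float(s))])
        written[f"scan_{name}"] = p

    if plot and (spd_items or scan_items):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        if spd_items:
            fig, ax = plt.subplots(figsize=(6, 4))
            for name, v in spd_items.items():
                vals = v.spectrum.values
                top = vals.max()
                ax.plot(v.spectrum.grid.wavelengths,
                        vals / top if top > 0 else vals, label=name)
            ax.set_xlabel("wavelength (nm)")
            ax.set_ylabel("normalized SPD")
            ax.legend()
            fig.savefig(out_dir / "spds.png", dpi=120)
            plt.close(fig)
            written["spds_png"] = out_dir / "spds.png"
        if scan_items:
            fig, ax = plt.subplots(figsize=(6, 4))
            for name, scan in scan_items.items():
                ax.plot(scan.wavelengths, scan.amplitudes, "o-", label=name)
            ax.set_xlabel("illumination wavelength (nm)")
            ax.set_ylabel("relative SPD amplitude")
            ax.legend()
            fig.savefig(out_dir / "scan.png", dpi=120)
            plt.close(fig)
            written["scan_png"] = out_dir / "scan.png"
    return written
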