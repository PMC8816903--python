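"""Spectral reflectance handling for the visual stimuli.

Reflectance spectra (wavelength in nm vs. reflectance fraction, as measured
with a spectrophotometer against a white standard) feed three object
descriptors used by the preference models:

* band intensity — trapezoidal integral of reflectance x illuminant over a
  wavelength band (default 400-700 nm, flat illuminant);
* Weber contrast — (I_object - I_background) / I_background on band
  intensities; negative for objects darker than the background;
* peak (dominant) wavelength — argmax of reflectance in 400-700 nm;
* a 13-vector of 25-nm area-under-curve bins spanning 350-675 nm, the
  feature vector for the PCA regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "Spectrum",
    "read_spectrum",
    "band_intensity",
    "brightness",
    "weber_contrast",
    "peak_wavelength",
    "auc_bins",
    "gaussian_spectrum",
    "gray_spectrum",
    "builtin_library",
]


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-indexed spectrum; linear interpolation between samples."""

    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray  # reflectance fraction or irradiance (uW/cm^2/nm)
    kind: Literal["reflectance", "irradiance"] = "reflectance"
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.size < 2 or wl.size != vals.size:
            raise ValueError("spectrum needs >= 2 (wavelength, value) samples")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be non-negative")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def at(self, wl: np.ndarray | float) -> np.ndarray | float:
        return np.interp(wl, self.wavelengths, self.values)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.values * factor, self.kind, self.name)


def read_spectrum(path: str | Path, kind: str = "reflectance", name: str = "") -> Spectrum:
    """Read a two-column (wavelength-nm, value) text file; comma or
    whitespace separated, '#' comments allowed."""
    path = Path(path)
    text = path.read_text()
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected two columns, got {line!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    return Spectrum(arr[order, 0], arr[order, 1], kind=kind, name=name or path.stem)


def _integrate(spectrum: Spectrum, lo: float, hi: float, illuminant: Spectrum | None) -> float:
    """Trapezoid integral of spectrum (x illuminant) over [lo, hi] on the
    native grid augmented with the exact band endpoints (and the illuminant
    grid when one is supplied)."""
    s_lo, s_hi = spectrum.support
    if lo < s_lo - 1e-9 or hi > s_hi + 1e-9:
        raise ValueError(
            f"band [{lo}, {hi}] nm outside spectrum support [{s_lo}, {s_hi}] nm"
        )
    grid = spectrum.wavelengths
    if illuminant is not None:
        grid = np.union1d(grid, illuminant.wavelengths)
    grid = np.union1d(grid, [lo, hi])
    grid = grid[(grid >= lo) & (grid <= hi)]
    vals = spectrum.at(grid)
    if illuminant is not None:
        vals = vals * illuminant.at(grid)
    return float(np.trapezoid(vals, grid))


def band_intensity(
    spectrum: Spectrum,
    lo_nm: float = 400.0,
    hi_nm: float = 700.0,
    illuminant: Spectrum | None = None,
) -> float:
    """Band-integrated intensity (uW/cm^2 equivalent under a unit-flat
    illuminant) over [lo_nm, hi_nm]."""
    if lo_nm >= hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    return _integrate(spectrum, lo_nm, hi_nm, illuminant)


def weber_contrast(i_object: float, i_background: float) -> float:
    """(I_object - I_background) / I_background; requires a positive
    background intensity."""
    if i_background <= 0:
        raise ValueError("background intensity must be positive")
    return (i_object - i_background) / i_background


def brightness(
    spectrum: Spectrum,
    method: Literal["band", "peak"] = "band",
    lo_nm: float = 400.0,
    hi_nm: float = 700.0,
) -> float:
    """Object "brightness" descriptor for the preference models.

    ``band`` (default) is the band-integrated reflectance over
    [lo_nm, hi_nm]; ``peak`` is the maximum reflectance in the band. Model
    reports should state which reading was used.
    """
    if method == "band":
        return band_intensity(spectrum, lo_nm, hi_nm)
    if method == "peak":
        s_lo, s_hi = spectrum.support
        grid = np.arange(max(lo_nm, s_lo), min(hi_nm, s_hi) + 0.5, 1.0)
        return float(np.max(spectrum.at(grid)))
    raise ValueError("method must be 'band' or 'peak'")


def peak_wavelength(
    spectrum: Spectrum, lo_nm: float = 400.0, hi_nm: float = 700.0, step: float = 1.0
) -> float:
    """Wavelength (nm) of maximum reflectance within [lo_nm, hi_nm].

    Evaluated on a regular grid via linear interpolation; exact ties are
    broken toward the longer wavelength.
    """
    s_lo, s_hi = spectrum.support
    lo = max(lo_nm, s_lo)
    hi = min(hi_nm, s_hi)
    if lo >= hi:
        raise ValueError("evaluation band is empty")
    grid = np.arange(lo, hi + step / 2, step)
    vals = spectrum.at(grid)
    best = np.max(vals)
    # ties toward longer wavelength
    return float(grid[np.flatnonzero(np.isclose(vals, best, rtol=0, atol=1e-12))[-1]])


def auc_bins(
    spectrum: Spectrum, lo: float = 350.0, hi: float = 675.0, width: float = 25.0
) -> np.ndarray:
    """Per-bin trapezoidal areas over consecutive ``width``-nm bins covering
    [lo, hi); defaults give the 13 bins of 25 nm from 350 to 675 nm."""
    n = (hi - lo) / width
    if abs(n - round(n)) > 1e-9:
        raise ValueError("band width must divide the range evenly")
    n = int(round(n))
    edges = lo + width * np.arange(n + 1)
    return np.array([_integrate(spectrum, a, b, None) for a, b in zip(edges[:-1], edges[1:])])


# ---------------------------------------------------------------------------
# Synthetic fixture library
#
# These are synthetic stand-ins shaped like real colored-paper reflectance
# curves (a Gaussian reflectance peak on a low baseline, or a flat gray), for
# tests and demos; they are not measurements of any physical stimulus set.

_DEFAULT_GRID = np.arange(300.0, 801.0, 1.0)


def gaussian_spectrum(
    peak_nm: float,
    width_nm: float = 40.0,
    amplitude: float = 0.6,
    baseline: float = 0.05,
    name: str = "",
) -> Spectrum:
    """Synthetic single-peak reflectance curve."""
    vals = baseline + amplitude * np.exp(
        -((_DEFAULT_GRID - peak_nm) ** 2) / (2.0 * width_nm**2)
    )
    return Spectrum(_DEFAULT_GRID, vals, name=name or f"peak{peak_nm:.0f}")


def gray_spectrum(reflectance: float, name: str = "") -> Spectrum:
    """Synthetic spectrally flat (gray/white) reflectance curve."""
    return Spectrum(
        _DEFAULT_GRID,
        np.full(_DEFAULT_GRID.shape, float(reflectance)),
        name=name or f"gray{reflectance:.2f}",
    )


def builtin_library() -> dict[str, Spectrum]:
    """Synthetic hue set with peaks at the tested dominant wavelengths
    (437-660 nm) plus a gray series and a white control."""
    lib: dict[str, Spectrum] = {}
    for peak in (437, 452, 496, 510, 520, 590, 600, 660):
        lib[f"hue{peak}"] = gaussian_spectrum(peak, name=f"hue{peak}")
    for refl in (0.07, 0.15, 0.30, 0.50, 0.70):
        key = f"gray{int(refl * 100):02d}"
        lib[key] = gray_spectrum(refl, name=key)
    lib["white"] = gray_spectrum(0.90, name="white")
    return lib
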