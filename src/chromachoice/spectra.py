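"""Spectral data model, I/O, resampling and radiometric/photometric conversions.

Everything downstream (receptor sensitivities, quantum catches, LED scans)
operates on :class:`Spectrum` objects living on a common 1-nm wavelength grid.
The default working grid spans 300–700 nm, the range over which the LED peak
scan is carried out; integrals are trapezoidal throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "WORKING_GRID",
    "PLANCK",
    "SPEED_OF_LIGHT",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "energy_to_photons",
    "photons_to_energy",
    "photopic_luminosity",
    "luminous_intensity",
    "normalize_peak",
    "total_photon_output",
    "average_spectra",
]

#: Planck constant, J·s
PLANCK = 6.62607015e-34
#: Speed of light in vacuum, m/s
SPEED_OF_LIGHT = 2.99792458e8

#: Default working grid: 300–700 nm at 1 nm.
WORKING_GRID = np.arange(300.0, 701.0, 1.0)

VALID_UNITS = frozenset(
    {"photon_flux", "energy", "transmittance", "sensitivity", "radiance", "irradiance"}
)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed non-negative function with a unit tag.

    Parameters
    ----------
    wavelengths : array of nm, strictly increasing
    values : non-negative array, same length
    unit : one of ``photon_flux, energy, transmittance, sensitivity,
        radiance, irradiance``
    """

    wavelengths: np.ndarray
    values: np.ndarray
    unit: str = "photon_flux"
    name: str = field(default="", compare=False)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        if np.any(v < 0):
            raise ValueError("spectrum values must be non-negative")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {sorted(VALID_UNITS)}")

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values, unit: str | None = None) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float), unit=unit or self.unit)

    @property
    def peak_wavelength(self) -> float:
        """Wavelength of the global maximum (first one on ties)."""
        return float(self.wavelengths[int(np.argmax(self.values))])


def read_spectrum(path, unit: str | None = None, name: str = "") -> Spectrum:
    """Read a two-column wavelength/value CSV.

    The dialect is ``wavelength_nm,value`` with an optional header row and
    optional ``# unit: <tag>`` comment. Rows are sorted by wavelength and
    duplicate wavelengths (instrument re-scans) are averaged.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    file_unit = None
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("unit:"):
                file_unit = body.split(":", 1)[1].strip()
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two comma-separated columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if lineno == 1 or (not rows and parts[0].lower().startswith("wave")):
                continue  # header row
            raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from None
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    df = pd.DataFrame(rows, columns=["wl", "v"]).groupby("wl", as_index=False).mean()
    return Spectrum(
        df["wl"].to_numpy(),
        df["v"].to_numpy(),
        unit=unit or file_unit or "photon_flux",
        name=name or path.stem,
    )


def write_spectrum(s: Spectrum, path) -> None:
    """Write a spectrum in the same CSV dialect that :func:`read_spectrum` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# unit: {s.unit}\n")
        fh.write("wavelength_nm,value\n")
        for wl, v in zip(s.wavelengths, s.values):
            fh.write(f"{wl:.10g},{v:.10g}\n")


def resample(s: Spectrum, grid) -> Spectrum:
    """Linearly interpolate ``s`` onto ``grid`` (unit preserved).

    Wavelengths outside the support of ``s`` get value 0 with a warning —
    measured sky/LED files routinely cover different ranges.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty target grid")
    if grid.min() < s.wavelengths[0] or grid.max() > s.wavelengths[-1]:
        warnings.warn(
            f"resample: grid [{grid.min():g}, {grid.max():g}] extends beyond spectrum "
            f"support [{s.wavelengths[0]:g}, {s.wavelengths[-1]:g}]; padding with 0",
            stacklevel=2,
        )
    v = np.interp(grid, s.wavelengths, s.values, left=0.0, right=0.0)
    return Spectrum(grid, v, unit=s.unit, name=s.name)


def energy_to_photons(s: Spectrum) -> Spectrum:
    """Convert spectral energy to photon flux: N(λ) = E(λ)·λ/(h·c), λ in metres."""
    if s.unit != "energy":
        raise ValueError(f"energy_to_photons expects unit 'energy', got {s.unit!r}")
    lam_m = s.wavelengths * 1e-9
    return s.with_values(s.values * lam_m / (PLANCK * SPEED_OF_LIGHT), unit="photon_flux")


def photons_to_energy(s: Spectrum) -> Spectrum:
    """Algebraic inverse of :func:`energy_to_photons`."""
    if s.unit != "photon_flux":
        raise ValueError(f"photons_to_energy expects unit 'photon_flux', got {s.unit!r}")
    lam_m = s.wavelengths * 1e-9
    return s.with_values(s.values * PLANCK * SPEED_OF_LIGHT / lam_m, unit="energy")


# CIE 1924 photopic luminous efficiency V(λ), 380–780 nm at 5 nm.
_VL_WL = np.arange(380.0, 781.0, 5.0)
_VL = np.array([
    0.0000390, 0.0000640, 0.000120, 0.000217, 0.000396, 0.000640, 0.00121, 0.00218,
    0.00400, 0.00730, 0.0116, 0.01684, 0.023, 0.0298, 0.0380, 0.0480,
    0.0600, 0.0739, 0.09098, 0.1126, 0.13902, 0.1693, 0.20802, 0.2586,
    0.323, 0.4073, 0.503, 0.6082, 0.710, 0.7932, 0.862, 0.91485,
    0.954, 0.9803, 0.99495, 1.0000, 0.995, 0.9786, 0.952, 0.9154,
    0.870, 0.8163, 0.757, 0.6949, 0.631, 0.5668, 0.503, 0.4412,
    0.381, 0.321, 0.265, 0.217, 0.175, 0.1382, 0.107, 0.0816,
    0.061, 0.04458, 0.032, 0.0232, 0.017, 0.01192, 0.00821, 0.005723,
    0.004102, 0.002929, 0.002091, 0.001484, 0.001047, 0.00074, 0.00052, 0.000361,
    0.000249, 0.000172, 0.00012, 0.0000848, 0.00006, 0.0000424, 0.00003, 0.0000212,
    0.00001499,
])


def photopic_luminosity(grid=None) -> Spectrum:
    """The CIE 1924 photopic weighting V(λ); peak 1 at 555 nm, 0 outside 380–780."""
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    v = np.interp(grid, _VL_WL, _VL, left=0.0, right=0.0)
    return Spectrum(grid, v, unit="sensitivity", name="V(lambda)")


def luminous_intensity(s: Spectrum, vl: Spectrum | None = None) -> float:
    """Photometric intensity in candela: 683 × ∫ s(λ)·V(λ) dλ (trapezoidal).

    ``s`` is spectral radiant intensity in W/(sr·nm). Returns 0 with a warning
    when the supports are disjoint.
    """
    if vl is None:
        vl = photopic_luminosity(s.wavelengths)
    else:
        vl = resample(vl, s.wavelengths) if not np.array_equal(vl.wavelengths, s.wavelengths) else vl
    prod = s.values * vl.values
    if not np.any(prod > 0):
        warnings.warn("luminous_intensity: disjoint spectral support, returning 0 cd", stacklevel=2)
        return 0.0
    return 683.002 * float(np.trapezoid(prod, s.wavelengths))


def normalize_peak(s: Spectrum, target: float) -> Spectrum:
    """Rescale so the maximum value equals ``target``; ratios are preserved."""
    peak = float(np.max(s.values))
    if peak <= 0:
        raise ValueError("cannot peak-normalize an all-zero spectrum")
    if target <= 0:
        raise ValueError("target peak must be positive")
    return s.with_values(s.values * (target / peak))


def total_photon_output(s: Spectrum) -> float:
    """Total photon count: sum of per-bin counts over the spectrum's range."""
    if s.unit != "photon_flux":
        raise ValueError(f"total_photon_output expects unit 'photon_flux', got {s.unit!r}")
    return float(np.sum(s.values))


def average_spectra(spectra) -> Spectrum:
    """Pointwise arithmetic mean of spectra on identical grids and units."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.unit != first.unit:
            raise ValueError(f"unit mismatch: {s.unit!r} vs {first.unit!r}")
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise ValueError("spectra must share a grid; resample first")
    mean = np.mean([s.values for s in spectra], axis=0)
    return Spectrum(first.wavelengths, mean, unit=first.unit, name="mean")
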