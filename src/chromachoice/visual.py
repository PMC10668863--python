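"""Receptor spectral sensitivities for a parameterized avian eye.

A cone's sensitivity is assembled from three multiplicative filters:

    S_i(λ) = A_i(λ) · D_i(λ) · O(λ)

where A_i is the visual-pigment absorbance (Govardovskii A1 nomogram,
alpha plus beta band), D_i is the oil-droplet transmittance (tabulated or a
parametric long-pass cutoff), and O is the ocular-media transmittance
measured from eye scans. Sensitivities are renormalized to a peak of 1.

Ocular-media processing follows the measurement workflow for enucleated
eyes: average the transmittance scans, max-normalize, locate the 50%% cutoff
wavelength λT0.5 by linear interpolation of the first upward crossing, then
fit a monotone four-parameter logistic and replace the raw curve below
λT0.5 so that short-wavelength instrument noise cannot leak into contrast
calculations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import curve_fit

from .spectra import Spectrum, WORKING_GRID, average_spectra, normalize_peak, resample

__all__ = [
    "OilDroplet",
    "ConeClass",
    "OcularMedia",
    "VisualSystem",
    "pigment_template",
    "ocular_media_from_scans",
    "receptor_sensitivity",
    "load_visual_system",
]


def pigment_template(lambda_max: float, grid=None) -> Spectrum:
    """A1 visual-pigment absorbance template (Govardovskii et al. 2000 nomogram).

    Alpha band:
        S_a(λ) = 1 / (exp[A(a − x)] + exp[B(b − x)] + exp[C(c − x)] + D)
    with x = λmax/λ, A=69.7, B=28, C=−14.9, D=0.674, b=0.922, c=1.104 and
    a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940).

    Beta band: A_β·exp(−((λ−λmβ)/bβ)²) with A_β=0.26,
    λmβ = 189 + 0.315·λmax, bβ = −40.5 + 0.195·λmax.

    Returned normalized to a global maximum of 1 at ``lambda_max``.
    """
    if not (330.0 <= lambda_max <= 700.0):
        raise ValueError(f"lambda_max {lambda_max} nm outside supported range [330, 700]")
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x)) + np.exp(-14.9 * (1.104 - x)) + 0.674
    )
    lam_b = 189.0 + 0.315 * lambda_max
    b_b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((grid - lam_b) / b_b) ** 2))
    v = alpha + beta
    v = v / v.max()
    return Spectrum(grid, v, unit="sensitivity", name=f"pigment_{lambda_max:g}nm")


@dataclass(frozen=True)
class OilDroplet:
    """Oil-droplet filter: tabulated transmittance or a parametric long-pass.

    The parametric form is a Gompertz cutoff
    ``T(λ) = exp(−exp(−slope·(λ − cut_nm)))`` — a smooth long-pass filter
    whose transmittance is 1/e at ``cut_nm`` and saturates at 1.
    """

    cut_nm: float | None = None
    slope: float = 0.08
    table: Spectrum | None = None

    def transmittance(self, grid) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        if self.table is not None:
            return np.clip(resample(self.table, grid).values, 0.0, 1.0)
        if self.cut_nm is None:
            return np.ones_like(grid)  # transparent droplet (typical for the VS cone)
        return np.exp(-np.exp(-self.slope * (grid - self.cut_nm)))


@dataclass(frozen=True)
class ConeClass:
    """One single-cone class: pigment peak, oil droplet, relative density."""

    name: str
    lambda_max: float
    oil_droplet: OilDroplet = field(default_factory=OilDroplet)
    relative_density: float = 1.0

    def __post_init__(self):
        if self.relative_density <= 0 or not np.isfinite(self.relative_density):
            raise ValueError(f"cone {self.name!r}: relative_density must be positive")


@dataclass(frozen=True)
class OcularMedia:
    """Combined cornea/lens/humor transmittance, max-normalized to 1."""

    transmittance: Spectrum
    lambda_t50: float
    fit_params: tuple | None = None

    def on_grid(self, grid) -> np.ndarray:
        return np.clip(resample(self.transmittance, grid).values, 0.0, 1.0)


@dataclass(frozen=True)
class VisualSystem:
    """Cone classes + ocular media + Weber fraction of the most abundant cone."""

    cones: tuple
    ocular: OcularMedia | None = None
    weber_fraction: float = 0.1
    name: str = ""

    def __post_init__(self):
        if len(self.cones) < 2:
            raise ValueError("a visual system needs at least 2 cone classes")
        if not (0.0 < self.weber_fraction < 1.0):
            raise ValueError("weber_fraction must lie in (0, 1)")
        object.__setattr__(self, "cones", tuple(self.cones))

    @property
    def n_cones(self) -> int:
        return len(self.cones)

    @property
    def densities(self) -> np.ndarray:
        return np.array([c.relative_density for c in self.cones])

    def sensitivities(self, grid=None) -> list[Spectrum]:
        grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
        return [receptor_sensitivity(c, self.ocular, grid) for c in self.cones]


def _logistic4(lam, lo, hi, mid, scale):
    # clip the exponent: curve_fit explores extreme (mid, scale) values
    z = np.clip((lam - mid) / scale, -500.0, 500.0)
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def _first_upward_crossing(grid: np.ndarray, v: np.ndarray, level: float = 0.5) -> float:
    """Lowest-wavelength upward crossing of ``level``, linearly interpolated."""
    above = v >= level
    if not above.any():
        raise ValueError("transmittance never reaches the 0.5 level; no cutoff")
    idx = int(np.argmax(above))
    if idx == 0:
        raise ValueError(
            "no upward 0.5 crossing: transmittance already above the level at "
            "the short-wavelength end, so no cutoff is measurable in range"
        )
    lo_v, hi_v = v[idx - 1], v[idx]
    if hi_v == lo_v:
        return float(grid[idx])
    frac = (level - lo_v) / (hi_v - lo_v)
    return float(grid[idx - 1] + frac * (grid[idx] - grid[idx - 1]))


def ocular_media_from_scans(scans, grid=None) -> OcularMedia:
    """Average transmittance scans, normalize to 1 and locate λT0.5.

    A four-parameter logistic is least-squares fitted to the normalized mean
    curve; below λT0.5 the raw (noisy) values are replaced by the fitted
    sigmoid. If the sigmoid fit fails (e.g. on degenerate step inputs) the
    raw curve is kept with a warning.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("need at least one transmittance scan")
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    resampled = [resample(s, grid) for s in scans]
    mean = average_spectra(resampled)
    mean = normalize_peak(mean, 1.0)
    lam50 = _first_upward_crossing(grid, mean.values, 0.5)

    values = mean.values.copy()
    fit_params = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _logistic4,
                grid,
                values,
                p0=(float(values.min()), 1.0, lam50, 8.0),
                maxfev=5000,
            )
        if popt[3] > 0 and popt[1] > popt[0]:  # keep only a monotone increasing fit
            fitted = np.clip(_logistic4(grid, *popt), 0.0, 1.0)
            below = grid < lam50
            values[below] = fitted[below]
            fit_params = tuple(float(p) for p in popt)
    except RuntimeError:
        warnings.warn("ocular media sigmoid fit failed; keeping raw curve", stacklevel=2)

    values = np.clip(values, 0.0, None)
    out = Spectrum(grid, values, unit="transmittance", name="ocular_media")
    out = normalize_peak(out, 1.0)
    return OcularMedia(transmittance=out, lambda_t50=lam50, fit_params=fit_params)


def receptor_sensitivity(cone: ConeClass, ocular: OcularMedia | None, grid=None) -> Spectrum:
    """S_i(λ) = A_i(λ)·D_i(λ)·O(λ), renormalized to peak 1."""
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    pigment = pigment_template(cone.lambda_max, grid).values
    droplet = cone.oil_droplet.transmittance(grid)
    omedia = np.ones_like(grid) if ocular is None else ocular.on_grid(grid)
    v = pigment * droplet * omedia
    if v.max() <= 0:
        raise ValueError(f"cone {cone.name!r}: sensitivity is zero everywhere on the grid")
    return Spectrum(grid, v / v.max(), unit="sensitivity", name=f"S_{cone.name}")


def load_visual_system(path) -> VisualSystem:
    """Load a visual-system config (YAML).

    Schema::

        name: goose-like
        weber_fraction: 0.1
        ocular_media: path/to/scan.csv         # optional; single CSV or list
        cones:
          - {name: VS,  lambda_max: 409, density: 1.0}
          - {name: SWS, lambda_max: 458, density: 1.9, droplet_cut: 415}
          - {name: MWS, lambda_max: 509, density: 2.2, droplet_cut: 480,
             droplet_slope: 0.08}
    """
    from .spectra import read_spectrum

    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    cones = []
    for c in cfg["cones"]:
        droplet = OilDroplet(
            cut_nm=c.get("droplet_cut"),
            slope=float(c.get("droplet_slope", 0.08)),
        )
        cones.append(
            ConeClass(
                name=str(c["name"]),
                lambda_max=float(c["lambda_max"]),
                oil_droplet=droplet,
                relative_density=float(c.get("density", 1.0)),
            )
        )
    ocular = None
    om = cfg.get("ocular_media")
    if om:
        paths = om if isinstance(om, list) else [om]
        scans = [read_spectrum(p, unit="transmittance") for p in paths]
        ocular = ocular_media_from_scans(scans)
    return VisualSystem(
        cones=tuple(cones),
        ocular=ocular,
        weber_fraction=float(cfg.get("weber_fraction", 0.1)),
        name=str(cfg.get("name", "")),
    )
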