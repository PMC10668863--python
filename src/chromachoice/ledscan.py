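"""LED stimulus design: the peak-shift contrast scan and radiometric matching.

The design procedure: take a measured LED emission spectrum as a template,
rigidly translate its peak across the working range (300–700 nm in 2-nm
steps → 201 simulated LEDs), peak-normalize every spectrum to the same
photon count (4000), score each LED's chromatic contrast against a sky
background with the RNL model, and pick candidate peak wavelengths at the
local maxima of the contrast curve. Finally, among the available intensity
settings of the two built stimuli, choose the pair whose peak photon
outputs are radiometrically most similar, so that the colors differ in
wavelength but not in photons delivered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rnl import chromatic_contrast
from .spectra import Spectrum, WORKING_GRID, normalize_peak, total_photon_output
from .visual import VisualSystem

__all__ = [
    "ScanResult",
    "ChosenSetting",
    "StimulusChoice",
    "simulate_led_series",
    "contrast_scan",
    "select_candidate_peaks",
    "radiometric_match",
]


@dataclass(frozen=True)
class ScanResult:
    """Per-peak-wavelength JND table from the LED scan."""

    table: pd.DataFrame  # columns: peak_nm, delta_s_jnd
    background_id: str = ""
    visual_system_id: str = ""

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def peaks(self) -> np.ndarray:
        return self.table["peak_nm"].to_numpy()

    @property
    def delta_s(self) -> np.ndarray:
        return self.table["delta_s_jnd"].to_numpy()


def simulate_led_series(
    template: Spectrum,
    start: float = 300.0,
    stop: float = 700.0,
    step: float = 2.0,
    peak_target: float = 4000.0,
    grid=None,
) -> list[Spectrum]:
    """Rigidly shift the template peak to start, start+step, …, stop.

    Each shifted spectrum is interpolated onto the working grid (tails
    falling off the grid truncate to 0) and then peak-normalized to
    ``peak_target`` photons, so every simulated LED has the same peak count.
    """
    if step <= 0 or start > stop:
        raise ValueError("need start <= stop and step > 0")
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    t_peak = template.peak_wavelength
    if template.values.max() <= 0:
        raise ValueError("template has no positive peak")
    peaks = np.arange(start, stop + step / 2, step)
    out = []
    for p in peaks:
        shifted_wl = template.wavelengths + (p - t_peak)
        v = np.interp(grid, shifted_wl, template.values, left=0.0, right=0.0)
        if v.max() <= 0:
            raise ValueError(f"shifted template at {p:g} nm has no support on the grid")
        led = Spectrum(grid, v, unit="photon_flux", name=f"led_{p:g}nm")
        out.append(normalize_peak(led, peak_target))
    return out


def contrast_scan(leds, background: Spectrum, vs: VisualSystem) -> ScanResult:
    """One (peak wavelength, ΔS) row per LED against the background.

    LEDs producing a zero quantum catch in some cone are recorded with a
    missing ΔS and a warning instead of aborting the scan.
    """
    leds = list(leds)
    if not leds:
        raise ValueError("empty LED list")
    rows = []
    for led in leds:
        try:
            ds = chromatic_contrast(led, background, vs).delta_s
        except ValueError as exc:
            warnings.warn(f"LED at {led.peak_wavelength:g} nm skipped: {exc}", stacklevel=2)
            ds = np.nan
        rows.append((led.peak_wavelength, ds))
    table = pd.DataFrame(rows, columns=["peak_nm", "delta_s_jnd"])
    return ScanResult(table=table, background_id=background.name, visual_system_id=vs.name)


def select_candidate_peaks(
    scan: ScanResult, min_separation: float = 60.0, include_edges: bool = True
) -> list[float]:
    """Local maxima of the ΔS curve, greedily thinned to a minimum separation.

    Candidates are kept in decreasing ΔS order subject to pairwise separation
    ≥ ``min_separation``; ties break toward the shorter wavelength. A scan
    with no strict local maximum (e.g. perfectly flat) returns the global
    argmax (shortest wavelength on ties) with a warning.

    ``include_edges=False`` drops the first/last grid point from candidacy:
    a maximum at the scan boundary is usually a truncation artifact, not a
    relative peak of the contrast curve.
    """
    tab = scan.table.dropna(subset=["delta_s_jnd"])
    if tab.empty:
        raise ValueError("all ΔS values are missing; nothing to select")
    wl = tab["peak_nm"].to_numpy()
    v = tab["delta_s_jnd"].to_numpy()
    n = v.size
    cand = []
    for i in range(n):
        if not include_edges and (i == 0 or i == n - 1):
            continue
        if i == 0:
            is_cand = n > 1 and v[0] > v[1]
        elif i == n - 1:
            is_cand = v[n - 1] > v[n - 2]
        else:
            is_cand = (
                v[i] >= v[i - 1]
                and v[i] >= v[i + 1]
                and (v[i] > v[i - 1] or v[i] > v[i + 1])
            )
        if is_cand:
            cand.append(i)
    if not cand:
        warnings.warn("no strict local maximum in scan (flat?); returning global argmax", stacklevel=2)
        cand = [int(np.argmax(v))]  # argmax takes the first (shortest λ) on ties
    # greedy: highest ΔS first, shorter wavelength on ties
    cand.sort(key=lambda i: (-v[i], wl[i]))
    kept: list[float] = []
    for i in cand:
        if all(abs(wl[i] - k) >= min_separation for k in kept):
            kept.append(float(wl[i]))
    return sorted(kept)


@dataclass(frozen=True)
class ChosenSetting:
    label: str
    peak_nm: float
    peak_photons: float
    total_photons: float


@dataclass(frozen=True)
class StimulusChoice:
    """The radiometrically matched pair: one intensity setting per color."""

    setting_a: ChosenSetting
    setting_b: ChosenSetting

    @property
    def relative_peak_difference(self) -> float:
        pa, pb = self.setting_a.peak_photons, self.setting_b.peak_photons
        return abs(pa - pb) / max(pa, pb)


def radiometric_match(settings_a, settings_b) -> StimulusChoice:
    """Pick one setting per color minimizing the relative peak-photon difference.

    ``settings_a``/``settings_b`` are lists of ``(label, Spectrum)`` pairs in
    photon-flux units (the intensity ladder of each built stimulus).
    """
    settings_a, settings_b = list(settings_a), list(settings_b)
    if not settings_a or not settings_b:
        raise ValueError("need at least one intensity setting per color")

    def _describe(label, spec):
        if spec.unit != "photon_flux":
            raise ValueError(f"setting {label!r} must be photon_flux, got {spec.unit!r}")
        return ChosenSetting(
            label=str(label),
            peak_nm=spec.peak_wavelength,
            peak_photons=float(spec.values.max()),
            total_photons=total_photon_output(spec),
        )

    best = None
    for la, sa in settings_a:
        for lb, sb in settings_b:
            ca, cb = _describe(la, sa), _describe(lb, sb)
            choice = StimulusChoice(ca, cb)
            if best is None or choice.relative_peak_difference < best.relative_peak_difference:
                best = choice
    return best
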