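"""Synthetic spectra and choice-trial datasets with the structure the
analysis assumes.

The spectral generators stand in for spectroradiometer exports: a smooth
unimodal LED emission template, smooth clear/cloudy sky photon radiance,
and sigmoidal ocular-media transmittance scans with instrument noise. The
choice-trial generator reproduces the experimental design — every bird sees
all four color×frequency cells twice, once per arena side, across eight
trials — with logistic treatment effects on avoidance, correlated paired
ambient-light covariates, gamma latencies capped by the 10-minute rule,
Poisson movement counts, and Gaussian individual random intercepts.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .spectra import Spectrum, WORKING_GRID, normalize_peak
from .visual import ConeClass, OcularMedia, OilDroplet, VisualSystem, ocular_media_from_scans

__all__ = [
    "synth_led_template",
    "synth_sky",
    "synth_ocular_scans",
    "synth_visual_system",
    "ChoiceSimParams",
    "synth_choice_dataset",
    "synth_side_bias_dataset",
]


def synth_led_template(peak: float = 525.0, fwhm: float = 30.0, grid=None,
                       floor: float = 1e-3) -> Spectrum:
    """Asymmetric-Gaussian LED emission with unit peak.

    The long-wavelength flank is slightly broader than the short one, as in
    real InGaN/AlGaInP emitters; ``fwhm`` is the full width at half maximum.
    ``floor`` is a broadband stray-light pedestal (fraction of the peak):
    spectroradiometer exports of real emitters never fall to exactly zero,
    and without it narrowband stimuli far from every cone peak produce
    pathologically extreme log catch ratios.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    if not (grid[0] <= peak <= grid[-1]):
        raise ValueError(f"peak {peak} nm outside grid")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sig_left, sig_right = 0.9 * sigma, 1.1 * sigma
    s = np.where(grid < peak, sig_left, sig_right)
    v = np.exp(-0.5 * ((grid - peak) / s) ** 2) + floor
    v = v / v.max()
    return Spectrum(grid, v, unit="photon_flux", name=f"led_template_{peak:g}nm")


def _planck_photons(grid_nm: np.ndarray, temp_k: float) -> np.ndarray:
    """Blackbody photon radiance shape (arbitrary scale)."""
    lam = grid_nm * 1e-9
    hckt = 6.62607015e-34 * 2.99792458e8 / (1.380649e-23 * temp_k)
    return 1.0 / (lam ** 4 * np.expm1(hckt / lam))


def synth_sky(condition: str = "clear", seed: int = 0, grid=None,
              total_photons: float = 1.0e6) -> Spectrum:
    """Smooth positive sky photon radiance; cloudy is flatter and dimmer.

    Clear sky: a 5800 K daylight shape with a Rayleigh-scattering blue tilt.
    Cloudy sky: the same shape mixed toward spectrally flat grey and scaled
    to 45% of the clear total. A small seeded low-order sinusoidal ripple
    (±3%) emulates measurement-to-measurement structure.
    """
    if condition not in ("clear", "cloudy"):
        raise ValueError("condition must be 'clear' or 'cloudy'")
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    base = _planck_photons(grid, 5800.0)
    base = base / base.max()
    rayleigh = (450.0 / grid) ** 2
    clear = base * (0.55 + 0.45 * rayleigh / rayleigh.max())
    if condition == "cloudy":
        shape = 0.5 * clear + 0.5 * clear.mean()
        scale = 0.45
    else:
        shape = clear
        scale = 1.0
    rng = np.random.default_rng(seed)
    ripple = np.ones_like(grid)
    x = (grid - grid[0]) / (grid[-1] - grid[0])
    for k in range(1, 4):
        amp = 0.03 * rng.uniform(0, 1) / k
        ripple += amp * np.sin(2 * np.pi * k * x + rng.uniform(0, 2 * np.pi))
    v = np.clip(shape * ripple, 1e-9, None)
    v = v * (scale * total_photons / v.sum())
    return Spectrum(grid, v, unit="photon_flux", name=f"sky_{condition}")


def synth_ocular_scans(
    n_scans: int = 20,
    midpoint: float = 369.0,
    slope: float = 8.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    grid=None,
) -> list:
    """Noisy logistic transmittance scans with a known 50% cutoff."""
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_scans):
        clean = 1.0 / (1.0 + np.exp(-(grid - midpoint) / slope))
        gain = rng.uniform(0.9, 1.1)  # instrument gain varies between scans
        noisy = np.clip(gain * clean + rng.normal(0, noise_sd, grid.size), 0.0, None)
        out.append(Spectrum(grid, noisy, unit="transmittance", name=f"scan_{i}"))
    return out


def synth_visual_system(n_cones: int = 4, seed: int = 0, weber_fraction: float = 0.1) -> VisualSystem:
    """A goose-like violet-sensitive tetrachromat (placeholder parameter set).

    Default four single-cone classes with pigment peaks spread over
    405–570 nm, long-pass oil droplets on all but the shortest cone,
    plausible relative densities, ω = 0.1, and a logistic ocular medium with
    its 50% cutoff near 369 nm. A small seeded jitter (±1 nm on pigment
    peaks) distinguishes replicate systems while staying reproducible.
    """
    if n_cones < 2:
        raise ValueError("need at least two cone classes")
    rng = np.random.default_rng(seed)
    base_names = ["VS", "SWS", "MWS", "LWS"]
    peaks = np.linspace(405.0, 570.0, n_cones)
    densities = np.linspace(1.0, 2.2, n_cones)
    cones = []
    for i in range(n_cones):
        lam = float(peaks[i] + rng.uniform(-1.0, 1.0))
        cut = None if i == 0 else float(lam - 55.0)
        name = base_names[i] if i < len(base_names) else f"C{i}"
        cones.append(
            ConeClass(
                name=name,
                lambda_max=lam,
                oil_droplet=OilDroplet(cut_nm=cut, slope=0.08),
                relative_density=float(densities[i]),
            )
        )
    scans = synth_ocular_scans(n_scans=5, midpoint=369.0, noise_sd=0.005,
                               seed=int(rng.integers(2 ** 31)))
    ocular = ocular_media_from_scans(scans)
    return VisualSystem(cones=tuple(cones), ocular=ocular,
                        weber_fraction=weber_fraction, name=f"synthetic_vs_seed{seed}")


# --------------------------------------------------------------------------
# choice-trial simulation
# --------------------------------------------------------------------------

#: Default per-cell avoidance probabilities, echoing the observed trends:
#: red starts strongly avoided and decays to attraction (mere-exposure),
#: blue follows a U-shape and settles at weak avoidance.
_DEFAULT_AVOID_PROBS = {
    "red": [0.90, 0.80, 0.65, 0.50, 0.35, 0.20, 0.12, 0.08],
    "blue": [0.27, 0.70, 0.65, 0.40, 0.35, 0.65, 0.65, 0.65],
}

#: Default latency means (s): red faster than blue, pulsing faster than steady.
_LATENCY_COLOR = {"red": 0.82, "blue": 1.18}
_LATENCY_FREQ = {"pulsing": 0.66, "steady": 1.34}
_LATENCY_BASE_S = 35.0

_HEAD_RATE = {"red": 1.20, "blue": 1.06}    # events/s
_BODY_RATE_BASE = 0.35                       # rises with trial order, then plateaus


def _default_beta_table() -> dict:
    return {
        (color, order): float(np.log(p / (1 - p)))
        for color, probs in _DEFAULT_AVOID_PROBS.items()
        for order, p in enumerate(probs, start=1)
    }


@dataclass
class ChoiceSimParams:
    """Generating parameters of the synthetic choice experiment.

    Defaults are the study conditions: 19 birds completing all 8 trials,
    ambient lux correlation 0.83 between the two arena sides, a small
    between-individual SD on the avoidance log-odds (σ_b = 0.2, echoing the
    near-zero between-individual variation in binary choices), and per-cell
    avoidance log-odds following the observed color-by-order reversal.
    """

    n_birds: int = 19
    trials_per_bird: int = 8
    beta_table: dict = field(default_factory=_default_beta_table)
    color_order_reversal: float = 0.0   # ± on the color log-odds, flipping at mid-sequence
    freq_ambient_coef: float = 0.6      # pulsing(+1)/steady(−1) × standardized ambient
    sigma_b: float = 0.2
    lux_correlation: float = 0.83
    lux_log_mean: float = np.log(900.0)
    lux_log_sd: float = 0.8
    latency_shape: float = 1.2
    latency_sigma_b: float = 0.40       # log-scale individual effect on latency
    movement_sigma_b: float = 0.08      # log-scale individual effect on rates
    mistrial_prob: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")
        if not (-1.0 < self.lux_correlation < 1.0):
            raise ValueError("lux correlation must lie in (−1, 1)")
        if self.trials_per_bird != 8:
            raise ValueError("the design is 8 trials per bird (4 cells × 2 sides)")

    def cell_logit(self, color: str, order: int) -> float:
        logit = self.beta_table.get((color, order), 0.0)
        if self.color_order_reversal:
            sign = -1.0 if order <= self.trials_per_bird // 2 else 1.0
            color_sign = 1.0 if color == "red" else -1.0
            logit += sign * color_sign * self.color_order_reversal / 2.0
        return logit


def _schedule(rng: np.random.Generator) -> list:
    """One bird's 8 trials: each color×frequency cell twice, once per side."""
    cells = [(c, f) for c in ("blue", "red") for f in ("steady", "pulsing")]
    first = list(rng.permutation(4))
    sides = {i: rng.choice(["left", "right"]) for i in range(4)}
    second = list(rng.permutation(4))
    flip = {"left": "right", "right": "left"}
    sched = []
    for order, i in enumerate(first, start=1):
        sched.append((order, *cells[i], sides[i]))
    for order, i in enumerate(second, start=5):
        sched.append((order, *cells[i], flip[sides[i]]))
    return sched


def synth_choice_dataset(params: ChoiceSimParams | None = None) -> pd.DataFrame:
    """Simulate the single-choice trial table.

    Per bird: a Gaussian random intercept on the avoidance log-odds;
    counterbalanced treatment schedule; bivariate-lognormal ambient lux with
    the requested correlation; avoidance ~ Bernoulli(logistic(cell logit +
    frequency×ambient interaction + intercept)); latency ~ gamma capped at
    600 s (capped trials become mistrials and are dropped); head/body counts
    ~ Poisson over the visible duration. Columns follow the trial-table CSV
    schema.
    """
    p = params or ChoiceSimParams()
    rng = np.random.default_rng(p.seed)
    # lux_correlation is the raw-scale Pearson target; a lognormal pair with
    # log-scale correlation rho_log has raw correlation
    # (exp(rho_log s^2)-1)/(exp(s^2)-1), inverted here
    s2 = p.lux_log_sd ** 2
    rho_log = float(np.log1p(p.lux_correlation * np.expm1(s2)) / s2)
    rho_log = float(np.clip(rho_log, -0.999, 0.999))
    cov = np.array([[1.0, rho_log], [rho_log, 1.0]])
    chol = np.linalg.cholesky(cov)
    rows = []
    for bird in range(p.n_birds):
        bird_id = f"G{bird + 1:02d}"
        b_avoid = rng.normal(0.0, p.sigma_b)
        b_lat = rng.normal(0.0, p.latency_sigma_b)
        b_move = rng.normal(0.0, p.movement_sigma_b)
        for order, color, freq, side in _schedule(rng):
            z = chol @ rng.standard_normal(2)
            lux_on, lux_off = np.exp(p.lux_log_mean + p.lux_log_sd * z)
            # standardized ambient score of the pair (what PCA1 estimates)
            ambient = float(z.sum() / np.sqrt(2.0 * (1.0 + rho_log)))
            freq_sign = 1.0 if freq == "pulsing" else -1.0
            eta = p.cell_logit(color, order) + p.freq_ambient_coef * freq_sign * ambient + b_avoid
            avoid = int(rng.random() < expit(eta))

            mean_lat = _LATENCY_BASE_S * _LATENCY_COLOR[color] * _LATENCY_FREQ[freq] * np.exp(b_lat)
            latency = rng.gamma(p.latency_shape, mean_lat / p.latency_shape)
            if latency > 600.0 or rng.random() < p.mistrial_prob:
                continue  # mistrial: no choice within 10 min; no measurements taken
            latency = max(latency, 2.0)
            visible = max(0.8 * latency, 2.0)
            head_rate = _HEAD_RATE[color] * np.exp(b_move)
            body_rate = (_BODY_RATE_BASE + 0.10 * min(order, 3) / 3.0 * 1.5) * np.exp(b_move)
            head_events = int(rng.poisson(head_rate * visible))
            body_events = int(rng.poisson(body_rate * visible))
            minutes = int(rng.uniform(9 * 60 + 30, 17 * 60))
            rows.append(
                {
                    "bird_id": bird_id,
                    "trial_order": order,
                    "color": color,
                    "frequency": freq,
                    "light_side": side,
                    "choice_avoid": avoid,
                    "latency_s": round(float(latency), 2),
                    "head_events": head_events,
                    "body_events": body_events,
                    "visible_s": round(float(visible), 2),
                    "lux_on": round(float(lux_on), 1),
                    "lux_off": round(float(lux_off), 1),
                    "temp_C": round(float(rng.normal(1.0, 4.0)), 1),
                    "time": f"{minutes // 60:02d}:{minutes % 60:02d}",
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("simulation produced no completed trials")
    return df


def synth_side_bias_dataset(
    n_birds: int = 23,
    trials_per_bird: int = 3,
    p_right: float = 0.41,
    sigma_b: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """No-light control trials for the side-bias test (right=1/left=0)."""
    rng = np.random.default_rng(seed)
    logit = np.log(p_right / (1 - p_right))
    rows = []
    for bird in range(n_birds):
        b = rng.normal(0.0, sigma_b)
        for t in range(1, trials_per_bird + 1):
            pr = expit(logit + b)
            rows.append(
                {
                    "bird_id": f"G{bird + 1:02d}",
                    "trial": t,
                    "chose_right": int(rng.random() < pr),
                }
            )
    return pd.DataFrame(rows)
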