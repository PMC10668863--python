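"""Statistical pipeline for the repeated-measures single-choice experiment.

The sequence mirrors how such choice-test data are analyzed in practice:

1. screen the measured confounders for collinearity (Pearson r),
2. summarize the correlated pair of ambient-light readings (lux on the lit
   and unlit sides) into one principal component, PCA1,
3. test for arena side bias with an intercept-only logistic GLMM,
4. fit mixed models for each response with a four-step stepwise evaluation
   of the two-way interactions (color×frequency; color×order and
   frequency×order; color×PCA1 and frequency×PCA1; then the final model
   keeping only the survivors),
5. report estimated marginal means, marginal/conditional R², and
   repeatability (the between-individual share of variance) with a
   parametric-bootstrap CI.

Trial order is categorical (8 levels): the design expects per-trial
patterns such as avoidance→attraction reversals, not a monotone slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.special import expit

from .glmm import (
    LATENT_LOGIT_VARIANCE,
    MixedModelFit,
    fit_mixed,
    refit_response,
    term_test,
    term_tests,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_choice_table",
    "movement_rate",
    "collinearity_screen",
    "PCAResult",
    "ambient_pca",
    "side_bias_test",
    "base_formula",
    "StepwiseReport",
    "stepwise_interaction_ladder",
    "estimated_marginal_means",
    "r2_mixed",
    "RepeatabilityEstimate",
    "repeatability",
]

REQUIRED_COLUMNS = [
    "bird_id", "trial_order", "color", "frequency", "light_side", "choice_avoid",
    "latency_s", "head_events", "body_events", "visible_s", "lux_on", "lux_off",
    "temp_C", "time",
]


def validate_choice_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the trial-table schema and basic invariants; returns the table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice table missing columns: {missing}")
    if not df["choice_avoid"].isin([0, 1]).all():
        raise ValueError("choice_avoid must be 0 (toward light) or 1 (away)")
    if not df["trial_order"].between(1, 8).all():
        raise ValueError("trial_order must lie in 1..8")
    if (df["latency_s"] > 600).any():
        raise ValueError("latency_s exceeds the 600 s (10 min) trial cap")
    if (df[["latency_s", "visible_s"]] < 0).any().any():
        raise ValueError("durations must be non-negative")
    counts = df.groupby("bird_id").size()
    if (counts > 8).any():
        bad = counts[counts > 8].index.tolist()
        raise ValueError(f"more than 8 trials for bird(s) {bad}")
    bad_color = set(df["color"]) - {"blue", "red"}
    bad_freq = set(df["frequency"]) - {"steady", "pulsing"}
    if bad_color or bad_freq:
        raise ValueError(f"unknown treatment levels: color={bad_color}, frequency={bad_freq}")
    return df


def movement_rate(event_count: int, visible_duration_s: float) -> float:
    """Movement frequency: distinct events divided by time visible (events/s)."""
    if visible_duration_s <= 0:
        raise ValueError("visible duration must be positive")
    if event_count < 0:
        raise ValueError("event count must be non-negative")
    return event_count / visible_duration_s


def collinearity_screen(df: pd.DataFrame, variables, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations among confounders, with two-sided p.

    Pairs with |r| above ``threshold`` are flagged as collinear. Constant
    variables yield a missing r with a warning.
    """
    rows = []
    variables = list(variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"constant variable in pair ({a}, {b}); r undefined", stacklevel=2)
                rows.append({"var_a": a, "var_b": b, "r": np.nan, "p_value": np.nan, "flagged": False})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"var_a": a, "var_b": b, "r": r, "p_value": p, "flagged": abs(r) > threshold})
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the ambient-light pair."""

    eigenvalues: np.ndarray
    proportion_variance: np.ndarray
    loadings: np.ndarray          # correlations between variables and components
    scores: np.ndarray            # per-trial component scores (zero mean)
    retained: list                # indices of components with eigenvalue > 1
    variables: list = field(default_factory=list)

    @property
    def pca1(self) -> np.ndarray:
        return self.scores[:, 0]


def ambient_pca(df: pd.DataFrame, columns=("lux_on", "lux_off")) -> PCAResult:
    """PCA of the standardized ambient-light readings on both arena sides.

    Eigendecomposition of the correlation matrix; components with eigenvalue
    above 1 are retained (Kaiser rule). PCA1 is oriented so that both
    loadings are positive — higher scores mean brighter ambient light on
    both sides. For two standardized variables the first eigenvalue is
    exactly 1 + r.
    """
    cols = list(columns)
    Xraw = df[cols].to_numpy(float)
    sd = Xraw.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant ambient-light column; PCA undefined")
    Z = (Xraw - Xraw.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # orient each component so the loading sum is positive
    for k in range(eigvec.shape[1]):
        if eigvec[:, k].sum() < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = Z @ eigvec
    loadings = eigvec * np.sqrt(np.clip(eigval, 0, None))
    retained = [k for k in range(len(eigval)) if eigval[k] > 1.0]
    if not retained:
        warnings.warn("no component with eigenvalue > 1 (uncorrelated pair?)", stacklevel=2)
    return PCAResult(
        eigenvalues=eigval,
        proportion_variance=eigval / eigval.sum(),
        loadings=loadings,
        scores=scores,
        retained=retained,
        variables=cols,
    )


def attach_pca1(df: pd.DataFrame, columns=("lux_on", "lux_off")) -> pd.DataFrame:
    """Return a copy of the table with the PCA1 ambient-light score as ``pca1``."""
    out = df.copy()
    out["pca1"] = ambient_pca(df, columns).pca1
    return out


def side_bias_test(df: pd.DataFrame, response: str = "chose_right", group: str = "bird_id") -> dict:
    """Intercept-only logistic GLMM for arena side bias.

    The response is right=1/left=0; a non-zero intercept indicates a bias.
    Returns intercept estimate, SE, Wald z, two-sided p, and the fit.
    """
    if not df[response].isin([0, 1]).all():
        raise ValueError(f"{response} must be coded 0/1")
    fit = fit_mixed(df, f"{response} ~ 1", family="binomial", group=group)
    est, se = float(fit.params[0]), float(fit.bse[0])
    z = est / se
    return {
        "intercept": est,
        "se": se,
        "z": z,
        "p_value": float(2 * stats.norm.sf(abs(z))),
        "fit": fit,
    }


# --------------------------------------------------------------------------
# the four-step interaction ladder
# --------------------------------------------------------------------------

_BASE_TERMS = "C(color, Sum) + C(frequency, Sum) + C(trial_order, Sum) + pca1"

_INTERACTIONS = {
    "color:frequency": "C(color, Sum):C(frequency, Sum)",
    "color:trial_order": "C(color, Sum):C(trial_order, Sum)",
    "frequency:trial_order": "C(frequency, Sum):C(trial_order, Sum)",
    "color:pca1": "C(color, Sum):pca1",
    "frequency:pca1": "C(frequency, Sum):pca1",
}


def base_formula(response: str) -> str:
    """Base model: color + frequency + trial order (categorical) + PCA1."""
    return f"{response} ~ {_BASE_TERMS}"


@dataclass
class StepwiseReport:
    """Every intermediate test of the interaction ladder."""

    steps: list = field(default_factory=list)  # dicts: step, term, statistic, df, p, kept
    kept_interactions: list = field(default_factory=list)
    final_formula: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _formula_with(response: str, interactions) -> str:
    rhs = _BASE_TERMS
    for key in interactions:
        rhs += " + " + _INTERACTIONS[key]
    return f"{response} ~ {rhs}"


def _interaction_test(fit: MixedModelFit, key: str) -> tuple:
    """(statistic, df, p) for one interaction term inside a fitted model."""
    r = term_test(fit, _INTERACTIONS[key])
    df_repr = (r["df1"], r["df2"]) if fit.family == "gaussian" else r["df1"]
    return float(r["statistic"]), df_repr, float(r["p_value"])


def stepwise_interaction_ladder(
    data: pd.DataFrame,
    response: str,
    family: str = "gaussian",
    alpha: float = 0.05,
    group: str = "bird_id",
) -> tuple:
    """Four-step evaluation of the two-way interactions.

    Step 1: base + color×frequency; drop if non-significant.
    Step 2: survivors + color×order + frequency×order; drop non-significant.
    Step 3: survivors + color×PCA1 + frequency×PCA1; drop non-significant.
    Step 4: refit base + all surviving interactions (the reported model).

    Returns ``(final_fit, StepwiseReport)``. The data must carry a ``pca1``
    column (see :func:`attach_pca1`); it is added automatically if absent.
    """
    if "pca1" not in data.columns:
        data = attach_pca1(data)
    report = StepwiseReport()
    kept: list = []
    plan = [
        (1, ["color:frequency"]),
        (2, ["color:trial_order", "frequency:trial_order"]),
        (3, ["color:pca1", "frequency:pca1"]),
    ]
    for step, candidates in plan:
        formula = _formula_with(response, kept + candidates)
        try:
            fit = fit_mixed(data, formula, family=family, group=group)
        except Exception as exc:
            raise RuntimeError(f"interaction ladder failed at step {step}: {exc}") from exc
        for key in candidates:
            stat, df_repr, p = _interaction_test(fit, key)
            keep = p < alpha
            report.steps.append(
                {"step": step, "term": key, "statistic": stat, "df": df_repr,
                 "p_value": p, "kept": keep}
            )
            if keep:
                kept.append(key)
    final_formula = _formula_with(response, kept)
    try:
        final_fit = fit_mixed(data, final_formula, family=family, group=group)
    except Exception as exc:
        raise RuntimeError(f"interaction ladder failed at step 4: {exc}") from exc
    report.kept_interactions = kept
    report.final_formula = final_formula
    return final_fit, report


# --------------------------------------------------------------------------
# estimated marginal means, R², repeatability
# --------------------------------------------------------------------------


def estimated_marginal_means(fit: MixedModelFit, factor: str) -> pd.DataFrame:
    """Least-squares means per level of ``factor`` on the response scale.

    Predictions are averaged on the link scale over a balanced grid of the
    other factors with covariates at their observed means, then
    back-transformed (delta-method SE) for the binomial family.
    """
    frame = fit.frame
    if factor not in frame.columns:
        raise ValueError(f"factor {factor!r} not in the model frame")
    factors = [c for c in ("color", "frequency", "trial_order", "light_side")
               if c in frame.columns and frame[c].nunique() > 1]
    if factor not in factors:
        factors = [factor] + factors
    grids = {f: sorted(frame[f].unique()) for f in factors}
    covariates = [c for c in frame.columns
                  if c not in factors and pd.api.types.is_numeric_dtype(frame[c])
                  and c in fit.formula]
    idx = pd.MultiIndex.from_product([grids[f] for f in factors], names=factors)
    grid = idx.to_frame(index=False)
    for c in covariates:
        grid[c] = frame[c].mean()
    (X_grid,) = patsy.build_design_matrices([fit.design_info], grid)
    X_grid = np.asarray(X_grid, dtype=float)
    rows = []
    for level in grids[factor]:
        mask = (grid[factor] == level).to_numpy()
        a = X_grid[mask].mean(axis=0)
        eta = float(a @ fit.params)
        var = float(a @ fit.cov_params @ a)
        se = np.sqrt(var)
        if fit.family == "binomial":
            mu = expit(eta)
            se_resp = mu * (1 - mu) * se  # delta method
            rows.append({"level": level, "mean": mu, "se": se_resp,
                         "link_mean": eta, "link_se": se})
        else:
            rows.append({"level": level, "mean": eta, "se": se,
                         "link_mean": eta, "link_se": se})
    return pd.DataFrame(rows)


def r2_mixed(fit: MixedModelFit) -> tuple:
    """(marginal, conditional) R² as percentages.

    marginal = Var(fixed predictions) / total; conditional adds the
    individual variance. The total includes the residual variance — the
    latent-scale π²/3 for the logistic family.
    """
    var_fixed = float(np.var(fit.fitted_fixed(), ddof=1))
    total = var_fixed + fit.var_individual + fit.var_residual
    marginal = 100.0 * var_fixed / total
    conditional = 100.0 * (var_fixed + fit.var_individual) / total
    return marginal, conditional


def _classify_repeatability(value_pct: float) -> str:
    if value_pct <= 20.0:
        return "low"
    if value_pct <= 40.0:
        return "moderate"
    return "high"


@dataclass
class RepeatabilityEstimate:
    """Between-individual share of variance, in percent, with bootstrap CI."""

    value: float
    ci_low: float
    ci_high: float
    category: str
    n_boot: int = 0


def repeatability(
    fit: MixedModelFit,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> RepeatabilityEstimate:
    """R = 100·V_individual/(V_individual + V_residual).

    The CI comes from a parametric bootstrap: ``n_boot`` datasets are
    simulated from the fitted model (fixed effects + fresh random intercepts
    and residuals), refitted, and the percentile interval of the refitted
    ratios is reported. Classification: ≤20% low, ≤40% moderate, else high.
    """
    vi, vr = fit.var_individual, fit.var_residual
    if vi + vr <= 0:
        raise ValueError("both variance components are zero; repeatability undefined")
    value = 100.0 * vi / (vi + vr)
    lo = hi = value
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        eta_fixed = fit.fitted_fixed()
        sims = []
        attempts = 0
        while len(sims) < n_boot and attempts < 2 * n_boot:
            attempts += 1
            b = rng.normal(0.0, np.sqrt(vi), size=fit.n_groups)
            eta = eta_fixed + b[fit.group_idx]
            if fit.family == "gaussian":
                y_new = eta + rng.normal(0.0, np.sqrt(fit.var_residual), size=fit.n_obs)
            else:
                y_new = rng.binomial(1, expit(eta)).astype(float)
            try:
                refit = refit_response(fit, y_new)
            except Exception:
                continue  # rare degenerate resample (e.g. separation)
            vi_b, vr_b = refit.var_individual, refit.var_residual
            sims.append(100.0 * vi_b / (vi_b + vr_b))
        if sims:
            a = (1 - ci_level) / 2
            lo, hi = np.quantile(sims, [a, 1 - a])
    return RepeatabilityEstimate(
        value=float(value),
        ci_low=float(min(lo, value)),
        ci_high=float(max(hi, value)),
        category=_classify_repeatability(value),
        n_boot=n_boot,
    )
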