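"""Random-intercept mixed models for repeated-measures choice data.

Two families, both with a single random intercept per individual:

* ``gaussian`` — linear mixed model fitted by REML. The profile REML
  criterion is optimized over the variance ratio φ = σ²_b/σ²_e (a 1-D
  search), which is exact and fast for the random-intercept structure.
  Per-term F tests use a Satterthwaite denominator-degrees-of-freedom
  approximation (the eigendecomposition form used for multi-df terms).
* ``binomial`` — logistic mixed model fitted by maximum likelihood with a
  Laplace approximation to the integrated likelihood. The joint mode of
  (β, b) is found by penalized iteratively reweighted least squares and the
  marginal likelihood is optimized over log σ_b (again 1-D). Per-term tests
  are likelihood-ratio χ² against the model without the term.

Design matrices come from patsy with sum-to-zero factor coding, so the
marginal (Type-III-style) term tests are well-defined in the presence of
interactions. Singular fits (σ²_b on the boundary) are flagged, not
discarded, since the scientific focus is on the fixed effects while the
random intercept accounts for repeated measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import expit

__all__ = ["MixedModelFit", "fit_mixed", "term_tests", "lrt", "LATENT_LOGIT_VARIANCE"]

#: Residual variance of the logistic latent scale, π²/3 (for R²/repeatability).
LATENT_LOGIT_VARIANCE = np.pi ** 2 / 3.0


# --------------------------------------------------------------------------
# fit container
# --------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    """Fixed-effect estimates, variance components and fit metadata."""

    family: str
    formula: str
    params: np.ndarray
    cov_params: np.ndarray
    param_names: list
    term_slices: dict
    var_individual: float
    var_residual: float
    loglik: float
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int
    # internals retained for refits, emmeans, bootstrap
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    group_idx: np.ndarray = field(repr=False, default=None)
    group_labels: np.ndarray = field(repr=False, default=None)
    design_info: object = field(repr=False, default=None)
    frame: pd.DataFrame = field(repr=False, default=None)
    group_col: str = "bird_id"
    blups: np.ndarray = field(repr=False, default=None)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def fixed_effects(self) -> pd.DataFrame:
        se = self.bse
        z = self.params / se
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": se,
                "z": z,
                "p_value": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.param_names,
        )

    def fitted_fixed(self) -> np.ndarray:
        """Linear predictor from fixed effects only (link scale)."""
        return self.X @ self.params


# --------------------------------------------------------------------------
# gaussian REML machinery (random intercept)
# --------------------------------------------------------------------------


class _GaussianRI:
    """Closed-form REML pieces for y = Xβ + b[g] + e with V0 = I + φ ZZ'."""

    def __init__(self, X, y, gidx, n_groups):
        self.X, self.y, self.gidx = X, y, gidx
        self.G = n_groups
        self.n, self.p = X.shape
        self.ng = np.bincount(gidx, minlength=n_groups).astype(float)
        self.SX = np.zeros((n_groups, self.p))
        np.add.at(self.SX, gidx, X)
        self.Sy = np.bincount(gidx, weights=y, minlength=n_groups)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _pieces(self, phi):
        w = phi / (1.0 + self.ng * phi)
        XtVX = self.XtX - self.SX.T @ (w[:, None] * self.SX)
        XtVy = self.Xty - self.SX.T @ (w * self.Sy)
        ytVy = self.yty - float(w @ self.Sy ** 2)
        beta = np.linalg.solve(XtVX, XtVy)
        q = ytVy - float(beta @ XtVy)
        logdetV0 = float(np.sum(np.log1p(self.ng * phi)))
        sign, logdetA = np.linalg.slogdet(XtVX)
        return beta, q, logdetV0, logdetA, XtVX

    def profile_criterion(self, log_phi):
        beta, q, ldV, ldA, _ = self._pieces(np.exp(log_phi))
        return (self.n - self.p) * np.log(max(q, 1e-300)) + ldV + ldA

    def reml_nll(self, sb2, se2):
        """−log REML likelihood at θ = (σ²_b, σ²_e), up to an additive constant."""
        phi = sb2 / se2
        _, q, ldV, ldA, _ = self._pieces(phi)
        return 0.5 * ((self.n - self.p) * np.log(se2) + ldV + ldA + q / se2)

    def cov_beta(self, sb2, se2):
        phi = sb2 / se2
        *_, XtVX = self._pieces(phi)
        return se2 * np.linalg.inv(XtVX)

    def fit(self):
        res = minimize_scalar(
            self.profile_criterion, bounds=(-14.0, 18.0), method="bounded",
            options={"xatol": 1e-10},
        )
        log_phi = float(res.x)
        phi = np.exp(log_phi)
        beta, q, ldV, ldA, XtVX = self._pieces(phi)
        se2 = q / (self.n - self.p)
        sb2 = phi * se2
        singular = log_phi <= -13.0
        if singular:
            sb2 = 0.0
        cov = se2 * np.linalg.inv(XtVX)
        loglik = -0.5 * (
            (self.n - self.p) * (np.log(se2) + 1 + np.log(2 * np.pi)) + ldV + ldA
        )
        w = phi / (1.0 + self.ng * phi)
        blups = sb2 / se2 / (1.0 + self.ng * phi) * (self.Sy - self.SX @ beta) if phi > 0 else np.zeros(self.G)
        return beta, cov, sb2, se2, loglik, singular, blups


# --------------------------------------------------------------------------
# binomial Laplace machinery (random intercept)
# --------------------------------------------------------------------------


def _bernoulli_loglik(y, eta):
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class _BinomialRI:
    def __init__(self, X, y, gidx, n_groups):
        self.X, self.y, self.gidx = X, y, gidx
        self.G = n_groups
        self.n, self.p = X.shape

    def _pirls(self, sb2, beta0=None, b0=None):
        """Joint Newton for (β, b) at fixed σ²_b. sb2=0 fits a plain GLM."""
        X, y, gidx, G = self.X, self.y, self.gidx, self.G
        beta = np.zeros(self.p) if beta0 is None else beta0.copy()
        b = np.zeros(G) if b0 is None else b0.copy()
        inv_sb2 = np.inf if sb2 <= 0 else 1.0 / sb2

        def penalized(beta, b):
            eta = X @ beta + (b[gidx] if sb2 > 0 else 0.0)
            pll = _bernoulli_loglik(y, eta)
            if sb2 > 0:
                pll -= 0.5 * float(b @ b) * inv_sb2
            return pll, eta

        pll, eta = penalized(beta, b)
        converged = False
        for _ in range(200):
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            resid = y - mu
            grad_beta = X.T @ resid
            if sb2 > 0:
                grad_b = np.bincount(gidx, weights=resid, minlength=G) - b * inv_sb2
                M = np.zeros((G, self.p))
                np.add.at(M, gidx, w[:, None] * X)
                Hbb = np.bincount(gidx, weights=w, minlength=G) + inv_sb2
                XtWX = X.T @ (w[:, None] * X)
                S = XtWX - M.T @ (M / Hbb[:, None])
                rhs = grad_beta - M.T @ (grad_b / Hbb)
                try:
                    dbeta = np.linalg.solve(S, rhs)
                except np.linalg.LinAlgError:
                    raise ValueError("singular working Hessian (possible complete separation)")
                db = (grad_b - M @ dbeta) / Hbb
                gnorm = max(np.abs(grad_beta).max(), np.abs(grad_b).max())
            else:
                XtWX = X.T @ (w[:, None] * X)
                try:
                    dbeta = np.linalg.solve(XtWX, grad_beta)
                except np.linalg.LinAlgError:
                    raise ValueError("singular working Hessian (possible complete separation)")
                db = np.zeros(G)
                S = XtWX
                gnorm = np.abs(grad_beta).max()
            step = 1.0
            for _h in range(30):
                nb, nbb = beta + step * dbeta, b + step * db
                npll, neta = penalized(nb, nbb)
                if npll >= pll - 1e-12:
                    break
                step *= 0.5
            improvement = npll - pll
            beta, b, pll, eta = nb, nbb, npll, neta
            if gnorm < 1e-7 or abs(improvement) < 1e-10:
                # either a genuine optimum or a quasi-separated plateau where
                # further Newton steps change the likelihood negligibly
                converged = gnorm < 1e-3
                break
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        sw = np.bincount(gidx, weights=w, minlength=G)
        ll = _bernoulli_loglik(y, eta)
        if sb2 > 0:
            laplace = ll - 0.5 * float(b @ b) / sb2 - 0.5 * float(np.sum(np.log1p(sb2 * sw)))
        else:
            laplace = ll
        return beta, b, laplace, S, converged, eta

    def fit(self):
        cache = {}

        def neg_ll(t):
            beta, b, lap, *_ = self._pirls(np.exp(t))
            cache[t] = lap
            return -lap

        res = minimize_scalar(neg_ll, bounds=(-9.0, 4.0), method="bounded",
                              options={"xatol": 1e-4})
        t_hat = float(res.x)
        sb2 = np.exp(t_hat)
        singular = t_hat <= -8.5
        # compare against the boundary (plain GLM) fit
        beta0, b0, lap0, S0, conv0, eta0 = self._pirls(0.0)
        if singular or lap0 >= -res.fun - 1e-9:
            beta, b, lap, S, conv, eta = beta0, b0, lap0, S0, conv0, eta0
            sb2, singular = 0.0, True
        else:
            beta, b, lap, S, conv, eta = self._pirls(sb2)
        mu = expit(eta)
        if np.all(np.abs(self.y - mu) < 1e-6):
            raise ValueError(
                "complete separation: every outcome is perfectly predicted and "
                "the fitted log-odds diverge"
            )
        cov = np.linalg.inv(S)
        return beta, cov, sb2, lap, conv, b, singular


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------


def _design(formula, data):
    y, X = patsy.dmatrices(formula, data, return_type="dataframe", NA_action="raise")
    yv = np.asarray(y).ravel().astype(float)
    di = X.design_info
    slices = {t: list(range(s.start, s.stop)) for t, s in di.term_name_slices.items()}
    return yv, np.asarray(X, dtype=float), list(di.column_names), slices, di


def fit_mixed(
    data: pd.DataFrame,
    formula: str,
    family: str = "gaussian",
    group: str = "bird_id",
) -> MixedModelFit:
    """Fit a random-intercept mixed model.

    ``formula`` is a patsy fixed-effects formula (e.g.
    ``"latency_s ~ C(color, Sum) + C(frequency, Sum) + C(trial_order, Sum) + pca1"``);
    the random intercept is on ``group``. Binary responses must be 0/1.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    if group not in data.columns:
        raise ValueError(f"grouping column {group!r} not in data")
    data = data.reset_index(drop=True)
    yv, X, names, slices, di = _design(formula, data)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (aliased term)")
    codes, labels = pd.factorize(data[group])
    G = len(labels)
    if family == "gaussian":
        eng = _GaussianRI(X, yv, codes, G)
        beta, cov, sb2, se2, ll, singular, blups = eng.fit()
        converged = True
        var_resid = se2
    else:
        if not np.isin(yv, [0.0, 1.0]).all():
            raise ValueError("binomial response must be coded 0/1")
        eng = _BinomialRI(X, yv, codes, G)
        beta, cov, sb2, ll, converged, blups, singular = eng.fit()
        var_resid = LATENT_LOGIT_VARIANCE
    fit = MixedModelFit(
        family=family,
        formula=formula,
        params=beta,
        cov_params=cov,
        param_names=names,
        term_slices=slices,
        var_individual=float(sb2),
        var_residual=float(var_resid),
        loglik=float(ll),
        converged=bool(converged),
        singular=bool(singular),
        n_obs=X.shape[0],
        n_groups=G,
        X=X,
        y=yv,
        group_idx=codes,
        group_labels=np.asarray(labels),
        design_info=di,
        frame=data,
        group_col=group,
        blups=blups,
    )
    if fit.singular:
        warnings.warn(
            "random-intercept variance estimated at the boundary (singular fit); "
            "fixed effects remain interpretable",
            stacklevel=2,
        )
    return fit


def refit_response(fit: MixedModelFit, y_new: np.ndarray) -> MixedModelFit:
    """Refit the same design with a new response (used by the bootstrap)."""
    if fit.family == "gaussian":
        eng = _GaussianRI(fit.X, np.asarray(y_new, float), fit.group_idx, fit.n_groups)
        beta, cov, sb2, se2, ll, singular, blups = eng.fit()
        var_resid, converged = se2, True
    else:
        eng = _BinomialRI(fit.X, np.asarray(y_new, float), fit.group_idx, fit.n_groups)
        beta, cov, sb2, ll, converged, blups, _sing = eng.fit()
        var_resid = LATENT_LOGIT_VARIANCE
    out = MixedModelFit(
        family=fit.family, formula=fit.formula, params=beta, cov_params=cov,
        param_names=fit.param_names, term_slices=fit.term_slices,
        var_individual=float(sb2), var_residual=float(var_resid), loglik=float(ll),
        converged=bool(converged), singular=bool(sb2 == 0.0), n_obs=fit.n_obs,
        n_groups=fit.n_groups, X=fit.X, y=np.asarray(y_new, float),
        group_idx=fit.group_idx, group_labels=fit.group_labels,
        design_info=fit.design_info, frame=fit.frame, group_col=fit.group_col,
        blups=blups,
    )
    return out


def lrt(fit_full: MixedModelFit, fit_reduced: MixedModelFit) -> tuple:
    """Likelihood-ratio χ² between nested binomial fits: (stat, df, p)."""
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    df = len(fit_full.params) - len(fit_reduced.params)
    return max(stat, 0.0), df, float(stats.chi2.sf(max(stat, 0.0), df))


# --------------------------------------------------------------------------
# Satterthwaite F tests (gaussian)
# --------------------------------------------------------------------------


def _satterthwaite_F(fit: MixedModelFit, cols: list) -> tuple:
    """(F, df1, df2, p) for the multi-df contrast selecting ``cols``.

    Eigendecomposition form: decompose the contrast covariance, convert to
    independent 1-df t², F is their mean; each 1-df denominator df comes from
    ν = 2f²/(g'Ag) with f the contrast variance, g its gradient in
    θ=(σ²_b, σ²_e) and A the asymptotic covariance of θ̂.
    """
    eng = _GaussianRI(fit.X, fit.y, fit.group_idx, fit.n_groups)
    theta = np.array([fit.var_individual, fit.var_residual])
    q = len(cols)
    fallback_ddf = fit.n_obs - fit.X.shape[1]

    C = fit.cov_params
    M = C[np.ix_(cols, cols)]
    d, P = np.linalg.eigh(M)
    order = np.argsort(d)[::-1]
    d, P = d[order], P[:, order]
    bt = P.T @ fit.params[cols]
    t2 = bt ** 2 / np.clip(d, 1e-300, None)
    F = float(np.sum(t2) / q)

    if fit.singular or theta[0] <= 0:
        ddf = float(fallback_ddf)
        return F, q, ddf, float(stats.f.sf(F, q, ddf))

    # asymptotic covariance of the variance components
    h = np.maximum(1e-8, 1e-4 * theta)
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = (
                eng.reml_nll(*tpp) - eng.reml_nll(*tpm) - eng.reml_nll(*tmp) + eng.reml_nll(*tmm)
            ) / (4 * h[i] * h[j])
    try:
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        ddf = float(fallback_ddf)
        return F, q, ddf, float(stats.f.sf(F, q, ddf))
    if not np.all(np.isfinite(A)):
        ddf = float(fallback_ddf)
        return F, q, ddf, float(stats.f.sf(F, q, ddf))

    nus = []
    for k in range(q):
        a = np.zeros(fit.X.shape[1])
        a[cols] = P[:, k]

        def fvar(sb2, se2, a=a):
            return float(a @ eng.cov_beta(sb2, se2) @ a)

        g = np.zeros(2)
        for i in range(2):
            tp = theta.copy(); tp[i] += h[i]
            tm = theta.copy(); tm[i] = max(tm[i] - h[i], 1e-12)
            g[i] = (fvar(*tp) - fvar(*tm)) / (tp[i] - tm[i])
        denom = float(g @ A @ g)
        nus.append(2 * fvar(*theta) ** 2 / denom if denom > 0 else np.inf)

    E = sum(nu / (nu - 2) for nu in nus if nu > 2)
    if E > q:
        ddf = 2 * E / (E - q)
    else:
        ddf = float(fallback_ddf)
    ddf = min(ddf, 1e7)
    return F, q, float(ddf), float(stats.f.sf(F, q, ddf))


def term_test(fit: MixedModelFit, term: str) -> dict:
    """Significance test for a single model term.

    gaussian → Satterthwaite F on the term's contrast; binomial →
    likelihood-ratio χ² against the refit without the term's columns.
    """
    if term not in fit.term_slices:
        raise ValueError(f"term {term!r} not in model ({list(fit.term_slices)})")
    cols = fit.term_slices[term]
    if fit.family == "gaussian":
        F, df1, df2, p = _satterthwaite_F(fit, cols)
        return {"term": term, "statistic": F, "df1": df1, "df2": df2, "p_value": p}
    keep = [j for j in range(fit.X.shape[1]) if j not in cols]
    eng = _BinomialRI(fit.X[:, keep], fit.y, fit.group_idx, fit.n_groups)
    ll_r = eng.fit()[3]
    stat = max(0.0, 2.0 * (fit.loglik - ll_r))
    df = len(cols)
    return {
        "term": term,
        "statistic": stat,
        "df1": df,
        "df2": np.nan,
        "p_value": float(stats.chi2.sf(stat, df)),
    }


def term_tests(fit: MixedModelFit) -> pd.DataFrame:
    """Per-term significance table (see :func:`term_test`)."""
    rows = [term_test(fit, t) for t in fit.term_slices if t != "Intercept"]
    return pd.DataFrame(rows)
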