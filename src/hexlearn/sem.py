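"""Maximum-likelihood structural equation modelling.

Supports confirmatory factor models and MIMIC models (latents measured by
indicators and regressed on observed covariates), specified in a small
text grammar:

    agg =~ physical + verbal + anger + hostility    # loadings
    agg ~ omega + mu + sigma + epsilon + zeta       # latent on covariates
    agg ~~ psyc                                     # latent residual covariance

The implied covariance of the observed vector (indicators y, covariates x)
is, with latent eta = Gamma x + disturbance (Var = Psi, unit diagonal for
identification), y = Lambda eta + e (Var = Theta, diagonal):

    Sigma_yy = Lambda (Gamma Phi Gamma' + Psi) Lambda' + Theta
    Sigma_yx = Lambda Gamma Phi
    Sigma_xx = Phi          (saturated; fixed at the sample value)

Estimation minimizes the normal-theory discrepancy
F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p with analytic gradients;
chi-square = (n-1) F_ML at the optimum. Fit indices: CFI against the
independence baseline, RMSEA, and SRMR over standardized residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import ConfigurationError, EstimationError

_LOG_THETA_MIN = np.log(1e-8)
_HEYWOOD_EPS = 1e-6


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SemModel:
    loadings_map: tuple      # ((latent, (ind1, ind2, ...)), ...)
    regressions_map: tuple   # ((latent, (cov1, ...)), ...)
    latent_covs: tuple       # ((latent_a, latent_b), ...)

    @property
    def latents(self):
        return [l for l, _ in self.loadings_map]

    @property
    def indicators(self):
        out = []
        for _, inds in self.loadings_map:
            out.extend(i for i in inds if i not in out)
        return out

    @property
    def covariates(self):
        out = []
        for _, covs in self.regressions_map:
            out.extend(c for c in covs if c not in out)
        return out

    @property
    def observed(self):
        return self.indicators + self.covariates

    def n_free(self) -> int:
        q = len(self.covariates)
        return (sum(len(i) for _, i in self.loadings_map)
                + sum(len(c) for _, c in self.regressions_map)
                + len(self.indicators) + len(self.latent_covs)
                + q * (q + 1) // 2)

    def degrees_of_freedom(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free()


def parse_model(spec: str) -> SemModel:
    """Parse the text grammar into a SemModel."""
    loadings, regressions, covs = {}, {}, []
    for raw in spec.replace(";", "\n").splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = line.split("=~")
            loadings.setdefault(lhs.strip(), [])
            loadings[lhs.strip()] += [v.strip() for v in rhs.split("+")]
        elif "~~" in line:
            lhs, rhs = line.split("~~")
            covs.append((lhs.strip(), rhs.strip()))
        elif "~" in line:
            lhs, rhs = line.split("~")
            regressions.setdefault(lhs.strip(), [])
            regressions[lhs.strip()] += [v.strip() for v in rhs.split("+")]
        else:
            raise ConfigurationError(f"cannot parse model line {line!r}")
    if not loadings:
        raise ConfigurationError("model defines no latent measurement part")
    for lat in regressions:
        if lat not in loadings:
            raise ConfigurationError(f"regression on undefined latent {lat!r}")
    for a, b in covs:
        if a not in loadings or b not in loadings:
            raise ConfigurationError(f"covariance between non-latents {a!r}, {b!r}")
    model = SemModel(
        loadings_map=tuple((l, tuple(v)) for l, v in loadings.items()),
        regressions_map=tuple((l, tuple(v)) for l, v in regressions.items()),
        latent_covs=tuple(covs),
    )
    if model.degrees_of_freedom() < 0:
        raise ConfigurationError("model is not identified (negative df)")
    return model


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------

class _Structure:
    """Index maps between the flat parameter vector and the model matrices."""

    def __init__(self, model: SemModel):
        self.model = model
        self.latents = model.latents
        self.indicators = model.indicators
        self.covariates = model.covariates
        self.m = len(self.latents)
        self.p = len(self.indicators)
        self.q = len(self.covariates)
        li = {v: i for i, v in enumerate(self.indicators)}
        lc = {v: i for i, v in enumerate(self.covariates)}
        ll = {v: i for i, v in enumerate(self.latents)}
        self.lam_idx = [(li[ind], ll[lat])
                        for lat, inds in model.loadings_map for ind in inds]
        self.gam_idx = [(ll[lat], lc[cov])
                        for lat, covs in model.regressions_map for cov in covs]
        self.psi_idx = [(ll[a], ll[b]) for a, b in model.latent_covs]
        self.n_lam = len(self.lam_idx)
        self.n_gam = len(self.gam_idx)
        self.n_the = self.p
        self.n_psi = len(self.psi_idx)
        self.d = self.n_lam + self.n_gam + self.n_the + self.n_psi

    def unpack(self, x):
        k = 0
        lam = np.zeros((self.p, self.m))
        for (i, j) in self.lam_idx:
            lam[i, j] = x[k]; k += 1
        gam = np.zeros((self.m, self.q))
        for (i, j) in self.gam_idx:
            gam[i, j] = x[k]; k += 1
        theta = np.exp(np.clip(x[k:k + self.p], _LOG_THETA_MIN, 50.0))
        k += self.p
        psi = np.eye(self.m)
        for (i, j) in self.psi_idx:
            rho = np.tanh(x[k]); k += 1
            psi[i, j] = psi[j, i] = rho
        return lam, gam, theta, psi

    def implied(self, x, phi):
        lam, gam, theta, psi = self.unpack(x)
        v = gam @ phi @ gam.T + psi if self.q else psi.copy()
        syy = lam @ v @ lam.T + np.diag(theta)
        n_obs = self.p + self.q
        sigma = np.empty((n_obs, n_obs))
        sigma[:self.p, :self.p] = syy
        if self.q:
            syx = lam @ gam @ phi
            sigma[:self.p, self.p:] = syx
            sigma[self.p:, :self.p] = syx.T
            sigma[self.p:, self.p:] = phi
        return sigma, (lam, gam, theta, psi, v)


def _fml_and_grad(x, struct: _Structure, s_mat, logdet_s, phi):
    p_all = s_mat.shape[0]
    sigma, (lam, gam, theta, psi, v) = struct.implied(x, phi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10, np.zeros(struct.d)
    sig_inv = np.linalg.inv(sigma)
    f = logdet + float(np.sum(sig_inv * s_mat)) - logdet_s - p_all
    if not np.isfinite(f):
        return 1e10, np.zeros(struct.d)

    a_mat = sig_inv @ (sigma - s_mat) @ sig_inv  # dF = tr(A dSigma)
    p, q, m = struct.p, struct.q, struct.m
    a_yy = a_mat[:p, :p]
    a_yx = a_mat[:p, p:] if q else None

    grad = np.empty(struct.d)
    k = 0
    m1 = v @ lam.T                       # m x p
    m2 = (gam @ phi) if q else None      # m x q
    for (i, j) in struct.lam_idx:
        g = 2.0 * float(a_yy[i] @ m1[j])
        if q:
            g += 2.0 * float(a_yx[i] @ m2[j])
        grad[k] = g; k += 1
    lam_a_yy = lam.T @ a_yy @ lam        # m x m
    if q:
        a_yx_phi = a_yx @ phi            # p x q
    for (i, j) in struct.gam_idx:
        # dV = e_i w' + w e_i', w = (Gamma Phi)[:, j]... here w indexes latents
        w = phi[j] @ gam.T               # m-vector: (Phi Gamma')[j]
        b = lam @ w
        a_col = lam[:, i]
        g = 2.0 * float(a_col @ a_yy @ b) + 2.0 * float(a_col @ a_yx_phi[:, j])
        grad[k] = g; k += 1
    for i in range(p):
        grad[k] = theta[i] * a_yy[i, i]; k += 1
    x_psi = x[struct.n_lam + struct.n_gam + struct.n_the:]
    for (idx, (i, j)) in enumerate(struct.psi_idx):
        drho = 1.0 - np.tanh(x_psi[idx]) ** 2
        grad[k] = 2.0 * drho * lam_a_yy[i, j]; k += 1
    return f, grad


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class SemFit:
    model: SemModel
    loadings: dict           # (latent, indicator) -> estimate
    regressions: dict        # (latent, covariate) -> estimate
    residual_vars: dict      # indicator -> estimate
    psi: dict                # (latent_a, latent_b) -> residual covariance
    se: dict                 # same keys as loadings/regressions
    p_values: dict           # Wald p per loading/regression
    std_loadings: dict
    std_regressions: dict
    chi_square: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    srmr: float
    converged: bool
    heywood: bool
    n: int
    fmin: float
    implied_cov: np.ndarray
    var_names: list
    x_opt: np.ndarray = field(repr=False, default=None)
    means: Optional[pd.Series] = field(repr=False, default=None)
    sds: Optional[pd.Series] = field(repr=False, default=None)

    def good_fit(self) -> dict:
        return {
            "chi_square_p": self.p_value > 0.05,
            "cfi": self.cfi > 0.95,
            "rmsea": self.rmsea < 0.05,
            "srmr": self.srmr < 0.08,
        }


def _prepare_data(data, model: SemModel, standardize: bool):
    names = model.observed
    if isinstance(data, tuple):
        s_mat, n = data
        s_mat = (s_mat.loc[names, names].to_numpy(dtype=float)
                 if isinstance(s_mat, pd.DataFrame) else np.asarray(s_mat, dtype=float))
        return s_mat, int(n), None, None, None
    df = pd.DataFrame(data)
    missing = [v for v in names if v not in df.columns]
    if missing:
        raise ConfigurationError(f"data lacks model variables {missing}")
    df = df[names].dropna()
    n = len(df)
    if n <= len(names):
        raise ConfigurationError("need more complete rows than observed variables")
    means = df.mean()
    sds = df.std(ddof=1)
    if (sds == 0).any():
        raise ConfigurationError(
            f"constant columns: {list(sds.index[sds == 0])}")
    work = (df - means) / sds if standardize else df
    s_mat = np.cov(work.to_numpy(dtype=float), rowvar=False, ddof=1)
    return s_mat, n, work, means, sds


def fit_ml_sem(data, model: Union[SemModel, str], standardize: bool = True,
               n_starts: int = 10, seed: int = 0, x0=None,
               compute_se: bool = True) -> SemFit:
    """Fit a CFA/MIMIC model by maximum likelihood.

    ``data`` is a DataFrame (listwise deletion, z-scored when
    ``standardize``) or a ``(S, n)`` tuple with a sample covariance. The
    latent scale is identified by unit residual latent variance.
    """
    if isinstance(model, str):
        model = parse_model(model)
    struct = _Structure(model)
    s_mat, n, work, means, sds = _prepare_data(data, model, standardize)
    p_all = struct.p + struct.q
    sign, logdet_s = np.linalg.slogdet(s_mat)
    if sign <= 0:
        raise ConfigurationError("sample covariance is not positive definite")
    phi = s_mat[struct.p:, struct.p:] if struct.q else np.empty((0, 0))

    diag_ind = np.sqrt(np.diag(s_mat)[:struct.p])
    base = np.concatenate([
        0.7 * np.repeat(diag_ind[[i for i, _ in struct.lam_idx]], 1),
        np.zeros(struct.n_gam),
        np.log(0.5 * np.diag(s_mat)[:struct.p]),
        np.zeros(struct.n_psi),
    ])
    if x0 is not None:
        base = np.asarray(x0, dtype=float)

    bounds = ([(None, None)] * (struct.n_lam + struct.n_gam)
              + [(_LOG_THETA_MIN, 20.0)] * struct.n_the
              + [(None, None)] * struct.n_psi)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        start = base if s == 0 else base + 0.3 * rng.standard_normal(struct.d)
        res = optimize.minimize(
            _fml_and_grad, start, args=(struct, s_mat, logdet_s, phi),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun >= 1e9:
        raise EstimationError("structural model estimation failed to converge")
    x_opt = np.asarray(best.x, dtype=float)
    fmin = max(float(best.fun), 0.0)

    sigma, (lam, gam, theta, psi, v) = struct.implied(x_opt, phi)
    heywood = bool((theta < _HEYWOOD_EPS).any())

    df_model = model.degrees_of_freedom()
    chi2 = (n - 1) * fmin
    p_value = float(sps.chi2.sf(chi2, df_model)) if df_model > 0 else 1.0

    # independence baseline for CFI
    f_base = float(np.sum(np.log(np.diag(s_mat)))) - logdet_s
    chi2_base = (n - 1) * f_base
    df_base = p_all * (p_all + 1) // 2 - p_all
    num = max(chi2 - df_model, 0.0)
    den = max(chi2_base - df_base, num, 1e-12)
    cfi = 1.0 - num / den
    rmsea = float(np.sqrt(num / (df_model * (n - 1)))) if df_model > 0 else 0.0
    d_s = np.sqrt(np.diag(s_mat))
    d_sig = np.sqrt(np.diag(sigma))
    resid = s_mat / np.outer(d_s, d_s) - sigma / np.outer(d_sig, d_sig)
    iu = np.triu_indices(p_all)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    # delta-method SEs / Wald tests from the Hessian of the fit function
    se, p_vals = {}, {}
    if compute_se:
        se_vec = _wald_se(x_opt, struct, s_mat, logdet_s, phi, n)
    else:
        se_vec = np.full(struct.d, np.nan)

    lam_named = {}
    for k, (i, j) in enumerate(struct.lam_idx):
        key = (struct.latents[j], struct.indicators[i])
        lam_named[key] = float(x_opt[k])
        se[key] = float(se_vec[k])
        p_vals[key] = _wald_p(x_opt[k], se_vec[k])
    gam_named = {}
    for k, (i, j) in enumerate(struct.gam_idx):
        key = (struct.latents[i], struct.covariates[j])
        kk = struct.n_lam + k
        gam_named[key] = float(x_opt[kk])
        se[key] = float(se_vec[kk])
        p_vals[key] = _wald_p(x_opt[kk], se_vec[kk])
    theta_named = {ind: float(theta[i]) for i, ind in enumerate(struct.indicators)}
    psi_named = {}
    for (a, b) in model.latent_covs:
        ia, ib = model.latents.index(a), model.latents.index(b)
        psi_named[(a, b)] = float(psi[ia, ib])

    sd_eta = np.sqrt(np.diag(v))
    sd_y = np.sqrt(np.diag(sigma)[:struct.p])
    sd_x = np.sqrt(np.diag(phi)) if struct.q else np.empty(0)
    std_load = {}
    for k, (i, j) in enumerate(struct.lam_idx):
        key = (struct.latents[j], struct.indicators[i])
        std_load[key] = float(x_opt[k] * sd_eta[j] / sd_y[i])
    std_reg = {}
    for k, (i, j) in enumerate(struct.gam_idx):
        key = (struct.latents[i], struct.covariates[j])
        std_reg[key] = float(x_opt[struct.n_lam + k] * sd_x[j] / sd_eta[i])

    return SemFit(
        model=model, loadings=lam_named, regressions=gam_named,
        residual_vars=theta_named, psi=psi_named, se=se, p_values=p_vals,
        std_loadings=std_load, std_regressions=std_reg,
        chi_square=float(chi2), df=int(df_model), p_value=p_value,
        cfi=float(cfi), rmsea=rmsea, srmr=srmr,
        converged=bool(best.success or fmin < 1e-10), heywood=heywood,
        n=int(n), fmin=fmin, implied_cov=sigma, var_names=model.observed,
        x_opt=x_opt, means=means, sds=sds,
    )


def _wald_se(x, struct, s_mat, logdet_s, phi, n):
    d = struct.d
    h = 1e-5 * (1.0 + np.abs(x))
    hess = np.empty((d, d))
    for j in range(d):
        xp = x.copy(); xp[j] += h[j]
        xm = x.copy(); xm[j] -= h[j]
        _, gp = _fml_and_grad(xp, struct, s_mat, logdet_s, phi)
        _, gm = _fml_and_grad(xm, struct, s_mat, logdet_s, phi)
        hess[:, j] = (gp - gm) / (2 * h[j])
    hess = 0.5 * (n - 1) * 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.pinv(hess)
        var = np.clip(np.diag(cov), 0, None)
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        return np.full(d, np.nan)


def _wald_p(est, se) -> float:
    if not np.isfinite(se) or se == 0:
        return float("nan")
    return float(2 * sps.norm.sf(abs(est / se)))


def factor_scores(fit: SemFit, data) -> pd.DataFrame:
    """Regression-method factor scores eta_hat = V Lambda' Sigma_yy^-1 (y - ybar),
    computed from the measurement part; zero mean by construction."""
    if not fit.converged:
        raise EstimationError("cannot score from a non-converged fit")
    struct = _Structure(fit.model)
    df = pd.DataFrame(data)[struct.indicators].dropna()
    y = df.to_numpy(dtype=float)
    if fit.sds is not None:
        y = (y - fit.means[struct.indicators].to_numpy()) / \
            fit.sds[struct.indicators].to_numpy()
    y = y - y.mean(axis=0)
    sigma, (lam, gam, theta, psi, v) = struct.implied(fit.x_opt,
                                                      fit.implied_cov[struct.p:, struct.p:])
    syy = sigma[:struct.p, :struct.p]
    try:
        weights = v @ lam.T @ np.linalg.inv(syy)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular implied covariance") from exc
    scores = y @ weights.T
    return pd.DataFrame(scores, index=df.index, columns=struct.latents)


def compare_structures(data, models: dict, standardize: bool = True,
                       seed: int = 0) -> pd.DataFrame:
    """Fit several candidate structures on the same data and tabulate fit
    indices side by side; estimation failures are recorded, not fatal."""
    rows = []
    fits = {}
    for name, model in models.items():
        try:
            fit = fit_ml_sem(data, model, standardize=standardize, seed=seed,
                             compute_se=False)
            good = fit.good_fit()
            rows.append({"model": name, "chi_square": fit.chi_square, "df": fit.df,
                         "p_value": fit.p_value, "cfi": fit.cfi,
                         "rmsea": fit.rmsea, "srmr": fit.srmr,
                         "converged": fit.converged,
                         "fails_all_cutoffs": not any(good.values())})
            fits[name] = fit
        except (EstimationError, ConfigurationError) as exc:
            rows.append({"model": name, "chi_square": np.nan, "df": np.nan,
                         "p_value": np.nan, "cfi": np.nan, "rmsea": np.nan,
                         "srmr": np.nan, "converged": False,
                         "fails_all_cutoffs": True, "error": str(exc)})
    table = pd.DataFrame(rows).sort_values("cfi", ascending=False).reset_index(drop=True)
    table.attrs["fits"] = fits
    return table


def bootstrap_ci(data, model: Union[SemModel, str], n_boot: int = 2000,
                 seed: int = 0, level: float = 0.95, standardize: bool = True,
                 fit: Optional[SemFit] = None) -> dict:
    """Nonparametric-bootstrap percentile intervals for the standardized
    regression coefficients (the second decision criterion alongside p<0.05)."""
    if isinstance(model, str):
        model = parse_model(model)
    df = pd.DataFrame(data)[model.observed].dropna().reset_index(drop=True)
    if fit is None:
        fit = fit_ml_sem(df, model, standardize=standardize, seed=seed,
                         compute_se=False)
    rng = np.random.default_rng(seed)
    keys = list(fit.std_regressions)
    draws = {k: [] for k in keys}
    n = len(df)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            bfit = fit_ml_sem(df.iloc[idx], model, standardize=standardize,
                              n_starts=1, x0=fit.x_opt, compute_se=False)
        except (EstimationError, ConfigurationError):
            continue
        for k in keys:
            draws[k].append(bfit.std_regressions[k])
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    out = {}
    for k in keys:
        arr = np.asarray(draws[k])
        if len(arr) < max(20, 0.5 * n_boot):
            raise EstimationError("too many bootstrap refits failed")
        out[k] = (float(np.quantile(arr, lo)), float(np.quantile(arr, hi)))
    return out
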