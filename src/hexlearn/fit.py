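"""Per-subject parameter estimation.

Models are fitted by MAP with Gaussian priors in an unconstrained
estimation space (log for positive parameters, logit for rates), using
multi-start quasi-Newton minimization. The log model evidence is the
Laplace approximation at the optimum,

    ln p(r | m) ~ -J(x*) + (d/2) ln 2*pi - (1/2) ln |H|,

with J the negative log joint and H its Hessian at the MAP point.
Also implements the cohort exclusion rules (missing-trial fraction,
+/- k SD parameter outliers) and per-condition trajectory summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from . import observers
from .errors import (ConfigurationError, InsufficientDataError, NumericalError,
                     OptimizationFailureError)
from .observers import MISSING, filter_predictions, response_prob

_BIG = 1e10

# estimation-space layout per model: (native name, transform)
MODEL_PARAMS = {
    "hgf2": (("omega", "identity"), ("zeta", "log")),
    "hgf3": (("omega2", "identity"), ("theta", "identity"), ("zeta", "log")),
    "rw": (("alpha", "logit"), ("zeta", "log")),
    "k1": (("mu_meta", "log"), ("beta0", "identity"), ("zeta", "log")),
    "kalman": (("q", "log"), ("r_obs", "log"), ("zeta", "log")),
}

# prior (mean, variance) in estimation space; 'wide' follows the convention of
# loose hyperpriors used for individual-differences work
PRIOR_PRESETS = {
    "default": {
        "hgf2": ((-3.0, 4.0), (0.0, 1.0)),
        "hgf3": ((-3.0, 4.0), (-6.0, 4.0), (0.0, 1.0)),
        "rw": ((0.0, 1.0), (0.0, 1.0)),
        "k1": ((-2.0, 1.0), (-1.5, 1.0), (0.0, 1.0)),
        "kalman": ((-3.0, 1.0), (-1.0, 1.0), (0.0, 1.0)),
    },
    "wide": {
        "hgf2": ((-3.0, 16.0), (0.0, 4.0)),
        "hgf3": ((-3.0, 16.0), (-6.0, 16.0), (0.0, 4.0)),
        "rw": ((0.0, 4.0), (0.0, 4.0)),
        "k1": ((-2.0, 4.0), (-1.5, 4.0), (0.0, 4.0)),
        "kalman": ((-3.0, 4.0), (-1.0, 4.0), (0.0, 4.0)),
    },
}


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors over a model's free parameters in estimation space."""

    model: str
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.variances) <= 0):
            raise ConfigurationError("prior variances must be positive")

    @classmethod
    def preset(cls, model: str, name: str = "default") -> "PriorSpec":
        if model not in MODEL_PARAMS:
            raise ConfigurationError(f"unknown model {model!r}")
        if name not in PRIOR_PRESETS:
            raise ConfigurationError(f"unknown prior preset {name!r}")
        mv = np.array(PRIOR_PRESETS[name][model], dtype=float)
        return cls(model=model, means=mv[:, 0], variances=mv[:, 1])

    @property
    def d(self) -> int:
        return len(self.means)


@dataclass
class FitResult:
    """MAP fit of one model to one subject's (or condition's) responses."""

    model: str
    estimates: dict                      # native-space parameter values
    x_est: np.ndarray                    # MAP point in estimation space
    log_model_evidence: float
    neg_log_joint: float
    hessian_log_det: float
    n_starts_converged: int
    nonpd_hessian: bool
    boundary_flags: dict
    trajectories: dict                   # opponent label -> trajectory
    predictions: np.ndarray
    p_shoot: np.ndarray
    opponents: Optional[np.ndarray]
    condition: str = "all"
    n_trials_used: int = 0

    @property
    def params(self):
        return _native_params(self.model, self.x_est)


def _resolve_priors(model: str, priors) -> PriorSpec:
    if priors is None:
        priors = "default"
    if isinstance(priors, str):
        return PriorSpec.preset(model, priors)
    if isinstance(priors, PriorSpec):
        if priors.model != model:
            raise ConfigurationError("priors were built for another model")
        return priors
    raise ConfigurationError(f"cannot interpret priors {priors!r}")


def _to_native(model: str, x: np.ndarray) -> dict:
    out = {}
    for (name, tf), xi in zip(MODEL_PARAMS[model], x):
        if tf == "identity":
            out[name] = float(xi)
        elif tf == "log":
            out[name] = float(np.exp(np.clip(xi, -700, 700)))
        elif tf == "logit":
            out[name] = float(1.0 / (1.0 + np.exp(-np.clip(xi, -700, 700))))
    return out


def _native_params(model: str, x: np.ndarray):
    cls, _ = observers.MODEL_FILTERS[model]
    return cls(**_to_native(model, x))


def neg_log_joint(x, u, responses, model: str, priors, opponents=None) -> float:
    """-(log likelihood of non-missing responses + log prior density).

    Missing responses are skipped in the likelihood; the Gaussian prior
    includes its normalization constant so the value is comparable across
    prior presets.
    """
    priors = _resolve_priors(model, priors)
    x = np.asarray(x, dtype=float)
    responses = np.asarray(responses)
    mask = responses != MISSING
    if len(responses) and not mask.any():
        raise InsufficientDataError("all responses are missing")
    try:
        params = _native_params(model, x)
        pred, _ = filter_predictions(model, params, u, opponents=opponents)
    except NumericalError:
        return _BIG
    p = response_prob(pred, params.zeta)
    r = responses[mask].astype(float)
    p = np.asarray(p)[mask]
    nll = -np.sum(r * np.log(p) + (1.0 - r) * np.log1p(-p))
    z = (x - priors.means)
    nlp = 0.5 * np.sum(z * z / priors.variances + np.log(2 * np.pi * priors.variances))
    val = float(nll + nlp)
    return val if np.isfinite(val) else _BIG


def _numerical_hessian(fun, x, rel_step=1e-4):
    d = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((d, d))
    f0 = fun(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def fit_map(u, responses, model: str = "hgf2", priors="default",
            n_starts: int = 8, seed: int = 0, opponents=None,
            condition: str = "all", min_trials: int = 10) -> FitResult:
    """Multi-start MAP fit with Laplace log model evidence."""
    priors = _resolve_priors(model, priors)
    responses = np.asarray(responses)
    n_used = int(np.sum(responses != MISSING))
    if n_used < min_trials:
        raise InsufficientDataError(
            f"{n_used} non-missing trials; at least {min_trials} required")

    def objective(x):
        return neg_log_joint(x, u, responses, model, priors, opponents=opponents)

    rng = np.random.default_rng(seed)
    sd = np.sqrt(priors.variances)
    best = None
    n_conv = 0
    diagnostics = []
    for s in range(max(1, n_starts)):
        x0 = priors.means if s == 0 else priors.means + 0.5 * sd * rng.standard_normal(priors.d)
        res = optimize.minimize(objective, x0, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        diagnostics.append((res.success, float(res.fun)))
        if np.isfinite(res.fun) and res.fun < _BIG / 2:
            n_conv += int(bool(res.success))
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise OptimizationFailureError(
            f"no start produced a finite optimum for model {model}", diagnostics)

    x_map = np.asarray(best.x, dtype=float)
    H = _numerical_hessian(objective, x_map)
    eigvals = np.linalg.eigvalsh(0.5 * (H + H.T))
    nonpd = bool(eigvals.min() <= 0)
    if nonpd:
        eigvals = np.clip(eigvals, 1e-6, None)
    logdet = float(np.sum(np.log(eigvals)))
    lme = -float(best.fun) + 0.5 * priors.d * np.log(2 * np.pi) - 0.5 * logdet

    params = _native_params(model, x_map)
    pred, trajs = filter_predictions(model, params, u, opponents=opponents)
    flags = {}
    for k, ((name, _), m, v) in enumerate(zip(MODEL_PARAMS[model], priors.means, priors.variances)):
        flags[name] = bool(abs(x_map[k] - m) > 3.0 * np.sqrt(v))

    return FitResult(
        model=model, estimates=_to_native(model, x_map), x_est=x_map,
        log_model_evidence=float(lme), neg_log_joint=float(best.fun),
        hessian_log_det=logdet, n_starts_converged=n_conv, nonpd_hessian=nonpd,
        boundary_flags=flags, trajectories=trajs, predictions=pred,
        p_shoot=np.asarray(response_prob(pred, params.zeta)),
        opponents=None if opponents is None else np.asarray(opponents),
        condition=condition, n_trials_used=n_used,
    )


def fit_by_condition(trials: pd.DataFrame, model: str = "hgf2", priors="default",
                     n_starts: int = 8, seed: int = 0,
                     per_opponent: bool = True, min_trials: int = 10) -> dict:
    """Split one subject's trials by threat condition (order preserved,
    per-opponent streams intact) and fit each condition independently."""
    required = {"threat", "u", "response"}
    if not required.issubset(trials.columns):
        raise ConfigurationError(f"trial table needs columns {sorted(required)}")
    conditions = observers.pd_unique(trials["threat"])
    if set(conditions) != {"high", "low"}:
        raise InsufficientDataError(
            f"both threat conditions required, found {sorted(set(conditions))}")
    out = {}
    for k, cond in enumerate(("high", "low")):
        sub = trials[trials["threat"] == cond]
        n_ok = int((sub["response"].to_numpy() != MISSING).sum())
        if n_ok < min_trials:
            raise InsufficientDataError(
                f"condition {cond!r} has only {n_ok} non-missing trials")
        opp = sub["opponent"].to_numpy() if (per_opponent and "opponent" in sub) else None
        out[cond] = fit_map(
            sub["u"].to_numpy(), sub["response"].to_numpy(), model=model,
            priors=priors, n_starts=n_starts, seed=seed + k, opponents=opp,
            condition=cond, min_trials=min_trials)
    return out


def summarize_conditions(condition_fits: dict, subject=None) -> pd.DataFrame:
    """Per-condition trajectory summaries: mean second-level belief mu2, mean
    uncertainty sigma2, mean signed precision-weighted prediction error, plus
    the condition's fitted omega and zeta."""
    rows = []
    for cond, fit in condition_fits.items():
        mu2, sig2, eps = [], [], []
        for traj in fit.trajectories.values():
            if not hasattr(traj, "mu2"):
                raise ConfigurationError(
                    "condition summaries require an HGF trajectory")
            mu2.append(traj.mu2); sig2.append(traj.sigma2); eps.append(traj.epsilon)
        mu2 = np.concatenate(mu2) if mu2 else np.array([])
        sig2 = np.concatenate(sig2) if sig2 else np.array([])
        eps = np.concatenate(eps) if eps else np.array([])
        rows.append({
            "subject": subject, "condition": cond,
            "mean_mu2": float(np.mean(mu2)) if mu2.size else np.nan,
            "mean_sigma2": float(np.mean(sig2)) if sig2.size else np.nan,
            "mean_epsilon": float(np.mean(eps)) if eps.size else np.nan,
            "omega": fit.estimates.get("omega", fit.estimates.get("omega2", np.nan)),
            "zeta": fit.estimates.get("zeta", np.nan),
        })
    return pd.DataFrame(rows)


def exclude_missing(trials: pd.DataFrame, max_missing_fraction: float = 0.25) -> pd.Series:
    """Inclusion mask per subject: excluded iff the missing-response fraction
    STRICTLY exceeds the threshold (a subject exactly at it stays in)."""
    if not 0 < max_missing_fraction < 1:
        raise ConfigurationError("max_missing_fraction must lie in (0, 1)")
    resp = trials["response"]
    missing = (resp == MISSING) if np.issubdtype(resp.dtype, np.number) else (resp == "missing")
    frac = missing.groupby(trials["subject"]).mean()
    return frac <= max_missing_fraction


def exclude_param_outliers(params: pd.DataFrame, k_sd: float = 2.0,
                           columns=None) -> pd.Series:
    """Inclusion mask: a subject is excluded iff any designated parameter lies
    outside sample mean +/- k_sd * SD. Moments come from the full sample in a
    single pass (no iterative re-trimming)."""
    if k_sd <= 0:
        raise ConfigurationError("k_sd must be positive")
    if len(params) < 3:
        raise InsufficientDataError("need at least 3 subjects for outlier screening")
    cols = list(columns) if columns is not None else [
        c for c in params.columns if np.issubdtype(params[c].dtype, np.number)]
    included = pd.Series(True, index=params.index)
    for c in cols:
        v = params[c].astype(float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"parameter {c!r} has zero variance; skipped in outlier rule")
            continue
        m = v.mean()
        included &= (v - m).abs() <= k_sd * sd
    return included
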