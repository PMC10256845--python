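"""Behavioural statistics: repeated-measures contrasts, default Bayes
factors, FDR, power, reliability, and PCA.

Bayes factors follow the Jeffreys-Zellner-Siow default convention: a
Cauchy prior (scale sqrt(2)/2) on the standardized effect for t-tests and
the corresponding default prior for correlations, both evaluated by
numerical integration. The dual decision rule used throughout the
pipeline flags an effect only when p < 0.05 AND BF10 > 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateDataError, NumericalError

DEFAULT_T_SCALE = math.sqrt(2) / 2


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    bf10: Optional[float] = None
    effect_size: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "df": self.df, "p_value": self.p_value,
            "bf10": self.bf10, "effect_size": self.effect_size, **self.extra,
        }


def significant_by_both(p_value: float, bf10: float,
                        p_threshold: float = 0.05, bf_threshold: float = 3.0) -> bool:
    """Dual decision criterion: flag only when both the p-value and the Bayes
    factor support the alternative."""
    return (p_value < p_threshold) and (bf10 > bf_threshold)


# ---------------------------------------------------------------------------
# t-tests and the 2x2 within-subject ANOVA
# ---------------------------------------------------------------------------

def paired_t(x, y, bayes: bool = True) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ConfigurationError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return TestResult(statistic=0.0, df=n - 1, p_value=1.0,
                              bf10=jzs_bf_ttest(0.0, n) if bayes else None,
                              effect_size=0.0)
        raise DegenerateDataError("zero variance of paired differences")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    dz = d.mean() / sd
    return TestResult(statistic=float(t), df=float(n - 1), p_value=float(p),
                      bf10=jzs_bf_ttest(t, n) if bayes else None,
                      effect_size=float(dz))


def independent_t(x, y, bayes: bool = True) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if min(n1, n2) < 2:
        raise ConfigurationError("need at least 2 observations per group")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, df=n1 + n2 - 2, p_value=1.0,
                              bf10=jzs_bf_ttest(0.0, n1, n2) if bayes else None,
                              effect_size=0.0)
        raise DegenerateDataError("zero pooled variance with unequal means")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sps.t.sf(abs(t), df)
    d = (x.mean() - y.mean()) / math.sqrt(sp2)
    return TestResult(statistic=float(t), df=float(df), p_value=float(p),
                      bf10=jzs_bf_ttest(t, n1, n2) if bayes else None,
                      effect_size=float(d))


def rm_anova_2x2(cells, bayes: bool = True) -> dict:
    """2x2 fully-within ANOVA on a subjects x 4 table with columns ordered
    (A1B1, A1B2, A2B1, A2B2).

    With two levels per factor each effect is a 1-df contrast, so each F is
    exactly the square of the paired t on the matching difference scores.
    Bayes factors use the BIC approximation (flagged in ``extra``).
    """
    m = np.asarray(cells, dtype=float)
    if isinstance(cells, pd.DataFrame):
        m = cells.to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ConfigurationError("expected a subjects x 4 cell-means table")
    if np.isnan(m).any():
        raise ConfigurationError("incomplete design: missing cells")
    n = m.shape[0]
    if n < 3:
        raise ConfigurationError("need at least 3 subjects")
    a1b1, a1b2, a2b1, a2b2 = m.T
    contrasts = {
        "A": (a1b1 + a1b2 - a2b1 - a2b2) / 2.0,
        "B": (a1b1 - a1b2 + a2b1 - a2b2) / 2.0,
        "AxB": (a1b1 - a1b2 - a2b1 + a2b2) / 2.0,
    }
    out = {}
    for name, c in contrasts.items():
        sd = c.std(ddof=1)
        if sd == 0:
            f_val, t_val, p = 0.0, 0.0, 1.0
        else:
            t_val = c.mean() / (sd / math.sqrt(n))
            f_val = t_val ** 2
            p = sps.f.sf(f_val, 1, n - 1)
        bf = bf10_bic_from_t(t_val, n) if bayes else None
        out[name] = TestResult(statistic=float(f_val), df=(1.0, float(n - 1)),
                               p_value=float(p), bf10=bf,
                               extra={"t": float(t_val), "bf_method": "bic_approx"})
    return out


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def jzs_bf_ttest(t: float, n: int, n2: Optional[int] = None,
                 scale: float = DEFAULT_T_SCALE) -> float:
    """JZS default Bayes factor for a t statistic.

    Cauchy(0, scale) prior on the standardized effect, i.e. an inverse-gamma
    (1/2, scale^2/2) mixing distribution over the relative prior variance g;
    one-sample/paired when ``n2`` is None, two-sample otherwise.
    """
    if n < 2 or (n2 is not None and n2 < 2):
        raise ConfigurationError("need n >= 2 per group")
    if n2 is None:
        big_n, nu = float(n), float(n - 1)
    else:
        big_n, nu = n * n2 / float(n + n2), float(n + n2 - 2)
    t2 = float(t) ** 2
    r2 = scale ** 2

    def log_integrand(g):
        # marginal likelihood under H1 at fixed g, times the IG(1/2, r^2/2) pdf
        lm = (-0.5 * math.log1p(big_n * g)
              - 0.5 * (nu + 1) * math.log1p(t2 / ((1 + big_n * g) * nu)))
        lp = (0.5 * math.log(r2 / 2) - math.lgamma(0.5)
              - 1.5 * math.log(g) - r2 / (2 * g))
        return lm + lp

    val, _ = integrate.quad(lambda g: math.exp(log_integrand(g)), 0, np.inf,
                            limit=200)
    if not np.isfinite(val) or val <= 0:
        raise NumericalError("JZS integration failed")
    log_h0 = -0.5 * (nu + 1) * math.log1p(t2 / nu)
    return float(val / math.exp(log_h0))


def jzs_bf_correlation(r: float, n: int) -> float:
    """Default Bayes factor for a Pearson correlation via the JZS linear-model
    route: BF10 = sqrt(n/2)/Gamma(1/2) * int_0^inf (1+g)^{(n-2)/2}
    [1+(1-r^2) g]^{-(n-1)/2} g^{-3/2} exp(-n/(2g)) dg."""
    if n < 4:
        raise ConfigurationError("need n >= 4")
    r2 = min(float(r) ** 2, 1.0 - 1e-12)

    def log_integrand(g):
        return (0.5 * (n - 2) * math.log1p(g)
                - 0.5 * (n - 1) * math.log1p((1 - r2) * g)
                - 1.5 * math.log(g) - n / (2 * g))

    val, _ = integrate.quad(lambda g: math.exp(log_integrand(g)), 0, np.inf,
                            limit=200)
    if not np.isfinite(val) or val < 0:
        raise NumericalError("correlation BF integration failed")
    return float(math.sqrt(n / 2.0) / math.gamma(0.5) * val)


def bf10_bic_from_t(t: float, n: int) -> float:
    """BIC-approximated Bayes factor for a 1-df within-subject contrast:
    BF10 ~ (1 - R^2)^(-n/2) / sqrt(n) with R^2 = t^2/(t^2 + nu)."""
    nu = n - 1
    r2 = t ** 2 / (t ** 2 + nu)
    return float((1.0 - r2) ** (-n / 2.0) / math.sqrt(n))


# ---------------------------------------------------------------------------
# correlations, FDR, power
# ---------------------------------------------------------------------------

def pearson_cor_test(x, y, bayes: bool = True) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ConfigurationError("need n >= 4")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise DegenerateDataError("zero variance input to correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    if 1.0 - r ** 2 < 1e-14:
        return TestResult(statistic=math.copysign(math.inf, r), df=float(n - 2),
                          p_value=0.0, bf10=math.inf if bayes else None,
                          effect_size=r, extra={"r": r})
    t = r * math.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    bf = jzs_bf_correlation(r, n) if bayes else None
    return TestResult(statistic=float(t), df=float(n - 2), p_value=float(p),
                      bf10=bf, effect_size=r, extra={"r": r})


def fdr_bh(p_values):
    """Benjamini-Hochberg step-up q-values (monotone adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def correlation_power(n: int, rho: float, alpha: float = 0.05) -> float:
    """Two-tailed power to detect a correlation of size rho at sample size n,
    by the Fisher z approximation."""
    if n < 4:
        raise ConfigurationError("need n >= 4")
    if not -1 < rho < 1:
        raise ConfigurationError("rho must lie in (-1, 1)")
    z_rho = math.atanh(rho)
    z_crit = sps.norm.ppf(1 - alpha / 2)
    se = math.sqrt(n - 3)
    power = sps.norm.cdf(z_rho * se - z_crit) + sps.norm.cdf(-z_rho * se - z_crit)
    return float(power)


# ---------------------------------------------------------------------------
# reliability and PCA
# ---------------------------------------------------------------------------

def cronbach_alpha(items) -> float:
    """alpha = k/(k-1) * (1 - sum of item variances / total-score variance)."""
    m = np.asarray(items, dtype=float)
    if isinstance(items, pd.DataFrame):
        m = items.to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ConfigurationError("need >= 3 subjects and >= 2 items")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - m.var(axis=0, ddof=1).sum() / total_var))


def mcdonald_omega(items) -> float:
    """omega_total from a single-factor maximum-likelihood fit:
    (sum lambda)^2 / ((sum lambda)^2 + sum residual variances)."""
    from . import sem  # deferred: sem depends on nothing here, avoid cycles

    m = pd.DataFrame(np.asarray(items, dtype=float))
    m.columns = [f"item{i}" for i in range(m.shape[1])]
    spec = "f =~ " + " + ".join(m.columns)
    fit = sem.fit_ml_sem(m, sem.parse_model(spec), standardize=False)
    lam = np.array([fit.loadings[("f", c)] for c in m.columns])
    theta = np.array([fit.residual_vars[c] for c in m.columns])
    s = abs(lam.sum())  # sign of the factor is arbitrary
    return float(s ** 2 / (s ** 2 + theta.sum()))


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame      # variables x components, scaled by sqrt(eigenvalue)
    scores: pd.DataFrame        # subjects x retained components
    n_retained: int
    n_dropped_rows: int


def pca_scores(table: pd.DataFrame, n_components="auto") -> PcaResult:
    """PCA of the correlation matrix with listwise deletion; ``auto`` retains
    components with eigenvalue > 1 (Kaiser rule)."""
    df = pd.DataFrame(table)
    if df.shape[1] < 2:
        raise ConfigurationError("need at least 2 variables")
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    for c in complete.columns:
        if complete[c].std(ddof=1) == 0:
            raise DegenerateDataError(f"constant column {c!r}")
    z = (complete - complete.mean()) / complete.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    k = int(np.sum(eigvals > 1.0)) if n_components == "auto" else int(n_components)
    k = max(k, 1)
    loadings = pd.DataFrame(eigvecs * np.sqrt(np.clip(eigvals, 0, None)),
                            index=df.columns,
                            columns=[f"pc{i + 1}" for i in range(len(eigvals))])
    scores = pd.DataFrame(z.to_numpy() @ eigvecs[:, :k], index=complete.index,
                          columns=[f"pc{i + 1}" for i in range(k)])
    return PcaResult(eigenvalues=eigvals, loadings=loadings, scores=scores,
                     n_retained=k, n_dropped_rows=n_dropped)
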