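"""Group-level Bayesian model selection.

Random-effects model selection treats model identity as varying across
subjects: given a subjects x models matrix of log model evidences, a
variational scheme estimates the Dirichlet posterior over population
model frequencies, from which expected frequencies and exceedance
probabilities (the probability that each model is the most prevalent)
follow. A fixed-effects companion simply sums log evidences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .errors import ConfigurationError, ConvergenceError


@dataclass(frozen=True)
class BmsResult:
    alpha: np.ndarray            # Dirichlet concentration parameters
    expected_freq: np.ndarray    # E[model frequency]
    exceedance_prob: np.ndarray  # P(model k most frequent)
    n_mc_samples: int
    converged: bool
    n_iterations: int


def random_effects_bms(lme, alpha0: float = 1.0, n_mc: int = 100_000,
                       seed: int = 0, tol: float = 1e-6,
                       max_iter: int = 10_000) -> BmsResult:
    """Variational Dirichlet scheme over log model evidences.

    Iterates, until the concentration parameters stabilize,

        g_nk  proportional to  exp(lme_nk + psi(alpha_k) - psi(sum alpha)),
        alpha_k = alpha0 + sum_n g_nk,

    then estimates exceedance probabilities by Monte-Carlo sampling from
    Dirichlet(alpha).
    """
    lme = np.asarray(lme, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ConfigurationError("need a subjects x models matrix with >= 2 models")
    if not np.isfinite(lme).all():
        raise ConfigurationError("log model evidences must be finite")
    if alpha0 <= 0:
        raise ConfigurationError("alpha0 must be positive")
    n, k = lme.shape
    alpha = np.full(k, alpha0, dtype=float)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logu = lme + (digamma(alpha) - digamma(alpha.sum()))
        logu -= logu.max(axis=1, keepdims=True)
        g = np.exp(logu)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        step = float(np.abs(alpha_new - alpha).max())
        trace.append(step)
        alpha = alpha_new
        if step < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"model-frequency update did not converge in {max_iter} iterations",
            trace=trace)

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_mc))
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=k) / float(n_mc)
    return BmsResult(alpha=alpha, expected_freq=expected, exceedance_prob=xp,
                     n_mc_samples=int(n_mc), converged=converged, n_iterations=it)


def fixed_effects_bms(lme) -> np.ndarray:
    """Group log Bayes factors: column-summed log evidences re-centred so the
    best model sits at 0 (all other entries are <= 0)."""
    lme = np.asarray(lme, dtype=float)
    if lme.ndim == 1:
        lme = lme[None, :]
    if not np.isfinite(lme).all():
        raise ConfigurationError("log model evidences must be finite")
    total = lme.sum(axis=0)
    return total - total.max()
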