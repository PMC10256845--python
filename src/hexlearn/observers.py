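"""Candidate learner models and the decision model.

Five observers filter the binary gun/phone stream into trial-wise
predictions: a 2-level hierarchical Gaussian filter (HGF), a 3-level HGF,
Rescorla-Wagner, Sutton's K1 (incremental delta-bar-delta), and a Kalman
filter. Predictions are mapped to shoot probabilities through a
unit-square sigmoid with decision-noise exponent zeta.

2-level HGF update cascade (binary outcomes), per trial t:

    mu1_hat = s(mu2)                prediction, s = logistic sigmoid
    pi1_hat = 1 / (mu1_hat (1 - mu1_hat))
    delta   = u - mu1_hat           first-level prediction error
    pi2_hat = 1 / (sigma2 + e^omega)
    pi2     = pi2_hat + 1/pi1_hat
    epsilon = delta / pi2           precision-weighted prediction error
    mu2    <- mu2 + epsilon
    sigma2 <- 1 / pi2

omega is the log-volatility of the second-level Gaussian random walk:
larger omega -> larger random-walk step variance -> faster belief updating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, NumericalError

PROB_FLOOR = 1e-12

MISSING = -1
WITHHOLD = 0
SHOOT = 1
RESPONSE_LABELS = {SHOOT: "shoot", WITHHOLD: "withhold", MISSING: "missing"}


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hgf2Params:
    omega: float = -3.0
    zeta: float = 2.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0

    def __post_init__(self):
        if self.zeta <= 0:
            raise ConfigurationError("zeta must be positive")
        if self.sigma2_0 <= 0:
            raise ConfigurationError("sigma2_0 must be positive")


@dataclass(frozen=True)
class Hgf3Params:
    omega2: float = -3.0
    kappa: float = 1.0
    theta: float = -6.0
    zeta: float = 2.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")
        if self.zeta <= 0 or self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ConfigurationError("zeta and variances must be positive")


@dataclass(frozen=True)
class RwParams:
    alpha: float = 0.2
    zeta: float = 2.0
    v0: float = 0.5

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.zeta <= 0:
            raise ConfigurationError("zeta must be positive")


@dataclass(frozen=True)
class K1Params:
    mu_meta: float = 0.1
    beta0: float = -1.5
    zeta: float = 2.0
    v0: float = 0.5

    def __post_init__(self):
        if self.mu_meta < 0:
            raise ConfigurationError("mu_meta must be non-negative")
        if self.zeta <= 0:
            raise ConfigurationError("zeta must be positive")


@dataclass(frozen=True)
class KalmanParams:
    q: float = 0.01
    r_obs: float = 0.25
    zeta: float = 2.0
    v0: float = 0.5
    s0: float = 1.0

    def __post_init__(self):
        if self.q < 0 or self.r_obs <= 0 or self.s0 <= 0:
            raise ConfigurationError("require q >= 0, r_obs > 0, s0 > 0")
        if self.zeta <= 0:
            raise ConfigurationError("zeta must be positive")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class BeliefTrajectory:
    """Per-trial filtered quantities of an HGF run (arrays of length n)."""

    mu1_hat: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    pi1_hat: np.ndarray
    pi2_hat: np.ndarray
    pi2: np.ndarray
    delta: np.ndarray
    epsilon: np.ndarray
    mu3: Optional[np.ndarray] = None
    sigma3: Optional[np.ndarray] = None

    @property
    def prediction(self) -> np.ndarray:
        """Predicted gun probability entering each trial (before seeing u)."""
        return self.mu1_hat

    def __len__(self) -> int:
        return len(self.mu1_hat)


@dataclass
class ValueTrajectory:
    """Per-trial quantities of a value-learning run (RW / K1 / Kalman)."""

    prediction: np.ndarray  # value entering the trial, clipped to (0, 1)
    v: np.ndarray           # value after the update
    delta: np.ndarray
    alpha: Optional[np.ndarray] = None  # K1 per-trial learning rate
    s: Optional[np.ndarray] = None      # Kalman posterior variance
    gain: Optional[np.ndarray] = None   # Kalman gain

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class ResponseSeries:
    """Simulated shoot/withhold responses with their generative probabilities."""

    p_shoot: np.ndarray
    response: np.ndarray  # int codes: SHOOT / WITHHOLD / MISSING

    def labels(self) -> np.ndarray:
        return np.array([RESPONSE_LABELS[int(r)] for r in self.response], dtype=object)

    def __len__(self) -> int:
        return len(self.response)


# ---------------------------------------------------------------------------
# elementary maps
# ---------------------------------------------------------------------------

def sigmoid(x, floor: float = PROB_FLOOR):
    """Logistic sigmoid 1/(1+exp(-x)), clamped into [floor, 1-floor]."""
    out = 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))
    return np.clip(out, floor, 1.0 - floor)


def response_prob(mu1_hat, zeta):
    """Unit-square sigmoid: p(shoot) = m^z / (m^z + (1-m)^z).

    zeta > 1 sharpens responding toward the more likely option; zeta = 1
    is probability matching; zeta -> 0 is random responding.
    Computed in log space for numerical stability at large zeta.
    """
    m = np.clip(np.asarray(mu1_hat, dtype=float), PROB_FLOOR, 1.0 - PROB_FLOOR)
    z = float(zeta)
    if z <= 0:
        raise ConfigurationError("zeta must be positive")
    # p = 1 / (1 + ((1-m)/m)^z) = logistic(z * logit(m))
    logit = np.log(m) - np.log1p(-m)
    out = 1.0 / (1.0 + np.exp(-np.clip(z * logit, -700, 700)))
    out = np.clip(out, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def hgf2_step(prev_mu2: float, prev_sigma2: float, u: int, omega: float) -> dict:
    """One trial of the 2-level binary HGF update cascade."""
    if prev_sigma2 <= 0:
        raise NumericalError(f"sigma2 must be positive, got {prev_sigma2}")
    mu1_hat = 1.0 / (1.0 + math.exp(-min(max(prev_mu2, -700.0), 700.0)))
    mu1_hat = min(max(mu1_hat, PROB_FLOOR), 1.0 - PROB_FLOOR)
    pi1_hat = 1.0 / (mu1_hat * (1.0 - mu1_hat))
    delta = float(u) - mu1_hat
    pi2_hat = 1.0 / (prev_sigma2 + math.exp(omega))
    pi2 = pi2_hat + 1.0 / pi1_hat
    epsilon = delta / pi2
    mu2 = prev_mu2 + epsilon
    sigma2 = 1.0 / pi2
    rec = dict(
        mu1_hat=mu1_hat, mu1=float(u), mu2=mu2, sigma2=sigma2,
        pi1_hat=pi1_hat, pi2_hat=pi2_hat, pi2=pi2, delta=delta, epsilon=epsilon,
    )
    if not all(math.isfinite(v) for v in rec.values()):
        raise NumericalError(f"non-finite HGF2 update: {rec}")
    return rec


def hgf2_filter(outcomes, params: Hgf2Params) -> BeliefTrajectory:
    """Fold the 2-level update over an outcome sequence."""
    u = _as_u(outcomes)
    n = len(u)
    cols = {k: np.empty(n) for k in
            ("mu1_hat", "mu1", "mu2", "sigma2", "pi1_hat", "pi2_hat", "pi2", "delta", "epsilon")}
    mu2, sigma2 = params.mu2_0, params.sigma2_0
    for t in range(n):
        try:
            rec = hgf2_step(mu2, sigma2, u[t], params.omega)
        except NumericalError as exc:
            raise NumericalError(f"trial {t + 1}: {exc}") from exc
        for k, v in rec.items():
            cols[k][t] = v
        mu2, sigma2 = rec["mu2"], rec["sigma2"]
    return BeliefTrajectory(**cols)


def hgf3_filter(outcomes, params: Hgf3Params) -> BeliefTrajectory:
    """3-level binary HGF: the level-2 step variance is exp(kappa*mu3 + omega2),
    with mu3 following its own random walk (step variance e^theta) driven by
    volatility prediction errors."""
    u = _as_u(outcomes)
    n = len(u)
    cols = {k: np.empty(n) for k in
            ("mu1_hat", "mu1", "mu2", "sigma2", "pi1_hat", "pi2_hat", "pi2",
             "delta", "epsilon", "mu3", "sigma3")}
    mu2, sigma2 = params.mu2_0, params.sigma2_0
    mu3, sigma3 = params.mu3_0, params.sigma3_0
    k = params.kappa
    for t in range(n):
        try:
            v2 = math.exp(min(k * mu3 + params.omega2, 700.0))
            mu1_hat = 1.0 / (1.0 + math.exp(-min(max(mu2, -700.0), 700.0)))
            mu1_hat = min(max(mu1_hat, PROB_FLOOR), 1.0 - PROB_FLOOR)
            pi1_hat = 1.0 / (mu1_hat * (1.0 - mu1_hat))
            delta = float(u[t]) - mu1_hat
            pi2_hat = 1.0 / (sigma2 + v2)
            pi2 = pi2_hat + 1.0 / pi1_hat
            epsilon = delta / pi2
            new_mu2 = mu2 + epsilon
            new_sigma2 = 1.0 / pi2
            # volatility prediction error at level 2
            w2 = v2 * pi2_hat
            delta2 = (new_sigma2 + (new_mu2 - mu2) ** 2) * pi2_hat - 1.0
            pi3_hat = 1.0 / (sigma3 + math.exp(min(params.theta, 700.0)))
            pi3 = pi3_hat + 0.5 * k * k * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
            if pi3 <= 0:
                raise NumericalError("level-3 precision became non-positive")
            mu3 = mu3 + 0.5 * k * w2 * delta2 / pi3
            sigma3 = 1.0 / pi3
            mu2, sigma2 = new_mu2, new_sigma2
            for key, val in (("mu1_hat", mu1_hat), ("mu1", float(u[t])), ("mu2", mu2),
                             ("sigma2", sigma2), ("pi1_hat", pi1_hat), ("pi2_hat", pi2_hat),
                             ("pi2", pi2), ("delta", delta), ("epsilon", epsilon),
                             ("mu3", mu3), ("sigma3", sigma3)):
                if not math.isfinite(val):
                    raise NumericalError(f"non-finite {key}")
                cols[key][t] = val
        except NumericalError as exc:
            raise NumericalError(f"trial {t + 1}: {exc}") from exc
    return BeliefTrajectory(**cols)


def rw_filter(outcomes, params: RwParams) -> ValueTrajectory:
    """Rescorla-Wagner: V <- V + alpha (u - V)."""
    u = _as_u(outcomes)
    n = len(u)
    pred = np.empty(n); v_out = np.empty(n); delta = np.empty(n)
    v = params.v0
    a = params.alpha
    for t in range(n):
        pred[t] = v
        d = u[t] - v
        v = v + a * d
        delta[t] = d
        v_out[t] = v
    return ValueTrajectory(prediction=np.clip(pred, PROB_FLOOR, 1 - PROB_FLOOR),
                           v=v_out, delta=delta)


def k1_filter(outcomes, params: K1Params) -> ValueTrajectory:
    """Sutton's K1 (incremental delta-bar-delta): the log learning rate beta
    is itself adapted by the correlation of successive prediction errors."""
    u = _as_u(outcomes)
    n = len(u)
    pred = np.empty(n); v_out = np.empty(n); delta = np.empty(n); alphas = np.empty(n)
    v = params.v0
    beta = params.beta0
    h = 0.0
    for t in range(n):
        pred[t] = v
        d = u[t] - v
        beta = beta + params.mu_meta * d * h
        beta = min(max(beta, -700.0), 0.0)  # cap alpha = exp(beta) at 1
        a = math.exp(beta)
        v = v + a * d
        h = h * max(0.0, 1.0 - a) + a * d
        delta[t] = d; alphas[t] = a; v_out[t] = v
    return ValueTrajectory(prediction=np.clip(pred, PROB_FLOOR, 1 - PROB_FLOOR),
                           v=v_out, delta=delta, alpha=alphas)


def kalman_filter(outcomes, params: KalmanParams) -> ValueTrajectory:
    """Scalar Kalman filter on outcome value with process noise q and
    observation noise r_obs."""
    u = _as_u(outcomes)
    n = len(u)
    pred = np.empty(n); v_out = np.empty(n); delta = np.empty(n)
    s_out = np.empty(n); gains = np.empty(n)
    v, s = params.v0, params.s0
    for t in range(n):
        pred[t] = v
        sp = s + params.q
        kgain = sp / (sp + params.r_obs)
        d = u[t] - v
        v = v + kgain * d
        s = (1.0 - kgain) * sp
        delta[t] = d; gains[t] = kgain; s_out[t] = s; v_out[t] = v
    return ValueTrajectory(prediction=np.clip(pred, PROB_FLOOR, 1 - PROB_FLOOR),
                           v=v_out, delta=delta, s=s_out, gain=gains)


MODEL_FILTERS = {
    "hgf2": (Hgf2Params, hgf2_filter),
    "hgf3": (Hgf3Params, hgf3_filter),
    "rw": (RwParams, rw_filter),
    "k1": (K1Params, k1_filter),
    "kalman": (KalmanParams, kalman_filter),
}
MODEL_NAMES = tuple(MODEL_FILTERS)


def filter_outcomes(model: str, params, outcomes):
    """Run the named model's filter over an outcome sequence."""
    if model not in MODEL_FILTERS:
        raise ConfigurationError(
            f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    _, fn = MODEL_FILTERS[model]
    return fn(outcomes, params)


def filter_predictions(model: str, params, u, opponents=None):
    """Per-trial gun-probability predictions, optionally with separate belief
    streams per opponent (sharing all parameters).

    Returns ``(predictions, trajectories)`` where ``trajectories`` maps
    opponent label (or ``'all'``) to the fitted trajectory over that
    opponent's trials, in encounter order.
    """
    u = _as_u(u)
    if opponents is None:
        traj = filter_outcomes(model, params, u)
        return np.asarray(traj.prediction, dtype=float), {"all": traj}
    opponents = np.asarray(opponents)
    if len(opponents) != len(u):
        raise ConfigurationError("opponent labels must align with outcomes")
    pred = np.empty(len(u))
    trajs = {}
    for opp in pd_unique(opponents):
        idx = np.where(opponents == opp)[0]
        traj = filter_outcomes(model, params, u[idx])
        pred[idx] = traj.prediction
        trajs[opp] = traj
    return pred, trajs


def simulate_agent(schedule, outcomes, model: str, params, seed: int,
                   missing_rate: float = 0.0, per_opponent: bool = True) -> ResponseSeries:
    """Simulate shoot/withhold responses from a learner.

    Filters the outcomes (per opponent by default), converts predictions to
    shoot probabilities via the unit-square sigmoid, and draws Bernoulli
    responses; a ``missing_rate`` fraction of trials is marked missing
    completely at random.
    """
    u = _as_u(outcomes)
    opp = schedule.opponent if (per_opponent and schedule is not None) else None
    pred, _ = filter_predictions(model, params, u, opponents=opp)
    p_shoot = response_prob(pred, params.zeta)
    rng = np.random.default_rng(seed)
    resp = (rng.random(len(u)) < p_shoot).astype(int)
    if missing_rate > 0:
        resp[rng.random(len(u)) < missing_rate] = MISSING
    return ResponseSeries(p_shoot=np.asarray(p_shoot, dtype=float), response=resp)


def trajectory_frame(subject, trajs: dict, opponents, zeta=None) -> "pd.DataFrame":
    """Tidy per-trial export of per-opponent HGF trajectories."""
    import pandas as pd

    opponents = np.asarray(opponents)
    n = len(opponents)
    out = {k: np.full(n, np.nan) for k in ("mu1_hat", "mu2", "sigma2", "delta", "epsilon")}
    for opp, traj in trajs.items():
        idx = np.arange(n) if opp == "all" else np.where(opponents == opp)[0]
        for k in out:
            out[k][idx] = getattr(traj, k)
    frame = pd.DataFrame({"subject": subject, "trial": np.arange(1, n + 1),
                          "opponent": opponents, **out})
    if zeta is not None:
        frame["p_shoot"] = response_prob(frame["mu1_hat"].to_numpy(), zeta)
    return frame


def _as_u(outcomes) -> np.ndarray:
    if hasattr(outcomes, "u"):
        outcomes = outcomes.u
    u = np.asarray(outcomes)
    if u.size and not np.isin(u, (0, 1)).all():
        raise ConfigurationError("outcomes must be coded 0 (phone) / 1 (gun)")
    return u.astype(int)


def pd_unique(values):
    """Unique values in order of first appearance."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
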