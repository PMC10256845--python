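"""Synthetic cohorts with known ground truth.

Agents play the shooting task as 2-level HGF learners whose volatility
differs by threat condition; a standard-normal latent antisociality trait
couples (with configurable signed weights) into the learning parameters,
and questionnaire subscales load linearly on two correlated traits
(aggression and psychopathy, r = 0.64 by default). A companion generator
emits subject-level MIMIC data (learning-parameter summaries + subscales)
directly from the structural model, for recovery studies of the
structural layer alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import observers, schedule as sched
from .errors import ConfigurationError
from .observers import Hgf2Params, MISSING, response_prob

BPAQ_SUBSCALES = ("bpaq_physical", "bpaq_verbal", "bpaq_anger", "bpaq_hostility")
SRP_SUBSCALES = ("srp_interpersonal", "srp_affective", "srp_lifestyle", "srp_antisocial")
EXTRA_SCALES = ("wsap_hostile", "spsrq_punishment", "spsrq_reward", "risq")

# default standardized couplings of the aggression trait into the learning
# parameters; signs follow hostile-expectation theory (slower belief updating,
# stronger prior hostile beliefs in more antisocial agents)
DEFAULT_COUPLINGS = {"omega": -0.3, "mu2_0": 0.3, "zeta": 0.0}

DEFAULT_LOADINGS = {
    **{k: v for k, v in zip(BPAQ_SUBSCALES, (0.75, 0.70, 0.80, 0.72))},
    **{k: v for k, v in zip(SRP_SUBSCALES, (0.78, 0.74, 0.70, 0.65))},
}

# per-emotion logistic intercepts/slopes of P(hostile) on intensity in [0,1];
# ordering of slopes (anger > disgust > fear > joy) follows the observed
# hostility-judgement gradient across emotions
DEFAULT_HIBT_STRUCTURE = {
    "anger": (-1.0, 4.0),
    "disgust": (-1.2, 2.5),
    "fear": (-1.5, 1.5),
    "joy": (-0.5, -2.0),
    "neutral": (-1.5, 0.0),
}


@dataclass(frozen=True)
class PopulationSpec:
    n_subjects: int = 40
    block_lengths: tuple = sched.DEFAULT_BLOCK_LENGTHS
    p_high: float = sched.DEFAULT_P_HIGH
    threat_period: int = sched.DEFAULT_THREAT_PERIOD
    # population means/SDs of the learning parameters, by condition
    omega_mean_high: float = -2.0
    omega_mean_low: float = -4.0
    omega_sd: float = 1.0
    log_zeta_mean: float = 0.5
    log_zeta_sd: float = 0.4
    mu2_0_sd: float = 0.5
    # trait -> parameter standardized couplings
    couplings: dict = field(default_factory=lambda: dict(DEFAULT_COUPLINGS))
    # questionnaire measurement model
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    trait_correlation: float = 0.64
    hibt_structure: dict = field(default_factory=lambda: dict(DEFAULT_HIBT_STRUCTURE))
    hibt_bias_coupling: float = 0.3
    missing_rate: float = 0.02

    def validate(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        if min(self.omega_sd, self.log_zeta_sd, self.mu2_0_sd) <= 0:
            raise ConfigurationError("population SDs must be positive")
        if any(abs(c) >= 1 for c in self.couplings.values()):
            raise ConfigurationError("standardized couplings must be in (-1, 1)")
        if not -1 < self.trait_correlation < 1:
            raise ConfigurationError("trait correlation must lie in (-1, 1)")
        if any(not 0 < abs(l) < 1 for l in self.loadings.values()):
            raise ConfigurationError("loadings must lie in (0, 1) in magnitude")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    trials: pd.DataFrame
    questionnaires: pd.DataFrame
    hibt: pd.DataFrame
    truth: pd.DataFrame
    spec: PopulationSpec
    seed: int


def _coupled(rng, trait, c, n):
    """Standardized draw correlating `c` with the trait."""
    return c * trait + np.sqrt(1.0 - c * c) * rng.standard_normal(n)


def generate_cohort(spec: PopulationSpec = PopulationSpec(), seed: int = 0) -> SyntheticCohort:
    """Draw a full synthetic cohort: task trials with HGF-generated responses,
    questionnaire subscales, interpretation-bias responses, and the truth table."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_subjects

    r = spec.trait_correlation
    trait_agg = rng.standard_normal(n)
    trait_psy = r * trait_agg + np.sqrt(1 - r * r) * rng.standard_normal(n)

    c = spec.couplings
    omega_z = _coupled(rng, trait_agg, c.get("omega", 0.0), n)
    omega_high = spec.omega_mean_high + spec.omega_sd * omega_z
    omega_low = spec.omega_mean_low + spec.omega_sd * omega_z
    log_zeta = spec.log_zeta_mean + spec.log_zeta_sd * _coupled(
        rng, trait_agg, c.get("zeta", 0.0), n)
    zeta = np.exp(log_zeta)
    mu2_0 = spec.mu2_0_sd * _coupled(rng, trait_agg, c.get("mu2_0", 0.0), n)
    hibt_bias = _coupled(rng, trait_agg, spec.hibt_bias_coupling, n)

    design = sched.build_schedule(spec.block_lengths, spec.p_high,
                                  spec.threat_period, seed=seed)
    trial_rows = []
    for s in range(n):
        u = sched.sample_outcomes(design, seed=int(seed + 7919 * (s + 1))).u
        resp = np.empty(design.n_trials, dtype=int)
        p_all = np.empty(design.n_trials)
        sub_rng = np.random.default_rng(seed + 104729 * (s + 1))
        for cond, om in (("high", omega_high[s]), ("low", omega_low[s])):
            idx = np.where(design.threat == cond)[0]
            params = Hgf2Params(omega=float(om), zeta=float(zeta[s]),
                                mu2_0=float(mu2_0[s]))
            pred, _ = observers.filter_predictions(
                "hgf2", params, u[idx], opponents=design.opponent[idx])
            p = response_prob(pred, params.zeta)
            resp[idx] = (sub_rng.random(len(idx)) < p).astype(int)
            p_all[idx] = p
        if spec.missing_rate > 0:
            resp[sub_rng.random(design.n_trials) < spec.missing_rate] = MISSING
        rt = np.exp(sub_rng.normal(np.log(500.0), 0.3, design.n_trials))
        rt[resp == MISSING] = np.nan
        frame = design.to_frame()
        frame.insert(0, "subject", s)
        frame["u"] = u
        frame["response"] = resp
        frame["rt_ms"] = rt
        trial_rows.append(frame)
    trials = pd.concat(trial_rows, ignore_index=True)

    quest = {"subject": np.arange(n)}
    for name in BPAQ_SUBSCALES:
        lam = spec.loadings[name]
        quest[name] = lam * trait_agg + np.sqrt(1 - lam * lam) * rng.standard_normal(n)
    for name in SRP_SUBSCALES:
        lam = spec.loadings[name]
        quest[name] = lam * trait_psy + np.sqrt(1 - lam * lam) * rng.standard_normal(n)
    quest["wsap_hostile"] = _coupled(rng, trait_agg, 0.25, n)
    quest["spsrq_punishment"] = _coupled(rng, trait_psy, -0.10, n)
    quest["spsrq_reward"] = _coupled(rng, trait_psy, 0.15, n)
    quest["risq"] = _coupled(rng, trait_psy, 0.30, n)
    questionnaires = pd.DataFrame(quest)

    hibt_design = sched.build_hibt_design(seed=seed)
    hibt = generate_hibt_responses(hibt_bias, hibt_design, seed=seed + 13,
                                   structure=spec.hibt_structure)

    truth = pd.DataFrame({
        "subject": np.arange(n), "trait_agg": trait_agg, "trait_psy": trait_psy,
        "omega_high": omega_high, "omega_low": omega_low, "zeta": zeta,
        "mu2_0": mu2_0, "hibt_bias": hibt_bias,
    })
    return SyntheticCohort(trials=trials, questionnaires=questionnaires,
                           hibt=hibt, truth=truth, spec=spec, seed=int(seed))


def generate_hibt_responses(bias, design: sched.HibtDesign, seed: int = 0,
                            structure=None) -> pd.DataFrame:
    """Simulate hostile/not judgements: P(hostile) = logistic(b0_emotion +
    b1_emotion * intensity + subject bias), intensity scaled to [0, 1]."""
    structure = dict(DEFAULT_HIBT_STRUCTURE if structure is None else structure)
    bias = np.asarray(bias, dtype=float)
    rng = np.random.default_rng(seed)
    main = design.main_trials
    emotions = main["emotion"].to_numpy()
    inten = np.nan_to_num(main["intensity"].to_numpy(dtype=float), nan=0.0) / 100.0
    b0 = np.array([structure[e][0] for e in emotions])
    b1 = np.array([structure[e][1] for e in emotions])
    rows = []
    for s, b in enumerate(bias):
        logits = b0 + b1 * inten + b
        p = 1.0 / (1.0 + np.exp(-logits))
        hostile = (rng.random(len(p)) < p).astype(int)
        rows.append(pd.DataFrame({
            "subject": s, "trial": np.arange(1, len(p) + 1),
            "emotion": emotions, "intensity": main["intensity"].to_numpy(),
            "hostile": hostile,
        }))
    return pd.concat(rows, ignore_index=True)


# default standardized structural weights for MIMIC recovery cohorts: the
# printed-scale pattern (omega negative; mu, sigma, epsilon positive; zeta
# null), with magnitudes scaled so the weights are admissible for independent
# standardized predictors (sum of squares < 1)
DEFAULT_MIMIC_B = {"omega": -0.20, "mu": 0.60, "sigma": 0.35,
                   "epsilon": 0.55, "zeta": 0.0}


def generate_mimic_cohort(n_subjects: int, b=None, loadings=(0.75, 0.80, 0.70, 0.85),
                          seed: int = 0,
                          subscales=BPAQ_SUBSCALES) -> pd.DataFrame:
    """Subject-level MIMIC data: independent standardized learning-parameter
    summaries, a latent trait regressed on them with weights ``b``, and
    subscales loading on the trait. The true trait is kept in column
    ``trait`` for recovery checks."""
    b = dict(DEFAULT_MIMIC_B if b is None else b)
    bvec = np.array(list(b.values()), dtype=float)
    resid = 1.0 - float(bvec @ bvec)
    if resid <= 0:
        raise ConfigurationError(
            "structural weights too large: sum of squares must be < 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_subjects, len(bvec)))
    trait = x @ bvec + np.sqrt(resid) * rng.standard_normal(n_subjects)
    data = {name: x[:, k] for k, name in enumerate(b)}
    for name, lam in zip(subscales, loadings):
        data[name] = lam * trait + np.sqrt(1 - lam * lam) * rng.standard_normal(n_subjects)
    data["trait"] = trait
    return pd.DataFrame(data)


def end_to_end_truth_check(cohort: SyntheticCohort, fitted_params: pd.DataFrame = None,
                           bms_result=None, generating_model: str = "hgf2",
                           condition_tests: dict = None,
                           sem_fit=None, sem_ci: dict = None) -> dict:
    """Compare pipeline outputs against the generator's ground truth.

    Any subset of outputs may be supplied; each present piece contributes a
    pass/fail entry with the measured value alongside.
    """
    from . import stats as st
    from .observers import MODEL_NAMES

    report = {}
    truth = cohort.truth.set_index("subject")
    if fitted_params is not None:
        fp = fitted_params.set_index("subject")
        for cond in ("high", "low"):
            sub = fp[fp["condition"] == cond] if "condition" in fp.columns else fp
            common = truth.index.intersection(sub.index)
            if len(common) >= 4 and "omega" in sub.columns:
                r = float(np.corrcoef(truth.loc[common, f"omega_{cond}"],
                                      sub.loc[common, "omega"])[0, 1])
                report[f"omega_recovery_r_{cond}"] = {"value": r, "pass": r > 0.0}
        if "zeta" in fp.columns:
            z = fp.groupby(level=0)["zeta"].mean()
            common = truth.index.intersection(z.index)
            r = float(np.corrcoef(truth.loc[common, "zeta"], z.loc[common])[0, 1])
            report["zeta_recovery_r"] = {"value": r, "pass": r > 0.0}
    if bms_result is not None:
        winner = MODEL_NAMES[int(np.argmax(bms_result.exceedance_prob))]
        report["bms_winner"] = {"value": winner, "pass": winner == generating_model}
    if condition_tests is not None:
        null_gen = np.isclose(cohort.spec.omega_mean_high, cohort.spec.omega_mean_low)
        flagged = [k for k, t in condition_tests.items()
                   if st.significant_by_both(t.p_value, t.bf10 or 0.0)]
        report["condition_contrasts_flagged"] = {
            "value": flagged,
            "pass": (len(flagged) == 0) if null_gen else ("omega" in flagged)}
    if sem_fit is not None:
        signs = {}
        expected = {"omega": -1, "mu": 1, "sigma": 1, "epsilon": 1}
        for (lat, cov), est in sem_fit.std_regressions.items():
            if cov in expected:
                ok = np.sign(est) == expected[cov] and sem_fit.p_values[(lat, cov)] < 0.05
                if sem_ci is not None:
                    lo, hi = sem_ci[(lat, cov)]
                    ok = ok and not (lo <= 0 <= hi)
                signs[cov] = bool(ok)
            elif cov == "zeta" and sem_ci is not None:
                lo, hi = sem_ci[(lat, cov)]
                signs["zeta_null"] = bool(lo <= 0 <= hi)
        report["sem_sign_recovery"] = {"value": signs, "pass": all(signs.values())}
    return report
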