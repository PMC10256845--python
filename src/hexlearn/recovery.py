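"""Recovery and calibration studies.

Parameter/model recovery — simulating agents from known parameters,
refitting, and quantifying agreement — is the core validity check for a
cognitive-modelling pipeline. This module bundles the four studies the
package uses to validate itself end to end; each is fully seeded and
returns plain dictionaries of measured quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bms as bms_mod, fit as fit_mod, schedule as sched, sem as sem_mod
from . import observers, stats as st, synth
from .errors import HexlearnError
from .observers import Hgf2Params, MODEL_NAMES

# population dispersion used when drawing agents for recovery studies
OMEGA_MEAN, OMEGA_SD = -3.0, 1.2
LOG_ZETA_MEAN, LOG_ZETA_SD = 0.5, 0.5

SEM_RECOVERY_MODEL = (
    "agg =~ bpaq_physical + bpaq_verbal + bpaq_anger + bpaq_hostility\n"
    "agg ~ omega + mu + sigma + epsilon + zeta"
)


def _draw_agent(rng) -> Hgf2Params:
    return Hgf2Params(omega=float(rng.normal(OMEGA_MEAN, OMEGA_SD)),
                      zeta=float(np.exp(rng.normal(LOG_ZETA_MEAN, LOG_ZETA_SD))))


def model_selection_study(n_agents: int = 50, seed: int = 0, n_starts: int = 3,
                          models=MODEL_NAMES, generating_model: str = "hgf2") -> dict:
    """Simulate a cohort from the 2-level HGF, fit all candidate models, and
    run random-effects model selection. Returns the log-evidence matrix and
    the exceedance probability of the generating model."""
    rng = np.random.default_rng(seed)
    design = sched.build_schedule(seed=seed)
    lme = np.empty((n_agents, len(models)))
    for a in range(n_agents):
        params = _draw_agent(rng)
        u = sched.sample_outcomes(design, seed=seed + 1000 + a).u
        resp = observers.simulate_agent(design, u, generating_model, params,
                                        seed=seed + 2000 + a)
        for k, m in enumerate(models):
            try:
                res = fit_mod.fit_map(u, resp.response, model=m,
                                      n_starts=n_starts, seed=seed + 31 * a + k,
                                      opponents=design.opponent)
                lme[a, k] = res.log_model_evidence
            except HexlearnError:
                lme[a, k] = -1e6
    bms_res = bms_mod.random_effects_bms(lme, seed=seed + 99)
    gen_idx = list(models).index(generating_model)
    return {
        "models": list(models),
        "lme": lme,
        "bms": bms_res,
        "exceedance_generating": float(bms_res.exceedance_prob[gen_idx]),
        "winner": list(models)[int(np.argmax(bms_res.exceedance_prob))],
    }


def parameter_recovery_study(n_agents: int = 100, seed: int = 0,
                             n_starts: int = 4) -> dict:
    """Simulate agents with dispersed (omega, zeta), refit, and measure
    true-vs-fitted parameter correlations plus per-agent correlations between
    generating and refitted belief trajectories (mu2, sigma2, epsilon)."""
    rng = np.random.default_rng(seed)
    design = sched.build_schedule(seed=seed)
    true_om, true_ze, est_om, est_ze = [], [], [], []
    traj_r = {"mu2": [], "sigma2": [], "epsilon": []}
    for a in range(n_agents):
        params = _draw_agent(rng)
        u = sched.sample_outcomes(design, seed=seed + 1000 + a).u
        resp = observers.simulate_agent(design, u, "hgf2", params,
                                        seed=seed + 2000 + a)
        res = fit_mod.fit_map(u, resp.response, model="hgf2", n_starts=n_starts,
                              seed=seed + 7 * a, opponents=design.opponent)
        true_om.append(params.omega); true_ze.append(params.zeta)
        est_om.append(res.estimates["omega"]); est_ze.append(res.estimates["zeta"])
        _, gen_trajs = observers.filter_predictions("hgf2", params, u,
                                                    opponents=design.opponent)
        for key in traj_r:
            g = np.concatenate([getattr(gen_trajs[o], key) for o in sorted(gen_trajs)])
            f = np.concatenate([getattr(res.trajectories[o], key)
                                for o in sorted(res.trajectories)])
            traj_r[key].append(float(np.corrcoef(g, f)[0, 1]))
    return {
        "r_omega": float(np.corrcoef(true_om, est_om)[0, 1]),
        "r_zeta": float(np.corrcoef(true_ze, est_ze)[0, 1]),
        "median_traj_r": {k: float(np.median(v)) for k, v in traj_r.items()},
        "true": pd.DataFrame({"omega": true_om, "zeta": true_ze}),
        "fitted": pd.DataFrame({"omega": est_om, "zeta": est_ze}),
    }


def sem_recovery_study(n_replicates: int = 50, n_subjects: int = 500,
                       n_boot: int = 200, seed: int = 0) -> dict:
    """Replicate MIMIC cohorts with the built-in signed structural weights
    (negative on omega; positive on mu, sigma, epsilon; null on zeta), fit the
    structural model, and score each replicate as recovered when every
    non-null path is significant (p < 0.05 AND bootstrap CI excluding zero)
    with the generating sign, while the zeta path's CI covers zero."""
    expected_sign = {k: np.sign(v) for k, v in synth.DEFAULT_MIMIC_B.items() if v != 0}
    model = sem_mod.parse_model(SEM_RECOVERY_MODEL)
    successes, records = [], []
    for rep in range(n_replicates):
        data = synth.generate_mimic_cohort(n_subjects, seed=seed + 101 * rep)
        fit = sem_mod.fit_ml_sem(data, model, seed=seed + rep)
        ci = sem_mod.bootstrap_ci(data, model, n_boot=n_boot,
                                  seed=seed + 13 * rep, fit=fit)
        ok = True
        rec = {"replicate": rep, "cfi": fit.cfi, "chi_square": fit.chi_square}
        for (lat, cov), est in fit.std_regressions.items():
            lo, hi = ci[(lat, cov)]
            rec[cov] = est
            if cov in expected_sign:
                ok &= (np.sign(est) == expected_sign[cov]
                       and fit.p_values[(lat, cov)] < 0.05
                       and not (lo <= 0 <= hi))
            elif cov == "zeta":
                ok &= (lo <= 0 <= hi)
        successes.append(bool(ok))
        records.append(rec)
    return {
        "recovery_rate": float(np.mean(successes)),
        "replicates": pd.DataFrame(records),
        "n_replicates": n_replicates,
    }


def null_condition_study(n_runs: int = 50, n_subjects: int = 24, seed: int = 0,
                         n_starts: int = 2) -> dict:
    """Calibration on cohorts with no condition difference and no trait
    coupling: fraction of runs in which no condition contrast is flagged by
    the dual criterion (p < 0.05 AND BF10 > 3)."""
    spec = synth.PopulationSpec(
        n_subjects=n_subjects, omega_mean_high=-3.0, omega_mean_low=-3.0,
        couplings={"omega": 0.0, "mu2_0": 0.0, "zeta": 0.0}, missing_rate=0.0)
    clean, flag_counts = [], []
    for run in range(n_runs):
        cohort = synth.generate_cohort(spec, seed=seed + 977 * run)
        rows = []
        for s, sub in cohort.trials.groupby("subject"):
            cond = fit_mod.fit_by_condition(sub, model="hgf2", n_starts=n_starts,
                                            seed=seed + 11 * run + int(s))
            rows.append(fit_mod.summarize_conditions(cond, subject=s))
        summaries = pd.concat(rows, ignore_index=True)
        wide = summaries.pivot(index="subject", columns="condition")
        flags = 0
        for par in ("omega", "mean_mu2", "mean_sigma2", "mean_epsilon", "zeta"):
            res = st.paired_t(wide[(par, "high")].to_numpy(),
                              wide[(par, "low")].to_numpy())
            flags += int(st.significant_by_both(res.p_value, res.bf10))
        flag_counts.append(flags)
        clean.append(flags == 0)
    return {
        "clean_rate": float(np.mean(clean)),
        "flag_counts": flag_counts,
        "n_runs": n_runs,
    }
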