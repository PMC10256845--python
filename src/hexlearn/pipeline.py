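"""Pipeline orchestration: simulate -> fit -> select -> summarize -> SEM.

Each stage reads and writes plain CSV/JSON under a run directory and is
driven by a YAML/dict config with explicit seeds. A machine-readable
manifest (stage seeds, file hashes, package version) and a human-readable
Markdown report are written at the end of a full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bms as bms_mod, fit as fit_mod, sem as sem_mod, stats as st
from . import synth
from .errors import ConfigurationError, HexlearnError, InsufficientDataError, ValidationError
from .observers import MISSING, MODEL_NAMES

log = logging.getLogger("hexlearn")

DEFAULT_CONFIG = {
    "seed": None,  # required, fail fast if absent
    "n_subjects": 20,
    "models": ["hgf2", "rw"],
    "prior_preset": "default",
    "n_starts": 3,
    "max_missing_fraction": 0.25,
    "outlier_k_sd": 2.0,
    "threat_period": 20,
    "missing_rate": 0.02,
    "sem_bootstrap": 200,
    "sem_model": (
        "agg =~ bpaq_physical + bpaq_verbal + bpaq_anger + bpaq_hostility\n"
        "agg ~ omega + mean_mu2 + mean_sigma2 + mean_epsilon + zeta"
    ),
}


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    n_subjects_trials: int = 0
    n_subjects_questionnaires: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping or a YAML file path")
    cfg = {**DEFAULT_CONFIG, **config}
    if cfg.get("seed") is None:
        raise ConfigurationError("config must set an explicit 'seed'")
    unknown = [m for m in cfg["models"] if m not in MODEL_NAMES]
    if unknown:
        raise ConfigurationError(f"unknown models in config: {unknown}")
    return cfg


def stage_seed(master_seed: int, stage_index: int) -> int:
    """One deterministic sub-seed per stage, recorded in the manifest."""
    return int((int(master_seed) + 1000003 * (stage_index + 1)) % (2 ** 31))


def validate_inputs(trials: pd.DataFrame, questionnaires: pd.DataFrame = None) -> ValidationReport:
    """Schema, range and alignment checks on pipeline input tables."""
    rep = ValidationReport()
    need = {"subject", "trial", "opponent", "threat", "u", "response"}
    missing_cols = sorted(need - set(trials.columns))
    if missing_cols:
        rep.errors.append(f"trial table missing columns {missing_cols}")
        return rep
    bad_u = trials.loc[~trials["u"].isin([0, 1])]
    for _, row in bad_u.iterrows():
        rep.errors.append(
            f"subject {row['subject']} trial {row['trial']}: u={row['u']} not in {{0,1}}")
    valid_resp = {MISSING, 0, 1, "shoot", "withhold", "missing"}
    bad_r = trials.loc[~trials["response"].isin(valid_resp)]
    for _, row in bad_r.iterrows():
        rep.errors.append(
            f"subject {row['subject']} trial {row['trial']}: "
            f"response={row['response']!r} invalid")
    bad_t = set(trials["threat"]) - {"high", "low"}
    if bad_t:
        rep.errors.append(f"unknown threat labels {sorted(bad_t)}")
    rep.n_subjects_trials = trials["subject"].nunique()
    if questionnaires is not None:
        if "subject" not in questionnaires.columns:
            rep.errors.append("questionnaire table lacks a 'subject' column")
        else:
            rep.n_subjects_questionnaires = questionnaires["subject"].nunique()
            task_only = set(trials["subject"]) - set(questionnaires["subject"])
            if task_only:
                rep.warnings.append(
                    f"{len(task_only)} subject(s) have trials but no questionnaires; "
                    "routed to task-only analyses")
            quest_only = set(questionnaires["subject"]) - set(trials["subject"])
            if quest_only:
                rep.warnings.append(
                    f"{len(quest_only)} subject(s) have questionnaires but no trials")
    return rep


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(cfg: dict, out_dir: Path) -> synth.SyntheticCohort:
    spec = synth.PopulationSpec(n_subjects=cfg["n_subjects"],
                                threat_period=cfg["threat_period"],
                                missing_rate=cfg["missing_rate"])
    cohort = synth.generate_cohort(spec, seed=stage_seed(cfg["seed"], 0))
    cohort.trials.to_csv(out_dir / "trials.csv", index=False)
    cohort.questionnaires.to_csv(out_dir / "questionnaires.csv", index=False)
    cohort.hibt.to_csv(out_dir / "hibt.csv", index=False)
    cohort.truth.to_csv(out_dir / "truth.csv", index=False)
    return cohort


def stage_fit(trials: pd.DataFrame, cfg: dict, out_dir: Path):
    """Fit every configured model per subject (whole task) for model
    selection, plus per-condition 2-level HGF fits and summaries."""
    seed = stage_seed(cfg["seed"], 1)
    include = fit_mod.exclude_missing(trials, cfg["max_missing_fraction"])
    kept = [s for s in include.index if include[s]]
    lme_rows, summary_rows = [], []
    for s in kept:
        sub = trials[trials["subject"] == s]
        u = sub["u"].to_numpy()
        resp = sub["response"].to_numpy()
        opp = sub["opponent"].to_numpy()
        row = {"subject": s}
        for m in cfg["models"]:
            try:
                res = fit_mod.fit_map(u, resp, model=m, priors=cfg["prior_preset"],
                                      n_starts=cfg["n_starts"], seed=seed + s,
                                      opponents=opp)
                row[m] = res.log_model_evidence
            except HexlearnError as exc:
                log.warning("subject %s model %s failed: %s", s, m, exc)
                row[m] = np.nan
        lme_rows.append(row)
        try:
            cond_fits = fit_mod.fit_by_condition(
                sub, model="hgf2", priors=cfg["prior_preset"],
                n_starts=cfg["n_starts"], seed=seed + s)
            summary_rows.append(fit_mod.summarize_conditions(cond_fits, subject=s))
        except InsufficientDataError as exc:
            log.warning("subject %s condition fits skipped: %s", s, exc)
    lme = pd.DataFrame(lme_rows).set_index("subject")
    summaries = (pd.concat(summary_rows, ignore_index=True)
                 if summary_rows else pd.DataFrame())
    lme.to_csv(out_dir / "log_model_evidence.csv")
    summaries.to_csv(out_dir / "condition_summaries.csv", index=False)
    excluded = sorted(set(include.index) - set(kept))
    (out_dir / "exclusions.json").write_text(json.dumps(
        {"missing_rule_excluded": excluded,
         "max_missing_fraction": cfg["max_missing_fraction"]}, indent=2))
    return lme, summaries


def stage_bms(lme: pd.DataFrame, cfg: dict, out_dir: Path) -> dict:
    seed = stage_seed(cfg["seed"], 2)
    clean = lme.dropna()
    res = bms_mod.random_effects_bms(clean.to_numpy(), seed=seed)
    fixed = bms_mod.fixed_effects_bms(clean.to_numpy())
    out = {
        "models": list(lme.columns),
        "n_subjects": int(len(clean)),
        "alpha": res.alpha.tolist(),
        "expected_freq": res.expected_freq.tolist(),
        "exceedance_prob": res.exceedance_prob.tolist(),
        "fixed_effects_log_bf": fixed.tolist(),
        "winner": lme.columns[int(np.argmax(res.exceedance_prob))],
    }
    (out_dir / "bms.json").write_text(json.dumps(out, indent=2))
    return out


def condition_contrasts(summaries: pd.DataFrame) -> dict:
    """Paired high-vs-low tests on the five condition-level parameters."""
    wide = summaries.pivot(index="subject", columns="condition")
    tests = {}
    for par in ("omega", "mean_mu2", "mean_sigma2", "mean_epsilon", "zeta"):
        hi = wide[(par, "high")].to_numpy()
        lo = wide[(par, "low")].to_numpy()
        ok = ~(np.isnan(hi) | np.isnan(lo))
        tests[par] = st.paired_t(hi[ok], lo[ok])
    return tests


def behavioural_anova(trials: pd.DataFrame) -> dict:
    """2x2 within-subject ANOVA on shoot percentage by gun-probability level
    and threat."""
    t = trials[trials["response"] != MISSING].copy()
    t["p_level"] = np.where(t["p_gun"] > 0.5, "high", "low")
    cells = (t.groupby(["subject", "p_level", "threat"])["response"].mean()
             .unstack(["p_level", "threat"]))
    ordered = cells[[("high", "high"), ("high", "low"),
                     ("low", "high"), ("low", "low")]]
    return st.rm_anova_2x2(ordered.to_numpy() * 100.0)


def stage_stats(trials: pd.DataFrame, summaries: pd.DataFrame, cfg: dict,
                out_dir: Path) -> dict:
    anova = behavioural_anova(trials)
    contrasts = condition_contrasts(summaries) if len(summaries) else {}
    out = {
        "shoot_anova": {k: v.to_dict() for k, v in anova.items()},
        "condition_contrasts": {
            k: {**v.to_dict(),
                "significant_by_both": st.significant_by_both(v.p_value, v.bf10)}
            for k, v in contrasts.items()},
    }
    (out_dir / "stats.json").write_text(json.dumps(out, indent=2, default=float))
    return out


def stage_sem(summaries: pd.DataFrame, questionnaires: pd.DataFrame, cfg: dict,
              out_dir: Path) -> dict:
    seed = stage_seed(cfg["seed"], 4)
    high = summaries[summaries["condition"] == "high"].set_index("subject")
    high = high.rename(columns={"omega": "omega", "zeta": "zeta"})
    data = questionnaires.set_index("subject").join(high, how="inner").dropna()
    model = sem_mod.parse_model(cfg["sem_model"])
    fit = sem_mod.fit_ml_sem(data, model, seed=seed)
    ci = sem_mod.bootstrap_ci(data, model, n_boot=cfg["sem_bootstrap"],
                              seed=seed, fit=fit)
    out = {
        "n": fit.n, "chi_square": fit.chi_square, "df": fit.df,
        "p_value": fit.p_value, "cfi": fit.cfi, "rmsea": fit.rmsea,
        "srmr": fit.srmr, "converged": fit.converged,
        "std_regressions": {f"{l}~{c}": v for (l, c), v in fit.std_regressions.items()},
        "std_loadings": {f"{l}=~{i}": v for (l, i), v in fit.std_loadings.items()},
        "p_values": {f"{l}~{c}": fit.p_values[(l, c)] for (l, c) in fit.regressions},
        "bootstrap_ci": {f"{l}~{c}": list(v) for (l, c), v in ci.items()},
        "significant_by_both": {
            f"{l}~{c}": bool(fit.p_values[(l, c)] < 0.05
                             and not (ci[(l, c)][0] <= 0 <= ci[(l, c)][1]))
            for (l, c) in fit.regressions},
    }
    (out_dir / "sem.json").write_text(json.dumps(out, indent=2, default=float))
    return out


def run_pipeline(config, out_dir) -> Path:
    """Execute all stages in order; returns the run directory."""
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": {k: v for k, v in cfg.items()},
                "stage_seeds": {name: stage_seed(cfg["seed"], i) for i, name in
                                enumerate(["simulate", "fit", "bms", "stats", "sem"])}}
    stage = "simulate"
    try:
        cohort = stage_simulate(cfg, out_dir)
        rep = validate_inputs(cohort.trials, cohort.questionnaires)
        if not rep.ok:
            raise ValidationError("generated tables failed validation", rep.errors)
        stage = "fit"
        lme, summaries = stage_fit(cohort.trials, cfg, out_dir)
        stage = "bms"
        bms_out = stage_bms(lme, cfg, out_dir) if lme.shape[1] >= 2 else None
        stage = "stats"
        stats_out = stage_stats(cohort.trials, summaries, cfg, out_dir)
        stage = "sem"
        sem_out = stage_sem(summaries, cohort.questionnaires, cfg, out_dir)
    except HexlearnError as exc:
        raise HexlearnError(f"stage {stage!r} failed: {exc}") from exc
    manifest["files"] = {p.name: _sha256(p) for p in sorted(out_dir.iterdir())
                         if p.suffix in (".csv", ".json") and p.name != "manifest.json"}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    _write_report(out_dir, bms_out, stats_out, sem_out)
    return out_dir


def _write_report(out_dir: Path, bms_out, stats_out, sem_out):
    lines = ["# Pipeline report", ""]
    if stats_out:
        lines += ["## Shoot-percentage ANOVA (gun probability x threat)", ""]
        for eff, d in stats_out["shoot_anova"].items():
            lines.append(f"- {eff}: F={d['statistic']:.2f}, p={d['p_value']:.4f}, "
                         f"BF10~{d['bf10']:.2f} (BIC approx.)")
        lines += ["", "## High vs low threat parameter contrasts", ""]
        for par, d in stats_out["condition_contrasts"].items():
            flag = "significant by both criteria" if d["significant_by_both"] else "ns"
            lines.append(f"- {par}: t={d['statistic']:.2f}, p={d['p_value']:.4f}, "
                         f"BF10={d['bf10']:.2f} -> {flag}")
    if bms_out:
        lines += ["", "## Bayesian model selection", ""]
        for m, xp in zip(bms_out["models"], bms_out["exceedance_prob"]):
            lines.append(f"- {m}: exceedance probability {xp:.3f}")
        lines.append(f"- winner: {bms_out['winner']}")
    if sem_out:
        lines += ["", "## Structural model (high threat)", ""]
        lines.append(f"- chi2({sem_out['df']}) = {sem_out['chi_square']:.2f}, "
                     f"p = {sem_out['p_value']:.3f}, CFI = {sem_out['cfi']:.3f}, "
                     f"RMSEA = {sem_out['rmsea']:.3f}, SRMR = {sem_out['srmr']:.3f}")
        for path, b in sem_out["std_regressions"].items():
            lines.append(f"- {path}: B = {b:+.3f}, p = {sem_out['p_values'][path]:.3f}, "
                         f"CI = [{sem_out['bootstrap_ci'][path][0]:+.3f}, "
                         f"{sem_out['bootstrap_ci'][path][1]:+.3f}]")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
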