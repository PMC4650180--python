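"""Reproducible pipeline: simulate -> activity -> breakpoints -> boost -> trends -> MECMR.

A single global seed is expanded deterministically into per-stage child
seeds; every artifact is a commented CSV (or JSON) carrying the seed, and a
run manifest records counts, seeds and headline statistics for the whole
run.  Stages can be toggled; disabled stages simply drop out of the manifest
without affecting the others (inputs are then read from the configured
paths).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import daily_profiles_all, read_profiles_csv, write_profiles_csv
from .boost import cv_error, cumulative_importance_ranking, permutation_pvalue, train_samme
from .config import EVENTS, RP_STATES, ConfigError, SimulationConfig
from .mecmr import (
    MecmrSpec,
    empirical_transition_matrix,
    fit_mecmr,
    longrun_success,
    model_table,
)
from .segmented import select_n_breakpoints
from .simulate import (
    read_encounters_csv,
    read_immersion_csv,
    read_phenology_csv,
    simulate_encounter_histories,
    simulate_immersion,
    simulate_phenology,
    write_encounters_csv,
    write_immersion_csv,
    write_phenology_csv,
)
from .trends import compare_groups, plot_ecdf_panels, pooled_group_trend_values, sex_contrasts

log = logging.getLogger("carryover")

ALL_STAGES = ("simulate", "activity", "breakpoints", "boost", "trends", "mecmr")


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run."""

    stages: tuple = ALL_STAGES
    outdir: str = "carryover_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)   # SimulationConfig overrides
    activity: dict = field(default_factory=dict)   # thresholds, include_night
    breakpoints: dict = field(default_factory=dict)  # max_k, criterion, n_restarts
    boost: dict = field(default_factory=dict)      # k_folds, m_rounds, tree_depth, n_perm
    trends: dict = field(default_factory=dict)     # period, alpha, plots
    mecmr: dict = field(default_factory=dict)      # n_starts, fit_mixture, n_boot
    inputs: dict = field(default_factory=dict)     # paths when simulate disabled
    write_immersion: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        if "simulate" not in self.stages:
            needed = set()
            if "activity" in self.stages:
                needed.add("immersion")
            if {"breakpoints", "trends"} & set(self.stages) and "activity" not in self.stages:
                needed.add("profiles")
            if {"boost", "trends", "breakpoints"} & set(self.stages):
                needed.add("phenology")
            if "mecmr" in self.stages:
                needed.add("encounters")
            missing = [k for k in needed if k not in self.inputs]
            if missing:
                raise ConfigError(
                    f"stages {self.stages} need input paths for {sorted(missing)}"
                )
            for k, p in self.inputs.items():
                if not Path(p).exists():
                    raise ConfigError(f"input path for {k!r} does not exist: {p}")


def _child_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ALL_STAGES))
    return {
        stage: int(c.generate_state(1)[0] % 2**31)
        for stage, c in zip(ALL_STAGES, children)
    }


def _sim_config(overrides: dict, seed: int) -> SimulationConfig:
    kw = dict(overrides)
    if "psi" in kw:
        kw["psi"] = np.asarray(kw["psi"], dtype=float)
    cfg = SimulationConfig(**kw, seed=seed) if "seed" not in kw else SimulationConfig(**kw)
    cfg.validate()
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: seeds[s] for s in config.stages},
        "generated": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    phenology = immersion = profiles = histories = None
    try:
        if "simulate" in config.stages:
            sim_cfg = _sim_config(config.simulate, seeds["simulate"])
            phenology = simulate_phenology(sim_cfg, seed=seeds["simulate"])
            immersion = simulate_immersion(sim_cfg, phenology, seed=seeds["simulate"] + 1)
            histories, truth = simulate_encounter_histories(
                sim_cfg, seed=seeds["simulate"] + 2
            )
            write_phenology_csv(phenology, outdir / "phenology.csv", seeds["simulate"])
            write_encounters_csv(histories, outdir / "encounters.csv", seeds["simulate"])
            if config.write_immersion:
                write_immersion_csv(immersion, outdir / "immersion.csv", seeds["simulate"])
            by_rp = phenology["rp"].value_counts().to_dict()
            manifest["stages"]["simulate"] = {
                "n_logger_bird_seasons": int(len(phenology)),
                "bird_seasons_by_rp": {k: int(by_rp.get(k, 0)) for k in RP_STATES},
                "n_history_only": int(sim_cfg.n_birds_history_only),
                "n_histories_total": int(len(histories)),
                "true_parameters": {
                    k: v for k, v in truth.items() if not isinstance(v, np.ndarray)
                },
            }
        else:
            if "phenology" in config.inputs:
                phenology = read_phenology_csv(config.inputs["phenology"])
            if "immersion" in config.inputs:
                immersion = read_immersion_csv(config.inputs["immersion"])
            if "encounters" in config.inputs:
                histories = read_encounters_csv(config.inputs["encounters"])

        if "activity" in config.stages:
            thresholds = tuple(config.activity.get("thresholds", (0.05, 0.95)))
            include_night = bool(config.activity.get("include_night", False))
            profiles = daily_profiles_all(immersion, thresholds, include_night)
            write_profiles_csv(profiles, outdir / "daily_profiles.csv", seeds["activity"])
            manifest["stages"]["activity"] = {
                "n_bird_days": int(len(profiles)),
                "n_birds": int(profiles["bird_id"].nunique()),
                "thresholds": list(thresholds),
            }
        elif "profiles" in config.inputs:
            profiles = read_profiles_csv(config.inputs["profiles"])

        if "breakpoints" in config.stages:
            bp = config.breakpoints
            rows = []
            for bird, sub in profiles.groupby("bird_id"):
                sub = sub.sort_values("date")
                x = np.arange(len(sub), dtype=float)
                fit = select_n_breakpoints(
                    x,
                    sub["p_fly"].to_numpy(float),
                    max_k=int(bp.get("max_k", 2)),
                    criterion=bp.get("criterion", "BIC"),
                    n_restarts=int(bp.get("n_restarts", 10)),
                    seed=seeds["breakpoints"],
                )
                rows.append(
                    {
                        "bird_id": bird,
                        "k": fit.n_breakpoints,
                        "tau": ";".join(f"{t:.2f}" for t in fit.tau),
                        "slopes": ";".join(f"{s:.6f}" for s in fit.slopes),
                        "rss": fit.rss,
                        "converged": fit.converged,
                    }
                )
            bp_df = pd.DataFrame(rows)
            bp_df.to_csv(outdir / "breakpoints.csv", index=False)
            manifest["stages"]["breakpoints"] = {
                "n_birds": int(len(bp_df)),
                "k_distribution": bp_df["k"].value_counts().sort_index().to_dict(),
            }

        if "boost" in config.stages:
            bo = config.boost
            report = cv_error(
                phenology,
                k_folds=int(bo.get("k_folds", 10)),
                m_rounds=int(bo.get("m_rounds", 100)),
                tree_depth=int(bo.get("tree_depth", 1)),
                seed=seeds["boost"],
            )
            model = train_samme(
                phenology,
                m_rounds=int(bo.get("m_rounds", 100)),
                tree_depth=int(bo.get("tree_depth", 1)),
                seed=seeds["boost"],
            )
            ranking = cumulative_importance_ranking(model)
            ranking.to_csv(outdir / "feature_importance.csv", index=False)
            summary = {
                "cv_error_percent": round(report.error_percent, 4),
                "cv_success_percent": round(report.success_percent, 4),
                "n_records": report.n_used,
                "top_features": ranking["feature"].head(3).tolist(),
            }
            n_perm = int(bo.get("n_perm", 0))
            if n_perm > 0:
                summary["permutation_p"] = permutation_pvalue(
                    phenology,
                    n_perm=n_perm,
                    k_folds=int(bo.get("k_folds", 10)),
                    m_rounds=int(bo.get("m_rounds", 100)),
                    seed=seeds["boost"],
                )
            manifest["stages"]["boost"] = summary

        if "trends" in config.stages:
            tr = config.trends
            period = int(tr.get("period", 7))
            alpha = float(tr.get("alpha", 0.01))
            labels = dict(zip(phenology["bird_id"], phenology["rp"]))
            pooled = pooled_group_trend_values(profiles, labels, period)
            comparisons = compare_groups(pooled, alpha=alpha)
            comp_df = pd.DataFrame([dataclasses.asdict(c) for c in comparisons])
            comp_df.to_csv(outdir / "comparisons.csv", index=False)
            sexes = dict(zip(phenology["bird_id"], phenology["sex"]))
            sex_res = sex_contrasts(profiles, sexes, period)
            if tr.get("plots", False):
                plot_ecdf_panels(pooled, outdir / "ecdf_panels.png")
            manifest["stages"]["trends"] = {
                "period": period,
                "n_comparisons": len(comparisons),
                "bonferroni_alpha": comparisons[0].bonferroni_alpha,
                "n_significant": int(sum(c.significant for c in comparisons)),
                "sex_p_values": {k: round(v[1], 4) for k, v in sex_res.items()},
            }

        if "mecmr" in config.stages:
            me = config.mecmr
            n_starts = int(me.get("n_starts", 10))
            fits = [
                fit_mecmr(
                    histories,
                    MecmrSpec(name="baseline"),
                    n_starts=n_starts,
                    seed=seeds["mecmr"],
                )
            ]
            if me.get("fit_mixture", True):
                fits.append(
                    fit_mecmr(
                        histories,
                        MecmrSpec(n_mixture_classes=2, name="mixture-2"),
                        n_starts=n_starts,
                        seed=seeds["mecmr"] + 1,
                    )
                )
            table = model_table(fits)
            table.to_csv(outdir / "mecmr_models.csv", index=False)
            best = fits[int(np.argmin([f.aic for f in fits]))]
            lr = longrun_success(
                best, mode=me.get("mode", "next_year"),
                n_boot=int(me.get("n_boot", 1000)), seed=seeds["mecmr"],
            )
            lr.to_csv(outdir / "longrun_success.csv", index=False)
            freq, counts, n_excl = empirical_transition_matrix(histories)
            pd.DataFrame(freq, index=RP_STATES, columns=RP_STATES).to_csv(
                outdir / "empirical_transitions.csv"
            )
            manifest["stages"]["mecmr"] = {
                "n_histories": len(histories),
                "best_model": best.spec.label(),
                "model_table": table.to_dict(orient="records"),
                "longrun_success": {
                    r.from_state: [round(r.prob_success, 4),
                                   round(r.ci_lo, 4) if np.isfinite(r.ci_lo) else None,
                                   round(r.ci_hi, 4) if np.isfinite(r.ci_hi) else None]
                    for r in lr.itertuples()
                },
                "empirical_psi": np.round(freq, 4).tolist(),
                "n_gap_pairs_excluded": int(n_excl),
            }
    except Exception as exc:  # record partial completion before re-raising
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: dict) -> dict:
    """Schema-check input CSVs; returns {path: [violations]} (empty = valid)."""
    report: dict[str, list[str]] = {}
    for kind, path in paths.items():
        path = str(path)
        violations: list[str] = []
        try:
            df = pd.read_csv(path, comment="#")
        except (OSError, pd.errors.ParserError) as exc:
            raise ValueError(f"unreadable file {path}: {exc}") from exc
        if kind == "immersion":
            for col in ("bird_id", "timestamp", "wet_fraction", "is_daytime"):
                if col not in df.columns:
                    violations.append(f"missing column {col!r}")
            if not violations:
                ts = pd.to_datetime(df["timestamp"], errors="coerce")
                for i in np.where(ts.isna())[0]:
                    violations.append(f"row {i}: bad timestamp {df['timestamp'].iloc[i]!r}")
                bad = ~df["wet_fraction"].between(0, 1)
                for i in np.where(bad)[0]:
                    violations.append(
                        f"row {i}: wet_fraction {df['wet_fraction'].iloc[i]} outside [0, 1]"
                    )
        elif kind == "phenology":
            for col in ("bird_id", "rp", "sex"):
                if col not in df.columns:
                    violations.append(f"missing column {col!r}")
            if "rp" in df.columns:
                bad = ~df["rp"].isin(RP_STATES)
                for i in np.where(bad)[0]:
                    violations.append(f"row {i}: unknown rp label {df['rp'].iloc[i]!r}")
        elif kind == "encounters":
            for col in ("bird_id", "sex", "occasion", "event"):
                if col not in df.columns:
                    violations.append(f"missing column {col!r}")
            if not violations:
                bad = ~df["event"].isin(EVENTS)
                for i in np.where(bad)[0]:
                    violations.append(
                        f"row {i}, column 'event': unknown code {df['event'].iloc[i]!r}"
                    )
                for bird, sub in df.groupby("bird_id"):
                    sub = sub.sort_values("occasion")
                    evs = sub["event"].tolist()
                    seen = [e for e in evs if e != "NOT_SEEN"]
                    if not seen:
                        violations.append(f"bird {bird}: never seen")
        elif kind == "profiles":
            for col in ("bird_id", "date", "p_fly", "p_rest", "p_forage"):
                if col not in df.columns:
                    violations.append(f"missing column {col!r}")
        else:
            violations.append(f"unknown input kind {kind!r}")
        report[path] = violations
    return report
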