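"""End-to-end pipeline: design -> simulation -> dependency -> stats -> coupling.

One master seed drives every stage through derived sub-seeds; rerunning
with the same config yields byte-identical CSV artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behav_stats, coupling, dependency, io, roi_sim
from .behavior_sim import simulate_cohort
from .design import (
    build_encoding_schedule,
    build_retrieval_schedule,
    generate_events,
)

__all__ = ["run_pipeline", "behavioral_report", "glmm_report"]

log = logging.getLogger("loopmem")


def behavioral_report(dep_summary: pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-sample t per condition vs zero plus the 2x2 within ANOVA."""
    wide = dep_summary.pivot_table(
        index="subject_id", columns=["loop", "delay"], values="dependency"
    )
    cols = [("closed", "delay"), ("closed", "no_delay"),
            ("open", "delay"), ("open", "no_delay")]
    anova = behav_stats.anova_2x2_within(wide[cols].to_numpy())
    m = len(cols)
    adj = behav_stats.bonferroni_alpha(alpha, m)
    per_condition = {}
    for loop, delay in cols:
        res = behav_stats.one_sample_t(wide[(loop, delay)].to_numpy(), 0.0)
        per_condition[f"{loop}.{delay}"] = {
            "mean_dependency": res.mean, "t": res.t, "df": res.df,
            "p": res.p, "d": res.d, "significant": res.p < adj,
        }
    return {
        "one_sample_vs_zero": per_condition,
        "bonferroni_alpha": adj,
        "bonferroni_alpha_display": behav_stats.format_alpha(adj),
        "anova": {
            name: dataclasses.asdict(eff)
            for name, eff in anova.effects.items()
        },
    }


def glmm_report(result: coupling.GLMMResult) -> dict:
    return {
        "fixed_effects": result.params.to_dict(),
        "contrasts": result.contrasts.reset_index().to_dict(orient="records"),
        "residual_df": result.residual_df,
        "subject_var": result.subject_var,
        "resid_var": result.resid_var,
        "n_subjects": result.n_subjects,
        "converged": result.converged,
        "method": result.method,
    }


def run_pipeline(config: io.PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write all artifacts; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config)
    artifacts: dict[str, str] = {}

    def save(name: str, path: Path) -> None:
        artifacts[name] = path.name

    log.info("design: generating %d events (seed=%d)",
             config.design.n_events, config.design.seed)
    events = generate_events(config.design)
    rng = np.random.default_rng(config.seed + 100)
    enc1 = build_encoding_schedule(events, 1, rng)
    enc2 = build_encoding_schedule(events, 2, rng)
    retrieval = build_retrieval_schedule(events, config.design, rng)
    encoding = pd.concat(
        [io.encoding_events_frame(enc1), io.encoding_events_frame(enc2)],
        ignore_index=True,
    )
    save("encoding", io.write_events_tsv(encoding, outdir / "encoding_events.tsv"))
    save("retrieval", io.write_events_tsv(
        io.retrieval_events_frame(retrieval), outdir / "retrieval_events.tsv"))

    log.info("simulate: %d subjects x %d trials", config.n_subjects,
             sum(not t.is_null for t in retrieval))
    events_frame = io.events_to_frame(events)
    outcomes = simulate_cohort(
        config.behavior, retrieval, config.n_subjects, events=events_frame
    )
    save("outcomes", io.write_outcomes_csv(outcomes, outdir / "outcomes.csv"))

    log.info("dependency: summarizing %d subjects", config.n_subjects)
    dep = dependency.dependency_summary(outcomes)
    dep_path = outdir / "dependency.csv"
    dep.to_csv(dep_path, index=False)
    save("dependency", dep_path)
    dependency.condition_summary(outcomes, dep).to_csv(
        outdir / "condition_summary.csv", index=False
    )

    stats_report = behavioral_report(dep, alpha=config.alpha)
    stats_path = outdir / "behav_stats.json"
    stats_path.write_text(json.dumps(
        {"config_hash": chash, "seed": config.seed, **stats_report}, indent=2
    ))
    save("behav_stats", stats_path)

    log.info("roi_sim: simulating contrasts")
    contrasts = roi_sim.simulate_contrasts(config.coupling_sim, config.n_subjects)
    save("contrasts", io.write_contrasts_csv(contrasts, outdir / "contrasts.csv"))

    log.info("coupling: fitting mixed model")
    glmm = coupling.fit_glmm(contrasts)
    glmm_path = outdir / "glmm.json"
    glmm_path.write_text(json.dumps(
        {"config_hash": chash, "seed": config.seed, **glmm_report(glmm)},
        indent=2,
    ))
    save("glmm", glmm_path)

    log.info("coupling: robustness k<=%d x %d iterations",
             config.robustness_k_max, config.robustness_iters)
    robust = coupling.robustness_analysis(
        contrasts,
        k_max=config.robustness_k_max,
        iters=config.robustness_iters,
        alpha_decision=config.robustness_alpha,
        seed=config.seed + 200,
    )
    robust_path = outdir / "robustness.csv"
    robust.to_csv(robust_path, index=False)
    save("robustness", robust_path)

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
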