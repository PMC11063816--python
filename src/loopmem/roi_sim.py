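"""Synthetic subject-level ROI contrasts with known hippocampal coupling.

Generates, per subject and delay condition, a hippocampal closed-vs-open
BOLD contrast and role-wise (cue/target/nontarget) neocortical contrasts.
The nontarget contrast follows the linear coupling model

    nontarget = alpha_c + beta_c * hipp + u_i + eps,

with condition-specific intercept ``alpha_c`` and slope ``beta_c``, a
subject-level random intercept ``u_i ~ N(0, subj_sd²)`` shared across the
subject's two conditions, and residual noise ``eps ~ N(0, resid_sd²)``.
A positive ``alpha_delay`` with ``alpha_nodelay = 0`` emulates
reinstatement that persists at delay without a corresponding hippocampal
signal — the additive, hippocampus-independent component.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "CouplingParams",
    "simulate_contrasts",
    "compute_contrasts",
    "expected_hipp_nontarget_r",
]

_DELAY_LEVELS = ("no_delay", "delay")


@dataclasses.dataclass(frozen=True)
class CouplingParams:
    """Generative parameters of the hippocampal-coupling model.

    Units are arbitrary BOLD contrast units (closed minus open parameter
    estimates).  Defaults give a strong positive coupling at no-delay, a
    weaker one at delay, and a nonzero delay intercept.
    """

    alpha_nodelay: float = 0.0
    alpha_delay: float = 0.25
    beta_nodelay: float = 1.0
    beta_delay: float = 0.55
    hipp_mean: float = 0.2
    hipp_sd: float = 0.3
    subj_sd: float = 0.15
    resid_sd: float = 0.25
    cue_alpha: float = 0.0
    cue_beta: float = 0.0
    target_alpha: float = 0.0
    target_beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hipp_sd", "subj_sd", "resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_contrasts(params: CouplingParams, n_subjects: int) -> pd.DataFrame:
    """Simulate subject x condition contrast rows (2 rows per subject).

    Columns: subject_id, delay, hipp_contrast, nontarget_contrast,
    cue_contrast, target_contrast.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(params.seed)
    u = rng.normal(0.0, params.subj_sd, size=n_subjects)
    rows = []
    alphas = {"no_delay": params.alpha_nodelay, "delay": params.alpha_delay}
    betas = {"no_delay": params.beta_nodelay, "delay": params.beta_delay}
    for cond in _DELAY_LEVELS:
        hipp = rng.normal(params.hipp_mean, params.hipp_sd, size=n_subjects)
        eps = rng.normal(0.0, params.resid_sd, size=n_subjects)
        nontarget = alphas[cond] + betas[cond] * hipp + u + eps
        cue = (params.cue_alpha + params.cue_beta * hipp + u
               + rng.normal(0.0, params.resid_sd, size=n_subjects))
        target = (params.target_alpha + params.target_beta * hipp + u
                  + rng.normal(0.0, params.resid_sd, size=n_subjects))
        for i in range(n_subjects):
            rows.append(
                {
                    "subject_id": i,
                    "delay": cond,
                    "hipp_contrast": hipp[i],
                    "nontarget_contrast": nontarget[i],
                    "cue_contrast": cue[i],
                    "target_contrast": target[i],
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["subject_id", "delay"]).reset_index(drop=True)


def expected_hipp_nontarget_r(params: CouplingParams, cond: str = "no_delay") -> float:
    """Population Pearson r between hipp and nontarget contrasts in one
    condition (closed form of the generative model)."""
    beta = params.beta_nodelay if cond == "no_delay" else params.beta_delay
    num = beta * params.hipp_sd
    den = np.sqrt(
        beta**2 * params.hipp_sd**2 + params.subj_sd**2 + params.resid_sd**2
    )
    if den == 0:
        raise ValueError("degenerate model: all variances zero")
    return float(num / den)


def compute_contrasts(role_means: pd.DataFrame, baseline: str = "within_condition") -> pd.DataFrame:
    """Closed-vs-open contrasts from per-subject ROI means.

    ``role_means`` is tidy with columns subject_id, delay, role
    (cue/target/nontarget; plus optionally ``hipp``), loop, bold.
    ``baseline='within_condition'`` subtracts each condition's own
    open-loop mean; ``'open_delay'`` subtracts the open-loop *delay* mean
    from the closed-loop no-delay mean (post hoc baseline for when the
    open no-delay condition itself shows holistic retrieval), leaving
    delay rows unchanged.
    """
    if baseline not in ("within_condition", "open_delay"):
        raise ValueError(f"unknown baseline {baseline!r}")
    required = {"subject_id", "delay", "role", "loop", "bold"}
    missing = required - set(role_means.columns)
    if missing:
        raise ValueError(f"role_means missing columns {sorted(missing)}")
    wide = role_means.pivot_table(
        index=["subject_id", "delay", "role"], columns="loop",
        values="bold", aggfunc="first",
    )
    if wide.isna().any().any() or not {"closed", "open"} <= set(wide.columns):
        raise ValueError("incomplete role x loop x condition means")
    open_delay_base = wide["open"].xs("delay", level="delay")
    contrast = wide["closed"] - wide["open"]
    if baseline == "open_delay":
        idx = contrast.index
        nodelay = idx.get_level_values("delay") == "no_delay"
        keys = list(zip(idx.get_level_values("subject_id"),
                        idx.get_level_values("role")))
        base = np.array([open_delay_base.loc[k] for k in keys])
        closed = wide["closed"].to_numpy()
        contrast = pd.Series(
            np.where(nodelay, closed - base, contrast.to_numpy()), index=idx
        )
    out = contrast.unstack("role")
    out.columns = [f"{r}_contrast" for r in out.columns]
    return out.reset_index()
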