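"""Hippocampal-neocortical coupling inference.

Fits a linear mixed-effects model of nontarget reinstatement (the
closed-vs-open nontarget contrast) on delay condition, the hippocampal
closed-vs-open contrast, and their interaction, with a random intercept
per participant.  The hippocampal predictor is deliberately *not*
centered: the model's intercepts are the expected reinstatement at zero
hippocampal contrast, i.e. the hippocampus-independent component, and a
nonzero delay intercept is the signature of a nonhippocampal
contribution to holistic retrieval.

Six derived contrasts are reported: slope and intercept at each delay
level and their differences, each with a t statistic referenced to
``N_obs − 4`` residual degrees of freedom (96 for 50 participants).

A leave-k-out robustness procedure refits the model on random subject
subsets and reports, per contrast and removal count, the fraction of
iterations whose reject/not-reject decision agrees with the full-sample
analysis.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .behav_stats import bonferroni_alpha, format_alpha, one_sample_t

__all__ = [
    "CONTRAST_NAMES",
    "GLMMResult",
    "StructureError",
    "pearson_r",
    "fit_glmm",
    "robustness_analysis",
    "role_contrast_tests",
]

CONTRAST_NAMES = (
    "intercept_nodelay",
    "intercept_delay",
    "intercept_diff",
    "slope_nodelay",
    "slope_delay",
    "slope_diff",
)

#: fixed-effect design columns (reference coding, no-delay basis)
_FIXED = ("intercept", "delay", "hipp", "delay_hipp")

#: contrast weights on the fixed effects (invariant results under any
#: equivalent parameterization)
_L = {
    "intercept_nodelay": np.array([1.0, 0.0, 0.0, 0.0]),
    "intercept_delay": np.array([1.0, 1.0, 0.0, 0.0]),
    "intercept_diff": np.array([0.0, 1.0, 0.0, 0.0]),
    "slope_nodelay": np.array([0.0, 0.0, 1.0, 0.0]),
    "slope_delay": np.array([0.0, 0.0, 1.0, 1.0]),
    "slope_diff": np.array([0.0, 0.0, 0.0, 1.0]),
}


class StructureError(ValueError):
    """Input rows do not form a balanced subject x condition structure."""


@dataclasses.dataclass(frozen=True)
class GLMMResult:
    """Fixed estimates (no-delay reference coding), their covariance, the
    six derived contrasts, and variance components."""

    params: pd.Series  # index _FIXED
    cov_params: pd.DataFrame
    contrasts: pd.DataFrame  # index CONTRAST_NAMES; estimate, se, t, p
    residual_df: int
    subject_var: float
    resid_var: float
    n_subjects: int
    converged: bool
    method: str  # "reml" or "exact" (perfect-fit degenerate path)

    def significant(self, alpha: float) -> pd.Series:
        return self.contrasts["p"] < alpha


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-tailed p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _design(data: pd.DataFrame, center_hipp: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    required = {"subject_id", "delay", "hipp_contrast", "nontarget_contrast"}
    missing = required - set(data.columns)
    if missing:
        raise StructureError(f"contrast rows missing columns {sorted(missing)}")
    counts = data.groupby("subject_id")["delay"].agg(["count", "nunique"])
    if not ((counts["count"] == 2) & (counts["nunique"] == 2)).all():
        bad = counts.index[
            ~((counts["count"] == 2) & (counts["nunique"] == 2))
        ].tolist()
        raise StructureError(
            f"each subject needs exactly one row per delay condition; "
            f"offending subjects: {bad}"
        )
    d = data.sort_values(["subject_id", "delay"]).reset_index(drop=True)
    hipp = d["hipp_contrast"].to_numpy(dtype=float)
    if center_hipp:
        hipp = hipp - hipp.mean()
    delay = (d["delay"] == "delay").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(d)), delay, hipp, delay * hipp])
    y = d["nontarget_contrast"].to_numpy(dtype=float)
    groups = d["subject_id"].to_numpy()
    return X, y, groups


def fit_glmm(
    data: pd.DataFrame,
    center_hipp: bool = False,
    subject_var: float | None = None,
) -> GLMMResult:
    """Fit the coupling mixed model on subject x condition contrast rows.

    REML estimation with a random intercept per subject (the only
    participant-level structure identifiable from two observations per
    subject).  ``subject_var=0.0`` fixes the random-intercept variance at
    zero, under which the mixed model degenerates exactly to ordinary
    least squares.  When the fixed design reproduces the response exactly
    (noise-free data) REML is undefined and exact least-squares estimates
    are returned with zero standard errors.
    """
    if subject_var is not None and subject_var != 0.0:
        raise ValueError("only subject_var=0.0 (the OLS degeneracy) is supported")
    X, y, groups = _design(data, center_hipp)
    n_obs = len(y)
    residual_df = n_obs - len(_FIXED)
    n_subjects = len(np.unique(groups))
    if residual_df <= 0:
        raise StructureError("not enough observations for 4 fixed effects")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    scale_ref = max(1.0, float(y @ y))
    if ssr <= 1e-12 * scale_ref:
        # perfect fit: zero noise; inference degenerates
        params = pd.Series(beta, index=_FIXED)
        cov = pd.DataFrame(np.zeros((4, 4)), index=_FIXED, columns=_FIXED)
        contrasts = _contrast_table(params, cov, residual_df, exact=True)
        return GLMMResult(
            params=params, cov_params=cov, contrasts=contrasts,
            residual_df=residual_df, subject_var=0.0, resid_var=0.0,
            n_subjects=n_subjects, converged=True, method="exact",
        )

    if subject_var == 0.0:
        # zero random-intercept variance: exact OLS with classical covariance
        sigma2 = ssr / residual_df
        params = pd.Series(beta, index=_FIXED)
        cov = pd.DataFrame(
            sigma2 * np.linalg.inv(X.T @ X), index=_FIXED, columns=_FIXED
        )
        contrasts = _contrast_table(params, cov, residual_df, exact=False)
        return GLMMResult(
            params=params, cov_params=cov, contrasts=contrasts,
            residual_df=residual_df, subject_var=0.0, resid_var=sigma2,
            n_subjects=n_subjects, converged=True, method="ols",
        )

    from statsmodels.regression.mixed_linear_model import MixedLM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        fit = model.fit(reml=True)
    params = pd.Series(np.asarray(fit.fe_params), index=_FIXED)
    cov = pd.DataFrame(
        np.asarray(fit.cov_params())[:4, :4], index=_FIXED, columns=_FIXED
    )
    subject_var = float(np.asarray(fit.cov_re)[0, 0])
    contrasts = _contrast_table(params, cov, residual_df, exact=False)
    return GLMMResult(
        params=params, cov_params=cov, contrasts=contrasts,
        residual_df=residual_df, subject_var=max(subject_var, 0.0),
        resid_var=float(fit.scale), n_subjects=n_subjects,
        converged=bool(fit.converged), method="reml",
    )


def _contrast_table(params: pd.Series, cov: pd.DataFrame,
                    residual_df: int, exact: bool) -> pd.DataFrame:
    rows = []
    for name in CONTRAST_NAMES:
        L = _L[name]
        est = float(L @ params.to_numpy())
        var = float(L @ cov.to_numpy() @ L)
        se = np.sqrt(max(var, 0.0))
        if exact or se == 0.0:
            t = 0.0 if est == 0.0 else np.inf * np.sign(est)
            p = 1.0 if est == 0.0 else 0.0
        else:
            t = est / se
            p = 2.0 * stats.t.sf(abs(t), residual_df)
        rows.append({"contrast": name, "estimate": est, "se": se,
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows).set_index("contrast")


def robustness_analysis(
    data: pd.DataFrame,
    k_max: int = 20,
    iters: int = 50,
    alpha_decision: float = bonferroni_alpha(0.05, 6),
    seed: int | None = None,
    center_hipp: bool = False,
) -> pd.DataFrame:
    """Leave-k-out stability of the six contrasts' significance decisions.

    For each removal count k in 1..k_max (k = 0 allowed and trivially
    consistent), ``iters`` random subsets of k subjects are removed, the
    model refit, and each contrast's reject/not-reject decision at
    ``alpha_decision`` compared with the full-sample decision.  Returns a
    tidy frame (k, contrast, consistency) including a ``joint`` row per k:
    the fraction of iterations where *all six* decisions match.
    """
    subjects = np.asarray(sorted(data["subject_id"].unique()))
    n = len(subjects)
    if k_max < 0 or n - k_max < 3:
        raise ValueError(
            f"k_max={k_max} leaves fewer than 3 of {n} subjects"
        )
    full = fit_glmm(data, center_hipp=center_hipp)
    full_dec = full.significant(alpha_decision)
    rng = np.random.default_rng(seed)
    records = []
    for k in range(0 if k_max == 0 else 1, k_max + 1):
        agree = np.zeros(len(CONTRAST_NAMES))
        joint = 0
        for _ in range(iters):
            if k == 0:
                keep = subjects
            else:
                removed = rng.choice(subjects, size=k, replace=False)
                keep = np.setdiff1d(subjects, removed)
            sub = data[data["subject_id"].isin(keep)]
            res = fit_glmm(sub, center_hipp=center_hipp)
            dec = res.significant(alpha_decision)
            match = (dec.values == full_dec.values)
            agree += match
            joint += int(match.all())
        for i, name in enumerate(CONTRAST_NAMES):
            records.append(
                {"k": k, "contrast": name, "consistency": agree[i] / iters}
            )
        records.append({"k": k, "contrast": "joint", "consistency": joint / iters})
    return pd.DataFrame(records)


def role_contrast_tests(
    data: pd.DataFrame,
    roles: tuple[str, ...] = ("cue", "target", "nontarget"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sample t tests of each role's closed-vs-open contrast against
    zero, per delay condition, with Bonferroni presentation alpha."""
    records = []
    conds = sorted(data["delay"].unique())
    m = len(roles) * len(conds)
    adj = bonferroni_alpha(alpha, m)
    for role in roles:
        col = f"{role}_contrast"
        if col not in data.columns:
            raise StructureError(f"missing column {col!r}")
        for cond in conds:
            vals = data.loc[data["delay"] == cond, col].to_numpy()
            res = one_sample_t(vals, 0.0)
            records.append(
                {
                    "role": role, "delay": cond, "t": res.t, "df": res.df,
                    "p": res.p, "d": res.d, "mean": res.mean,
                    "alpha_adjusted": adj,
                    "alpha_adjusted_display": format_alpha(adj),
                    "significant": res.p < adj,
                }
            )
    return pd.DataFrame(records)
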