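"""Behavioral inference: t tests, 2x2 within-subject ANOVA, power.

The 2x2 repeated-measures ANOVA is computed through orthogonal paired
contrasts: every 1-df within-subject effect is a one-sample t test on the
corresponding per-subject contrast score, with F = t² and
partial eta² = F / (F + df_den).  This is algebraically identical to the
classical repeated-measures decomposition for 2x2 designs and exactly
testable.

Power for the one-sample two-tailed t test uses the noncentral t
distribution with noncentrality d·√n and df n−1, including the
opposite-tail rejection region.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "TTestResult",
    "AnovaEffect",
    "AnovaResult",
    "DegenerateDataError",
    "one_sample_t",
    "paired_t",
    "anova_2x2_within",
    "bonferroni_alpha",
    "format_alpha",
    "power_one_sample_t",
    "sample_size_one_sample_t",
]


class DegenerateDataError(ValueError):
    """Zero-variance or otherwise degenerate input to a test."""


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float  # Cohen's d: mean difference / SD of the (difference) scores
    mean: float
    sd: float
    n: int


@dataclasses.dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, AnovaEffect]  # keys: factor names and "interaction"


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-tailed one-sample t test of ``values`` against ``mu0``.

    Cohen's d is (mean − mu0) / sd.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateDataError(f"need at least 2 values, got {n}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("zero variance: t statistic undefined")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p),
                       d=(mean - mu0) / sd, mean=mean, sd=sd, n=n)


def paired_t(x, y) -> TTestResult:
    """Paired t test, equivalent to a one-sample t on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DegenerateDataError("paired samples must have equal length")
    return one_sample_t(x - y, 0.0)


#: cell order of the 2x2 within-subject matrix: (A1B1, A1B2, A2B1, A2B2)
_CONTRASTS = {
    "factor_a": np.array([1.0, 1.0, -1.0, -1.0]) / 2.0,
    "factor_b": np.array([1.0, -1.0, 1.0, -1.0]) / 2.0,
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]) / 2.0,
}


def anova_2x2_within(cell_matrix, factors: tuple[str, str] = ("loop", "delay")) -> AnovaResult:
    """2x2 fully-within-subject ANOVA from an n x 4 cell-means matrix.

    Column order is (A1B1, A1B2, A2B1, A2B2) where A is the first factor.
    Each effect is the squared one-sample t of its per-subject contrast
    scores (df_num = 1, df_den = n − 1).
    """
    m = np.asarray(cell_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise DegenerateDataError(
            f"cell matrix must be n x 4, got shape {m.shape}"
        )
    if np.isnan(m).any():
        bad = int(np.argwhere(np.isnan(m))[0][0])
        raise DegenerateDataError(f"missing cells for subject row {bad}")
    n = m.shape[0]
    if n < 2:
        raise DegenerateDataError("need at least 2 subjects")
    effects: dict[str, AnovaEffect] = {}
    names = {"factor_a": factors[0], "factor_b": factors[1],
             "interaction": "interaction"}
    for key, w in _CONTRASTS.items():
        scores = m @ w
        sd = np.std(scores, ddof=1)
        df_den = n - 1
        if sd == 0.0:
            eff = AnovaEffect(F=0.0, df_num=1, df_den=df_den, p=1.0,
                              partial_eta_sq=0.0)
        else:
            res = one_sample_t(scores, 0.0)
            F = res.t**2
            eff = AnovaEffect(
                F=float(F), df_num=1, df_den=df_den, p=res.p,
                partial_eta_sq=float(F / (F + df_den)),
            )
        effects[names[key]] = eff
    return AnovaResult(effects=effects)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison alpha (raw, unrounded)."""
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / m


def format_alpha(alpha: float, decimals: int = 3) -> str:
    """Presentation rounding, half-up (0.0125 -> '0.013')."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(alpha)).quantize(q, rounding=ROUND_HALF_UP))


def power_one_sample_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Two-tailed power of the one-sample t test at effect size ``d``.

    Noncentral t with ncp = d·√n and df = n − 1; both rejection tails.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    df = n - 1
    ncp = d * np.sqrt(n)
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(t_crit, df, ncp)
    lower = stats.nct.cdf(-t_crit, df, ncp)
    return float(upper + lower)


def sample_size_one_sample_t(
    d: float, alpha: float = 0.05, power: float = 0.90, n_max: int = 100_000
) -> int:
    """Smallest n with two-tailed one-sample-t power >= ``power``."""
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not 0 < power < 1:
        raise ValueError(f"power must be in (0, 1), got {power}")
    for n in range(2, n_max + 1):
        if power_one_sample_t(d, n, alpha) >= power:
            return n
    raise ValueError(f"power {power} not reached by n = {n_max}")
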