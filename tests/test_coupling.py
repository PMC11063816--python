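"""Coupling mixed model: contrasts, degenerate paths, robustness."""

import numpy as np
import pandas as pd
import pytest

from loopmem.coupling import (
    CONTRAST_NAMES,
    StructureError,
    fit_glmm,
    pearson_r,
    robustness_analysis,
    role_contrast_tests,
)
from loopmem.roi_sim import CouplingParams, simulate_contrasts

NOISELESS = CouplingParams(subj_sd=0.0, resid_sd=0.0, seed=5)


class TestPearson:
    def test_perfect_and_null_correlations(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        y = np.concatenate([np.ones(5), -np.ones(5)])  # orthogonal to linear trend
        x_sym = np.concatenate([np.arange(5), np.arange(5)])
        r, p = pearson_r(x_sym, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_sums(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 30))
        r, p = pearson_r(x, y)
        mx, my = x.mean(), y.mean()
        r_manual = (((x - mx) * (y - my)).sum()
                    / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
        assert r == pytest.approx(r_manual, abs=1e-12)
        t = r_manual * np.sqrt(28 / (1 - r_manual**2))
        from scipy import stats
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFitGlmm:
    def test_residual_df_is_n_obs_minus_four(self):
        data = simulate_contrasts(CouplingParams(seed=7), 50)
        res = fit_glmm(data)
        assert res.residual_df == 96
        assert res.n_subjects == 50

    def test_noiseless_recovery_is_exact(self):
        data = simulate_contrasts(NOISELESS, 20)
        res = fit_glmm(data)
        assert res.method == "exact"
        c = res.contrasts["estimate"]
        assert c["intercept_nodelay"] == pytest.approx(NOISELESS.alpha_nodelay, abs=1e-10)
        assert c["intercept_delay"] == pytest.approx(NOISELESS.alpha_delay, abs=1e-10)
        assert c["slope_nodelay"] == pytest.approx(NOISELESS.beta_nodelay, abs=1e-10)
        assert c["slope_delay"] == pytest.approx(NOISELESS.beta_delay, abs=1e-10)

    def test_contrast_linearity(self):
        data = simulate_contrasts(CouplingParams(seed=8), 40)
        c = fit_glmm(data).contrasts["estimate"]
        assert c["slope_diff"] == pytest.approx(
            c["slope_delay"] - c["slope_nodelay"], abs=1e-12)
        assert c["intercept_diff"] == pytest.approx(
            c["intercept_delay"] - c["intercept_nodelay"], abs=1e-12)

    def test_zero_subject_variance_degenerates_to_ols(self):
        params = CouplingParams(subj_sd=0.0, seed=9)
        data = simulate_contrasts(params, 50)
        res = fit_glmm(data, subject_var=0.0)
        X = np.column_stack([
            np.ones(100),
            (data.sort_values(["subject_id", "delay"])["delay"] == "delay"),
            data.sort_values(["subject_id", "delay"])["hipp_contrast"],
        ])
        X = np.column_stack([X, X[:, 1] * X[:, 2]])
        y = data.sort_values(["subject_id", "delay"])["nontarget_contrast"]
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.params.to_numpy() == pytest.approx(beta, abs=1e-6)
        # free REML on the same data estimates a near-zero subject variance
        free = fit_glmm(data)
        assert free.subject_var < 0.25 * params.resid_sd**2

    def test_contrasts_invariant_to_centering_for_slopes(self):
        data = simulate_contrasts(CouplingParams(seed=10), 30)
        raw = fit_glmm(data).contrasts
        centered = fit_glmm(data, center_hipp=True).contrasts
        for name in ("slope_nodelay", "slope_delay", "slope_diff"):
            assert raw.loc[name, "estimate"] == pytest.approx(
                centered.loc[name, "estimate"], abs=1e-6)

    def test_unbalanced_subjects_rejected(self):
        data = simulate_contrasts(CouplingParams(seed=11), 10)
        with pytest.raises(StructureError):
            fit_glmm(data.iloc[1:])

    def test_parameter_recovery_mean_unbiased(self):
        """Small replicate study: average estimates track the generative
        slopes/intercepts within Monte-Carlo error."""
        truth = CouplingParams(alpha_nodelay=0.0, alpha_delay=0.25,
                               beta_nodelay=0.8, beta_delay=0.8, seed=0)
        keys = ("intercept_nodelay", "intercept_delay",
                "slope_nodelay", "slope_delay")
        true_vals = {"intercept_nodelay": 0.0, "intercept_delay": 0.25,
                     "slope_nodelay": 0.8, "slope_delay": 0.8}
        ests = {k: [] for k in keys}
        for rep in range(60):
            data = simulate_contrasts(
                CouplingParams(**{**truth.__dict__, "seed": 1000 + rep}), 50)
            c = fit_glmm(data).contrasts["estimate"]
            for k in keys:
                ests[k].append(c[k])
        for k in keys:
            arr = np.asarray(ests[k])
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - true_vals[k]) < 3 * se


class TestRobustness:
    def test_degenerate_k_zero(self):
        data = simulate_contrasts(CouplingParams(seed=12), 20)
        report = robustness_analysis(data, k_max=0, iters=10, seed=1)
        assert (report["consistency"] == 1.0).all()
        assert set(report["k"]) == {0}

    def test_noiseless_fully_consistent(self):
        data = simulate_contrasts(NOISELESS, 30)
        report = robustness_analysis(data, k_max=5, iters=10, seed=2)
        assert (report["consistency"] == 1.0).all()

    def test_report_dimensions(self):
        data = simulate_contrasts(CouplingParams(seed=13), 25)
        k_max, iters = 4, 6
        report = robustness_analysis(data, k_max=k_max, iters=iters, seed=3)
        # six contrasts plus the joint decision row, per k
        assert len(report) == k_max * (len(CONTRAST_NAMES) + 1)
        assert report["consistency"].between(0, 1).all()

    def test_k_max_too_large(self):
        data = simulate_contrasts(CouplingParams(seed=14), 10)
        with pytest.raises(ValueError):
            robustness_analysis(data, k_max=9, iters=2)


class TestRoleContrasts:
    def test_df_and_zero_effect(self):
        data = simulate_contrasts(CouplingParams(seed=15), 50)
        out = role_contrast_tests(data)
        assert (out["df"] == 49).all()
        assert len(out) == 6
        assert out["alpha_adjusted_display"].iloc[0] == "0.008"

    def test_exact_zero_contrast(self):
        data = simulate_contrasts(CouplingParams(seed=16), 10).copy()
        # symmetric +/-0.1 across subjects within each condition: mean 0
        for cond in ("delay", "no_delay"):
            idx = data.index[data["delay"] == cond]
            data.loc[idx, "cue_contrast"] = np.resize([0.1, -0.1], len(idx))
        out = role_contrast_tests(data)
        row = out[(out["role"] == "cue") & (out["delay"] == "delay")].iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)

    def test_type_i_rate_near_nominal(self):
        """Null cue/target channels reject at ~alpha over replicates."""
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            data = simulate_contrasts(CouplingParams(seed=20_000 + rep), 20)
            out = role_contrast_tests(data, roles=("cue",), alpha=0.05)
            rejections += int((out["p"] < 0.05).sum())
        rate = rejections / (n_rep * 2)  # two conditions per replicate
        assert 0.02 < rate < 0.09
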