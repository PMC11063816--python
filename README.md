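# loopmem

Tools for studying **holistic episodic retrieval**: when one element of a
multi-element event is used to cue another, are the remaining elements
retrieved too?  `loopmem` implements the full analysis stack around the
*closed-loop / open-loop* cued-recognition paradigm — design generation,
behavioral and ROI-level simulators with known ground truth, the
retrieval-dependency statistic, and the hippocampal–neocortical coupling
mixed model — for cognitive neuroscientists who want to test, power, or
extend these analyses on data with known generative structure.

## The paradigm and the statistics

Each *event* is a triad (location, person, object).  **Closed loops**
encode all three pairwise associations; **open loops** encode only the two
pairs sharing a *common element*, so the third pair is never shown.
Events are crossed with a delay factor (encoded ~24 h before vs
immediately before retrieval), 18 events per cell (72 total).  Every
encoded pair is tested in both directions with six-alternative forced
choice (chance ≈ 16.7%), giving 6 directed tests per closed loop and 4
per open loop, 360 retrieval trials across two runs.

**Retrieval dependency.**  For each subject and condition, pairs of
directed tests sharing an element A form 2×2 contingency tables over the
condition's N events.  The independent model predicts the cells from the
marginal accuracies P<sub>AB</sub>, P<sub>AC</sub>:

    N·P_AB·P_AC    N·P_AC(1−P_AB)
    N·P_AB(1−P_AC) N·(1−P_AB)(1−P_AC)

The proportion of joint retrieval of a table is its leading diagonal over
N; averaged over the condition's tables (6 closed, 4 open),

    dependency = p_joint(data) − p_joint(independent model),

positive when events succeed or fail *as wholes*.

**Hippocampal coupling.**  With per-subject closed-vs-open contrasts for
the hippocampus and for the nontarget element's neocortical ROI, the
mixed model

    nontarget_i,c = α_c + β_c · hipp_i,c + u_i + ε_i,c,   u_i ~ N(0, σ_u²)

is fitted by REML (random intercept per participant; the hippocampal
predictor is left uncentered so α_c is the reinstatement expected at
*zero* hippocampal contrast).  Six contrasts — slope and intercept per
delay level and their differences — are tested with t statistics on
N<sub>obs</sub> − 4 residual df (96 for 50 participants).  A leave-k-out
procedure (k = 1..20, 50 random subsets each) reports how consistently
each significance decision survives subject removal.

## Worked example

```bash
loopmem run --seed 7 --out demo/      # or: python -m loopmem.cli
```

runs design → behavioral simulation (50 subjects) → dependency → ANOVA/t
tests → ROI simulation → mixed model → robustness, writing eight
artifacts plus a manifest.  With the default generative parameters the
condition summary (`condition_summary.csv`) comes out as

```
  loop    delay  accuracy_mean  joint_data_mean  joint_independent_mean  dependency_mean
closed    delay          0.617            0.574                   0.531            0.043
closed no_delay          0.679            0.611                   0.564            0.046
  open    delay          0.503            0.513                   0.503            0.010
  open no_delay          0.623            0.561                   0.534            0.028
```

i.e. accuracy falls with delay and rises for closed loops, and dependency
is concentrated in the closed-loop conditions (closed delay:
t(49) = 5.74, p < 0.001, d = 0.81; open delay: t(49) = 1.31, p = 0.20).
The coupling model on the simulated contrasts gives (`glmm.json`)

```
 intercept_nodelay est=+0.009 t=+0.17 p=0.868
   intercept_delay est=+0.246 t=+5.09 p<0.001
    intercept_diff est=+0.237 t=+3.37 p=0.001
     slope_nodelay est=+1.067 t=+7.42 p<0.001
       slope_delay est=+0.599 t=+4.76 p<0.001
        slope_diff est=-0.468 t=-2.45 p=0.016
```

— hippocampal coupling in both conditions, plus a delay intercept
significantly above zero: reinstatement at delay that is not accompanied
by a hippocampal closed-vs-open difference.  All t statistics are on
96 df.  `robustness.csv` then records, per contrast and k, the fraction
of the 50 refits that reproduce the full-sample decision.

The a-priori power computation is a one-liner:

```python
>>> from loopmem.behav_stats import sample_size_one_sample_t
>>> sample_size_one_sample_t(d=0.62, alpha=0.05, power=0.90)
30
```

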