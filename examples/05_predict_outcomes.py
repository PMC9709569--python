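"""Predict trial outcomes from the pre-stimulus brain state.

Trials are simulated so that correct and incorrect trials follow
different cointegrated dynamics.  The per-trial log-likelihood
difference d_m between the two condition models (fitted leave-one-
trial-out on the final 100 ms before stimulus onset) is then used as a
predictor in logistic regressions alongside the design covariates.
"""

import numpy as np

import cointnet as cn

# factorial design and covariate-driven outcomes (the outcome model does
# not see the EEG: any predictive power of d_m comes from the dynamics)
design = cn.make_task_design(
    {"duration_ms": [20, 40, 70, 110], "orientation_deg": [0, 45],
     "contrast": ["high", "low"]}, repetitions=5, seed=7)
design = design.iloc[:80].reset_index(drop=True)
acc = cn.simulate_outcomes(
    design, {"intercept": 0.2,
             "duration_ms": {20: -0.8, 40: -0.2, 70: 0.3, 110: 0.8}},
    seed=8)

var_a = cn.discretize_ou(cn.random_cointegrated_ou(5, 2, seed=20))
var_b = cn.discretize_ou(cn.random_cointegrated_ou(5, 2, seed=21))
ta = cn.simulate_trials(var_a, 80, 40, seed=9)
tb = cn.simulate_trials(var_b, 80, 40, seed=10)
values = [ta.values[m] if acc[m] == 1 else tb.values[m] for m in range(80)]
data = cn.EpochedData(values, ta.channel_labels, ta.delta, design)

d = cn.leave_one_trial_out_d(data, acc, window_ms=100.0, rank=2)
print(f"mean d_m | correct: {d[acc == 1].mean():6.2f}   "
      f"| incorrect: {d[acc == 0].mean():6.2f}")
# positive d_m = the trial looks more like the 'correct' dynamics

table = cn.build_outcome_table(design, acc, d)
_, auc_d = cn.roc_auc(d, acc)
print(f"AUC of d_m alone: {auc_d:.2f}   (0.5 would be chance)")

full = cn.fit_logistic(table, ["C(duration_ms)", "C(contrast)", "d"])
reduced = cn.fit_logistic(table, ["C(duration_ms)", "C(contrast)"])
stat, df_, p = cn.drop_in_deviance(full, reduced)
print(f"full model: df = {full.df}, AIC = {full.aic:.1f}; "
      f"dropping d: deviance change = {stat:.1f} on {df_} df, p = {p:.2g}")
# a small p says the pre-stimulus state adds predictive information
# beyond the experimental design
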