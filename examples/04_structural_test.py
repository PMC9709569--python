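"""Chow test: is the network the same under two conditions?

Two batches of trials are simulated, first from one model (the null is
true), then from models whose networks differ; the likelihood-ratio
statistic is referred to chi-squared with p(2r+1) - r^2 degrees of
freedom.
"""

import numpy as np

import cointnet as cn

ou = cn.random_cointegrated_ou(p=6, r=2, seed=1000)
var_a = cn.discretize_ou(ou)

# same network in both batches
a = cn.simulate_trials(var_a, 5, 1001, seed=10)
b = cn.simulate_trials(var_a, 5, 1001, seed=11)
res = cn.chow_test(a, b, r=2)
print(f"null true:   Q = {res.Q:7.1f}, df = {res.df}, p = {res.p_value:.3f}")
# p should be unremarkable: no structural difference to find

# perturbed loadings in the second batch -> different network
ou_b = cn.OUParams(m=ou.m, a=ou.a * 3.0, b=ou.b, D=ou.D, delta=ou.delta)
var_b = cn.discretize_ou(ou_b)
print("||Pi_B - Pi_A||_F =", round(float(np.linalg.norm(var_b.Pi - var_a.Pi)), 3))
b2 = cn.simulate_trials(var_b, 5, 1001, seed=12)
res2 = cn.chow_test(a, b2, r=2)
print(f"null false:  Q = {res2.Q:7.1f}, df = {res2.df}, p = {res2.p_value:.3g}")
# Q far beyond the chi-squared scale: the networks differ
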