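"""Likelihood-ratio (Chow) test of structural network difference.

Null hypothesis: two data subsets A and B follow one VECM with common
(mu0, Pi0); alternative: each subset has its own (mu_k, Pi_k).  The
statistic is

    Q = -2 [ l_pooled - l_A - l_B ],

asymptotically chi-squared with p (2r + 1) - r^2 degrees of freedom at
fixed cointegration rank r, where p is the estimation dimension (after
any reference channel has been dropped).  The degree-of-freedom count
covers mu (p) and the rank-r matrix Pi (2pr - r^2) and presumes a common
innovation covariance under both hypotheses; accordingly the likelihoods
are profiled with a single pooled Sigma under the alternative,
Sigma_c = (N_A Sigma_A + N_B Sigma_B) / (N_A + N_B).

The chi-squared theory assumes maximum-likelihood fits: penalized
(elastic-net) fits are accepted but flagged as non-calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .epochs import EpochedData, concat_trials
from .vecm import VECMParams, fit_vecm

__all__ = ["ChowResult", "chow_test", "chow_df", "chisq_upper"]


@dataclass
class ChowResult:
    """Chow test outcome: statistic, dof, p-value and fit components."""

    Q: float
    df: int
    p_value: float
    loglik_pooled: float
    loglik_a: float
    loglik_b: float
    rank: int
    calibrated: bool = True

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        note = "" if self.calibrated else " [penalized fit: chi2 not calibrated]"
        return (
            f"Chow test: Q = {self.Q:.1f}, df = {self.df}, "
            f"p = {self.p_value:.3g}{note}"
        )


def chow_df(p_model: int, r: int) -> int:
    """Degrees of freedom p_model (2r + 1) - r^2.

    ``p_model`` is the dimension the model was estimated in — with
    common-average referenced data this is the channel count after
    exclusions minus the dropped reference channel.
    """
    if r > p_model:
        raise ValueError("rank cannot exceed the estimation dimension")
    return int(p_model * (2 * r + 1) - r * r)


def chisq_upper(q: float, df: int) -> float:
    """Upper-tail chi-squared probability P(X >= q)."""
    return float(stats.chi2.sf(q, df))


def _resid_cov(fit: VECMParams, data: EpochedData) -> tuple[np.ndarray, int]:
    e = np.concatenate(
        [np.diff(t, axis=0) - fit.mu - t[:-1] @ fit.Pi.T for t in data.values]
    )
    n = e.shape[0]
    return e.T @ e / n, n


def chow_test(
    data_a: EpochedData,
    data_b: EpochedData,
    r: int,
    penalty=None,
) -> ChowResult:
    """Test whether subsets A and B share one network at rank r."""
    if data_a.channel_labels != data_b.channel_labels:
        raise ValueError("subsets must share the channel set")
    if data_a.delta != data_b.delta:
        raise ValueError("subsets must share the timestep")
    p = data_a.n_channels
    if data_a.n_increments <= p or data_b.n_increments <= p:
        raise ValueError("a subset is too small to estimate the model")

    pooled = concat_trials([data_a, data_b])
    fit0 = fit_vecm(pooled, r, penalty)
    fit_a = fit_vecm(data_a, r, penalty)
    fit_b = fit_vecm(data_b, r, penalty)

    # residual covariances at the fitted (mu, Pi); common Sigma profiling
    S0, n0 = _resid_cov(fit0, pooled)
    Sa, na = _resid_cov(fit_a, data_a)
    Sb, nb = _resid_cov(fit_b, data_b)
    Sc = (na * Sa + nb * Sb) / (na + nb)

    def _ll(Sig, resid_cov, n):
        sign, logdet = np.linalg.slogdet(Sig)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "singular residual covariance; drop the redundant reference "
                "channel before testing"
            )
        quad = n * float(np.trace(np.linalg.solve(Sig, resid_cov)))
        return -0.5 * n * logdet - 0.5 * quad

    ll0 = _ll(S0, S0, n0)
    lla = _ll(Sc, Sa, na)
    llb = _ll(Sc, Sb, nb)
    Q = -2.0 * (ll0 - lla - llb)
    if Q < -1e-6:
        raise RuntimeError(f"likelihood-ratio statistic {Q:.3g} < 0")
    Q = max(Q, 0.0)
    df = chow_df(p, r)
    return ChowResult(
        Q=Q,
        df=df,
        p_value=chisq_upper(Q, df),
        loglik_pooled=ll0,
        loglik_a=lla,
        loglik_b=llb,
        rank=r,
        calibrated=penalty is None or penalty.gamma == 0,
    )
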