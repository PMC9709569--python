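"""Elastic-net penalized estimation of the loading matrix.

With the cointegration matrix beta fixed from the Johansen step, the
loadings solve

    alpha-hat = argmin (1/2N) sum_n ||z0_n - alpha u_n||^2
                + gamma [ (1-omega)/2 sum_i ||alpha_i.||^2
                          + omega sum_i ||alpha_i.||_1 ],

where u_n = beta' z1_n are the r stationary predictors, gamma >= 0 is the
overall penalty strength and omega in [0, 1] the lasso proportion.  The
objective separates across channels (rows of alpha), so each row is a
standard elastic-net regression of that channel's centered increments on
u; the lasso part produces exact zeros.  Penalizing alpha leaves the
estimated cointegration space sp(beta-hat) untouched.

Predictors are deliberately NOT standardized internally: the Johansen
normalization beta' S11 beta = I_r already puts them on unit scale, so
gamma retains its interpretable magnitude.  No intercept is fitted (the
streams are pre-centered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .epochs import EpochedData
from .vecm import CenteredStreams, center

__all__ = ["PenaltyConfig", "elastic_net_alpha", "tune_penalty"]


@dataclass(frozen=True)
class PenaltyConfig:
    """Elastic-net penalty: overall strength gamma, lasso proportion omega."""

    gamma: float
    omega: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")


def elastic_net_alpha(
    z: CenteredStreams,
    beta: np.ndarray,
    cfg: PenaltyConfig,
) -> np.ndarray:
    """Penalized loadings given a fixed cointegration matrix.

    gamma = 0 reduces to the closed-form least-squares loadings; omega = 0
    is ridge with its own closed form; otherwise each row is solved by
    coordinate descent (exact zeros reported as such).
    """
    beta = np.asarray(beta, dtype=float).reshape(z.p, -1)
    r = beta.shape[1]
    if r == 0:
        return np.zeros((z.p, 0))
    U = z.z1 @ beta  # (Ntot, r) stationary predictors
    Y = z.z0
    n = z.n_total
    if cfg.gamma == 0.0:
        return np.linalg.solve(U.T @ U, U.T @ Y).T
    if cfg.omega == 0.0:
        # ridge: row-wise closed form (U'U/N + gamma I)^{-1} U'Y/N
        G = U.T @ U / n + cfg.gamma * np.eye(r)
        return np.linalg.solve(G, U.T @ Y / n).T
    model = ElasticNet(
        alpha=cfg.gamma,
        l1_ratio=cfg.omega,
        fit_intercept=False,
        tol=1e-10,
        max_iter=100_000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(U, Y)
    coef = np.atleast_2d(model.coef_)
    return coef.reshape(z.p, r)


def penalty_objective(
    z: CenteredStreams, beta: np.ndarray, alpha: np.ndarray, cfg: PenaltyConfig
) -> float:
    """Value of the penalized least-squares objective at alpha."""
    U = z.z1 @ np.asarray(beta)
    resid = z.z0 - U @ np.asarray(alpha).T
    fit = 0.5 * np.sum(resid**2) / z.n_total
    ridge = 0.5 * (1.0 - cfg.omega) * np.sum(np.asarray(alpha) ** 2)
    lasso = cfg.omega * np.sum(np.abs(alpha))
    return float(fit + cfg.gamma * (ridge + lasso))


def tune_penalty(
    data: EpochedData,
    beta: np.ndarray,
    gamma_grid,
    omega_grid,
    n_folds: int = 5,
    seed: int | None = None,
) -> tuple[PenaltyConfig, "np.ndarray"]:
    """Trial-wise K-fold cross-validation of (gamma, omega).

    For each fold the loadings are refitted on the remaining trials (with
    their own centering) and scored by the mean squared one-step
    prediction error on the held-out trials.  Ties are broken toward
    larger gamma, then larger omega (the sparser model).  Returns the
    selected configuration and the CV table as a structured array with
    fields (gamma, omega, cv_mse).
    """
    import pandas as pd

    gamma_grid = list(gamma_grid)
    omega_grid = list(omega_grid)
    if data.n_trials < n_folds or n_folds < 2:
        raise ValueError("need 2 <= n_folds <= number of trials")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n_trials)
    folds = np.array_split(perm, n_folds)
    beta = np.asarray(beta, dtype=float)

    records = []
    errors = np.zeros((len(gamma_grid), len(omega_grid)))
    for fold in folds:
        test_mask = np.zeros(data.n_trials, dtype=bool)
        test_mask[fold] = True
        train = data.select_trials(~test_mask)
        test = data.select_trials(test_mask)
        z_tr = center(train)
        z_te = center(test)
        # evaluate test residuals around the training means
        dx_te = z_te.z0 + z_te.mean_dx - z_tr.mean_dx
        lag_te = z_te.z1 + z_te.mean_lag - z_tr.mean_lag
        U_te = lag_te @ beta
        for i, g in enumerate(gamma_grid):
            for j, w in enumerate(omega_grid):
                alpha = elastic_net_alpha(z_tr, beta, PenaltyConfig(g, w))
                resid = dx_te - U_te @ alpha.T
                errors[i, j] += float(np.mean(np.sum(resid**2, axis=1)))
    errors /= n_folds
    for i, g in enumerate(gamma_grid):
        for j, w in enumerate(omega_grid):
            records.append({"gamma": g, "omega": w, "cv_mse": errors[i, j]})
    table = pd.DataFrame(records)
    # minimal MSE; ties (within numerical noise) go to larger gamma, omega
    best = table.sort_values(
        ["cv_mse", "gamma", "omega"], ascending=[True, False, False]
    ).iloc[0]
    return PenaltyConfig(float(best["gamma"]), float(best["omega"])), table
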