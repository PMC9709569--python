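"""Cointegration rank determination.

Four complementary routes, none of which is a formal test at EEG-scale
dimension (asymptotic critical values for the likelihood-ratio statistics
exist only for small p, and bootstrap nulls are computationally out of
reach), so the statistics are reported raw and weighed jointly:

1. eigenvalue scree: the ordered eigenvalues of the reduced-rank
   regression eigenproblem; eigenvalues clearly above zero indicate
   cointegration relationships;
2. likelihood-ratio statistics: trace and maximum-eigenvalue statistics
   per candidate rank r0;
3. rank selection criterion (RSC): the number of eigenvalues of
   Z0' P_Z1 Z0 at or above a residual-variance-scaled threshold theta,
   equivalent to a rank-penalized least-squares estimator;
4. out-of-sample comparisons over trial-wise folds: matrix-angle curves
   between a fold's rank-r estimate and the full-rank estimate from the
   complementary folds, plus cross-validated prediction MSE and average
   held-out log-likelihood per rank.

Folds always partition TRIALS, never time points, so increment/lag pairs
stay intact and folds are genuinely independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochedData
from .vecm import (
    EigenSolution,
    SufficientStats,
    center,
    fit_vecm,
    solve_eigenproblem,
    sufficient_stats,
)

__all__ = [
    "RankDiagnostics",
    "trace_stat",
    "maxeig_stat",
    "rsc_rank",
    "rsc_threshold",
    "matrix_angle",
    "angle_curves",
    "cv_rank",
    "select_rank",
    "rank_diagnostics",
]

# eigenvalues are clamped below 1 before logs; a numerically degenerate
# lambda = 1 would otherwise send the statistics to infinity
_LAMBDA_CEIL = 1.0 - 1e-12


def _clamped_lambdas(eig: EigenSolution) -> np.ndarray:
    lam = np.asarray(eig.lambdas, dtype=float)
    if np.any(lam >= 1.0):
        raise ValueError("eigenvalue >= 1: degenerate likelihood-ratio statistics")
    return np.clip(lam, 0.0, _LAMBDA_CEIL)


def trace_stat(eig: EigenSolution, r0: int, n_total: int) -> float:
    """Trace statistic -Ntot sum_{i>r0} log(1 - lambda_i) for H0: r <= r0."""
    lam = _clamped_lambdas(eig)
    p = lam.size
    if not 0 <= r0 <= p:
        raise ValueError("r0 out of range")
    return float(-n_total * np.log1p(-lam[r0:]).sum())


def maxeig_stat(eig: EigenSolution, r0: int, n_total: int) -> float:
    """Maximum-eigenvalue statistic -Ntot log(1 - lambda_{r0+1})."""
    lam = _clamped_lambdas(eig)
    if not 0 <= r0 < lam.size:
        raise ValueError("r0 out of range")
    return float(-n_total * np.log1p(-lam[r0]))


def rsc_threshold(S: SufficientStats, z) -> tuple[float, int]:
    """Threshold theta of the rank selection criterion, and predictor rank q.

    theta = 2 (p + q) / (p (Ntot - q)) * RSS_p, where RSS_p is the residual
    sum of squares of the full-rank least-squares fit Pi-hat_p = S01 S11^{-1}
    and q = rank(Z1) by SVD at numpy's default tolerance.
    """
    p = S.p
    n = S.n_total
    Pi_p = np.linalg.solve(S.S11, S.S01.T).T  # S01 S11^{-1}
    resid = z.z0 - z.z1 @ Pi_p.T
    rss = float(np.sum(resid**2))
    q = int(np.linalg.matrix_rank(z.z1))
    if n <= q:
        raise ValueError("need more pooled samples than predictor rank")
    theta = 2.0 * (p + q) / (p * (n - q)) * rss
    return theta, q


def rsc_rank(S: SufficientStats, z) -> tuple[int, float, int]:
    """Rank selection criterion: (rank, theta, q).

    Counts the eigenvalues of Z0' P_Z1 Z0 (= Ntot times the eigenvalues of
    S01 S11^{-1} S10) at or above theta.  This is exactly the rank of the
    penalized least-squares estimator argmin RSS(Pi) + theta rank(Pi).
    """
    theta, q = rsc_threshold(S, z)
    M = S.S01 @ np.linalg.solve(S.S11, S.S10)
    lam = np.linalg.eigvalsh(0.5 * (M + M.T))
    lam = np.clip(lam, 0.0, None) * S.n_total
    rank = int(np.sum(lam >= theta))
    return rank, theta, q


def matrix_angle(U: np.ndarray, V: np.ndarray) -> float:
    """Angle between matrices via the Frobenius inner product.

    Theta(U, V) = arccos( <U,V>_F / (||U||_F ||V||_F) ), clamped to
    [-1, 1] before the arccos; by convention Theta is pi/2 when either
    argument is the zero matrix.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    nu = np.linalg.norm(U)
    nv = np.linalg.norm(V)
    if nu == 0.0 or nv == 0.0:
        return float(np.pi / 2)
    c = float(np.sum(U * V) / (nu * nv))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _trial_folds(n_trials: int, n_folds: int, seed) -> list[np.ndarray]:
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_trials < n_folds:
        raise ValueError("more folds than trials")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n_trials), n_folds)


def angle_curves(
    data: EpochedData,
    n_folds: int = 5,
    ranks=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Matrix-angle curves Theta(Pi_r^(k), Pi_p^(-k)) per fold and rank.

    For each trial-fold k, the full-rank network is estimated from all
    other folds, the rank-r network from fold k alone, and their angle is
    recorded.  Curves flatten once r passes the true rank: beyond it the
    estimate only accumulates sampling noise.
    """
    p = data.n_channels
    if ranks is None:
        ranks = range(p + 1)
    folds = _trial_folds(data.n_trials, n_folds, seed)
    rows = []
    for k, fold in enumerate(folds):
        mask = np.zeros(data.n_trials, dtype=bool)
        mask[fold] = True
        fit_ref = fit_vecm(data.select_trials(~mask), p)
        fold_data = data.select_trials(mask)
        for r in ranks:
            fit_r = fit_vecm(fold_data, int(r))
            rows.append(
                {
                    "fold": k,
                    "rank": int(r),
                    "angle": matrix_angle(fit_r.Pi, fit_ref.Pi),
                }
            )
    return pd.DataFrame(rows)


def cv_rank(
    data: EpochedData,
    n_folds: int = 5,
    ranks=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cross-validated prediction MSE and average log-likelihood per rank.

    MSE(r) averages over folds the per-sample squared prediction error
    (summed across the p channels) of the rank-r model fitted without the
    fold; l(r) averages the held-out Gaussian log-likelihood per fold
    normalized by the fold's sample count.
    """
    p = data.n_channels
    if ranks is None:
        ranks = range(p + 1)
    ranks = [int(r) for r in ranks]
    folds = _trial_folds(data.n_trials, n_folds, seed)
    mse = dict.fromkeys(ranks, 0.0)
    ll = dict.fromkeys(ranks, 0.0)
    for fold in folds:
        mask = np.zeros(data.n_trials, dtype=bool)
        mask[fold] = True
        train = data.select_trials(~mask)
        test = data.select_trials(mask)
        dx = np.concatenate([np.diff(t, axis=0) for t in test.values])
        lag = np.concatenate([t[:-1] for t in test.values])
        n_k = dx.shape[0]
        for r in ranks:
            fit = fit_vecm(train, r)
            e = dx - fit.mu - lag @ fit.Pi.T
            mse[r] += float(np.mean(np.sum(e**2, axis=1)))
            sign, logdet = np.linalg.slogdet(fit.Sigma)
            quad = float(np.sum(e * np.linalg.solve(fit.Sigma, e.T).T))
            ll[r] += -0.5 * (logdet + quad / n_k)
    rows = [
        {"rank": r, "cv_mse": mse[r] / len(folds), "cv_loglik": ll[r] / len(folds)}
        for r in ranks
    ]
    return pd.DataFrame(rows)


@dataclass
class RankDiagnostics:
    """Bundle of every rank diagnostic computed for one dataset."""

    scree: pd.DataFrame
    lr_stats: pd.DataFrame
    rsc: int
    rsc_theta: float
    rsc_q: int
    angles: pd.DataFrame | None = None
    cv: pd.DataFrame | None = None
    n_folds: int | None = None
    provenance: dict = field(default_factory=dict)


def rank_diagnostics(
    data: EpochedData,
    n_folds: int = 5,
    ranks=None,
    seed: int | None = None,
    include_cv: bool = True,
) -> RankDiagnostics:
    """Compute scree, LR statistics, RSC, and the fold-based diagnostics."""
    z = center(data)
    S = sufficient_stats(z)
    eig = solve_eigenproblem(S)
    p = S.p
    scree = pd.DataFrame({"rank": np.arange(1, p + 1), "eigenvalue": eig.lambdas})
    lr = pd.DataFrame(
        {
            "r0": np.arange(p),
            "trace": [trace_stat(eig, r0, S.n_total) for r0 in range(p)],
            "max_eig": [maxeig_stat(eig, r0, S.n_total) for r0 in range(p)],
        }
    )
    rank, theta, q = rsc_rank(S, z)
    angles = cv = None
    if include_cv:
        angles = angle_curves(data, n_folds, ranks, seed)
        cv = cv_rank(data, n_folds, ranks, seed)
    return RankDiagnostics(
        scree=scree,
        lr_stats=lr,
        rsc=rank,
        rsc_theta=theta,
        rsc_q=q,
        angles=angles,
        cv=cv,
        n_folds=n_folds if include_cv else None,
    )


def select_rank(diagnostics: RankDiagnostics, policy: str = "rsc", manual: int | None = None) -> int:
    """Pick a working rank from the diagnostics.

    Policies: ``"rsc"`` takes the rank selection criterion estimate;
    ``"cv-mse-knee"`` takes the smallest rank whose CV-MSE improvement
    over the previous rank falls below 1% of the total MSE range;
    ``"manual"`` records the user's choice.  The choice and its origin
    are stored in ``diagnostics.provenance``.
    """
    if policy == "rsc":
        rank = diagnostics.rsc
    elif policy == "manual":
        if manual is None:
            raise ValueError("manual policy requires a rank")
        rank = int(manual)
    elif policy == "cv-mse-knee":
        if diagnostics.cv is None:
            raise ValueError("cv diagnostics missing")
        tab = diagnostics.cv.sort_values("rank")
        m = tab["cv_mse"].to_numpy()
        rng_ = m.max() - m.min()
        rank = int(tab["rank"].iloc[-1])
        for i in range(1, len(m)):
            if m[i - 1] - m[i] < 0.01 * rng_:
                rank = int(tab["rank"].iloc[i - 1])
                break
    else:
        raise ValueError(f"unknown policy {policy!r}")
    diagnostics.provenance = {"policy": policy, "rank": rank}
    return rank
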