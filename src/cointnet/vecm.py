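"""Johansen estimation of the vector error-correction model (VECM).

The VECM reparametrizes a VAR(1) as

    Delta x_n = mu + Pi x_{n-1} + eps_n,     eps_n ~ N(0, Sigma),

where Pi = alpha beta' has reduced rank r: the columns of beta span the
stationary (equilibrium) combinations beta' x, and alpha holds the
loadings that pull the system back when beta' x_{n-1} deviates from its
long-run mean.  Estimation is by reduced-rank regression: center the
increments and lags, form the product-moment matrices S00, S01, S11, and
solve the generalized eigenproblem

    lambda_i S11 v_i = S01' S00^{-1} S01 v_i,

whose r leading eigenvectors (normalized so v_i' S11 v_j = delta_ij) give
beta-hat; alpha, Sigma and mu then have closed forms.  With repeated
trials the only change is that sums run over trials as well as time, and
increment/lag pairs never straddle a trial boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .epochs import EpochedData

__all__ = [
    "CenteredStreams",
    "SufficientStats",
    "EigenSolution",
    "VECMParams",
    "center",
    "sufficient_stats",
    "solve_eigenproblem",
    "estimate_beta",
    "estimate_alpha",
    "estimate_sigma",
    "estimate_mu",
    "log_likelihood",
    "max_log_likelihood",
    "fit_vecm",
    "equilibrium_deviation",
]

#: Condition-number ceiling beyond which S00/S11 are treated as singular.
#: Exceeding it almost always means a redundant (common-average reference)
#: channel was not dropped.
COND_LIMIT = 1e10


@dataclass
class CenteredStreams:
    """Stacked centered increments (z0) and lags (z1), paired within trials.

    Centering removes the grand mean pooled over *all* trials and samples
    (not per trial).  Row t of z0 and row t of z1 come from adjacent
    samples of the same trial.
    """

    z0: np.ndarray
    z1: np.ndarray
    trial_index: np.ndarray
    mean_dx: np.ndarray
    mean_lag: np.ndarray

    @property
    def n_total(self) -> int:
        return self.z0.shape[0]

    @property
    def p(self) -> int:
        return self.z0.shape[1]


@dataclass
class SufficientStats:
    """Product-moment matrices S00, S01, S11 pooled over trials."""

    S00: np.ndarray
    S01: np.ndarray
    S11: np.ndarray
    n_total: int

    @property
    def S10(self) -> np.ndarray:
        return self.S01.T

    @property
    def p(self) -> int:
        return self.S00.shape[0]


@dataclass
class EigenSolution:
    """All p eigenpairs of the reduced-rank regression eigenproblem.

    ``lambdas`` are sorted descending in [0, 1]; column i of ``vectors``
    satisfies v_i' S11 v_j = delta_ij.
    """

    lambdas: np.ndarray
    vectors: np.ndarray


@dataclass
class VECMParams:
    """Fitted (or true) VECM parameters; Pi = alpha beta'."""

    mu: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    Sigma: np.ndarray
    rank: int
    info: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        p = self.mu.size
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(p, -1)
        self.beta = np.asarray(self.beta, dtype=float).reshape(p, -1)
        self.Sigma = np.asarray(self.Sigma, dtype=float).reshape(p, p)
        if self.alpha.shape[1] != self.rank or self.beta.shape[1] != self.rank:
            raise ValueError("alpha and beta must have r columns")

    @property
    def p(self) -> int:
        return self.mu.size

    @property
    def Pi(self) -> np.ndarray:
        return self.alpha @ self.beta.T


# ---------------------------------------------------------------------------
# estimation kernel
# ---------------------------------------------------------------------------

def center(data: EpochedData) -> CenteredStreams:
    """Center increments and lags by their grand means pooled over trials."""
    if np.any(data.n_per_trial < 2):
        bad = int(np.argmin(data.n_per_trial))
        raise ValueError(f"trial {bad} has fewer than 2 samples")
    dx_parts, lag_parts, idx_parts = [], [], []
    for m, t in enumerate(data.values):
        dx_parts.append(np.diff(t, axis=0))
        lag_parts.append(t[:-1])
        idx_parts.append(np.full(t.shape[0] - 1, m))
    dx = np.concatenate(dx_parts)
    lag = np.concatenate(lag_parts)
    mean_dx = dx.mean(axis=0)
    mean_lag = lag.mean(axis=0)
    return CenteredStreams(
        z0=dx - mean_dx,
        z1=lag - mean_lag,
        trial_index=np.concatenate(idx_parts),
        mean_dx=mean_dx,
        mean_lag=mean_lag,
    )


def sufficient_stats(z: CenteredStreams) -> SufficientStats:
    """S_ij = Ntot^{-1} sum_n z_i z_j' over all trials and samples."""
    n = z.n_total
    return SufficientStats(
        S00=z.z0.T @ z.z0 / n,
        S01=z.z0.T @ z.z1 / n,
        S11=z.z1.T @ z.z1 / n,
        n_total=n,
    )


def _checked_cholesky(S: np.ndarray, name: str) -> np.ndarray:
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"{name} is numerically singular (condition number {cond:.3g}); "
            "with common-average referenced data drop one channel before "
            "fitting (see cointnet.reference)"
        )
    return np.linalg.cholesky(S)


def solve_eigenproblem(S: SufficientStats) -> EigenSolution:
    """Solve lambda S11 v = S01' S00^{-1} S01 v for all p eigenpairs.

    Whitening route: with S11 = L L', the problem becomes an ordinary
    symmetric eigendecomposition of L^{-1} S01' S00^{-1} S01 L'^{-1};
    back-transforming the orthonormal eigenvectors by L'^{-1} yields the
    v_i' S11 v_j = delta_ij normalization directly.  Signs are fixed by
    making each vector's largest-magnitude entry positive.
    """
    L11 = _checked_cholesky(S.S11, "S11")
    L00 = _checked_cholesky(S.S00, "S00")
    # M = S01' S00^{-1} S01 via the triangular factor of S00
    T = solve_triangular(L00, S.S01, lower=True)
    M = T.T @ T
    # whiten by L11: C = L11^{-1} M L11^{-T} is symmetric PSD with the
    # same eigenvalues as the pencil (M, S11)
    C = solve_triangular(L11, M, lower=True)
    C = solve_triangular(L11, C.T, lower=True).T
    C = 0.5 * (C + C.T)
    lam, U = np.linalg.eigh(C)
    order = np.argsort(-lam, kind="stable")  # descending, stable ties
    lam = lam[order]
    U = U[:, order]
    if lam.min() < -1e-8 or lam.max() > 1.0 + 1e-8:
        raise np.linalg.LinAlgError(
            f"eigenvalues outside [0, 1]: range [{lam.min():.3g}, {lam.max():.3g}]"
        )
    lam = np.clip(lam, 0.0, 1.0)
    V = solve_triangular(L11.T, U, lower=False)
    # deterministic signs: largest-magnitude entry of each vector positive
    flip = V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    return EigenSolution(lambdas=lam, vectors=V)


def estimate_beta(eig: EigenSolution, r: int) -> np.ndarray:
    """First r eigenvectors as columns; beta' S11 beta = I_r."""
    p = eig.vectors.shape[0]
    if not 0 <= r <= p:
        raise ValueError("rank out of range")
    return eig.vectors[:, :r].copy()


def estimate_alpha(S: SufficientStats, beta: np.ndarray) -> np.ndarray:
    """alpha-hat = S01 beta (beta' S11 beta)^{-1} (least squares given beta)."""
    beta = np.asarray(beta, dtype=float).reshape(S.p, -1)
    if beta.shape[1] == 0:
        return np.zeros((S.p, 0))
    gram = beta.T @ S.S11 @ beta
    return S.S01 @ beta @ np.linalg.inv(gram)


def estimate_sigma(S: SufficientStats, beta: np.ndarray) -> np.ndarray:
    """Sigma-hat = S00 - S01 beta (beta' S11 beta)^{-1} beta' S01'."""
    beta = np.asarray(beta, dtype=float).reshape(S.p, -1)
    if beta.shape[1] == 0:
        return S.S00.copy()
    gram = beta.T @ S.S11 @ beta
    B = S.S01 @ beta
    Sig = S.S00 - B @ np.linalg.solve(gram, B.T)
    return 0.5 * (Sig + Sig.T)


def estimate_mu(z: CenteredStreams, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """mu-hat = pooled mean of (Delta x - alpha beta' x_lag)."""
    Pi = np.asarray(alpha) @ np.asarray(beta).T
    return z.mean_dx - Pi @ z.mean_lag


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _residuals(params: VECMParams, data: EpochedData) -> np.ndarray:
    parts = []
    for t in data.values:
        dx = np.diff(t, axis=0)
        parts.append(dx - params.mu - t[:-1] @ params.Pi.T)
    return np.concatenate(parts)


def log_likelihood(
    params: VECMParams,
    data: EpochedData,
    include_constant: bool = False,
) -> float:
    """Gaussian conditional log-likelihood of the increments given the lags.

    l = -(Ntot/2) log|Sigma| - (1/2) sum_n e_n' Sigma^{-1} e_n, with
    e_n = Delta x_n - mu - Pi x_{n-1}.  ``include_constant`` adds the
    -(Ntot p / 2) log 2 pi term; it cancels between equal-dimension models
    but is needed when the value is interpreted as a true log-likelihood
    (e.g. the per-trial log-likelihood difference classifier feature).
    """
    e = _residuals(params, data)
    n = e.shape[0]
    p = params.p
    sign, logdet = np.linalg.slogdet(params.Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "Sigma is singular; reduce the channel set (e.g. drop the "
            "redundant common-average reference channel) before evaluating "
            "the likelihood"
        )
    quad = float(np.sum(e * np.linalg.solve(params.Sigma, e.T).T))
    value = -0.5 * n * logdet - 0.5 * quad
    if include_constant:
        value -= 0.5 * n * p * np.log(2.0 * np.pi)
    return float(value)


def max_log_likelihood(
    sigma_hat: np.ndarray,
    n_total: int,
    include_constant: bool = False,
) -> float:
    """Maximized log-likelihood -(Ntot/2)(log|Sigma-hat| + p) (+ constant)."""
    p = sigma_hat.shape[0]
    sign, logdet = np.linalg.slogdet(sigma_hat)
    if sign <= 0:
        raise np.linalg.LinAlgError("Sigma-hat is singular")
    value = -0.5 * n_total * (logdet + p)
    if include_constant:
        value -= 0.5 * n_total * p * np.log(2.0 * np.pi)
    return float(value)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def fit_vecm(
    data: EpochedData,
    r: int,
    penalty=None,
    *,
    drop_channel: int | str | None = None,
) -> VECMParams:
    """Full Johansen fit at rank r.

    Pipeline: center -> sufficient stats -> generalized eigenproblem ->
    beta (r leading eigenvectors) -> alpha (closed form, or elastic-net
    penalized when ``penalty`` is a :class:`cointnet.regularization.PenaltyConfig`)
    -> Sigma, mu.  ``drop_channel`` removes one (redundant) channel before
    estimation; see :mod:`cointnet.reference` for re-expansion to full
    dimension.
    """
    if drop_channel is not None:
        from .reference import drop_channel as _drop

        data = _drop(data, drop_channel)
    z = center(data)
    S = sufficient_stats(z)
    eig = solve_eigenproblem(S)
    beta = estimate_beta(eig, r)
    if penalty is not None and penalty.gamma > 0 and r > 0:
        from .regularization import elastic_net_alpha

        alpha = elastic_net_alpha(z, beta, penalty)
    else:
        alpha = estimate_alpha(S, beta)
    Sigma = estimate_sigma(S, beta)
    mu = estimate_mu(z, alpha, beta)
    info = {
        "n_total": S.n_total,
        "eigenvalues": eig.lambdas.copy(),
        "penalty": None if penalty is None else (penalty.gamma, penalty.omega),
        "dropped_channel": data.dropped_channel,
        "channel_labels": list(data.channel_labels),
    }
    return VECMParams(mu=mu, alpha=alpha, beta=beta, Sigma=Sigma, rank=r, info=info)


def equilibrium_deviation(params: VECMParams, data: EpochedData) -> np.ndarray:
    """Disequilibrium errors beta' x_{n-1} minus their pooled sample mean.

    The pooled mean stands in for the long-run mean E(beta' x_inf); the
    output (Ntot x r) is a diagnostic of how far each sample sits from the
    estimated equilibria.
    """
    z = center(data)
    lag = z.z1 + z.mean_lag
    u = lag @ params.beta
    return u - u.mean(axis=0)
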