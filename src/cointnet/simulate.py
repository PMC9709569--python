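"""Cointegrated Ornstein-Uhlenbeck / VAR(1) trial simulator.

The generative model is the multivariate OU process

    dx_t = P (x_t - m) dt + D dW_t,

with drift matrix P = a b' of reduced rank r; all eigenvalues of b'a have
strictly negative real parts, so the process is null recurrent with p - r
independent stochastic trends and r stationary linear combinations (the
cointegration relationships).  Sampled at timestep delta the process obeys
the VAR(1)

    x_n = mu + A x_{n-1} + eps_n,    eps_n ~ N(0, Sigma),

with A = exp(P delta), mu = (I - A) m and
Sigma = \\int_0^delta exp(uP) DD' exp(uP') du.  Exactly p - r eigenvalue
moduli of A equal 1.

The module also generates factorial task designs (stimulus duration x
orientation x contrast x repetition, with per-trial fixation duration and
location) and Bernoulli trial outcomes from a logistic model, so the whole
analysis pipeline can be exercised on data with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .epochs import EpochedData

__all__ = [
    "OUParams",
    "VARParams",
    "build_cointegrated_drift",
    "discretize_ou",
    "simulate_trials",
    "apply_common_average",
    "make_task_design",
    "simulate_outcomes",
    "random_cointegrated_ou",
]

#: Levels of the visual-task factorial design used throughout the package:
#: 8 gap orientations x 2 luminance contrasts x 4 stimulus durations,
#: repeated 12 times (768 trials); fixation duration and stimulus location
#: are drawn per trial.
DEFAULT_DESIGN_LEVELS = {
    "duration_ms": [20, 40, 70, 110],
    "orientation_deg": [0, 45, 90, 135, 180, 225, 270, 315],
    "contrast": ["high", "low"],
}
DEFAULT_FIXATION_LEVELS = [round(1.5 + 0.1 * i, 1) for i in range(11)]
DEFAULT_LOCATION_LEVELS = ["left", "right"]
DEFAULT_REPETITIONS = 12

#: Default sampling timestep (seconds); 256 Hz.
DEFAULT_DELTA = 1.0 / 256.0


def _as_factor(x) -> np.ndarray:
    """Coerce a rank factor to a p x r matrix; 1-D input is one column."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x.reshape(-1, 1)
    if x.ndim != 2:
        raise ValueError("factor matrices must be 1- or 2-dimensional")
    return x


@dataclass
class OUParams:
    """Parameters (m, P, D, delta) of the continuous-time model.

    ``a`` and ``b`` are the rank factors of the drift, P = a b'.
    """

    m: np.ndarray
    a: np.ndarray
    b: np.ndarray
    D: np.ndarray
    delta: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float).ravel()
        self.a = _as_factor(self.a)
        self.b = _as_factor(self.b)
        self.D = np.atleast_2d(np.asarray(self.D, dtype=float))
        p = self.m.size
        if self.a.shape[0] != p or self.b.shape[0] != p or self.D.shape[0] != p:
            raise ValueError("a, b, D must have p rows")
        if self.a.shape[1] != self.b.shape[1]:
            raise ValueError("a and b must share the factor dimension r")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.rank > 0:
            check_stable_factorization(self.a, self.b)

    @property
    def p(self) -> int:
        return self.m.size

    @property
    def rank(self) -> int:
        return self.a.shape[1]

    @property
    def P(self) -> np.ndarray:
        return self.a @ self.b.T


@dataclass
class VARParams:
    """Discrete-time VAR(1) parameters (mu, A, Sigma)."""

    mu: np.ndarray
    A: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        p = self.mu.size
        if self.A.shape != (p, p) or self.Sigma.shape != (p, p):
            raise ValueError("A and Sigma must be p x p")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        w = np.linalg.eigvalsh(self.Sigma)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise ValueError("Sigma must be positive semidefinite")

    @property
    def p(self) -> int:
        return self.mu.size

    @property
    def Pi(self) -> np.ndarray:
        return self.A - np.eye(self.p)


def check_stable_factorization(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Validate the rank factors of a cointegrated drift P = a b'.

    Requires full column rank, b'a nonsingular, and every eigenvalue of
    b'a to have strictly negative real part (so the r combinations b'x
    are mean reverting).  Returns the eigenvalues of b'a.
    """
    a = _as_factor(a)
    b = _as_factor(b)
    r = a.shape[1]
    if np.linalg.matrix_rank(a) < r or np.linalg.matrix_rank(b) < r:
        raise ValueError("a and b must have full column rank")
    ba = b.T @ a
    if abs(np.linalg.det(ba)) < 1e-12:
        raise ValueError("b'a is singular")
    eig = np.linalg.eigvals(ba)
    worst = eig[np.argmax(eig.real)]
    if worst.real >= 0:
        raise ValueError(
            f"eigenvalue {worst:.6g} of b'a has nonnegative real part"
        )
    return eig


def build_cointegrated_drift(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Drift matrix P = a b' of rank r, after stability checks."""
    a = _as_factor(a)
    b = _as_factor(b)
    check_stable_factorization(a, b)
    return a @ b.T


def _van_loan_covariance(P: np.ndarray, Q: np.ndarray, delta: float) -> np.ndarray:
    """Exact integral S = int_0^delta e^{uP} Q e^{uP'} du.

    Van Loan block construction: exponentiate [[-P, Q], [0, P']] * delta;
    the integral is F22' F12 where F12, F22 are the upper-right and
    lower-right blocks.  Exact to machine precision and well behaved when
    P has zero eigenvalues (unlike a Lyapunov solve).
    """
    p = P.shape[0]
    block = np.zeros((2 * p, 2 * p))
    block[:p, :p] = -P
    block[:p, p:] = Q
    block[p:, p:] = P.T
    F = expm(block * delta)
    S = F[p:, p:].T @ F[:p, p:]
    return 0.5 * (S + S.T)


def discretize_ou(ou: OUParams) -> VARParams:
    """Exact discretization of the OU model at timestep delta."""
    P = ou.P
    A = expm(P * ou.delta)
    mu = (np.eye(ou.p) - A) @ ou.m
    Sigma = _van_loan_covariance(P, ou.D @ ou.D.T, ou.delta)
    return VARParams(mu=mu, A=A, Sigma=Sigma)


def simulate_trials(
    var: VARParams,
    n_trials: int,
    n_samples: int,
    *,
    delta: float = DEFAULT_DELTA,
    x0: np.ndarray | None = None,
    burn_in: int = 0,
    seed: int | np.random.SeedSequence | None = None,
    channel_labels: list[str] | None = None,
    trial_meta: pd.DataFrame | None = None,
) -> EpochedData:
    """Simulate independent trials of the VAR(1) recursion.

    Each trial starts from ``x0`` (default: the long-run mean implied by
    mu where it exists, otherwise 0, plus one innovation draw), optionally
    runs ``burn_in`` discarded steps, then records ``n_samples`` states.
    Per-trial generators are spawned from one root seed, so a trial's
    stream does not depend on how many trials precede it.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples per trial")
    if n_trials < 1:
        raise ValueError("need at least 1 trial")
    p = var.p
    # innovations via Cholesky of Sigma (PSD: fall back to eigh factor)
    try:
        L = np.linalg.cholesky(var.Sigma)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(var.Sigma)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise ValueError("Sigma is not positive semidefinite")
        L = V * np.sqrt(np.clip(w, 0.0, None))
    if x0 is None:
        # least-squares fixed point of the recursion: recovers the long-run
        # mean m in the stationary directions; trend directions start at 0
        base = np.linalg.lstsq(np.eye(p) - var.A, var.mu, rcond=None)[0]
    else:
        base = np.asarray(x0, dtype=float).ravel()

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_trials)
    trials = []
    for child in children:
        rng = np.random.default_rng(child)
        n_steps = burn_in + n_samples - 1
        eps = rng.standard_normal((n_steps + 1, p)) @ L.T
        x = np.empty((n_steps + 1, p))
        x[0] = base + eps[0]
        for n in range(1, n_steps + 1):
            x[n] = var.mu + var.A @ x[n - 1] + eps[n]
        trials.append(x[burn_in:])
    if channel_labels is None:
        channel_labels = [f"ch{i:02d}" for i in range(p)]
    return EpochedData(trials, channel_labels, delta, trial_meta)


def apply_common_average(data: EpochedData) -> EpochedData:
    """Common-average reference: subtract the across-channel mean of every
    time sample, so channels sum to zero and one channel becomes linearly
    redundant."""
    values = [t - t.mean(axis=1, keepdims=True) for t in data.values]
    return EpochedData(
        values,
        list(data.channel_labels),
        data.delta,
        data.trial_meta,
        common_average=True,
    )


def make_task_design(
    levels: dict | None = None,
    repetitions: int = DEFAULT_REPETITIONS,
    seed: int | None = None,
    *,
    fixation_levels=None,
    location_levels=None,
) -> pd.DataFrame:
    """Full factorial task design, randomized trial order.

    ``levels`` crosses duration x orientation x contrast; each combination
    appears exactly ``repetitions`` times.  Fixation duration and stimulus
    location are drawn independently per trial from their level sets.
    """
    lv = dict(DEFAULT_DESIGN_LEVELS if levels is None else levels)
    for name, vals in lv.items():
        if len(vals) == 0:
            raise ValueError(f"empty level set for {name}")
    if fixation_levels is None:
        fixation_levels = DEFAULT_FIXATION_LEVELS
    if location_levels is None:
        location_levels = DEFAULT_LOCATION_LEVELS
    names = list(lv)
    rows = [
        dict(zip(names, combo), repetition=rep)
        for rep in range(1, repetitions + 1)
        for combo in product(*(lv[n] for n in names))
    ]
    design = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    design = design.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    design["fixation_s"] = rng.choice(fixation_levels, size=len(design))
    design["location"] = rng.choice(location_levels, size=len(design))
    design.index.name = "trial"
    return design.reset_index()


def simulate_outcomes(
    design: pd.DataFrame,
    coefs: dict,
    *,
    d: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Bernoulli trial outcomes from a logistic model on the design.

    ``coefs`` maps covariate names to effects: a scalar for numeric terms
    (including ``"d"`` for the per-trial log-likelihood difference passed
    via ``d``), a ``{level: effect}`` dict for categorical terms, plus an
    optional ``"intercept"``.  The success probability of trial m is
    ``expit`` of the linear predictor.
    """
    n = len(design)
    eta = np.full(n, float(coefs.get("intercept", 0.0)))
    for name, effect in coefs.items():
        if name == "intercept":
            continue
        if name == "d":
            if d is None:
                raise ValueError("coefficient on d given but no d values")
            eta += float(effect) * np.asarray(d, dtype=float)
            continue
        if name not in design.columns:
            raise ValueError(f"unknown covariate {name!r}")
        col = design[name]
        if isinstance(effect, dict):
            unknown = set(col.unique()) - set(effect)
            if unknown:
                raise ValueError(f"no effect for levels {sorted(map(str, unknown))} of {name!r}")
            eta += col.map(effect).to_numpy(dtype=float)
        else:
            eta += float(effect) * col.to_numpy(dtype=float)
    prob = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(seed)
    return (rng.random(n) < prob).astype(int)


def random_cointegrated_ou(
    p: int,
    r: int,
    *,
    seed: int | None = None,
    delta: float = DEFAULT_DELTA,
    mean_scale: float = 0.0,
    noise_scale: float = 1.0,
    reversion: float = 20.0,
) -> OUParams:
    """Random rank-r cointegrated OU model, guaranteed stable.

    Draws Gaussian factors and reshapes them so b'a = -(reversion) * (I_r
    + K'K / r), whose eigenvalues all have negative real part.
    ``reversion`` is the mean-reversion rate in 1/s: with the default
    timestep of 1/256 s the stationary directions decorrelate over tens of
    milliseconds, the scale of fast transients in electrophysiology.
    """
    if not 0 <= r <= p:
        raise ValueError("need 0 <= r <= p")
    rng = np.random.default_rng(seed)
    m = mean_scale * rng.standard_normal(p)
    D = noise_scale * np.eye(p)
    if r == 0:
        a = np.zeros((p, 0))
        b = np.zeros((p, 0))
    else:
        b = rng.standard_normal((p, r))
        b, _ = np.linalg.qr(b)
        K = rng.standard_normal((r, r))
        target = -reversion * (np.eye(r) + K.T @ K / r)
        # choose a with b'a = target: a = b target + orth-complement noise
        a = b @ target
    return OUParams(m=m, a=a, b=b, D=D, delta=delta)
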