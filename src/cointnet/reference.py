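"""Common-average reference handling.

Common-average referencing subtracts the across-channel mean from every
time sample, so the p channels sum to zero and any one channel is a
linear function of the others.  The product-moment matrices of such data
are singular (S11 1_p = 0), so estimation must run on p - 1 channels.
This module drops one channel, re-expands the reduced cointegration
vectors back to full dimension (the expansion constant per column is
arbitrary; the default minimizes the column norm), and verifies the
invariances that make the network product Pi-hat x_{n-1} independent of
which channel was dropped.
"""

from __future__ import annotations

import warnings

import numpy as np

from .epochs import EpochedData
from .vecm import VECMParams, center, estimate_alpha, estimate_mu, estimate_sigma, fit_vecm, sufficient_stats

__all__ = [
    "drop_channel",
    "expand_beta",
    "expand_fit",
    "fit_vecm_referenced",
    "check_invariance",
]


def _resolve_channel(data: EpochedData, channel: int | str | None) -> int:
    if channel is None:
        return data.n_channels - 1
    if isinstance(channel, str):
        try:
            return data.channel_labels.index(channel)
        except ValueError:
            raise ValueError(f"unknown channel label {channel!r}") from None
    idx = int(channel)
    if not -data.n_channels <= idx < data.n_channels:
        raise ValueError(f"channel index {idx} out of range")
    return idx % data.n_channels


def drop_channel(data: EpochedData, channel: int | str | None = None) -> EpochedData:
    """Remove one channel (default: the last) before estimation.

    Warns when the data are not flagged as common-average referenced, in
    which case dropping a channel discards information instead of
    redundancy.
    """
    if data.n_channels < 2:
        raise ValueError("need at least 2 channels to drop one")
    idx = _resolve_channel(data, channel)
    if not data.common_average:
        warnings.warn(
            "dropping a channel from data without the common-average flag; "
            "the removed channel is not redundant",
            stacklevel=2,
        )
    keep = [i for i in range(data.n_channels) if i != idx]
    out = EpochedData(
        [t[:, keep] for t in data.values],
        [data.channel_labels[i] for i in keep],
        data.delta,
        data.trial_meta,
        common_average=False,
        dropped_channel=data.channel_labels[idx],
    )
    return out


def expand_beta(
    beta_reduced: np.ndarray,
    dropped_index: int,
    constants: np.ndarray | str = "min-norm",
) -> np.ndarray:
    """Re-expand a (p-1) x r cointegration matrix to full dimension p.

    On zero-sum data the combination beta_j' x^{(p-1)} equals
    (beta_j + c_j 1)' x^{(p-1)} + c_j x_dropped for any constant c_j, so
    the dropped channel's weight is a free choice.  The default
    ``"min-norm"`` rule, c_j = -(1/p) sum_i beta_ij, minimizes the
    Euclidean norm of the expanded column; explicit per-column constants
    are also accepted.  The expanded matrix keeps the p-dimensional
    normalization beta' S11 beta = I_r because S11 annihilates 1_p.
    """
    beta_reduced = np.asarray(beta_reduced, dtype=float)
    if beta_reduced.ndim == 1:
        beta_reduced = beta_reduced.reshape(-1, 1)
    pm1, r = beta_reduced.shape
    p = pm1 + 1
    if not 0 <= dropped_index < p:
        raise ValueError("dropped_index out of range")
    if isinstance(constants, str):
        if constants != "min-norm":
            raise ValueError(f"unknown expansion rule {constants!r}")
        c = -beta_reduced.sum(axis=0) / p
    else:
        c = np.asarray(constants, dtype=float).ravel()
        if c.size != r:
            raise ValueError("need one constant per column")
        if not np.all(np.isfinite(c)):
            raise ValueError("expansion constants must be finite")
    out = np.empty((p, r))
    keep = [i for i in range(p) if i != dropped_index]
    out[keep] = beta_reduced + c
    out[dropped_index] = c
    return out


def expand_fit(
    fit_reduced: VECMParams,
    data_full: EpochedData,
    constants: np.ndarray | str = "min-norm",
) -> VECMParams:
    """Lift a reduced-channel fit back to the full channel set.

    beta is expanded with :func:`expand_beta`; alpha, Sigma and mu are
    then re-estimated from the full p-dimensional sufficient statistics
    with the closed forms, exactly as if the expanded beta had been
    obtained directly.  The returned Sigma is singular on zero-sum data
    (rank p - 1): use the reduced fit for likelihoods, the expanded fit
    for the network Pi and its invariant product Pi x.
    """
    dropped = fit_reduced.info.get("dropped_channel")
    if dropped is None:
        raise ValueError("fit does not record a dropped channel")
    idx = data_full.channel_labels.index(dropped)
    beta_full = expand_beta(fit_reduced.beta, idx, constants)
    z = center(data_full)
    S = sufficient_stats(z)
    alpha = estimate_alpha(S, beta_full)
    Sigma = estimate_sigma(S, beta_full)
    mu = estimate_mu(z, alpha, beta_full)
    info = dict(fit_reduced.info)
    info.update(expanded_from=dropped, channel_labels=list(data_full.channel_labels))
    return VECMParams(mu=mu, alpha=alpha, beta=beta_full, Sigma=Sigma,
                      rank=fit_reduced.rank, info=info)


def fit_vecm_referenced(
    data: EpochedData,
    r: int,
    penalty=None,
    drop: int | str | None = None,
    constants: np.ndarray | str = "min-norm",
) -> tuple[VECMParams, VECMParams]:
    """Fit on p-1 channels and expand: returns (reduced_fit, full_fit)."""
    reduced = fit_vecm(data, r, penalty, drop_channel=drop)
    return reduced, expand_fit(reduced, data, constants)


def check_invariance(
    fit_a: VECMParams,
    fit_b: VECMParams,
    data: EpochedData,
    tol: float = 1e-6,
) -> dict:
    """Verify that the network product Pi-hat x_{n-1} does not depend on
    the dropped reference channel.

    Pi-hat itself is basis dependent (adding any constant d_i to row i
    leaves Pi x unchanged on zero-sum data), so only the product is
    compared.  Returns a report with the max absolute discrepancy over
    all lag samples, the row-shift check, and a pass flag.
    """
    lag = np.concatenate([t[:-1] for t in data.values])
    prod_a = lag @ fit_a.Pi.T
    prod_b = lag @ fit_b.Pi.T
    max_diff = float(np.abs(prod_a - prod_b).max())
    rng = np.random.default_rng(0)
    d = rng.standard_normal(fit_a.p)
    shifted = fit_a.Pi + d[:, None]  # constant added to each row
    shift_diff = float(np.abs(lag @ shifted.T - prod_a).max())
    return {
        "max_product_diff": max_diff,
        "row_shift_diff": shift_diff,
        "tol": tol,
        "passed": bool(max_diff < tol and shift_diff < tol),
    }
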