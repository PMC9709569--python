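"""Epoched multichannel data container.

An *epoch* (trial) is one repetition of an experimental task yielding a
short multichannel time-series segment; trials are treated as independent
realizations of the same stochastic process. :class:`EpochedData` is the
universal input of every estimation routine in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EpochedData"]

ZERO_SUM_TOL = 1e-10


@dataclass
class EpochedData:
    """M trials of p-channel recordings sampled on a regular grid.

    Parameters
    ----------
    values
        Either a single ``(M, N, p)`` array (all trials of equal length)
        or a list of ``(N_m, p)`` arrays.  Stored internally as a list so
        trials of unequal length are supported.
    channel_labels
        ``p`` channel names.
    delta
        Sampling timestep in seconds (> 0).
    trial_meta
        Optional table with one row per trial (condition labels, design
        covariates).
    common_average
        True when the data have been common-average referenced, i.e. the
        channels of every time sample sum to zero.  Set by
        :func:`cointnet.simulate.apply_common_average`.
    """

    values: list[np.ndarray]
    channel_labels: list[str]
    delta: float
    trial_meta: pd.DataFrame | None = None
    common_average: bool = False
    dropped_channel: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if isinstance(self.values, np.ndarray):
            if self.values.ndim != 3:
                raise ValueError("array input must have shape (M, N, p)")
            self.values = [np.asarray(t, dtype=float) for t in self.values]
        else:
            self.values = [np.asarray(t, dtype=float) for t in self.values]
        if not self.values:
            raise ValueError("need at least one trial")
        p = self.values[0].shape[1]
        for m, t in enumerate(self.values):
            if t.ndim != 2 or t.shape[1] != p:
                raise ValueError(f"trial {m} has channel count {t.shape} != {p}")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"trial {m} contains non-finite values")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != p:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {p} channels"
            )
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.trial_meta is not None and len(self.trial_meta) != len(self.values):
            raise ValueError("trial_meta must have one row per trial")
        if self.common_average:
            worst = max(
                float(np.abs(t.sum(axis=1)).max()) for t in self.values
            )
            if worst > ZERO_SUM_TOL:
                raise ValueError(
                    "common_average flag set but channel sums reach "
                    f"{worst:.2e} > {ZERO_SUM_TOL}"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.values)

    @property
    def n_channels(self) -> int:
        return self.values[0].shape[1]

    @property
    def n_per_trial(self) -> np.ndarray:
        """Number of samples N_m in each trial."""
        return np.array([t.shape[0] for t in self.values])

    @property
    def n_increments(self) -> int:
        """Total number of (lag, increment) pairs, sum of N_m - 1."""
        return int((self.n_per_trial - 1).sum())

    def as_tensor(self) -> np.ndarray:
        """Stack trials into an (M, N, p) array; requires equal lengths."""
        lengths = set(self.n_per_trial.tolist())
        if len(lengths) != 1:
            raise ValueError("trials have unequal lengths; cannot stack")
        return np.stack(self.values)

    # -- derived views --------------------------------------------------
    def select_trials(self, index) -> "EpochedData":
        """Subset of trials (boolean mask or integer index array)."""
        idx = np.arange(self.n_trials)[np.asarray(index)]
        meta = None
        if self.trial_meta is not None:
            meta = self.trial_meta.iloc[idx].reset_index(drop=True)
        return EpochedData(
            [self.values[i] for i in idx],
            list(self.channel_labels),
            self.delta,
            meta,
            self.common_average,
            self.dropped_channel,
        )

    def select_window(self, window: slice) -> "EpochedData":
        """Restrict every trial to a contiguous span of time samples."""
        return EpochedData(
            [t[window] for t in self.values],
            list(self.channel_labels),
            self.delta,
            self.trial_meta,
            self.common_average,
            self.dropped_channel,
        )

    def prestimulus_window(self, window_ms: float) -> "EpochedData":
        """Final ``window_ms`` milliseconds of every trial.

        Keeps ``k + 1`` samples where ``k = round(window_ms / 1000 / delta)``
        so that the window contributes exactly k increment pairs spanning
        the requested duration.
        """
        k = int(round(window_ms / 1000.0 / self.delta))
        if k < 1:
            raise ValueError("window shorter than one timestep")
        if np.any(self.n_per_trial < k + 1):
            raise ValueError("window longer than the shortest trial")
        return self.select_window(slice(-(k + 1), None))


def concat_trials(datasets: Sequence[EpochedData]) -> EpochedData:
    """Pool the trials of several datasets sharing channels and timestep."""
    first = datasets[0]
    for d in datasets[1:]:
        if d.channel_labels != first.channel_labels:
            raise ValueError("channel sets differ")
        if d.delta != first.delta:
            raise ValueError("timesteps differ")
    metas = [d.trial_meta for d in datasets]
    meta = None
    if all(m is not None for m in metas):
        meta = pd.concat(metas, ignore_index=True)
    return EpochedData(
        [t for d in datasets for t in d.values],
        list(first.channel_labels),
        first.delta,
        meta,
        all(d.common_average for d in datasets),
    )
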