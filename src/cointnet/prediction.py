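"""Trial-outcome prediction from the pre-stimulus brain state.

The classifier feature is the per-trial log-likelihood difference

    d_m = log L(mu_A, Pi_A, Sigma_A; x^(m)) - log L(mu_B, Pi_B, Sigma_B; x^(m)),

where model A is the VECM fitted to the pre-stimulus window (default the
final 100 ms before stimulus onset, one full period of 10 Hz activity) of
the correctly answered trials and model B to the incorrectly answered
ones, under a leave-one-trial-out principle: a trial never contributes to
the fit it is scored against.  d_m then enters a logistic regression for
response accuracy alongside the design covariates (stimulus duration,
orientation, contrast, fixation duration, location — all categorical),
and models are compared by AIC, BIC, ROC/AUC and drop-in-deviance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .epochs import EpochedData
from .vecm import VECMParams, fit_vecm, log_likelihood

__all__ = [
    "TrialOutcomeTable",
    "LogisticFit",
    "loglik_difference",
    "leave_one_trial_out_d",
    "build_outcome_table",
    "fit_logistic",
    "standard_model_terms",
    "roc_auc",
    "drop_in_deviance",
]

#: Pre-stimulus window length (milliseconds) used for the condition fits.
DEFAULT_WINDOW_MS = 100.0

#: Coefficient magnitude beyond which the logistic fit is flagged as
#: (quasi-)separated.
_SEPARATION_LIMIT = 15.0


@dataclass
class TrialOutcomeTable:
    """Per-trial table: binary accuracy, d_m, and the design covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "accuracy" not in self.table.columns:
            raise ValueError("table must contain an 'accuracy' column")
        if "d" in self.table.columns and not np.all(np.isfinite(self.table["d"])):
            raise ValueError("d must be finite")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with the conventions used here.

    ``df`` counts non-intercept parameters; AIC = deviance + 2 (df + 1)
    and BIC = deviance + (df + 1) log n, the intercept included in the
    penalty.  (For a binary response the saturated log-likelihood is 0,
    so deviance = -2 loglik and this AIC is the usual one.)
    """

    params: pd.Series
    deviance: float
    df: int
    n_obs: int
    fitted: np.ndarray
    formula: str
    separation: bool = False
    result: object = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * (self.df + 1)

    @property
    def bic(self) -> float:
        return self.deviance + (self.df + 1) * np.log(self.n_obs)


def loglik_difference(
    trial: EpochedData,
    model_a: VECMParams,
    model_b: VECMParams,
) -> float:
    """d = l(A; trial) - l(B; trial), full log-likelihoods (constants on).

    Both models must share the channel dimension; the 2-pi constants then
    cancel, but including them keeps each term a genuine log-likelihood.
    """
    if model_a.p != model_b.p:
        raise ValueError("models must share the channel dimension")
    return log_likelihood(model_a, trial, include_constant=True) - log_likelihood(
        model_b, trial, include_constant=True
    )


def leave_one_trial_out_d(
    data: EpochedData,
    labels: np.ndarray,
    window_ms: float | None = DEFAULT_WINDOW_MS,
    rank: int = 1,
    penalty=None,
) -> np.ndarray:
    """Leave-one-trial-out log-likelihood differences.

    For trial m: model A is fitted to all label-1 trials (excluding m when
    its label is 1), model B to all label-0 trials (excluding m when its
    label is 0), both on the pre-stimulus window; d_m is evaluated on
    trial m's window.  Deterministic given the data.
    """
    labels = np.asarray(labels).astype(int).ravel()
    if labels.size != data.n_trials:
        raise ValueError("one label per trial required")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("each label class needs at least 2 trials")
    win = data if window_ms is None else data.prestimulus_window(window_ms)
    idx_a = np.flatnonzero(labels == 1)
    idx_b = np.flatnonzero(labels == 0)
    fit_a_all = fit_vecm(win.select_trials(idx_a), rank, penalty)
    fit_b_all = fit_vecm(win.select_trials(idx_b), rank, penalty)
    d = np.empty(data.n_trials)
    for m in range(data.n_trials):
        trial = win.select_trials([m])
        if labels[m] == 1:
            fa = fit_vecm(win.select_trials(idx_a[idx_a != m]), rank, penalty)
            fb = fit_b_all
        else:
            fa = fit_a_all
            fb = fit_vecm(win.select_trials(idx_b[idx_b != m]), rank, penalty)
        d[m] = loglik_difference(trial, fa, fb)
    return d


def build_outcome_table(
    design: pd.DataFrame, accuracy: np.ndarray, d: np.ndarray
) -> TrialOutcomeTable:
    """Assemble the per-trial outcome table from design, labels and d."""
    table = design.copy()
    table["accuracy"] = np.asarray(accuracy).astype(int)
    table["d"] = np.asarray(d, dtype=float)
    return TrialOutcomeTable(table)


def standard_model_terms() -> dict[str, list[str]]:
    """Formula terms of the standard model battery.

    M1: all covariates; M2: all except d; M01..M06: one covariate each.
    Categorical covariates use treatment coding with the first sorted
    level as reference; d is the only continuous term.
    """
    cat = {
        "duration": "C(duration_ms)",
        "orientation": "C(orientation_deg)",
        "contrast": "C(contrast)",
        "fixation": "C(fixation_s)",
        "location": "C(location)",
    }
    full = [cat["duration"], cat["orientation"], "d", cat["contrast"],
            cat["fixation"], cat["location"]]
    return {
        "M1": full,
        "M2": [t for t in full if t != "d"],
        "M01": [cat["duration"]],
        "M02": [cat["orientation"]],
        "M03": ["d"],
        "M04": [cat["contrast"]],
        "M05": [cat["fixation"]],
        "M06": [cat["location"]],
    }


def fit_logistic(
    table: TrialOutcomeTable | pd.DataFrame,
    terms: list[str] | str,
    response: str = "accuracy",
) -> LogisticFit:
    """Maximum-likelihood logistic regression of the trial outcome.

    ``terms`` is a list of patsy terms (or a ready right-hand side).
    Levels absent from the data are dropped by the design-matrix builder.
    Separation (diverging coefficients) is detected and flagged rather
    than silently returned.
    """
    df_tab = table.table if isinstance(table, TrialOutcomeTable) else table
    rhs = terms if isinstance(terms, str) else " + ".join(terms) or "1"
    formula = f"{response} ~ {rhs}"
    model = smf.glm(formula, data=df_tab, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    params = res.params
    separation = bool(np.any(np.abs(params.values) > _SEPARATION_LIMIT)) or not res.converged
    return LogisticFit(
        params=params,
        deviance=float(res.deviance),
        df=int(res.df_model),
        n_obs=int(res.nobs),
        fitted=np.asarray(res.fittedvalues),
        formula=formula,
        separation=separation,
        result=res,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC by the rank (Mann-Whitney) formulation.

    AUC = (R1 - n1 (n1 + 1) / 2) / (n0 n1) with midranks, which counts
    tied score pairs as half; the ROC table lists (threshold, FPR, TPR)
    at every distinct score.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("need both classes to compute a ROC curve")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)
    # ROC points: sweep thresholds over distinct scores, descending
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), sorted_labels.size - 1]
    roc = pd.DataFrame(
        {
            "threshold": np.r_[np.inf, sorted_scores[distinct]],
            "fpr": np.r_[0.0, fps[distinct] / n0],
            "tpr": np.r_[0.0, tps[distinct] / n1],
        }
    )
    return roc, float(auc)


def drop_in_deviance(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int, float]:
    """Chi-squared test of a reduced model nested in a full model.

    Returns (statistic, df, p-value); df is the parameter-count difference.
    """
    if reduced.df > full.df:
        raise ValueError("the reduced model must be nested in the full model")
    stat = reduced.deviance - full.deviance
    df = full.df - reduced.df
    if df == 0:
        return max(stat, 0.0), 0, 1.0
    return float(max(stat, 0.0)), int(df), float(stats.chi2.sf(max(stat, 0.0), df))
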