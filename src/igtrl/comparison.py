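"""WAIC and PSIS-LOO model comparison from pointwise log-likelihoods.

Both criteria operate on a (draws x observations) matrix of per-trial
log-likelihoods; observations are trials (subject-level aggregation is
available via ``aggregate='subject'``).  Lower values are better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import FitResult

PARETO_K_THRESHOLD = 0.7


def _check_pointwise(pointwise: np.ndarray) -> np.ndarray:
    pw = np.asarray(pointwise, dtype=float)
    if pw.ndim != 2:
        raise ValueError("pointwise matrix must be (draws, observations)")
    if pw.shape[0] < 2:
        raise ValueError("at least 2 draws are required")
    if not np.all(np.isfinite(pw)):
        raise ValueError("pointwise log-likelihoods must be finite")
    return pw


def waic(pointwise: np.ndarray) -> tuple[float, float, float]:
    """Widely applicable information criterion.

    lppd_i = log mean_s exp(ll_si); p_i = var_s(ll_si);
    WAIC = -2 * sum_i (lppd_i - p_i), SE from the per-observation
    components.  Returns (waic, se, p_waic).
    """
    pw = _check_pointwise(pointwise)
    D, N = pw.shape
    lppd_i = logsumexp(pw, axis=0) - np.log(D)
    p_i = pw.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    value = -2.0 * elpd_i.sum()
    se = 2.0 * np.sqrt(N * elpd_i.var(ddof=1)) if N > 1 else 0.0
    return float(value), float(se), float(p_i.sum())


def looic(pointwise: np.ndarray) -> tuple[float, float, np.ndarray]:
    """PSIS-LOO information criterion.

    Importance ratios 1/p(y_i|theta_s) are Pareto-smoothed in the tail;
    elpd_loo_i = log sum_s w_si p(y_i|theta_s).  Returns
    (looic, se, pareto_k per observation); observations with k above
    0.7 are unreliable and should be flagged by the caller.
    """
    from arviz.stats import psislw

    pw = _check_pointwise(pointwise)
    D, N = pw.shape
    if np.allclose(pw, pw[0]):  # degenerate posterior: LOO == WAIC == -2*sum ll
        elpd_i = pw[0]
        value = -2.0 * elpd_i.sum()
        se = 2.0 * np.sqrt(N * elpd_i.var(ddof=1)) if N > 1 else 0.0
        return float(value), float(se), np.zeros(N)
    # psislw expects samples on the last axis: (observations, draws)
    lw, k = psislw(-pw.T)
    elpd_i = logsumexp(lw + pw.T, axis=1)
    value = -2.0 * elpd_i.sum()
    se = 2.0 * np.sqrt(N * elpd_i.var(ddof=1)) if N > 1 else 0.0
    return float(value), float(se), np.asarray(k)


@dataclass(frozen=True)
class ComparisonRow:
    model: str
    looic: float
    looic_se: float
    waic: float
    waic_se: float
    p_waic: float
    n_bad_pareto_k: int
    rank: int


def _pointwise_matrix(
    fit: FitResult, n_draws: int, seed: int, aggregate: str
) -> np.ndarray:
    ll = fit.pointwise_draws(n_draws=n_draws, seed=seed)  # (D, S, T)
    if aggregate == "subject":
        return ll.sum(axis=2)
    if aggregate == "trial":
        D = ll.shape[0]
        return ll.reshape(D, -1)
    raise ValueError("aggregate must be 'trial' or 'subject'")


def compare(
    fits: Mapping[str, FitResult],
    n_draws: int = 200,
    seed: int = 0,
    aggregate: str = "trial",
) -> pd.DataFrame:
    """Rank candidate models by LOOIC (WAIC breaks ties).

    All fits must be on the identical cohort (same subjects, same trial
    counts).  Returns one row per model with criteria, SEs, the number
    of unreliable Pareto-k observations, and the rank (1 = best).
    """
    if not fits:
        raise ValueError("no fits to compare")
    items = list(fits.items())
    ref = items[0][1]
    for name, fit in items[1:]:
        if fit.subject_ids != ref.subject_ids or fit.choices.shape != ref.choices.shape:
            raise ValueError(
                f"fit {name!r} is not on the same cohort as {items[0][0]!r}"
            )
    rows = []
    for name, fit in items:
        pw = _pointwise_matrix(fit, n_draws, seed, aggregate)
        w, w_se, p_w = waic(pw)
        lo, lo_se, k = looic(pw)
        rows.append(
            {
                "model": name,
                "looic": lo,
                "looic_se": lo_se,
                "waic": w,
                "waic_se": w_se,
                "p_waic": p_w,
                "n_bad_pareto_k": int(np.sum(k > PARETO_K_THRESHOLD)),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["looic", "waic", "model"], kind="mergesort"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)
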