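"""Group-level statistics: Levene-gated t-tests, mixed and repeated-
measures ANOVA, and Pearson correlations, with the effect sizes used in
behavioural work (Cohen's d, partial eta squared).

Conventions: all tests are two-sided; the independent-samples gate runs
Levene's test (mean-centred by default) and switches to Welch's t with
Satterthwaite df when it rejects at 0.05; Cohen's d uses the pooled SD
for independent comparisons and the SD of the differences for paired
ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LEVENE_ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    cohen_d: float
    variant: str                      # pooled | welch | paired
    levene_p: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = x.size, y.size
    return np.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )


def independent_t(
    x, y, gate_by_levene: bool = True, levene_center: str = "mean"
) -> TTestResult:
    """Independent two-sample t-test with a variance-homogeneity gate.

    If the gate is on and Levene's test rejects at 0.05, Welch's t with
    Satterthwaite df is used; otherwise the pooled-variance Student t.
    Cohen's d always uses the pooled SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            raise ValueError("t undefined: both samples constant and equal")
    levene_p = None
    welch = False
    if gate_by_levene:
        levene_p = float(stats.levene(x, y, center=levene_center).pvalue)
        welch = levene_p < LEVENE_ALPHA
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    sp = _pooled_sd(x, y)
    d = (x.mean() - y.mean()) / sp if sp > 0 else np.inf * np.sign(x.mean() - y.mean())
    return TTestResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        cohen_d=float(d),
        variant="welch" if welch else "pooled",
        levene_p=levene_p,
    )


def t_from_summaries(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> TTestResult:
    """Independent t-test from summary statistics alone."""
    if sd1 < 0 or sd2 < 0 or n1 < 2 or n2 < 2:
        raise ValueError("need sds >= 0 and ns >= 2")
    if sd1 == 0 and sd2 == 0 and m1 == m2:
        raise ValueError("t undefined: zero variance and equal means")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    res = stats.ttest_ind_from_stats(
        m1, sd1, n1, m2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (m1 - m2) / sp if sp > 0 else np.inf * np.sign(m1 - m2)
    return TTestResult(
        t=float(res.statistic), df=df, p=float(res.pvalue),
        cohen_d=float(d), variant=variant,
    )


def paired_t(pre, post) -> TTestResult:
    """Paired t-test on pre - post differences; d = mean(diff)/sd(diff)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("paired samples must have equal length")
    if pre.size < 2:
        raise ValueError("need n >= 2 pairs")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("t undefined: all paired differences identical")
    n = diff.size
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return TTestResult(
        t=float(t), df=float(n - 1), p=float(p),
        cohen_d=float(diff.mean() / sd), variant="paired",
    )


def _eta_from_f(F: float, df1: float, df2: float) -> float:
    return (F * df1) / (F * df1 + df2)


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "time",
    between: str = "group",
    subject: str = "subject",
) -> list[AnovaResult]:
    """2 x 2 mixed ANOVA (one within factor, one between factor).

    Every subject must contribute every level of the within factor; a
    missing cell raises with the subject named.
    """
    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    bad = counts[counts < n_levels]
    if len(bad):
        raise ValueError(f"incomplete within-factor data for subject(s): "
                         f"{list(bad.index)}")
    import pingouin as pg

    res = pg.mixed_anova(
        data=data, dv=dv, within=within, subject=subject, between=between
    )
    out = []
    name_map = {"Interaction": f"{within} * {between}"}
    for _, row in res.iterrows():
        F, p, np2 = _degenerate_safe(row, "F", "p_unc", "np2")
        out.append(
            AnovaResult(
                effect=name_map.get(row["Source"], row["Source"]),
                F=F,
                df_num=float(row["DF1"]),
                df_den=float(row["DF2"]),
                p=p,
                partial_eta_sq=np2,
            )
        )
    return out


def _degenerate_safe(row, f_col: str, p_col: str, eta_col: str | None):
    """Normalize degenerate ANOVA cells: a zero effect sum of squares
    (even with zero error SS, e.g. perfectly constant data) is reported
    as F = 0, p = 1."""
    F = float(row[f_col]) if f_col in row and np.isfinite(row.get(f_col, np.nan)) else np.nan
    p = float(row[p_col]) if p_col in row and np.isfinite(row.get(p_col, np.nan)) else np.nan
    eta = (
        float(row[eta_col])
        if eta_col and eta_col in row and np.isfinite(row.get(eta_col, np.nan))
        else np.nan
    )
    if not np.isfinite(F):
        if abs(float(row.get("SS", 0.0))) < 1e-12:
            return 0.0, 1.0, 0.0
        return float("inf"), 0.0, 1.0
    if not np.isfinite(eta):
        eta = _eta_from_f(F, float(row.get("DF1", row.get("ddof1", 1))),
                          float(row.get("DF2", row.get("ddof2", 1))))
    return F, p, eta


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, str] = ("time", "block"),
    subject: str = "subject",
) -> list[AnovaResult]:
    """Two-way fully-within repeated-measures ANOVA.

    Requires a complete crossing of both within factors per subject;
    partial eta squared is recovered from F and the dfs.
    """
    w1, w2 = within
    expected = data[w1].nunique() * data[w2].nunique()
    cell_counts = data.groupby(subject).size()
    bad = cell_counts[cell_counts != expected]
    if len(bad):
        raise ValueError(
            f"incomplete {w1} x {w2} crossing for subject(s): {list(bad.index)}"
        )
    import pingouin as pg

    res = pg.rm_anova(
        data=data, dv=dv, within=list(within), subject=subject, detailed=True
    )
    out = []
    for _, row in res.iterrows():
        df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        F, p, _ = _degenerate_safe(row, "F", "p_unc", None)
        out.append(
            AnovaResult(
                effect=str(row["Source"]),
                F=F,
                df_num=df1,
                df_den=df2,
                p=p,
                partial_eta_sq=_eta_from_f(F, df1, df2) if np.isfinite(F) else 1.0,
            )
        )
    return out


def pearson_r(x, y) -> tuple[float, int, float]:
    """Pearson correlation with df = n - 2 and a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), int(x.size - 2), float(res.pvalue)
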