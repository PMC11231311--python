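"""Statistics layer: t-tests, ANOVA, correlations against scalar oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from igtrl.stats import (
    independent_t,
    mixed_anova,
    paired_t,
    pearson_r,
    rm_anova,
    t_from_summaries,
)


# ---------------------------------------------------------------------------
# independent t
# ---------------------------------------------------------------------------

def test_independent_t_identical_samples():
    r = independent_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
    assert r.t == pytest.approx(0.0)
    assert r.cohen_d == pytest.approx(0.0)


def test_independent_t_hand_computed():
    # x=(1,2,3), y=(4,5,6): pooled sd = 1, SE = sqrt(2/3), t = -3/SE
    r = independent_t([1, 2, 3], [4, 5, 6], gate_by_levene=False)
    expected_t = -3.0 / math.sqrt(2.0 / 3.0)
    assert r.t == pytest.approx(expected_t)
    assert r.df == 4
    assert r.variant == "pooled"
    assert r.cohen_d == pytest.approx(-3.0)


def test_levene_gate_selects_welch():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0, 10, 40)
    r = independent_t(x, y)
    assert r.variant == "welch"
    assert r.levene_p < 0.05
    assert r.df < 78  # Welch df below pooled df


def test_welch_equals_pooled_for_equal_variance_equal_n():
    x = np.array([1.0, 2, 3, 4, 5])
    y = x + 2
    pooled = independent_t(x, y, gate_by_levene=False)
    welch = t_from_summaries(x.mean(), x.std(ddof=1), 5, y.mean(), y.std(ddof=1), 5,
                             variant="welch")
    assert welch.t == pytest.approx(pooled.t)
    assert welch.df <= pooled.df + 1e-9


def test_independent_t_degenerate_error():
    with pytest.raises(ValueError):
        independent_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    with pytest.raises(ValueError):
        independent_t([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# t from summaries
# ---------------------------------------------------------------------------

def test_t_from_summaries_usage_per_month_row():
    """Worked example from the published demographic table: monthly
    methamphetamine usage in the treated vs untreated patient groups."""
    r = t_from_summaries(15.83, 13.54, 24, 16.19, 8.88, 26)
    assert abs(r.t) == pytest.approx(0.112, abs=5e-4)
    assert r.df == 48


def test_t_from_summaries_group_df():
    r = t_from_summaries(36.20, 9.96, 50, 35.34, 6.81, 39)
    assert r.df == 87


def test_t_from_summaries_agrees_with_raw_samples():
    rng = np.random.default_rng(3)
    x, y = rng.normal(0, 1, 20), rng.normal(0.4, 1.3, 25)
    raw = independent_t(x, y, gate_by_levene=False)
    summ = t_from_summaries(x.mean(), x.std(ddof=1), 20, y.mean(), y.std(ddof=1), 25)
    assert summ.t == pytest.approx(raw.t, abs=1e-10)
    assert summ.p == pytest.approx(raw.p, abs=1e-10)
    assert summ.cohen_d == pytest.approx(raw.cohen_d, abs=1e-10)


def test_t_from_summaries_zero_mean_difference():
    r = t_from_summaries(5.0, 1.0, 10, 5.0, 2.0, 10)
    assert r.t == pytest.approx(0.0)
    with pytest.raises(ValueError):
        t_from_summaries(5.0, 0.0, 10, 5.0, 0.0, 10)


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def test_paired_t_hand_computed():
    # differences post-pre: (1,0,2,2) -> pre-post = (-1,0,-2,-2)
    r = paired_t([1, 2, 3, 4], [2, 2, 5, 6])
    d = np.array([-1.0, 0, -2, -2])
    t_expected = d.mean() / (d.std(ddof=1) / 2)
    assert r.t == pytest.approx(t_expected)
    assert r.df == 3
    assert r.cohen_d == pytest.approx(d.mean() / d.std(ddof=1))


@pytest.mark.parametrize("pre,post", [([1, 2, 3], [1, 2, 3]), ([1, 2, 3], [2, 3, 4])])
def test_paired_t_degenerate_differences_error(pre, post):
    with pytest.raises(ValueError):
        paired_t(pre, post)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _mixed_toy():
    # 3 subjects per group, 2 time points
    rows = []
    values = {
        ("g1", "s1"): (10, 12), ("g1", "s2"): (11, 14), ("g1", "s3"): (9, 13),
        ("g2", "s4"): (10, 10), ("g2", "s5"): (12, 11), ("g2", "s6"): (11, 12),
    }
    for (g, s), (pre, post) in values.items():
        rows.append({"subject": s, "group": g, "time": "pre", "value": pre})
        rows.append({"subject": s, "group": g, "time": "post", "value": post})
    return pd.DataFrame(rows)


def test_mixed_anova_constant_data_gives_zero_f():
    df = _mixed_toy()
    df["value"] = 7.0
    res = {r.effect: r for r in mixed_anova(df)}
    for effect in res.values():
        assert effect.F == pytest.approx(0.0, abs=1e-10)


def test_mixed_anova_pure_group_effect():
    df = _mixed_toy()
    base = {"s1": 0, "s2": 0, "s3": 0, "s4": 5, "s5": 5, "s6": 5}
    df["value"] = df["subject"].map(base) + 1.0
    res = {r.effect: r for r in mixed_anova(df)}
    assert res["time"].F == pytest.approx(0.0, abs=1e-10)
    assert res["time * group"].F == pytest.approx(0.0, abs=1e-10)
    assert res["group"].F > 10


def test_mixed_anova_matches_hand_decomposition():
    """Two time points: the interaction F equals the squared independent
    t on the difference scores (classic algebraic identity)."""
    df = _mixed_toy()
    res = {r.effect: r for r in mixed_anova(df)}
    piv = df.pivot_table(index=["group", "subject"], columns="time", values="value")
    diff = piv["post"] - piv["pre"]
    t = independent_t(diff.loc["g1"].to_numpy(), diff.loc["g2"].to_numpy(),
                      gate_by_levene=False)
    assert res["time * group"].F == pytest.approx(t.t**2, rel=1e-9)
    assert res["time * group"].df_num == 1
    assert res["time * group"].df_den == 4
    # partial eta squared consistent with F and dfs
    F, d1, d2 = res["group"].F, res["group"].df_num, res["group"].df_den
    assert res["group"].partial_eta_sq == pytest.approx(F * d1 / (F * d1 + d2))


def test_mixed_anova_missing_cell_names_subject():
    df = _mixed_toy().iloc[:-1]
    with pytest.raises(ValueError, match="s6"):
        mixed_anova(df)


def _rm_toy(signal="block"):
    rows = []
    rng = np.random.default_rng(1)
    for s in range(6):
        for t_idx, t in enumerate(["pre", "post"]):
            for b in range(1, 6):
                v = 0.1 * rng.normal()
                if signal == "block":
                    v += 0.3 * b
                elif signal == "time":
                    v += 0.8 * t_idx
                rows.append({"subject": f"s{s}", "time": t, "block": b, "value": v})
    return pd.DataFrame(rows)


def test_rm_anova_constant_data():
    df = _rm_toy()
    df["value"] = 3.0
    for r in rm_anova(df):
        assert r.F == pytest.approx(0.0, abs=1e-9)


def test_rm_anova_block_signal_detected():
    res = {r.effect: r for r in rm_anova(_rm_toy("block"))}
    assert res["block"].p < 1e-6
    assert res["time"].p > 0.05
    assert res["block"].df_num == 4
    assert res["block"].df_den == 20
    assert 0 <= res["block"].partial_eta_sq <= 1


def test_rm_anova_matches_manual_two_level_reduction():
    """With the block factor ignored, the time effect from the two-way
    within ANOVA equals the paired t on subject means (F = t^2)."""
    df = _rm_toy("time")
    res = {r.effect: r for r in rm_anova(df)}
    piv = df.pivot_table(index="subject", columns="time", values="value")
    t = paired_t(piv["pre"].to_numpy(), piv["post"].to_numpy())
    assert res["time"].F == pytest.approx(t.t**2, rel=1e-9)


def test_rm_anova_incomplete_crossing_error():
    df = _rm_toy().iloc[:-2]
    with pytest.raises(ValueError):
        rm_anova(df)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def test_pearson_perfect_and_inverse():
    x = np.array([1.0, 2, 3, 4, 5])
    r, df, p = pearson_r(x, 2 * x)
    assert r == pytest.approx(1.0)
    assert df == 3
    r, _, _ = pearson_r(x, -x)
    assert r == pytest.approx(-1.0)


def test_pearson_null_calibration():
    rng = np.random.default_rng(6)
    hits = 0
    n_reps = 300
    for _ in range(n_reps):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _, _ = pearson_r(x, y)
        hits += abs(r) < 0.28
    assert hits / n_reps > 0.93


def test_pearson_errors():
    with pytest.raises(ValueError):
        pearson_r([1, 2], [3, 4])
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])
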