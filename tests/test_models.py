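"""Choice models: elementary operations, likelihood oracle, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igtrl.models import (
    MODELS,
    PVLDeltaParams,
    VPPParams,
    choice_probs,
    combine_value,
    decay_update,
    delta_update,
    perseverance_update,
    sensitivity,
    sequence_loglik,
    utility_ev,
    utility_pv,
)
from igtrl.task import make_subject


# ---------------------------------------------------------------------------
# independent scalar-loop oracle (pure python, no numpy vector path)
# ---------------------------------------------------------------------------

def oracle_loglik(decks, nets, params, model, scale=100.0):
    """Step-by-step likelihood computed with plain python floats.

    decks: deck indices 0..3; nets: raw RMB net outcomes; params: dict.
    """
    E = [0.0, 0.0, 0.0, 0.0]
    P = [0.0, 0.0, 0.0, 0.0]
    theta = 3.0 ** params["cons"] - 1.0
    total = []
    for c, net in zip(decks, nets):
        if model == "vpp":
            V = [params["w"] * E[j] + (1 - params["w"]) * P[j] for j in range(4)]
        else:
            V = list(E)
        m = max(theta * v for v in V)
        lse = math.log(sum(math.exp(theta * v - m) for v in V))
        total.append(theta * V[c] - m - lse)
        x = net / scale
        if x >= 0:
            u = x ** params["alpha"]
        else:
            u = -params["lam"] * abs(x) ** params["alpha"]
        if model == "pvl_decay":
            E = [params["A"] * e for e in E]
            E[c] += u
        else:
            E[c] = E[c] + params["A"] * (u - E[c])
        if model == "vpp":
            P = [params["K"] * p for p in P]
            P[c] += params["epP"] if x >= 0 else params["epN"]
    return total


def _random_params(model, rng):
    if model == "vpp":
        return {
            "A": rng.uniform(0, 1), "alpha": rng.uniform(0.1, 1.9),
            "cons": rng.uniform(0, 3), "lam": rng.uniform(0, 5),
            "epP": rng.normal(0, 1.5), "epN": rng.normal(0, 1.5),
            "K": rng.uniform(0, 1), "w": rng.uniform(0, 1),
        }
    return {
        "A": rng.uniform(0, 1), "alpha": rng.uniform(0.1, 1.9),
        "cons": rng.uniform(0, 3), "lam": rng.uniform(0, 5),
    }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x,alpha,lam,expected",
    [(0, 0.5, 3.0, 0.0), (100, 1.0, 3.0, 100.0), (-100, 0.5, 2.0, -20.0)],
)
def test_utility_pv(x, alpha, lam, expected):
    assert utility_pv(x, alpha, lam) == pytest.approx(expected)


@pytest.mark.parametrize(
    "win,loss,w,expected",
    [(100, 0, 0.5, 50.0), (0, 1250, 0.5, -625.0), (100, 100, 1.0, 100.0)],
)
def test_utility_ev(win, loss, w, expected):
    assert utility_ev(win, loss, w) == pytest.approx(expected)


def test_delta_update_limits():
    assert delta_update(0.0, 1.0, 0.5) == pytest.approx(0.5)
    assert delta_update(3.0, 1.0, 0.0) == pytest.approx(3.0)
    assert delta_update(3.0, 1.0, 1.0) == pytest.approx(1.0)


@given(
    E=st.floats(-10, 10), u=st.floats(-10, 10), A=st.floats(0, 1),
)
@settings(derandomize=True, max_examples=50)
def test_delta_update_is_contraction_toward_u(E, u, A):
    out = delta_update(E, u, A)
    assert min(E, u) - 1e-12 <= out <= max(E, u) + 1e-12
    # repeated application with constant u converges to u
    x = E
    for _ in range(2000):
        x = delta_update(x, u, max(A, 0.1))
    assert x == pytest.approx(u, abs=1e-6)


def test_decay_update():
    out = decay_update(np.ones(4), 0.0, 0, 0.5)
    assert out.tolist() == [0.5, 0.5, 0.5, 0.5]
    out = decay_update(np.zeros(4), 2.0, 2, 0.9)
    assert out.tolist() == [0.0, 0.0, 2.0, 0.0]
    out = decay_update(np.array([1.0, 2.0, 3.0, 4.0]), 5.0, 1, 0.0)
    assert out.tolist() == [0.0, 5.0, 0.0, 0.0]


def test_perseverance_update():
    out = perseverance_update(np.zeros(4), 0, 50.0, 0.5, 1.0, -0.5)
    assert out.tolist() == [1.0, 0.0, 0.0, 0.0]
    out = perseverance_update(np.array([2.0, 1.0, 1.0, 1.0]), 0, -1250.0, 0.5, 1.0, -0.5)
    assert out[0] == pytest.approx(0.5)  # 0.5*2 - 0.5
    assert out[1:].tolist() == [0.5, 0.5, 0.5]
    out = perseverance_update(np.ones(4), 3, 10.0, 0.0, 0.7, -0.2)
    assert out.tolist() == [0.0, 0.0, 0.0, 0.7]


def test_combine_value():
    E = np.array([2.0, 0, 0, 0])
    P = np.array([0, 2.0, 0, 0])
    assert combine_value(E, P, 1.0).tolist() == E.tolist()
    assert combine_value(E, P, 0.0).tolist() == P.tolist()
    assert combine_value(E, P, 0.5).tolist() == [1.0, 1.0, 0.0, 0.0]


@pytest.mark.parametrize("cons,theta", [(0, 0.0), (1, 2.0), (5, 242.0)])
def test_sensitivity(cons, theta):
    assert sensitivity(cons) == pytest.approx(theta)


def test_choice_probs_examples():
    assert choice_probs(np.full(4, 7.3), 2.0) == pytest.approx([0.25] * 4)
    assert choice_probs(np.array([5.0, -1.0, 0.0, 2.0]), 0.0) == pytest.approx(
        [0.25] * 4
    )
    p = choice_probs(np.array([1.0, 0, 0, 0]), math.log(3))
    assert p[0] == pytest.approx(0.5)
    assert p[1:] == pytest.approx([1 / 6] * 3)
    with pytest.raises(ValueError):
        choice_probs(np.array([np.inf, 0, 0, 0]), 1.0)


@given(
    v=st.lists(st.floats(-20, 20), min_size=4, max_size=4),
    shift=st.floats(-50, 50),
    theta=st.floats(0, 10),
)
@settings(derandomize=True, max_examples=100)
def test_choice_probs_sum_to_one_and_shift_invariant(v, shift, theta):
    V = np.array(v)
    p = choice_probs(V, theta)
    assert abs(p.sum() - 1.0) < 1e-12
    q = choice_probs(V + shift, theta)
    assert p == pytest.approx(q, abs=1e-10)


# ---------------------------------------------------------------------------
# sequence likelihood
# ---------------------------------------------------------------------------

def test_cons_zero_gives_uniform_loglik(schedule):
    subj = make_subject("s", np.random.default_rng(0).integers(0, 4, 100), schedule)
    params = VPPParams(A=0.3, alpha=1.0, cons=0.0, lam=1.0, epP=1.0, epN=-1.0,
                       K=0.5, w=0.5)
    total, per_trial = sequence_loglik(subj, params, "vpp")
    assert total == pytest.approx(100 * math.log(0.25))
    assert per_trial == pytest.approx(np.full(100, math.log(0.25)))


def test_five_trial_toy_sequence_matches_hand_loop(schedule):
    # decks B,B,A,C,D; VPP reduces to delta-rule RL (w=1, no perseverance)
    subj = make_subject("s", ["B", "B", "A", "C", "D"], schedule)
    params = VPPParams(A=0.5, alpha=1.0, cons=1.0, lam=1.0, epP=0.0, epN=0.0,
                       K=0.0, w=1.0)
    total, per_trial = sequence_loglik(subj, params, "vpp")
    oracle = oracle_loglik(
        [1, 1, 0, 2, 3], [t.net for t in subj.trials],
        {"A": 0.5, "alpha": 1.0, "cons": 1.0, "lam": 1.0, "epP": 0.0,
         "epN": 0.0, "K": 0.0, "w": 1.0},
        "vpp",
    )
    assert per_trial == pytest.approx(oracle, abs=1e-12)
    assert total == pytest.approx(sum(oracle), abs=1e-12)


@pytest.mark.parametrize("model", sorted(MODELS))
def test_vectorized_loglik_matches_scalar_oracle(model, schedule):
    """100 random parameter/sequence draws agree with the independent
    scalar-loop implementation to 1e-10."""
    rng = np.random.default_rng(2024)
    info = MODELS[model]
    for _ in range(100 // len(MODELS) + 1):
        decks = rng.integers(0, 4, size=100)
        subj = make_subject("s", decks, schedule)
        pdict = _random_params(model, rng)
        params = info.param_class(**{k: pdict[k] for k in info.param_names})
        _, per_trial = sequence_loglik(subj, params, model)
        oracle = oracle_loglik(decks.tolist(), [t.net for t in subj.trials],
                               pdict, model)
        np.testing.assert_allclose(per_trial, oracle, atol=1e-10)


def test_vpp_nests_pvl_delta(schedule):
    """VPP with w=1 and no perseverance impacts equals PVL-Delta exactly."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        decks = rng.integers(0, 4, size=100)
        subj = make_subject("s", decks, schedule)
        shared = dict(
            A=rng.uniform(0, 1), alpha=rng.uniform(0.1, 1.9),
            cons=rng.uniform(0, 3), lam=rng.uniform(0, 5),
        )
        vpp = VPPParams(**shared, epP=0.0, epN=0.0, K=rng.uniform(0, 1), w=1.0)
        pvl = PVLDeltaParams(**shared)
        tot_v, ll_v = sequence_loglik(subj, vpp, "vpp")
        tot_p, ll_p = sequence_loglik(subj, pvl, "pvl_delta")
        np.testing.assert_array_equal(ll_v, ll_p)


def test_higher_cons_raises_loglik_of_dominant_deck(schedule):
    """On a greedy sequence from a high-sensitivity agent, increasing
    cons never lowers the likelihood of the observed choices."""
    from igtrl.synthetic import simulate_agent

    gen = PVLDeltaParams(A=0.2, alpha=1.0, cons=2.2, lam=1.0)
    subj = simulate_agent(gen, "pvl_delta", schedule, seed=11)
    lls = []
    for cons in [0.0, 0.5, 1.0, 1.5, 2.0]:
        params = PVLDeltaParams(A=0.2, alpha=1.0, cons=cons, lam=1.0)
        total, _ = sequence_loglik(subj, params, "pvl_delta")
        lls.append(total)
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_plugin_model_registry_contract(schedule):
    """An external model registered with a python likelihood and policy
    flows through simulation and fitting without touching the kernels."""
    from dataclasses import dataclass

    from igtrl.inference import fit_map
    from igtrl.models import ModelInfo
    from igtrl.synthetic import simulate_agent

    @dataclass(frozen=True)
    class BiasParams:
        bias: float  # preference strength for deck D in [0, 5]

    def loglik(choices, nets, params):
        logits = np.array([0.0, 0.0, 0.0, params[0]])
        logp = logits - np.log(np.exp(logits).sum())
        return logp[choices]

    def policy(choices_so_far, nets_so_far, params):
        logits = np.array([0.0, 0.0, 0.0, params[0]])
        e = np.exp(logits)
        return e / e.sum()

    MODELS["deck_d_bias"] = ModelInfo(
        name="deck_d_bias",
        param_class=BiasParams,
        param_names=("bias",),
        bounds=((0.0, 5.0),),
        loglik_fn=loglik,
        policy_fn=policy,
    )
    try:
        subj = simulate_agent(BiasParams(bias=2.0), "deck_d_bias", schedule, seed=0)
        counts = subj.deck_counts()
        assert counts["D"] > 50  # strong bias expressed in behaviour
        total, per_trial = sequence_loglik(subj, BiasParams(bias=2.0), "deck_d_bias")
        assert per_trial.shape == (100,)
        fit = fit_map([subj], "deck_d_bias", seed=0, n_restarts=3)
        assert 1.0 < fit.estimates.iloc[0]["bias"] < 3.5
    finally:
        del MODELS["deck_d_bias"]


def test_param_bounds_enforced():
    with pytest.raises(ValueError):
        PVLDeltaParams(A=1.2, alpha=1.0, cons=1.0, lam=1.0)
    with pytest.raises(ValueError):
        VPPParams(A=0.5, alpha=2.5, cons=1.0, lam=1.0, epP=0, epN=0, K=0.5, w=0.5)
    with pytest.raises(KeyError):
        sequence_loglik(None, None, "orl")
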