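"""Trial-level reinforcement-learning models for the IGT.

Three models share a common structure — a prospect-valence utility of
each net outcome, an expectancy update per deck, and a softmax over
deck values with sensitivity ``theta = 3**cons - 1``:

* **PVL-Delta** — expectancies follow the delta rule
  ``E <- E + A*(u - E)`` on the chosen deck (A is a learning rate).
* **PVL-DecayRI** — all expectancies decay multiplicatively,
  ``E <- A*E``, and the chosen deck adds the utility (A is a decay).
* **VPP** — PVL-Delta expectancies plus a perseverance strength per
  deck that decays at rate K and is kicked by epP after gains / epN
  after losses; deck value is ``w*E + (1-w)*P``.

All state starts at zero, so the first trial is a uniform choice.
Net outcomes are divided by ``outcome_scale`` (default 100) before the
utility, keeping ``x**alpha`` in a numerically comfortable range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from . import _kernels
from .task import SubjectDataset

#: divisor applied to net RMB outcomes before the utility function
OUTCOME_SCALE = 100.0


def _check_bounds(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class VPPParams:
    """Value-Plus-Perseverance parameters.

    A: learning rate [0,1]; alpha: outcome-sensitivity shape (0,2);
    cons: response consistency [0,5]; lam: loss aversion [0,5];
    epP/epN: gain/loss perseverance impacts (unbounded);
    K: perseverance decay [0,1]; w: reinforcement-learning weight [0,1].
    """

    A: float
    alpha: float
    cons: float
    lam: float
    epP: float
    epN: float
    K: float
    w: float

    def __post_init__(self) -> None:
        _check_bounds("A", self.A, 0.0, 1.0)
        _check_bounds("alpha", self.alpha, 0.0, 2.0)
        _check_bounds("cons", self.cons, 0.0, 5.0)
        _check_bounds("lam", self.lam, 0.0, 5.0)
        _check_bounds("K", self.K, 0.0, 1.0)
        _check_bounds("w", self.w, 0.0, 1.0)


@dataclass(frozen=True)
class PVLDeltaParams:
    """PVL-Delta parameters: delta-rule learning rate A plus the shared
    utility (alpha, lam) and consistency (cons) parameters."""

    A: float
    alpha: float
    cons: float
    lam: float

    def __post_init__(self) -> None:
        _check_bounds("A", self.A, 0.0, 1.0)
        _check_bounds("alpha", self.alpha, 0.0, 2.0)
        _check_bounds("cons", self.cons, 0.0, 5.0)
        _check_bounds("lam", self.lam, 0.0, 5.0)


@dataclass(frozen=True)
class PVLDecayParams:
    """PVL-DecayRI parameters: here A is the multiplicative decay (recency)
    applied to every deck's expectancy each trial."""

    A: float
    alpha: float
    cons: float
    lam: float

    def __post_init__(self) -> None:
        _check_bounds("A", self.A, 0.0, 1.0)
        _check_bounds("alpha", self.alpha, 0.0, 2.0)
        _check_bounds("cons", self.cons, 0.0, 5.0)
        _check_bounds("lam", self.lam, 0.0, 5.0)


@dataclass(frozen=True)
class ModelInfo:
    """Registry entry: one model's parameter space and likelihood.

    ``bounds`` uses ``(-inf, inf)`` for unbounded parameters.  Built-in
    models dispatch to a compiled kernel via ``kernel_id``; external
    models (e.g. ORL) plug in by registering an entry with
    ``loglik_fn(choices, scaled_nets, param_array) -> per-trial log-p``
    (and optionally ``policy_fn(choices_so_far, scaled_nets_so_far,
    param_array) -> 4 choice probabilities`` for simulation), leaving
    ``kernel_id`` at -1.
    """

    name: str
    param_class: type
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    kernel_id: int = -1
    loglik_fn: Callable | None = None
    policy_fn: Callable | None = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def to_vector(self, params) -> np.ndarray:
        """Dense 8-slot kernel layout [A, alpha, cons, lam, epP, epN, K, w]."""
        vec = np.zeros(8, dtype=np.float64)
        vec[7] = 1.0  # w=1: PVL variants are pure-RL in the kernel layout
        for i, name in enumerate(("A", "alpha", "cons", "lam", "epP", "epN", "K", "w")):
            if name in self.param_names:
                vec[i] = getattr(params, name)
        return vec

    def from_array(self, values: Iterable[float]):
        return self.param_class(**dict(zip(self.param_names, values)))

    def as_array(self, params) -> np.ndarray:
        return np.array([getattr(params, n) for n in self.param_names], dtype=float)


MODELS: dict[str, ModelInfo] = {
    "vpp": ModelInfo(
        name="vpp",
        param_class=VPPParams,
        param_names=("A", "alpha", "cons", "lam", "epP", "epN", "K", "w"),
        bounds=(
            (0.0, 1.0),
            (0.0, 2.0),
            (0.0, 5.0),
            (0.0, 5.0),
            (-np.inf, np.inf),
            (-np.inf, np.inf),
            (0.0, 1.0),
            (0.0, 1.0),
        ),
        kernel_id=_kernels.MODEL_VPP,
    ),
    "pvl_delta": ModelInfo(
        name="pvl_delta",
        param_class=PVLDeltaParams,
        param_names=("A", "alpha", "cons", "lam"),
        bounds=((0.0, 1.0), (0.0, 2.0), (0.0, 5.0), (0.0, 5.0)),
        kernel_id=_kernels.MODEL_PVL_DELTA,
    ),
    "pvl_decay": ModelInfo(
        name="pvl_decay",
        param_class=PVLDecayParams,
        param_names=("A", "alpha", "cons", "lam"),
        bounds=((0.0, 1.0), (0.0, 2.0), (0.0, 5.0), (0.0, 5.0)),
        kernel_id=_kernels.MODEL_PVL_DECAY,
    ),
}


def get_model(name: str) -> ModelInfo:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# elementary operations (pure functions over scalars / 4-vectors)
# ---------------------------------------------------------------------------

def utility_pv(x: float, alpha: float, lam: float) -> float:
    """Prospect-valence utility: ``x**alpha`` for gains,
    ``-lam * |x|**alpha`` for losses (x = 0 counts as a gain)."""
    if x >= 0:
        return float(x) ** alpha
    return -lam * abs(float(x)) ** alpha


def utility_ev(win: float, loss: float, w_ev: float) -> float:
    """Expectancy-valence utility: ``w*win - (1-w)*loss`` with both
    arguments entered as non-negative magnitudes."""
    if not (0.0 <= w_ev <= 1.0):
        raise ValueError("w_ev must lie in [0, 1]")
    return w_ev * win - (1.0 - w_ev) * loss


def delta_update(E_prev: float, u: float, A: float) -> float:
    """Delta rule for the chosen deck: move a fraction A toward u."""
    if not (0.0 <= A <= 1.0):
        raise ValueError("A must lie in [0, 1]")
    return E_prev + A * (u - E_prev)


def decay_update(E: np.ndarray, u: float, chosen: int, A: float) -> np.ndarray:
    """Decay rule: every expectancy is discounted by A; the chosen deck
    additionally absorbs the utility."""
    if not (0.0 <= A <= 1.0):
        raise ValueError("A must lie in [0, 1]")
    out = A * np.asarray(E, dtype=float)
    out[chosen] += u
    return out


def perseverance_update(
    P: np.ndarray, chosen: int, net: float, K: float, epP: float, epN: float
) -> np.ndarray:
    """Perseverance strengths decay by K everywhere; the chosen deck is
    kicked by epP after a non-negative net outcome, epN after a loss."""
    if not (0.0 <= K <= 1.0):
        raise ValueError("K must lie in [0, 1]")
    out = K * np.asarray(P, dtype=float)
    out[chosen] += epP if net >= 0 else epN
    return out


def combine_value(E: np.ndarray, P: np.ndarray, w: float) -> np.ndarray:
    """Deck value as the RL-weighted mixture ``w*E + (1-w)*P``."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must lie in [0, 1]")
    return w * np.asarray(E, dtype=float) + (1.0 - w) * np.asarray(P, dtype=float)


def sensitivity(cons: float) -> float:
    """Softmax sensitivity ``theta = 3**cons - 1`` (cons=0 -> random)."""
    if not (0.0 <= cons <= 5.0):
        raise ValueError("cons must lie in [0, 5]")
    return 3.0 ** cons - 1.0


def choice_probs(V: np.ndarray, theta: float) -> np.ndarray:
    """Softmax choice probabilities ``exp(theta*V_j) / sum_k exp(theta*V_k)``,
    computed with max-subtraction."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("deck values must be finite")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    z = theta * V
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# sequence likelihood
# ---------------------------------------------------------------------------

def sequence_loglik(
    subject: SubjectDataset,
    params,
    model: str,
    outcome_scale: float = OUTCOME_SCALE,
) -> tuple[float, np.ndarray]:
    """Log-likelihood of a subject's choice sequence under a model.

    Iterates trials in order from zero initial state, scoring the
    probability of each observed choice *before* updating the state
    with that trial's outcome.  Returns the total and the per-trial
    vector (the pointwise quantities WAIC/LOOIC need).
    """
    info = get_model(model)
    choices = subject.choices()
    nets = subject.nets() / outcome_scale
    if info.loglik_fn is not None:
        ll = np.asarray(info.loglik_fn(choices, nets, info.as_array(params)))
    else:
        vec = info.to_vector(params)
        ll = _kernels.loglik_trials(choices, nets, vec, info.kernel_id)
    return float(ll.sum()), ll


def loglik_pointwise_batch(
    choices: np.ndarray,
    nets: np.ndarray,
    param_matrix: np.ndarray,
    model: str,
    outcome_scale: float = OUTCOME_SCALE,
) -> np.ndarray:
    """Vectorized per-trial log-likelihoods for B (sequence, params) pairs.

    choices: int (B, T); nets: raw RMB (B, T); param_matrix: (B, P) in
    the model's natural parameter order.  Returns (B, T).
    """
    info = get_model(model)
    choices = np.ascontiguousarray(choices, dtype=np.int64)
    nets = np.ascontiguousarray(np.asarray(nets, dtype=np.float64) / outcome_scale)
    B = choices.shape[0]
    if info.loglik_fn is not None:
        return np.stack(
            [
                np.asarray(info.loglik_fn(choices[b], nets[b], param_matrix[b]))
                for b in range(B)
            ]
        )
    dense = np.zeros((B, 8), dtype=np.float64)
    dense[:, 7] = 1.0
    slots = {"A": 0, "alpha": 1, "cons": 2, "lam": 3, "epP": 4, "epN": 5, "K": 6, "w": 7}
    for j, name in enumerate(info.param_names):
        dense[:, slots[name]] = param_matrix[:, j]
    return _kernels.loglik_batch(choices, nets, dense, info.kernel_id)
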