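"""Synthetic cohorts: model-driven agents with group-typical parameters.

The generator plays VPP/PVL agents against a payoff schedule to produce
100-trial choice sequences, drawing each subject's true parameters from
truncated normals whose means/SDs default to the published group
summaries (healthy controls, methamphetamine-use-disorder patients, and
the treated subgroup pre/post).  Craving scores are integer-valued on a
1-100 scale.  True parameters are returned alongside the data so that
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .models import OUTCOME_SCALE, get_model
from .task import DECK_LABELS, PayoffSchedule, SubjectDataset, make_subject
from . import _kernels

_DATA = Path(__file__).parent / "data" / "cohorts.yaml"

#: group-typical VPP parameter means/SDs (natural scale)
PARAM_TABLE: dict[str, dict[str, tuple[float, float]]] = yaml.safe_load(
    _DATA.read_text()
)["groups"]
PARAM_TABLE = {
    g: {k: tuple(v) for k, v in block.items()} for g, block in PARAM_TABLE.items()
}

#: craving score means/SDs per group and session, 1-100 scale
CRAVING_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "MUD-t": {"pre": (66.0, 17.6), "post": (34.6, 13.8)},
    "MUD-n": {"pre": (67.31, 17.79), "post": (67.31, 17.79)},
}

#: treated-group pre -> post mean shift of the true parameters
DEFAULT_POST_SHIFT: dict[str, float] = {
    "A": -0.14,
    "alpha": -0.38,
    "cons": 0.13,
    "lam": 0.38,
    "epP": 0.41,
    "epN": 0.49,
    "K": 0.13,
    "w": -0.11,
}


@dataclass(frozen=True)
class CravingModel:
    """Integer craving scores, clipped to [1, 100].

    ``round_to_ten`` emulates the tendency of self-reports to cluster
    on multiples of ten; off by default.
    """

    mean: float
    sd: float
    round_to_ten: bool = False

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = rng.normal(self.mean, self.sd, size=n)
        if self.round_to_ten:
            x = np.round(x / 10.0) * 10.0
        return np.clip(np.round(x), 1, 100).astype(int)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic group.

    ``params`` maps parameter name to (mean, sd) on the natural scale;
    truncation at the model bounds is applied on draw.  ``post_shift``
    (additive, per parameter) defines the post-session true parameters
    for paired designs.
    """

    group: str
    n: int
    params: dict[str, tuple[float, float]]
    seed: int = 0
    sessions: tuple[str, ...] = ("pre",)
    post_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name, (mean, sd) in self.params.items():
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")

    @classmethod
    def from_table(
        cls, group: str, n: int, seed: int = 0, table_key: str | None = None, **kw
    ) -> "CohortSpec":
        key = table_key or group
        if key not in PARAM_TABLE:
            raise KeyError(f"no parameter table for group {key!r}")
        return cls(group=group, n=n, params=dict(PARAM_TABLE[key]), seed=seed, **kw)


def _check_means_in_bounds(spec: CohortSpec, model: str) -> None:
    info = get_model(model)
    for name, (lo, hi) in zip(info.param_names, info.bounds):
        if name not in spec.params:
            raise ValueError(f"spec for {spec.group} missing parameter {name}")
        mean = spec.params[name][0]
        if not (lo <= mean <= hi):
            raise ValueError(
                f"{spec.group}: mean of {name} ({mean}) outside bounds [{lo}, {hi}]"
            )


def _draw_params(
    spec_params: dict[str, tuple[float, float]],
    model: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-subject true parameters: truncated normal within the model's
    bounds (plain normal for the unbounded perseverance impacts)."""
    info = get_model(model)
    out = np.empty((n, info.n_params))
    for j, (name, (lo, hi)) in enumerate(zip(info.param_names, info.bounds)):
        mean, sd = spec_params[name]
        if sd == 0:
            out[:, j] = mean
        elif np.isinf(lo) or np.isinf(hi):
            out[:, j] = rng.normal(mean, sd, size=n)
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            out[:, j] = stats.truncnorm.rvs(
                a, b, loc=mean, scale=sd, size=n, random_state=rng
            )
    return out


def simulate_agent(
    params,
    model: str,
    schedule: PayoffSchedule,
    seed: int,
    subject_id: str = "sim",
    group: str = "HC",
    session: str = "pre",
    n_trials: int | None = None,
    outcome_scale: float = OUTCOME_SCALE,
) -> SubjectDataset:
    """Play one agent through the task.

    At each trial the deck is sampled from the model's current choice
    probabilities, the outcome is read off the schedule at the deck's
    next position, and the latent state is updated with that outcome.
    """
    info = get_model(model)
    rng = np.random.default_rng(seed)
    T = n_trials or schedule.n_trials
    if info.policy_fn is not None:
        return _simulate_plugin(
            info, params, schedule, rng, T, subject_id, group, session, outcome_scale
        )
    dense = info.to_vector(params)
    A, alpha, cons, lam, epP, epN, K, w = dense
    theta = 3.0 ** cons - 1.0

    E = np.zeros(4)
    P = np.zeros(4)
    positions = np.zeros(4, dtype=int)
    choices: list[int] = []
    for _ in range(T):
        if info.kernel_id == _kernels.MODEL_VPP:
            V = w * E + (1.0 - w) * P
        else:
            V = E
        z = theta * V
        z = z - z.max()
        p = np.exp(z)
        p /= p.sum()
        c = int(rng.choice(4, p=p))
        choices.append(c)
        positions[c] += 1
        gain, loss = schedule.card_orders[DECK_LABELS[c]][
            (positions[c] - 1) % len(schedule.card_orders[DECK_LABELS[c]])
        ]
        x = (gain - loss) / outcome_scale
        u = x ** alpha if x >= 0 else -lam * (-x) ** alpha
        if info.kernel_id == _kernels.MODEL_PVL_DECAY:
            E = A * E
            E[c] += u
        else:
            E[c] += A * (u - E[c])
        if info.kernel_id == _kernels.MODEL_VPP:
            P = K * P
            P[c] += epP if x >= 0 else epN
    return make_subject(subject_id, choices, schedule, group=group, session=session)


def _simulate_plugin(
    info, params, schedule, rng, T, subject_id, group, session, outcome_scale
):
    """Generic sampling loop for registry plug-in models: the model's
    ``policy_fn`` maps the observed history to choice probabilities."""
    theta_vec = info.as_array(params)
    choices: list[int] = []
    nets: list[float] = []
    positions = np.zeros(4, dtype=int)
    for _ in range(T):
        p = np.asarray(
            info.policy_fn(
                np.array(choices, dtype=np.int64),
                np.array(nets, dtype=float),
                theta_vec,
            ),
            dtype=float,
        )
        c = int(rng.choice(4, p=p / p.sum()))
        choices.append(c)
        positions[c] += 1
        label = DECK_LABELS[c]
        gain, loss = schedule.card_orders[label][
            (positions[c] - 1) % len(schedule.card_orders[label])
        ]
        nets.append((gain - loss) / outcome_scale)
    return make_subject(subject_id, choices, schedule, group=group, session=session)


def generate_cohort(
    spec: CohortSpec,
    model: str,
    schedule: PayoffSchedule,
) -> tuple[list[SubjectDataset], "pd.DataFrame"]:
    """Simulate a cohort; returns the datasets and the true parameters."""
    import pandas as pd

    _check_means_in_bounds(spec, model)
    info = get_model(model)
    rng = np.random.default_rng(spec.seed)
    truths = _draw_params(spec.params, model, spec.n, rng)
    subjects = []
    for i in range(spec.n):
        sid = f"{spec.group}_{i + 1:03d}"
        seed = int(rng.integers(0, 2**31 - 1))
        subjects.append(
            simulate_agent(
                info.from_array(truths[i]),
                model,
                schedule,
                seed=seed,
                subject_id=sid,
                group=spec.group,
            )
        )
    truth_df = pd.DataFrame(truths, columns=list(info.param_names))
    truth_df.insert(0, "subjID", [s.subject_id for s in subjects])
    truth_df.insert(1, "session", "pre")
    return subjects, truth_df


def generate_treatment_cohort(
    pre_spec: CohortSpec,
    post_shift: dict[str, float] | None = None,
    model: str = "vpp",
    schedule: PayoffSchedule | None = None,
    craving_pre: CravingModel = CravingModel(66.0, 17.6),
    craving_post: CravingModel = CravingModel(34.6, 13.8),
    n_drop_post: int = 0,
) -> tuple[list[SubjectDataset], list[SubjectDataset], "pd.DataFrame"]:
    """Paired pre/post cohort with a treatment shift on the true parameters.

    Post-session true parameters are the pre values plus ``post_shift``
    (defaults to the treated-group mean differences), truncated back to
    the bounds.  Both sessions replay the same payoff schedule.  Returns
    (pre subjects, post subjects, truth table with cravings).
    """
    import pandas as pd

    from .task import SubjectDataset as _SD  # noqa: F401  (doc anchor)

    if schedule is None:
        raise ValueError("a payoff schedule is required")
    if post_shift is None:
        post_shift = dict(DEFAULT_POST_SHIFT)
    _check_means_in_bounds(pre_spec, model)
    info = get_model(model)
    # shifted means must stay inside the bounds
    for name, (lo, hi) in zip(info.param_names, info.bounds):
        shifted = pre_spec.params[name][0] + post_shift.get(name, 0.0)
        if not np.isinf(lo) and not (lo <= shifted <= hi):
            raise ValueError(
                f"post shift pushes mean of {name} to {shifted}, outside [{lo}, {hi}]"
            )

    rng = np.random.default_rng(pre_spec.seed)
    pre_truth = _draw_params(pre_spec.params, model, pre_spec.n, rng)
    shift_vec = np.array([post_shift.get(n, 0.0) for n in info.param_names])
    post_truth = pre_truth + shift_vec
    lo = np.array([b[0] for b in info.bounds])
    hi = np.array([b[1] for b in info.bounds])
    eps = 1e-9
    post_truth = np.clip(post_truth, np.where(np.isinf(lo), -np.inf, lo + eps),
                         np.where(np.isinf(hi), np.inf, hi - eps))

    crav_pre = craving_pre.sample(pre_spec.n, rng)
    crav_post = craving_post.sample(pre_spec.n, rng)

    pre_subjects, post_subjects, rows = [], [], []
    for i in range(pre_spec.n):
        sid = f"{pre_spec.group}_{i + 1:03d}"
        for session, truth, craving, bucket in (
            ("pre", pre_truth[i], crav_pre[i], pre_subjects),
            ("post", post_truth[i], crav_post[i], post_subjects),
        ):
            seed = int(rng.integers(0, 2**31 - 1))
            subj = simulate_agent(
                info.from_array(truth),
                model,
                schedule,
                seed=seed,
                subject_id=sid,
                group=pre_spec.group,
                session=session,
            )
            subj.session = session
            subj.craving = int(craving)
            bucket.append(subj)
            rows.append(
                {"subjID": sid, "session": session, "craving": int(craving),
                 **dict(zip(info.param_names, truth))}
            )
    if n_drop_post:
        drop = set(rng.choice(pre_spec.n, size=n_drop_post, replace=False).tolist())
        post_subjects = [s for i, s in enumerate(post_subjects) if i not in drop]
    return pre_subjects, post_subjects, pd.DataFrame(rows)
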