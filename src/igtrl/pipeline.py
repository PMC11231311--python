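"""End-to-end analysis pipeline.

Stages: obtain trial data (CSV or synthetic cohorts) -> participant QC
-> fit every candidate model -> WAIC/LOOIC comparison and winner
selection -> group statistics on the winner's parameters (control vs
patient contrasts, pre/post treatment contrasts, craving mixed ANOVA,
advantageous-rate repeated-measures ANOVA, and correlations between
parameter changes and craving changes).  Every artifact is written to
the output directory together with a provenance log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as igt_io
from .comparison import compare
from .inference import FitResult, fit_hierarchical, fit_map
from .stats import (
    AnovaResult,
    TTestResult,
    independent_t,
    mixed_anova,
    paired_t,
    pearson_r,
    rm_anova,
)
from .synthetic import (
    CohortSpec,
    CravingModel,
    generate_cohort,
    generate_treatment_cohort,
)
from .task import block_advantage_rates, build_schedule, qc_filter

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = {
    "input", "models", "method", "qc_min_fraction", "seed", "outdir",
    "n_hc", "n_mud_t", "n_mud_n", "n_restarts", "chains", "iterations",
    "warmup", "n_draws", "winner_preference", "outcome_scale",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``input``: trial CSV path, or None to simulate the default
    three-group synthetic study (controls, treated patients pre/post,
    untreated patients).
    """

    input: str | None = None
    models: tuple[str, ...] = ("vpp", "pvl_delta", "pvl_decay")
    method: str = "map"
    qc_min_fraction: float = 0.05
    seed: int = 0
    outdir: str = "igtrl_out"
    n_hc: int = 39
    n_mud_t: int = 24
    n_mud_n: int = 26
    n_restarts: int = 8
    chains: int = 2
    iterations: int = 500
    warmup: int = 250
    n_draws: int = 200
    winner_preference: tuple[str, ...] = ("vpp", "pvl_delta", "pvl_decay")
    outcome_scale: float = 100.0

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model list must not be empty")
        from .models import MODELS

        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")
        if self.method not in ("map", "mcmc"):
            raise ValueError("method must be 'map' or 'mcmc'")
        if not (0 <= self.qc_min_fraction < 1):
            raise ValueError("qc_min_fraction must lie in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "winner_preference"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    config: RunConfig
    qc_reasons: dict[str, str]
    fits: dict[str, FitResult]
    comparison: pd.DataFrame
    winner: str
    stats: dict
    estimates: pd.DataFrame
    outdir: Path


def _ttest_dict(r: TTestResult) -> dict:
    return {
        "t": r.t, "df": r.df, "p": r.p, "cohen_d": r.cohen_d,
        "variant": r.variant, "levene_p": r.levene_p,
    }


def _anova_dicts(rows: list[AnovaResult]) -> list[dict]:
    return [dataclasses.asdict(r) for r in rows]


def _simulate_study(config: RunConfig):
    """The default synthetic study: a control group, a treated patient
    group measured pre and post, and an untreated patient group."""
    rng = np.random.default_rng(config.seed)
    schedule = build_schedule(int(rng.integers(0, 2**31 - 1)))

    hc_spec = CohortSpec.from_table("HC", config.n_hc, seed=int(rng.integers(0, 2**31 - 1)))
    hc, hc_truth = generate_cohort(hc_spec, "vpp", schedule)

    mud_t_spec = CohortSpec.from_table(
        "MUD-t", config.n_mud_t, seed=int(rng.integers(0, 2**31 - 1)),
        table_key="MUD_t_pre",
    )
    mud_t_pre, mud_t_post, mud_t_truth = generate_treatment_cohort(
        mud_t_spec, model="vpp", schedule=schedule
    )

    mud_n_spec = CohortSpec.from_table(
        "MUD-n", config.n_mud_n, seed=int(rng.integers(0, 2**31 - 1)),
        table_key="MUD",
    )
    mud_n, mud_n_truth = generate_cohort(mud_n_spec, "vpp", schedule)
    crav = CravingModel(67.31, 17.79)
    crav_pre = crav.sample(config.n_mud_n, rng)
    crav_post = crav.sample(config.n_mud_n, rng)
    for s, c in zip(mud_n, crav_pre):
        s.craving = int(c)
    mud_n_post_craving = {s.subject_id: int(c) for s, c in zip(mud_n, crav_post)}

    subjects = hc + mud_t_pre + mud_n + mud_t_post
    truth = pd.concat([hc_truth, mud_t_truth, mud_n_truth], ignore_index=True)
    return subjects, truth, schedule, mud_n_post_craving


def craving_correlation_analysis(
    params_delta: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Correlate per-subject parameter changes (and covariates) with the
    craving change.  ``params_delta`` and ``clinical`` are matched on
    ``subjID``; ``clinical`` must carry a ``craving_delta`` column."""
    merged = params_delta.merge(clinical, on="subjID", how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched subjects")
    y = merged["craving_delta"].to_numpy(dtype=float)
    rows = []
    for col in merged.columns:
        if col in ("subjID", "craving_delta"):
            continue
        x = merged[col].to_numpy(dtype=float)
        try:
            r, df, p = pearson_r(x, y)
        except ValueError:
            continue
        rows.append({"variable": col, "r": r, "df": df, "p": p})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis; artifacts land in ``config.outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        mud_n_post_craving: dict[str, int] = {}
        if config.input:
            subjects = igt_io.read_trials(config.input)
            schedule = None
            truth = None
        else:
            subjects, truth, schedule, mud_n_post_craving = _simulate_study(config)
            igt_io.write_trials(subjects, outdir / "trials.csv")
            truth.to_csv(outdir / "true_parameters.csv", index=False)
            igt_io.write_schedule(schedule, outdir / "schedule.json")

        stage = "qc"
        pre = [s for s in subjects if s.session == "pre"]
        post = [s for s in subjects if s.session == "post"]
        kept_pre, excluded, reasons = qc_filter(pre, config.qc_min_fraction)
        kept_pre_ids = {s.subject_id for s in kept_pre}
        kept_post = [s for s in post if s.subject_id in kept_pre_ids]
        if kept_post:
            kept_post, post_excl, post_reasons = qc_filter(
                kept_post, config.qc_min_fraction
            )
            reasons.update(post_reasons)

        stage = "fit"
        fits: dict[str, FitResult] = {}
        for model in config.models:
            if config.method == "map":
                fits[model] = fit_map(
                    kept_pre, model, n_restarts=config.n_restarts,
                    seed=config.seed, outcome_scale=config.outcome_scale,
                )
            else:
                fits[model] = fit_hierarchical(
                    kept_pre, model, chains=config.chains,
                    iterations=config.iterations, warmup=config.warmup,
                    seed=config.seed, outcome_scale=config.outcome_scale,
                )

        stage = "compare"
        table = compare(fits, n_draws=config.n_draws, seed=config.seed)
        best = table.iloc[0]
        winner = str(best["model"])
        if len(table) > 1:
            runner = table.iloc[1]
            if abs(best["looic"] - runner["looic"]) <= best["looic_se"]:
                pref = [m for m in config.winner_preference
                        if m in (best["model"], runner["model"])]
                if pref:
                    winner = pref[0]
                logger.info(
                    "LOOIC within 1 SE of runner-up; preference order chose %s",
                    winner,
                )

        stage = "stats"
        from .models import get_model

        info = get_model(winner)
        params = list(info.param_names)
        est = fits[winner].estimates

        stats_report: dict = {"winner": winner}
        hc_est = est[est["group"] == "HC"]
        mud_est = est[est["group"].str.startswith("MUD")]
        group_tests = {}
        if len(hc_est) >= 2 and len(mud_est) >= 2:
            for p_ in params:
                group_tests[p_] = _ttest_dict(
                    independent_t(hc_est[p_].to_numpy(), mud_est[p_].to_numpy())
                )
        stats_report["hc_vs_mud"] = group_tests

        # pre/post contrasts on the treated group need a post-session fit
        paired_tests = {}
        post_est = None
        if kept_post:
            post_fit = (
                fit_map(kept_post, winner, n_restarts=config.n_restarts,
                        seed=config.seed, outcome_scale=config.outcome_scale)
                if config.method == "map"
                else fit_hierarchical(
                    kept_post, winner, chains=config.chains,
                    iterations=config.iterations, warmup=config.warmup,
                    seed=config.seed, outcome_scale=config.outcome_scale)
            )
            post_est = post_fit.estimates
            merged = est.merge(post_est, on="subjID", suffixes=("_pre", "_post"))
            if len(merged) >= 2:
                for p_ in params:
                    try:
                        paired_tests[p_] = _ttest_dict(
                            paired_t(merged[f"{p_}_pre"], merged[f"{p_}_post"])
                        )
                    except ValueError as e:
                        paired_tests[p_] = {"error": str(e)}
        stats_report["pre_vs_post"] = paired_tests

        # craving mixed ANOVA: treated vs untreated patients, pre vs post
        craving_rows = []
        post_craving = {s.subject_id: s.craving for s in kept_post}
        post_craving.update(mud_n_post_craving)
        for s in kept_pre:
            if not s.group.startswith("MUD") or s.craving is None:
                continue
            pc = post_craving.get(s.subject_id)
            if pc is None:
                continue
            craving_rows.append(
                {"subject": s.subject_id, "group": s.group, "time": "pre",
                 "value": s.craving}
            )
            craving_rows.append(
                {"subject": s.subject_id, "group": s.group, "time": "post",
                 "value": pc}
            )
        if craving_rows:
            cr = pd.DataFrame(craving_rows)
            if cr["group"].nunique() == 2:
                stats_report["craving_mixed_anova"] = _anova_dicts(
                    mixed_anova(cr)
                )

        # advantageous-rate RM ANOVA: treated group, time x block
        adv_rows = []
        post_ids = {s.subject_id for s in kept_post}
        for s in kept_pre + kept_post:
            if s.subject_id not in post_ids:
                continue
            rates = block_advantage_rates(s)
            for b, r_ in enumerate(rates, start=1):
                adv_rows.append(
                    {"subject": s.subject_id, "time": s.session,
                     "block": b, "value": r_}
                )
        if adv_rows:
            adv = pd.DataFrame(adv_rows)
            complete = adv.groupby("subject").size() == 2 * adv["block"].nunique()
            adv = adv[adv["subject"].map(complete)]
            if adv["subject"].nunique() >= 2:
                stats_report["advantage_rm_anova"] = _anova_dicts(rm_anova(adv))

        # correlations: parameter deltas and covariates vs craving delta
        if paired_tests and post_est is not None:
            merged = est.merge(post_est, on="subjID", suffixes=("_pre", "_post"))
            delta = pd.DataFrame({"subjID": merged["subjID"]})
            for p_ in params:
                delta[f"delta_{p_}"] = merged[f"{p_}_pre"] - merged[f"{p_}_post"]
            clin_rows = []
            for s in kept_pre:
                pc = post_craving.get(s.subject_id)
                if pc is None or s.craving is None:
                    continue
                clin_rows.append(
                    {"subjID": s.subject_id,
                     "craving_delta": s.craving - pc,
                     "pre_craving": s.craving,
                     **s.covariates}
                )
            if clin_rows:
                clinical = pd.DataFrame(clin_rows)
                try:
                    corr = craving_correlation_analysis(delta, clinical)
                    stats_report["craving_correlations"] = corr.to_dict("records")
                except ValueError as e:
                    stats_report["craving_correlations"] = {"error": str(e)}

        stage = "write"
        est_out = est.copy()
        if post_est is not None:
            est_out = pd.concat([est_out, post_est], ignore_index=True)
        est_out.to_csv(outdir / "parameter_estimates.csv", index=False)
        table.to_csv(outdir / "model_comparison.csv", index=False)
        (outdir / "stats_report.json").write_text(
            json.dumps(stats_report, indent=1, default=float)
        )
        provenance = {
            "config": dataclasses.asdict(config),
            "config_hash": config.digest(),
            "seed": config.seed,
            "qc_excluded": reasons,
            "winner": winner,
            "elapsed_s": round(time.time() - t0, 2),
            "versions": _versions(),
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=1, default=str)
        )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    return ReportBundle(
        config=config,
        qc_reasons=reasons,
        fits=fits,
        comparison=table,
        winner=winner,
        stats=stats_report,
        estimates=est_out,
        outdir=outdir,
    )


def _versions() -> dict[str, str]:
    import arviz
    import emcee
    import numba
    import pingouin
    import scipy

    import igtrl

    return {
        "igtrl": getattr(igtrl, "__version__", "0"),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "numba": numba.__version__,
        "emcee": emcee.__version__,
        "arviz": arviz.__version__,
        "pingouin": pingouin.__version__,
    }
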