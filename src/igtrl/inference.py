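"""Parameter estimation for the IGT choice models.

Two fitting routes share one parameterization:

* bounded parameters (all lower-bounded at 0) live on an unbounded
  probit scale, ``natural = upper * Phi(z)``;
* the unbounded perseverance impacts use an identity link.

``fit_map`` maximizes log-likelihood + log-prior per subject with
multi-restart quasi-Newton optimization and returns a Laplace
(normal) approximation around each optimum, from which posterior-style
parameter draws and pointwise log-likelihood draws can be generated
cheaply.  ``fit_hierarchical`` samples a full hierarchical posterior
(group location/scale plus subject-level parameters) with an affine-
invariant ensemble sampler, reporting R-hat and effective sample size;
runs with any R-hat above 1.1 carry a non-convergence warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from . import _kernels
from .models import OUTCOME_SCALE, ModelInfo, get_model
from .task import PayoffSchedule, SubjectDataset, block_advantage_rates
from .synthetic import simulate_agent

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class PriorSpec:
    """Priors on the transformed scale.

    ``z_loc``/``z_scale``: normal prior on every transformed coordinate
    (bounded parameters via probit, perseverance impacts via identity).
    ``group_scale``: half-normal scale on the hierarchical group SDs.
    """

    z_loc: float = 0.0
    z_scale: float = 1.0
    group_scale: float = 0.2


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _upper_bounds(info: ModelInfo) -> np.ndarray:
    """Upper bound per parameter; NaN marks identity-link parameters."""
    ubs = []
    for (lo, hi) in info.bounds:
        if np.isinf(hi):
            ubs.append(np.nan)
        else:
            if lo != 0.0:
                raise ValueError("bounded parameters must have lower bound 0")
            ubs.append(hi)
    return np.array(ubs)


def to_natural(z: np.ndarray, info: ModelInfo) -> np.ndarray:
    """Transformed -> natural scale (probit for bounded parameters)."""
    z = np.asarray(z, dtype=float)
    ub = _upper_bounds(info)
    nat = np.where(np.isnan(ub), z, np.nan_to_num(ub) * ndtr(z))
    return nat


def to_transformed(nat: np.ndarray, info: ModelInfo) -> np.ndarray:
    """Natural -> transformed scale (inverse probit, clipped away from
    the boundary for numerical safety)."""
    nat = np.asarray(nat, dtype=float)
    ub = _upper_bounds(info)
    out = np.array(nat, dtype=float)
    for j, u in enumerate(ub):
        if not np.isnan(u):
            frac = np.clip(nat[..., j] / u, 1e-12, 1 - 1e-12)
            out[..., j] = ndtri(frac)
    return out


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, pointwise log-likelihoods and diagnostics for one fit."""

    method: str
    model: str
    subject_ids: list[str]
    sessions: list[str]
    estimates: pd.DataFrame
    pointwise: np.ndarray            # (S, T) at the point estimates
    choices: np.ndarray              # (S, T) data the fit was run on
    nets: np.ndarray                 # (S, T) raw RMB nets
    prior: PriorSpec
    seed: int
    outcome_scale: float = OUTCOME_SCALE
    z_map: np.ndarray | None = None        # (S, P)
    z_cov: np.ndarray | None = None        # (S, P, P) Laplace covariance
    draws_z: np.ndarray | None = None      # (D, S, P) posterior draws (mcmc)
    group_summary: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def param_names(self) -> list[str]:
        return list(get_model(self.model).param_names)

    def parameter_draws(
        self,
        n_draws: int = 200,
        seed: int = 0,
        sampler: str = "mcmc",
        burn: int = 300,
        keep_steps: int = 150,
    ) -> np.ndarray:
        """Posterior draws of the transformed parameters, (draws, S, P).

        Hierarchical fits return stored draws.  For MAP fits the
        default is a short per-subject ensemble MCMC started at the
        MAP (the model's flat directions make a plain Laplace normal a
        poor posterior approximation); ``sampler='laplace'`` gives the
        cheaper normal approximation instead.
        """
        info = get_model(self.model)
        S, T = self.choices.shape
        P = info.n_params
        if self.draws_z is not None:
            z = self.draws_z
            idx = np.linspace(0, z.shape[0] - 1, min(n_draws, z.shape[0])).astype(int)
            return z[idx]
        rng = np.random.default_rng(seed)
        if sampler == "laplace":
            z = np.empty((n_draws, S, P))
            for s in range(S):
                z[:, s, :] = rng.multivariate_normal(
                    self.z_map[s], self.z_cov[s], size=n_draws
                )
            return z
        if sampler != "mcmc":
            raise ValueError("sampler must be 'mcmc' or 'laplace'")
        import emcee

        from .models import loglik_pointwise_batch

        z = np.empty((n_draws, S, P))
        nwalkers = max(2 * P + 2, 4 * P)
        if nwalkers % 2:
            nwalkers += 1
        prior = self.prior
        for s in range(S):
            ch = np.ascontiguousarray(self.choices[s])
            ne = self.nets[s] / self.outcome_scale

            def logp(zbatch):
                zb = np.atleast_2d(zbatch)
                nat = to_natural(zb, info)
                ll = loglik_pointwise_batch(
                    np.broadcast_to(ch, (zb.shape[0], T)),
                    np.broadcast_to(ne, (zb.shape[0], T)),
                    nat,
                    self.model,
                    outcome_scale=1.0,
                ).sum(axis=1)
                return ll - 0.5 * np.sum(
                    ((zb - prior.z_loc) / prior.z_scale) ** 2, axis=1
                )

            p0 = self.z_map[s] + 0.1 * rng.standard_normal((nwalkers, P))
            sam = emcee.EnsembleSampler(nwalkers, P, logp, vectorize=True)
            sam.random_state = np.random.RandomState(
                int(rng.integers(0, 2**31 - 1))
            ).get_state()
            sam.run_mcmc(p0, burn + keep_steps, progress=False)
            flat = sam.get_chain(discard=burn).reshape(-1, P)
            idx = np.linspace(0, flat.shape[0] - 1, n_draws).astype(int)
            z[:, s, :] = flat[idx]
        return z

    def pointwise_draws(
        self, n_draws: int = 200, seed: int = 0, sampler: str = "mcmc"
    ) -> np.ndarray:
        """Pointwise log-likelihood draws, shape (draws, subjects, trials).

        Hierarchical fits evaluate stored posterior draws; MAP fits use
        per-subject posterior sampling (see :meth:`parameter_draws`).
        """
        info = get_model(self.model)
        S, T = self.choices.shape
        z = self.parameter_draws(n_draws=n_draws, seed=seed, sampler=sampler)
        D = z.shape[0]
        nat = to_natural(z.reshape(D * S, info.n_params), info)
        choices = np.broadcast_to(self.choices, (D, S, T)).reshape(D * S, T)
        nets = np.broadcast_to(self.nets, (D, S, T)).reshape(D * S, T)
        from .models import loglik_pointwise_batch

        ll = loglik_pointwise_batch(
            choices, nets, nat, self.model, outcome_scale=self.outcome_scale
        )
        return ll.reshape(D, S, T)


def _stack_cohort(cohort: Sequence[SubjectDataset]) -> tuple[np.ndarray, np.ndarray]:
    T = cohort[0].n_trials
    if any(s.n_trials != T for s in cohort):
        raise ValueError("all subjects must share the same trial count")
    choices = np.stack([s.choices() for s in cohort])
    nets = np.stack([s.nets() for s in cohort])
    return choices, nets


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------

def _pointwise_single(info: ModelInfo, choices, nets_scaled, nat) -> np.ndarray:
    """Per-trial log-likelihood at one natural-scale parameter vector."""
    if info.loglik_fn is not None:
        return np.asarray(info.loglik_fn(choices, nets_scaled, np.asarray(nat)))
    vec = np.zeros(8)
    vec[7] = 1.0
    slots = {"A": 0, "alpha": 1, "cons": 2, "lam": 3, "epP": 4, "epN": 5, "K": 6, "w": 7}
    for j, name in enumerate(info.param_names):
        vec[slots[name]] = nat[j]
    return _kernels.loglik_trials(choices, nets_scaled, vec, info.kernel_id)


def _neg_log_post(z, choices, nets, info, prior):
    nat = to_natural(z, info)
    ll = _pointwise_single(info, choices, nets, nat).sum()
    lp = -0.5 * np.sum(((z - prior.z_loc) / prior.z_scale) ** 2)
    return -(ll + lp)


def _numerical_hessian(f, x, h=1e-4):
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def _laplace_cov(f, z_opt):
    H = _numerical_hessian(f, z_opt)
    n = z_opt.size
    ridge = 0.0
    for _ in range(12):
        try:
            cov = np.linalg.inv(H + ridge * np.eye(n))
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-6)
    return np.eye(n)  # flat/ill-conditioned posterior: fall back to unit cov


def fit_map(
    cohort: Sequence[SubjectDataset],
    model: str,
    prior: PriorSpec | None = None,
    n_restarts: int = 8,
    seed: int = 0,
    outcome_scale: float = OUTCOME_SCALE,
) -> FitResult:
    """Per-subject MAP estimation with multi-restart L-BFGS.

    Restart initial points are prior draws on the transformed scale;
    ties break by objective value then restart index, so the result is
    deterministic for a given seed.  Subjects for whom every restart
    fails are flagged in ``diagnostics['failed_subjects']`` rather than
    silently dropped.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    prior = prior or PriorSpec()
    info = get_model(model)
    choices, nets = _stack_cohort(cohort)
    nets_scaled = nets / outcome_scale
    rng = np.random.default_rng(seed)
    S, T = choices.shape
    P = info.n_params

    z_map = np.empty((S, P))
    z_cov = np.empty((S, P, P))
    pointwise = np.empty((S, T))
    failed: list[str] = []
    est_rows = []
    for s in range(S):
        f = lambda z: _neg_log_post(z, choices[s], nets_scaled[s], info, prior)
        best = None
        inits = prior.z_loc + prior.z_scale * rng.standard_normal((n_restarts, P))
        for z0 in inits:
            try:
                res = optimize.minimize(f, z0, method="L-BFGS-B")
            except Exception:  # pragma: no cover - optimizer blow-up
                continue
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None:
            failed.append(cohort[s].subject_id)
            z_map[s] = prior.z_loc
            z_cov[s] = np.eye(P)
        else:
            z_map[s] = best.x
            z_cov[s] = _laplace_cov(f, best.x)
        nat = to_natural(z_map[s], info)
        pointwise[s] = _pointwise_single(info, choices[s], nets_scaled[s], nat)
        est_rows.append(
            {"subjID": cohort[s].subject_id, "session": cohort[s].session,
             "group": cohort[s].group, **dict(zip(info.param_names, nat))}
        )

    estimates = pd.DataFrame(est_rows)
    diagnostics = {"failed_subjects": failed, "n_restarts": n_restarts}
    if failed:
        logger.warning("MAP optimisation failed for subjects: %s", failed)
    return FitResult(
        method="map",
        model=model,
        subject_ids=[s.subject_id for s in cohort],
        sessions=[s.session for s in cohort],
        estimates=estimates,
        pointwise=pointwise,
        choices=choices,
        nets=nets,
        prior=prior,
        seed=seed,
        outcome_scale=outcome_scale,
        z_map=z_map,
        z_cov=z_cov,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# hierarchical MCMC
# ---------------------------------------------------------------------------

def _hier_log_prob_batch(theta, choices_tiled, nets_tiled, info, prior, S, T):
    """Vectorized log posterior for a batch of walker positions.

    theta: (W, 2P + S*P) laid out [mu, log_sigma, z_1..z_S].
    """
    from .models import loglik_pointwise_batch

    theta = np.atleast_2d(theta)
    W = theta.shape[0]
    P = info.n_params
    mu = theta[:, :P]
    log_sigma = theta[:, P:2 * P]
    z = theta[:, 2 * P:].reshape(W, S, P)
    sigma = np.exp(log_sigma)

    lp = -0.5 * np.sum(mu**2, axis=1)
    # half-normal on sigma plus log-Jacobian of the log transform
    lp += np.sum(-0.5 * (sigma / prior.group_scale) ** 2 + log_sigma, axis=1)
    lp += np.sum(
        -0.5 * ((z - mu[:, None, :]) / sigma[:, None, :]) ** 2
        - np.log(sigma)[:, None, :],
        axis=(1, 2),
    )

    nat = to_natural(z.reshape(W * S, P), info)
    ll = loglik_pointwise_batch(
        np.broadcast_to(choices_tiled, (W, S, T)).reshape(W * S, T),
        np.broadcast_to(nets_tiled, (W, S, T)).reshape(W * S, T),
        nat,
        info.name,
        outcome_scale=1.0,  # nets are pre-scaled by the caller
    )
    lp += ll.reshape(W, S, T).sum(axis=(1, 2))
    return lp


def _rhat_ess(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split-R-hat and bulk ESS per scalar dimension.

    samples: (chains, draws, dim) with walkers treated as chains.
    """
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(samples)
        rhat = az.rhat(ds)["x"].values
        ess = az.ess(ds)["x"].values
    return np.atleast_1d(rhat), np.atleast_1d(ess)


def fit_hierarchical(
    cohort: Sequence[SubjectDataset],
    model: str,
    prior: PriorSpec | None = None,
    chains: int = 2,
    iterations: int = 500,
    warmup: int = 250,
    seed: int = 0,
    n_keep_draws: int = 200,
    outcome_scale: float = OUTCOME_SCALE,
) -> FitResult:
    """Hierarchical Bayesian fit with an ensemble MCMC sampler.

    Group-level location (normal) and scale (half-normal) govern the
    subject-level transformed parameters.  ``chains`` independent
    ensembles are run for ``iterations`` steps each, the first
    ``warmup`` discarded.  Walkers within each ensemble are treated as
    chains for R-hat/ESS; any scalar R-hat above 1.1 marks the fit
    non-converged (with a warning, not an error).
    """
    import emcee

    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if iterations <= warmup:
        raise ValueError("iterations must exceed warmup")
    prior = prior or PriorSpec()
    info = get_model(model)
    choices, nets = _stack_cohort(cohort)
    nets_scaled = nets / outcome_scale
    S, T = choices.shape
    P = info.n_params
    ndim = 2 * P + S * P
    nwalkers = max(2 * ndim, 2 * P + 2)
    if nwalkers % 2:
        nwalkers += 1

    rng = np.random.default_rng(seed)
    all_chains = []
    for c in range(chains):
        p0 = 0.1 * rng.standard_normal((nwalkers, ndim))
        p0[:, P:2 * P] = np.log(0.2) + 0.1 * rng.standard_normal((nwalkers, P))
        sampler = emcee.EnsembleSampler(
            nwalkers,
            ndim,
            _hier_log_prob_batch,
            args=(choices, nets_scaled, info, prior, S, T),
            vectorize=True,
        )
        sampler.random_state = np.random.RandomState(
            int(rng.integers(0, 2**31 - 1))
        ).get_state()
        sampler.run_mcmc(p0, iterations, progress=False)
        all_chains.append(sampler.get_chain(discard=warmup))  # (draws, W, D)

    # (chains*walkers, draws, dim) with walkers treated as chains
    stacked = np.concatenate(
        [np.moveaxis(ch, 0, 1) for ch in all_chains], axis=0
    )
    rhat, ess = _rhat_ess(stacked)
    converged = bool(np.nanmax(rhat) <= RHAT_THRESHOLD)
    if not converged:
        warnings.warn(
            f"hierarchical fit of {model}: max R-hat "
            f"{np.nanmax(rhat):.3f} > {RHAT_THRESHOLD}; treat results with caution",
            RuntimeWarning,
        )

    flat = stacked.reshape(-1, ndim)
    idx = np.linspace(0, flat.shape[0] - 1, min(n_keep_draws, flat.shape[0])).astype(int)
    kept = flat[idx]
    draws_z = kept[:, 2 * P:].reshape(-1, S, P)

    # posterior-mean subject estimates on the natural scale
    nat_draws = to_natural(draws_z.reshape(-1, P), info).reshape(-1, S, P)
    est = nat_draws.mean(axis=0)
    est_rows = [
        {"subjID": cohort[s].subject_id, "session": cohort[s].session,
         "group": cohort[s].group, **dict(zip(info.param_names, est[s]))}
        for s in range(S)
    ]

    # group-level summaries: both the transformed group location mapped to
    # the natural scale and the mean of subject-level posterior means
    mu_draws = kept[:, :P]
    mu_nat = to_natural(mu_draws, info)
    group_summary = pd.DataFrame(
        {
            "parameter": list(info.param_names),
            "group_location_natural": mu_nat.mean(axis=0),
            "mean_of_subject_means": est.mean(axis=0),
            "group_sd_transformed": np.exp(kept[:, P:2 * P]).mean(axis=0),
        }
    )

    # pointwise at posterior-mean estimates
    pointwise = np.empty((S, T))
    for s in range(S):
        pointwise[s] = _pointwise_single(info, choices[s], nets_scaled[s], est[s])

    diagnostics = {
        "rhat_max": float(np.nanmax(rhat)),
        "ess_min": float(np.nanmin(ess)),
        "converged": converged,
        "acceptance_fraction_mean": float(
            np.mean(sampler.acceptance_fraction)
        ),
        "chains": chains,
        "iterations": iterations,
        "warmup": warmup,
        "nwalkers": nwalkers,
    }
    return FitResult(
        method="mcmc",
        model=model,
        subject_ids=[s.subject_id for s in cohort],
        sessions=[s.session for s in cohort],
        estimates=pd.DataFrame(est_rows),
        pointwise=pointwise,
        choices=choices,
        nets=nets,
        prior=prior,
        seed=seed,
        outcome_scale=outcome_scale,
        draws_z=draws_z,
        group_summary=group_summary,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# posterior prediction
# ---------------------------------------------------------------------------

def posterior_predict(
    fit: FitResult,
    schedule: PayoffSchedule,
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed-vs-predicted block summaries from the fitted parameters.

    Each subject is re-simulated ``n_reps`` times from their estimated
    parameters; returns one row per subject and block with the observed
    advantageous-choice rate and the predictive mean/sd.
    """
    info = get_model(fit.model)
    rng = np.random.default_rng(seed)
    rows = []
    if n_reps == 0:
        return pd.DataFrame(
            columns=["subjID", "block", "observed", "predicted_mean", "predicted_sd"]
        )
    block_size = schedule.block_size
    for s, sid in enumerate(fit.subject_ids):
        est = fit.estimates.iloc[s][list(info.param_names)].to_numpy(dtype=float)
        params = info.from_array(est)
        obs_adv = (
            np.isin(fit.choices[s], [2, 3])
            .reshape(-1, block_size)
            .mean(axis=1)
        )
        sims = []
        for _ in range(n_reps):
            subj = simulate_agent(
                params,
                fit.model,
                schedule,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_trials=fit.choices.shape[1],
                outcome_scale=fit.outcome_scale,
            )
            sims.append(block_advantage_rates(subj, block_size))
        sims = np.array(sims)
        for b in range(obs_adv.size):
            rows.append(
                {
                    "subjID": sid,
                    "block": b + 1,
                    "observed": obs_adv[b],
                    "predicted_mean": sims[:, b].mean(),
                    "predicted_sd": sims[:, b].std(ddof=1) if n_reps > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
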