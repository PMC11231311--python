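# Methods

## The task environment

The Iowa Gambling Task as implemented here is a 100-selection, four-deck
card task played from a 2000 RMB bankroll, with 5 blocks of 20 trials.
Every draw pays a constant gain — 100 RMB for decks A and B, 50 RMB for
C and D — and, with deck-specific probability, also a loss:

| deck | gain | losses (magnitude, probability) | cycle | net/draw |
|------|------|--------------------------------|-------|----------|
| A | 100 | 150, 200, 250, 300, 350 each 10% | 10 | −25 |
| B | 100 | 1250 at 10% | 10 | −25 |
| C | 50 | 25 at 12.5%, 50 at 25%, 75 at 12.5% | 8 | +25 |
| D | 50 | 250 at 10% | 10 | +25 |

Loss frequencies are realized *exactly* within each deck cycle: a cycle
contains precisely the loss multiset implied by the probabilities, and a
seeded RNG shuffles positions within each cycle.  This reproduces the
"predetermined card order" style of administration while keeping the
schedule reproducible from a single integer seed.  The published card
order itself is not available, so any seed defines an equally valid
administration; all long-run expectations are seed-invariant by
construction.  Draws past the stored order wrap by whole cycles, so
wrapping preserves the frequencies.  The bankroll may go negative; no
stopping rule is applied.

Participant-level quality control excludes a subject iff any deck was
chosen `floor(0.05 × n_trials)` times or fewer (the "five times or less"
rule on 100 trials).  The filter is idempotent on its kept partition.

## Choice models

All models share a prospect-valence utility of the trial's net outcome
x (gain − loss, divided by 100 before the utility so magnitudes stay in
a numerically comfortable range; the divisor is configurable):

    u(x) = x^alpha            if x ≥ 0
    u(x) = −lambda · |x|^alpha  if x < 0

with outcome sensitivity alpha ∈ (0,2) and loss aversion
lambda ∈ [0,5], and a softmax over deck values V_j with sensitivity
theta = 3^cons − 1, cons ∈ [0,5] (cons = 0 is uniform random choice).
A gain/loss-weighted linear utility (`utility_ev`) is provided as an
option but no model here uses it by default.

* **PVL-Delta** — the chosen deck's expectancy moves toward the
  utility: E_c ← E_c + A·(u − E_c), learning rate A ∈ [0,1]; unchosen
  decks are unchanged; V = E.
* **PVL-DecayRI** — every expectancy decays, E ← A·E, and the chosen
  deck adds u; here A is a recency/decay parameter.
* **VPP** — PVL-Delta expectancies plus a perseverance strength per
  deck: every P decays by K ∈ [0,1] each trial and the chosen deck
  receives ε_p after a non-negative net outcome or ε_n after a loss
  (break-even counts as a gain).  Deck value mixes the two systems:
  V = w·E + (1−w)·P with RL weight w ∈ [0,1].

All latent state starts at zero, so the first trial is uniform.  The
likelihood of a sequence scores each observed choice *before* updating
the state with that trial's outcome.  The trial loop is compiled with
numba; tests pin it against an independently written plain-python
scalar loop at 1e−10.  A registry keyed by model name exposes parameter
names, bounds and the kernel, so further models (e.g. ORL) can be
plugged in without touching the fitting code.

### Identifiability

The VPP softmax sees only θ·w·E and θ·(1−w)·P, and P is linear in
(ε_p, ε_n).  Hence only the products θw, θ(1−w)ε_p and θ(1−w)ε_n enter
the likelihood: (cons, w, ε_p, ε_n) lie on an exact ridge that only the
parameter bounds and the prior break.  We verified this numerically —
the profile likelihood over cons is flat to <0.5 log-units across
cons ∈ [0.8, 2.0] even at 4000 trials.  Separately, with 100 trials the
per-subject estimation noise for A and alpha (SD ≈ 0.2 measured on a
zero-variance cohort) is large compared with clinically reported
between-subject spreads of ~0.07.  Individual-difference correlations
for those parameters at 100 trials are therefore capped well below what
longer sessions or strong hierarchical pooling would give, and group
contrasts on weakly identified parameters (alpha, lambda, w) have low
power at desk scale.  The group-contrast and recovery experiments in
the test suite report exactly what is attainable under these
conditions; learning rate and consistency carry most of the recoverable
group signal.

## Synthetic cohorts

The generator plays model agents against a payoff schedule.  Per-subject
true parameters are drawn from normal distributions truncated at the
parameter bounds (plain normals for the unbounded ε_p, ε_n), with
means/SDs defaulting to the published group summaries shipped in
`igtrl/data/cohorts.yaml`: healthy controls (n=39 scale), patients
(n=50), and the treated subgroup pre/post (n=24).  Treatment is an
additive shift on each subject's true parameters (defaults are the
pre→post mean differences: learning rate −0.14, outcome sensitivity
−0.38, consistency +0.13, loss aversion +0.38, K +0.13, w −0.11),
truncated back to bounds; both sessions replay the same schedule.
Craving scores are integers on 1–100, clipped, with treated-group means
66.0 (SD 17.6) pre and 34.6 (13.8) post and no mean change in the
untreated group; an optional mode rounds to multiples of ten to mimic
self-report clustering.  Between-parameter correlations are not modelled
(unreported in the source summaries); parameters are drawn
independently.  What passing tests on these cohorts show is therefore
that the pipeline recovers what the generative process puts in — not
that real patient data carry the same structure.

## Fitting

Both routes share one parameterization: bounded parameters (all
lower-bounded at zero) live on a probit scale, natural = upper·Φ(z);
ε_p, ε_n use an identity link.  The default prior is standard normal on
every transformed coordinate (which makes the implied natural prior
uniform for the probit-linked parameters).

* `fit_map` maximizes log-likelihood + log-prior per subject with
  8 restarts of L-BFGS from prior draws (ties: best objective, then
  lowest restart index — deterministic given the seed).  Failed
  subjects are flagged, never dropped silently.  A Laplace covariance
  is computed at each optimum from a central-difference Hessian (with a
  ridge escalation if not positive definite).
* Posterior draws for MAP fits come from a short per-subject ensemble
  MCMC (emcee) started at the MAP (default 300 burn-in + 150 kept
  steps, 32 walkers for 8 parameters).  The ridge directions make a
  Laplace normal a poor posterior stand-in — it inflated the WAIC
  effective-parameter count by orders of magnitude — while per-subject
  MCMC in 4–8 dimensions is cheap and well mixed.  Laplace draws remain
  available via `sampler="laplace"`.
* `fit_hierarchical` samples group location (normal(0,1) prior) and
  scale (half-normal, default scale 0.2) over subject-level transformed
  parameters with an affine-invariant ensemble sampler, `chains`
  independent ensembles × `iterations` steps (defaults 2 × 500, warmup
  250 — scaled-down settings; production runs should use more).
  Walkers are treated as chains for split-R-hat and ESS; any R-hat
  above 1.1 marks the fit non-converged with a warning.  Joint
  dimension grows as subjects × parameters, and ensemble samplers mix
  poorly beyond ~100 dimensions, so for realistic cohort sizes the MAP
  route is the workhorse and the hierarchical sampler serves small
  cohorts and methodological checks.
* `posterior_predict` re-simulates each subject from the fitted
  parameters and reports observed vs predicted block-wise
  advantageous-choice rates.

## Model comparison

WAIC and PSIS-LOO are computed from (draws × observations) pointwise
log-likelihood matrices; observations are trials by default (subject
aggregation optional).  WAIC follows the standard formulas
(lppd − p_waic, deviance scale, SE from observation-wise components);
LOO uses Pareto-smoothed importance sampling (smoothing via arviz's
`psislw`), flagging observations with k > 0.7.  Both are cross-checked
against arviz's full implementations in the tests.  Ranking is LOOIC
first, WAIC as tie-break; the pipeline also applies a preference order
when the top two models sit within one SE.

## Statistics layer

Independent comparisons run Levene's test (mean-centred; median option)
and switch to Welch's t with Satterthwaite df when it rejects at 0.05,
else pooled Student's t.  Cohen's d uses the pooled SD for independent
contrasts and the SD of differences for paired ones.  Summary-statistic
variants reproduce printed demographic rows exactly.  The 2×2 mixed
ANOVA and the two-way within-subjects ANOVA go through pingouin with
partial η² recovered from F and the dfs where pingouin reports a
different effect size; degenerate zero-SS effects are normalized to
F = 0, p = 1.  All tests are two-sided at α = 0.05; no multiple-testing
correction is applied; paired analyses are complete-case.

## Pipeline

`run_pipeline` chains simulate/ingest → QC → fit per model → LOOIC/WAIC
comparison → winner selection → group statistics (control vs patient
t-tests per parameter, treated-group paired pre/post tests, craving
mixed ANOVA, advantageous-rate repeated-measures ANOVA, correlations of
parameter changes with craving change), writing CSV/JSON artifacts and
a provenance log (config hash, seeds, package versions) sufficient to
regenerate every table.  Pre and post sessions are fitted
independently.  Configuration is validated up front; unknown keys are
rejected; any stage failure aborts with a stage-named error.

## Numerical choices and problem sizes

Softmax uses max-subtraction; x = 0 takes the gain branch of the
utility; probit transforms clip at 1e−12 from the boundary.  The
default experiment sizes in the acceptance suite — 30-subject recovery
cohorts, 10 replicates of the 39+50 group contrast, 20 replicates of
8-subject model-recovery runs, 2×500-iteration hierarchical chains —
are the package's scaled-down defaults chosen to keep a full run on one
CPU in the tens of minutes; all are plain function arguments.

## Known limitations

* The VPP consistency/perseverance block is structurally non-identified
  (see above); reported cons, w, ε values are prior-dependent.
* The hierarchical sampler is not a substitute for gradient-based HMC
  on large cohorts; its scaled-down defaults do not converge and say so.
* The synthetic generator treats parameters as independent across
  subjects and sessions apart from the fixed treatment shift.
* The ORL model is accommodated by the registry interface but not
  implemented (its update equations are not part of this package's
  sources).
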