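# Methods

## Generative model

Decisions are simulated as a discrete-time random walk approximating the
drift-diffusion model. Evidence starts at `z·a` (z = 0 throughout: unbiased
start), and at each step of `τ` seconds changes by

    Δ = v·τ + σ·√τ·N(0, 1)

until it reaches `+a` or `−a`; the sign of the bound hit is the choice, and
decision RT is the number of steps times τ plus the non-decision time `ter`.
Evidence at the moment of decision is recorded as exactly ±a: the online
feedback construction infers threshold-level evidence at the decision, and
clipping removes step-size overshoot artifacts from everything downstream.
Conventions fixed throughout: τ = 1 ms, σ = 0.1, times in seconds, evidence
unitless. A walk that has not terminated after 20 s of simulated time raises
an error (degenerate parameters); inside the fitting objective such censored
walks are instead resolved to the sign of the current evidence, since
candidates at the edge of the parameter box must still receive an objective
value.

Post-decisional accumulation continues the same walk, unbounded, for the
duration of the confidence report. A sum of k independent Gaussian increments
is exactly Gaussian, so this stage is collapsed into a single draw with mean
`drift · kτ` and variance `σ²·kτ` (k = duration/τ rounded): identical in
distribution to the step loop at a tiny fraction of its cost. In generative
simulation the post-decision drift is the true (signed) stimulus drift, so
errors accumulate disconfirming evidence; in online feedback generation it is
±(pilot drift) by observed accuracy, mirroring what an experimenter can
compute online.

### Discretization note

At τ = 1 ms the walk overshoots the bound by ≈ `0.5826·σ·√τ` on average
(Siegmund's corrected-diffusion constant), so simulated choice probabilities
follow the two-barrier absorption formula at an effective bound
`a + 0.5826·σ·√τ` rather than `a` — a ~0.4-percentage-point shift at
(v = 0.1, a = 0.1) that the test oracles account for.

## Confidence readouts

* Probit posterior: `p(correct | e, t) = Φ(e/(σ·t^γ))`. The printed model
  equations scale by `1/t`, but the flat-prior posterior of a Wiener process
  is `Φ(e/(σ√t))`, and the time-exponent extension is explicitly calibrated
  at γ = 0.5; the implementation therefore defaults to γ = 0.5 with γ exposed
  as a parameter. Corroboration: λ/σ = 17 at σ = 0.1 matches the baseline
  feedback setting α = 18.
* Logistic approximation: `Φ(z) ≈ 1/(1+exp(−λz))`, λ ≈ 1.7. `fit_lambda`
  recomputes λ by minimax grid search; the deviation is even in z and
  unimodal in λ, so the search runs on z ≥ 0 with a coarse-to-fine pass that
  provably returns the exhaustive grid argmin (λ* = 1.7017, max deviation
  0.0095).
* Low-dimensional confidence: `conf = sigmoid((x·α·e + β)/t^γ)`, the package's
  core model. Equivalence `α = λ/σ, β = 0` reduces it to the logistic-probit
  readout exactly (the dimensionally consistent reading of the equivalence).
* Discrete-drift mixture: the posterior that the drift sign matches the
  choice under equiprobable signed drifts at the task's known magnitudes,
  computed on log densities. This is the readout used by the Bayesian-readout
  candidate models; the flat-prior probit form is the target when fitting
  (α, β) to the posterior, which is how the model equations are derived.

Confidence heatmaps fold trials into the chosen option's frame (evidence
× choice) and bin the empirical fraction correct over accumulation time
(decision time net of ter, plus post-decision duration), 50×50 equal-width
cells by default, cells under 50 trials undefined.

Ratings discretize confidence into 6 equal-width bins on [0, 1],
right-closed at 1.

## Elapsed time conventions

The time entering the confidence mapping is accumulation time
(first-passage + post-decision duration) in simulation and fitting — the
quantity the posterior is defined on. The feedback engine alone uses
decision RT + confidence RT, because that is what the online procedure it
reproduces can observe; both conventions are available behind a
`time_basis` flag.

## Fitting

The objective is quantile-proportion least squares. Observed trials are
cross-classified by accuracy × six RT groups (bounded by the .1/.3/.5/.7/.9
RT quantiles per accuracy class) and accuracy × six confidence levels;
proportions are joint over (accuracy × group) so that accuracy itself
constrains the fit (per-class normalization would leave it free). An
accuracy class with no observed trials contributes zero proportions and no
cutoffs; predicted mass in such a class is spread evenly over its six groups
so it is still penalized. Predictions simulate 20× the observed trial count
(each observed trial's difficulty, stimulus side and confidence RT
replicated exactly 20 times — sampling without replacement), and predicted
RTs are grouped by the observed cutoffs.

Minimization is differential evolution, rand/1/bin, F = 0.8, CR = 0.9,
population 10× the number of free parameters (latin-hypercube initialized),
stopping after 100 generations without improvement, hard generation
ceiling 1000. Two implementation choices matter:

* **Common random numbers.** One noise pool (~16M standard normals, scaled
  by σ√τ) is generated per fit and read at fixed per-trial offsets, so every
  candidate vector sees identical noise: the SSE surface is a deterministic
  function of the parameters, which differential evolution's stagnation rule
  requires, and one evaluation costs ~10 ms at 13k simulated trials. The
  public simulators always draw fresh noise; the pool exists only inside the
  fitting objective.
* **Initialization and refinement.** The initial population includes a
  moment-based candidate (EZ-style closed-form inversion of accuracy and
  correct-RT mean/variance per difficulty, known to degrade at ceiling
  accuracy but excellent as a starting region) and a copy with (α, β)
  pre-profiled on that candidate's simulation. After the global search, a
  Nelder-Mead pass refines the full vector, and the parameters that do not
  require re-simulation — ter and the confidence parameters — get a cheap
  final pass on the cached simulation (changing ter only re-bins RTs;
  changing α, β only re-maps confidence).

Candidate drifts are sorted in decreasing order before simulation
(difficulty levels are ordered by design; `order_drifts=False` disables).
Default bounds: ter ∈ [0.05, 0.9·min RT], a ∈ [0.01, 0.3], v ∈ [0, 1],
α ∈ [0, 100], β ∈ [−5, 5] — bracketing every parameterization the feedback
presets use, with headroom.

Two-stage fitting for model comparison first fits the five decision
parameters to the RT term alone, then fits each candidate's confidence
parameters to the confidence term with the decision parameters frozen and
identical across candidates (null k=2; α-free and β-free k=4 at three
conditions; full k=6; Bayesian readout k=0 fixed-drifts or 3 per condition
free-drifts, where candidate drifts enter the readout only). Stage-2
objectives reuse the cached stage-1 simulation, so they always run to
stagnation-based convergence even when stage 1 was budget-capped.

## Model comparison

`BIC = k·ln(n) + n·ln(SSE/n)` (Gaussian residuals); n is the number of data
points of the minimized term — 12 per condition for the confidence-only
stage-2 comparison — and a saturated fit (SSE = 0) has no BIC and raises.
Candidate tables report mean BIC distance from the best model, ties all
reported as 0. Group-level selection treats candidates as random effects:
model evidence −BIC/2, variational Dirichlet posterior over model
frequencies (fixed-point updates, tolerance 1e−6), exceedance probabilities
from 1e5 Dirichlet draws, and the Bayesian omnibus risk from the free-energy
comparison against the equal-frequency null. Bootstrap confidence contrasts
simulate 500 datasets of the observed design from the fitted parameters;
interval endpoints are the .025/.975 order statistics (inverted-CDF
quantiles).

## Signatures

Four curves: confidence by accuracy; the folded X (confidence by evidence
strength × accuracy, evidence strength = difficulty level, the observable
quantity); conditional accuracy by median-split confidence half; and
confidence across six within-participant RT-quantile bins. The median split
uses the continuous model confidence when the table carries it — a discrete
rating scale at ceiling can put the median at the top rating and empty the
high half — and otherwise splits ratings with ties assigned to the lower
half (deterministic). Cells with no trials are absent from the output, not
errors.

## Synthetic cohorts and what they do (not) show

`ExperimentDesign` emulates the study layout: three difficulty levels, 216
trials per level per condition, 6-level ratings, confidence RTs from a
log-normal stand-in (median 0.5 s, log-sd 0.5). Participant parameters are
drawn uniformly from declared ranges — a ∈ [0.06, 0.16], ter ∈ [0.2, 0.5] s,
α ∈ [5, 40], β ∈ [−1.5, 1.5], drifts in [0.05, 0.4] with each difficulty
drawn from its own wide, overlapping tier (distinct on average, widely
spread across participants, sorted within participant). The generator
produces ideal-observer data: no across-trial parameter drift, no lapses, no
metacognitive noise, no scale-use idiosyncrasies. Passing recovery and
signature tests therefore demonstrates internal consistency of simulator +
estimator, not that real participants satisfy the model.

## Study scales

Reduced, desk-top scales used by the test suite and `scripts/acceptance.py`
(chosen as the package's default quick-validation sizes):

* posterior-correlation study: 20 parameter sets × 6000 trials (120k trials);
* recovery study: 20 participants × 648 trials, oversample 20, DE generation
  cap 25 (reduced) with the full stopping rules; the full study (200
  participants, 1000-generation ceiling) runs via `ldcconf recover --full`;
* property checks: 10–50k trials per assertion.

At the reduced recovery scale the per-parameter recovery correlations sit
below the full-scale figures — fewer optimizer generations leave residual
estimation noise, and 20 participants estimate a correlation coarsely — so
the reduced study is a smoke-level check of the estimation pipeline, with
the full study as the strict benchmark.

## Known limitations

* No across-trial drift/start variability, collapsing bounds, or biased
  starts (z = 0 everywhere, as in all fits the package mirrors).
* The quantile-SSE objective is a simulation-based approximation; its Monte
  Carlo floor (~1e−4 at oversample 20) bounds how sharply nearly-equivalent
  parameter combinations can be separated at 648 trials.
* (α, β) are weakly identified when ratings saturate (very easy tasks,
  large α): many mappings then produce the same binned proportions.
* The logit-scale linear solve for posterior targets weights saturated
  trials by their clipped logits; on heavily saturated simulation ranges the
  fitted α drifts above λ/σ while rank agreement with the posterior remains
  ≥ .99 (the quantity of interest).
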