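# Methods

This note documents the models, algorithms and design choices in `admkit`:
what is computed, which conventions were fixed where several were
defensible, and what the synthetic-data generator does and does not
emulate.

## Task and data model

A session comprises two task domains ("perceptual", "value"), two blocks
per domain, 15 trials per block and 30 stimulus pairs per trial. Each pair
is shown for 1.3–1.5 s while the slider position is sampled at 30 Hz. The
instantaneous evidence (IE) of a pair is the signed right-minus-left
stimulus difference on a nine-level alphabet {−0.4, −0.3, …, +0.4}; the
simple average evidence (AE) is its running mean. For analysis, slider
position, white-square differences and rating differences all live on a
common −1…+1 scale: one IE level of 0.1 corresponds to a
14-percentage-point white-square difference, and the slider endpoints mean
a 60% difference, so a level `x` rescales to `x·140/60` (±0.4 ↦ ±0.933…).
Both task domains reuse the same abstract sequences and the same rescaled
evidence; the value domain's item pairs are drawn from rating-difference
bins matched to the levels.

Canonical file formats are plain CSV (UTF-8, comma, header, floats at 17
significant digits for exact round-trips): traces as
`subject,task,block,trial,pair,t_seconds,y` and sequences as
`block,trial,pair,ie_level,ie_rescaled,simple_ae`, where `simple_ae` is
the running mean on the rescaled scale.

## Stimulus sequence generation

Trial sequences are bounded random walks on the alphabet: the initial
level is uniform over the nine levels (the design only fixes the support;
uniform is the minimal assumption), each step goes up when a Uniform(0,1)
draw is ≥ 0.5 (the measure-zero tie resolves upward for determinism), and
the magnitude is `(Poisson(0.3) + 1)/10`. Steps that would leave
[−0.4, +0.4] are **clipped to the boundary**: clipping keeps values on the
alphabet and preserves gradual change; reflection would be an equally
defensible alternative but changes the stationary distribution. The walk
is carried out in integer tenths so values sit exactly on the grid.

A block is chosen from 100 candidate blocks of 15 trials as the one whose
pooled Pearson correlation between all 15×30 (IE, simple AE) points is
smallest in absolute value (ties to the earliest candidate). Pooling all
points into a single correlation — rather than averaging per-trial
correlations — matches how the IE/AE collinearity later enters any
regression on the pooled data.

Value-pair construction drops the `ceil(0.05·n)` lowest- and highest-rated
items plus anything rated exactly 0 or 10, splits the symmetric range of
signed rating differences of all ordered pairs into nine equal-width bins
(half-open, last closed, bin 5 centred on zero), and draws pairs from the
bin matched to each sequence level — without replacement within a block,
falling back to replacement when a bin runs dry (repeats are not
prohibited by the design). An empty required bin raises an
`UnsatisfiableDesignError` naming the bin.

## The Averaging Diffusion Model

The weight on item `i` of `s_t` shown is

    w(s_t, i) = [1 − (1 − εp^i)(1 − εr^(s_t−i+1))](1 − η) + η,  η = 0.01,

bounded in [η, 1]. The decision variable is the weight-normalised average
of the rescaled IE; it updates at pair onsets and is **held constant
between onsets**. The slider sample at time `t` is
`Normal(μ(t), σ_w²/t)`. Two conventions had to be fixed where the
observation model leaves them open:

- **Time base.** `t` is clock time in seconds since trial onset (first
  stimulus onset = 0), restarting every trial; the likelihood iterates
  over recorded samples, which carry clock times. Using the pair index
  instead would only rescale `σ_w`.
- **First-pair exclusion.** All samples recorded during the first stimulus
  pair of a trial are excluded from the likelihood (they reflect the
  initial joystick ramp from the centre, not the estimate). A trace with
  no included samples yields a log-likelihood of 0 (empty product) with a
  warning rather than an error, so degenerate traces do not abort batch
  fits.

A useful geometric fact: with `εp = 0` the weights reduce to
`εr^(s_t−i+1)(1−η) + η`, a geometric decay from the newest item with ratio
`εr`. *Smaller* `εr` therefore means stronger recency — down to roughly
`εr ≈ 0.4`, where the `η` floor (29 items × 0.01 of baseline mass) starts
to dominate and re-introduces averaging. Sweeps that vary "recency
strength" must stay above that floor; the deviance index is monotone in
recency strength only on that range.

Because μ is constant within a pair, the Gaussian likelihood collapses
onto per-pair sufficient statistics (Σt, Σty, Σty², N, Σlog t), which the
sampler evaluates for a whole ensemble of parameter vectors in one
vectorised call; a literal sample-by-sample implementation is retained as
a reference path and the two are held to agreement in tests.

Four variants share or separate the bias pair (εp, εr) and σ_w across
domains (3–6 free parameters). Priors: `ε ~ Beta(2, 4)`,
`log σ_w ~ Normal(−1, 1)`. Sampling is performed on logit(ε) and
log(σ_w) with the appropriate Jacobians.

## Inference

**Sampler.** Any adaptive MCMC meeting the convergence contract suffices;
the package uses the affine-invariant ensemble sampler (emcee) with a
differential-evolution move mixture, which mixes well on the narrow,
correlated posteriors that ~75 000 slider samples produce. The familiar
chains × draws accounting is preserved: `FitConfig(n_chains,
n_samples_per_chain, n_warmup)` is translated into an ensemble of
`max(n_chains, 2·ndim + 2)` walkers run for `thin` (default 20) times as
many steps as the retained-draw budget requires, keeping every `thin`-th
state, so the retained draws total ≈ `n_chains · n_samples_per_chain`.
Walkers serve as the chains of the rank-normalised split-R̂ diagnostic
(computed via ArviZ). Ensemble walkers are not fully independent chains,
which makes this R̂ slightly optimistic; the long thinned runs compensate
in practice, and the refit protocol below catches residual failures.

**Initialisation.** The posterior of the weighting function is multimodal
(e.g. a near-uniform-weights basin competes with a sharp-recency basin),
so random prior starts are unreliable. The mode search scores the full
cartesian grid ε ∈ {0.05, 0.25, 0.5, 0.75, 0.95}, σ_w ∈ {0.15, 0.4, 0.9}
in one vectorised call and polishes the best grid points with L-BFGS;
walkers start in a small ball around the best mode. With no data
(prior-only fits), walkers start from prior draws instead.

**Convergence and refits.** A fit is converged when every parameter's R̂
is ≤ 1.01. Otherwise the fit is repeated once with informed initial
values: the chain with the highest log posterior is selected, each
parameter's walker inits are drawn independently and uniformly within that
chain's marginal 95% HDI (the protocol specifies the interval, not a joint
law; independent uniforms are the least informative choice), and the
sampler reruns with the same budget. A refit that still fails raises (or,
in batch/lenient mode, returns the fit flagged `converged=False` with a
warning).

**WAIC.** `WAIC = −2(lppd − p_waic)` with
`lppd = Σᵢ log meanₐ exp(llₐᵢ)` and `p_waic = Σᵢ Varₐ(llₐᵢ)` using the
population variance (ddof = 0) — fixed as the package convention and
cross-checked against ArviZ, which uses the same one. The pointwise matrix
over all retained draws is never materialised; a streaming accumulator
(running log-sum-exp plus Welford/Chan variance) folds in draw blocks. The
preferred variant is the WAIC argmin, ties broken toward fewer parameters.

**HDI.** Shortest contiguous interval over sorted draws. Multimodal
posteriors still receive a single interval — a known limitation, adequate
for the unimodal marginals seen here.

## Synthetic populations

The generator emulates the statistical structure the analysis assumes, at
the study's scale (38 subjects by default, full sessions). Each subject
carries four latent standard-normal traits (bias type, strong-ε strength,
weak-ε strength, log-noise); per-task realisations share latent
correlation ρ = 0.9 of each trait (Gaussian copula), giving cross-task
consistency without identical parameters. A subject-task is recency-typed
when the bias trait's quantile falls below `recency_fraction` (default
34/38 ≈ 0.895); the favoured ε draws from Beta(6, 2), the disfavoured one
from Beta(2, 8) via quantile transform. `log σ_w` is Normal(−1, 0.4) plus
a +0.3 offset in the value task, so most subjects are noisier there.
Pair durations are uniform on [1.3, 1.5] s (the design states the range,
not the law). All of this is overridable through `PopulationConfig`.

Traces are simulated from exactly the observation model the likelihood
assumes — independent Normal samples around μ(t), clipped to ±1 — so fits
are internally consistent. Deliberately *not* emulated: joystick inertia
and velocity control (available only behind an optional, off-by-default
slider speed limit), autocorrelated motor noise, the initial first-pair
ramp (the generator draws first-pair samples from the same model, which
makes them high-variance; the likelihood excludes them anyway), learning
or fatigue across blocks, and per-subject value-scale endpoints (both
domains use the canonical rescaled evidence). Passing recovery tests
therefore show the inference machinery is correct and well-calibrated
under the model's own assumptions; they do not show the model captures
real motor dynamics. Under the default parameter ranges fewer than 5% of
non-first-pair samples hit the ±1 clip (guarded by a test).

## Behavioral metrics

Per subject and task, with `y(b,l,s)` the last slider sample of pair `s`:

- **Mean error** `ME = mean |y − simpleAE|` over all 900 pairs —
  including each trial's first pair, unlike the likelihood.
- **Deviance index** `d_a = Σ|y − IE| / Σ|y − simpleAE|` (sums over all
  pairs before dividing); 0 = pure IE reporting, ∞ = perfect AE tracking.
  A zero denominator yields an `inf` sentinel with a warning; infinite
  values are excluded from group means with a reported count.
- **Error regression**: `|y − simpleAE|` on time, task type and their
  interaction. **Update regression**: `y_s − y_{s−1}` (s ≥ 2) on IE, time,
  task type and all interactions. "Time within a trial" is operationalised
  as the pair index 1–30 (configurable to seconds); task is coded
  1 = value-based. Both use OLS with subject-clustered standard errors
  (statsmodels CR1-type small-sample correction, recorded in the result
  metadata); with a single subject clustering is undefined and the code
  falls back to HC1, also recorded.
- **Temporal weighting curves** evaluate the weight function at the 30th
  pair from posterior means, averaged across subjects when given a set.
- **Cross-task correlations** are pairwise-complete Pearson correlations
  across subjects.
- **Bonus payoff**: $10 for mean deviations ≤ 4% of the scale length,
  $1 for ≥ 20%, linear in between (the schedule between the stated
  endpoints is linear by declared choice).

## Simulation studies and problem sizes

- **Parameter recovery**: 20 subjects from the default population, full
  sessions, fully separate variant, reduced budget (2 chains × 1000
  retained draws). Reported: sign agreement between generating and
  recovered `ε_recency − ε_primacy` per subject-task cell, and their
  Pearson correlation.
- **Model recovery**: 10 replicates of one subject on a single-block
  session per task, all four variants fitted at a short budget
  (2 × 500 draws), scored by which variant wins the WAIC comparison.
  Single-block sessions keep the study brisk while leaving WAIC margins of
  hundreds of deviance units.

These sizes are the package's defaults for its own validation studies;
both studies scale up through their arguments.

## Known limitations

- R̂ across ensemble walkers is mildly optimistic (see above).
- The HDI is a single contiguous interval.
- The generator's value task reuses the canonical level rescaling rather
  than per-subject rating endpoints, so value-domain evidence is
  discretised exactly like perceptual evidence.
- Subject-level fitting only; no hierarchical pooling across subjects.
- Choice/response-time predictions of diffusion models are out of scope;
  the ADM here is purely an observation model for continuous reports.
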