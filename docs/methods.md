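# Methods

`gazechoice` models how people choose one snack-food item from large grids
(9, 16, 25 or 36 alternatives) while their gaze is tracked. Each subject
rates every item once on a 7-point liking scale (−3..3); on each trial they
freely inspect the grid and press a key when decided. The package links
the stream of item gazes to the observed choice and response time (RT)
through three likelihood models, fits them per subject and set size by
MCMC, compares them by WAIC, and validates the whole pipeline on synthetic
experiments it generates itself.

## Models

All models rescale ratings to `l ∈ {1..7}` (`l = rating + 4`) so values
are strictly positive, and share two gaze-bias parameters: a
multiplicative bias `γ ∈ [0,1]` discounting momentarily unattended items
and an additive bias `ζ ∈ [0,10]` boosting the attended item. The
*passive-gaze* variant of each model is the exact restriction `γ = 1,
ζ = 0` (gaze then only gates which items are considered); this is
implemented literally as the active code path with those two parameters
fixed, so the two variants cannot drift apart.

**Probabilistic satisficing (PSM).** At each millisecond the search stops
with probability `q(t) = min(α·C(t) + v·t, 1)`, where the cached value
`C(t) = max_j c_j(t)` is the best gaze-weighted value seen so far,

    c_i(t) = g_i(t)·(l_i + ζ) + (1 − g_i(t))·γ·l_i,

`g_i(t)` the fraction of elapsed time spent on item *i* (zero before the
item is first gazed, in which case `c_i = 0`). Survival
`Q(t) = ∏_{s≤t}(1 − q(s))` and stop mass `f(t) = q(t)·Q(t−1)` give the RT
density; the choice at the stop time follows a softmax with sensitivity
`τ` over the seen items' cached values. Free parameters: `v, α ∈
[0, 0.001]` (1/ms), `τ ∈ [0, 10]`, `γ`, `ζ`.

**Independent accumulation (IAM).** One accumulator per *seen* item,
started at the item's first-gaze onset `t0_i`, drifting at `v·D_i` with
Gaussian increment noise `σ` toward a common boundary `b = 1`. The drift
signal is `D_i = g_i·(l_i+ζ) + (1−g_i)·γ·l_i` with `g_i` the fraction of
*remaining* trial time (after `t0_i`) spent on the item. First-passage
times are Inverse-Gaussian with `μ_i = b/(v·D_i)`, `λ = b²/σ²`; the trial
likelihood is the winner's density at `rt − t0_i` times the other seen
accumulators' survival at `rt − t0_j`. `v ∈ [1e−7, 0.005]`,
`σ ∈ [1e−7, 0.05]`.

**Relative accumulation (GLAM).** All seen items race from trial onset.
The absolute signal `A_i` uses the same gaze weighting with `g_i` the
item's share of total trial time; the relative signal `R_i = A_i −
max_{j≠i} A_j` passes through a logistic with sensitivity `τ`, `D_i =
1/(1 + e^{−τR_i})`, keeping drifts positive and discrimination sharpest
near `R = 0`. Likelihood as for the IAM without onset offsets.

**Contaminants.** Every fitted likelihood is the 95/5 mixture
`l = 0.95·p_model + 0.05·u` with `u = 1/(N·(maxRT − minRT))`, the density
of a uniformly random item at a uniformly random time inside the
subject-condition's observed RT range. The floor keeps every trial's
log-likelihood finite anywhere in the prior box. The RT range is taken
per subject × set-size cell (the unit of fitting); an explicit shared
range can be passed for sensitivity checks.

## Numerical choices

* Time is integer milliseconds; the PSM hazard grid uses Δt = 1 ms by
  default. A coarser grid (`dt_ms`) replaces per-ms survival by
  `(1−q)^w` per grid step of width `w`; at Δt = 10 ms the summed
  log-likelihood of a 150-trial subject differs from Δt = 1 by ≲ 0.5,
  and a regression test pins that agreement. MCMC fits inside the
  validation studies use Δt = 10 for speed; reported densities and
  normalization checks use Δt = 1.
* The hazard is floored just below 1 (`1 − 1e−12`) inside likelihood
  evaluations so the per-ms density at the response time stays defined.
* The PSM density support is truncated where residual survival falls
  below 1e−16 (the hazard only grows after the response), so stop masses
  sum to 1 to ≈ 1e−14.
* Inverse-Gaussian densities are evaluated in log space
  (`exp(2λ/μ)·Φ(−·)` via `log Φ`), survival by complement with clipping;
  zero-drift accumulators are defined to never finish (density and CDF
  zero). Sampling uses the Michael–Schucany–Haas transform (scipy's
  generator), a route independent of the closed-form density, which the
  equivalence tests exploit.
* Race simulators round RTs to the nearest ms, matching the midpoint-rule
  evaluation of the continuous density on the integer grid; ties in the
  race go to the lowest item index (probability zero in continuous time).
* Softmax and logistic transforms subtract the maximum before
  exponentiating.

## Estimation

Each subject × set-size cell is fitted independently. The prior is
uniform on the parameter box, so the log posterior is the summed trial
log-likelihood inside the box. The sampler is a single-chain
random-walk Metropolis with two refinements that the flat gaze-bias
ridges make necessary:

* **Initialization.** The posterior occupies a tiny corner of the box
  (hazard and drift scales are orders of magnitude below their bounds),
  so the chain starts from the best point of a 192-point Latin-hypercube
  screen polished by bounded Nelder–Mead (≤ 400 evaluations).
* **Adaptive proposals.** During burn-in the proposal covariance tracks
  the empirical covariance of the chain (so proposals move along the
  γ–ζ–τ trade-off ridge) and a Robbins–Monro recursion steers the step
  size toward ~23% acceptance. Out-of-box proposals are rejected, which
  implements the truncation exactly; adaptation freezes after burn-in.

Defaults are 5000 burn-in + 5000 kept draws; convergence requires
`|R̂ − 1| < 0.05` for every free parameter (split-chain R̂) and mean
effective sample size > 100 (arviz estimators on the two chain halves).
Non-converged fits are retried with the burn-in extended by another
tuning phase up to `max_retries`, then returned flagged. The MAP is the
best posterior draw, not a separate optimum. WAIC is reported on the
log-score scale, `lppd − p_waic` with the draw variance computed with
`ddof = 1` (arviz uses `ddof = 0`; the cross-check test rescales).

The γ–ζ–τ ridge is genuinely flat in places: both biases raise the
attended item's momentary value, and the sensitivity rescales the
spread, so single-parameter posteriors can be wide while the fit (and
WAIC) is stable. The recovery studies below quantify what the MAP can
and cannot pin down.

## Synthetic experiments

The generator produces complete subjects: ratings (default Binomial(6,½)
− 3, a symmetric bell like empirical liking histograms), item sizes
(U(0.3, 0.95) of image area), random grid placement, and a sequential
gaze scaffold. The scaffold starts near the grid centre, prefers
highly-rated, larger and spatially adjacent items, revisits more as the
trial progresses (revisit probability grows per completed gaze), shortens
first visits by 44 ms, draws gamma durations (default mean 400 ms, shape
2 — artifact choices; only the initial-gaze shortening magnitude comes
from reported effects), and targets a seen fraction of
`frac_seen_base + slope·N` so larger sets leave more items unseen.

The configured model then generates (choice, RT) on the scaffold, and the
emitted trial is reconciled with the simulated RT per family so that
*refitting the emitted data recovers the generating process*:

* PSM: sequential stopping on the scaffold, truncation at the RT. The
  running gaze fractions the likelihood reads are unchanged by
  truncation, so this is exactly consistent. If the stop falls beyond
  the scaffold, the scaffold is regrown longer and the trial resimulated
  (freezing gaze past the stream would distort refitted fractions).
* IAM: the drifts depend on remaining-time gaze shares of the emitted
  trial, which depend on the RT being generated. With the auxiliary
  randomness held fixed (common random numbers through the
  Michael–Schucany–Haas transform) the map RT → winner arrival is
  iterated to a fixed point; first-gaze onsets are exact, remaining-time
  shares self-consistent at the fixed point.
* GLAM: the scaffold's time axis is rescaled onto the RT, preserving
  cumulative gaze fractions (the only gaze statistic GLAM reads)
  exactly.

Contaminant trials are injected at the configured rate (default 5%):
uniform item, uniform RT in the condition's realized range, gaze
truncated accordingly; a contaminant that picks an unseen item is then
excluded by the standard rules, as in real data.

The negative control (`gen_null_gaze_subject`) draws choices from a
rating-only softmax with full gaze coverage and rating-independent gaze.
Full coverage matters: if some items were unseen, the consideration set
alone would couple gaze to choice and the null would not be centred on
zero.

What the generator does *not* emulate: pixel-level saliency, the
empirical covariance of gaze duration with set size, non-item gaze time
(scaffolds are contiguous item gazes), and any feedback from the
emerging decision onto gaze. Passing tests therefore show internal
consistency of likelihoods, fitting and measures — not that real gaze
obeys the scaffold process.

## Validation studies and the sizes they run at

* **Simulator–likelihood equivalence** (the central oracle): on a fixed
  9-item trial, 1e5 simulated (choice, RT) pairs per family and variant
  are tested against the joint density (χ² on choice counts and on
  decile-binned RTs, α = 0.01).
* **Degeneracy**: passive log-likelihoods are bitwise equal to the active
  path at `γ=1, ζ=0` over 1000 random trials.
* **Normalization**: PSM stop mass 1 ± 1e−8; race win probabilities
  1 ± 1e−4 (numeric integration to 150 s); IG density 1 ± 1e−6.
* **WAIC**: matches a naive two-pass oracle to 1e−10 and the constant
  closed form exactly.
* **Parameter recovery**: 20 subjects × 150 trials per family, one
  25-item condition, concentrated revisit-heavy gaze (this condition
  carries the most per-trial information about the gaze biases),
  generating parameters sampled at realistic magnitudes (RT scale
  0.5–4 s; `γ ∈ [0.15, 0.95]`, `ζ ∈ [0, 8]` — the span of fitted
  additive biases across subjects — and sensitivities high enough
  that choices track value). Reduced chains: PSM 800+800 draws at
  Δt = 10, races 1000+1000. Requirement: r ≥ 0.7 between generating and
  MAP values for `v, γ, ζ` (and `τ` where present).
* **Model recovery**: 10 subjects per generating family (strong gaze
  bias, `γ ∈ [0.2, 0.45]`, `ζ ∈ [2, 4]`), 100 trials, 9-item condition;
  all three active models fitted with 600+600 draws; the WAIC winner must
  be the generating family for a majority of each row.
* **Gaze-influence calibration**: the measure (residual choice
  probability after a per-subject logistic regression of choice on
  relative rating and the others' mean and range, contrasted between
  positively and non-positively gaze-advantaged items) averages < 2
  percentage points in absolute value over 20 null subjects, and is
  positive for ≥ 18/20 subjects generated with `γ = 0.3, ζ = 3`.

The reproduction script (`scripts/acceptance.py`) reruns these studies
from scratch at the same sizes (20 recovery subjects per family, 10 per
model-recovery row) and adds the behavioural summary of one synthetic
subject across all four set sizes.

## Design choices where the design was open

* The gaze-influence regression is logistic (binary outcome), fitted per
  subject × set size over all items of each trial (unseen items enter
  with zero cumulative gaze); `seen_only=True` and `method="linear"`
  flags cover the alternatives. On complete separation the fit falls
  back to a weakly L2-regularized logistic regression.
* A tie for the longest cumulative gaze yields no positively-advantaged
  item.
* Gaze cleaning order: same-item missing gaps are relabelled first, then
  leading/trailing and between-item non-item/missing time is dropped,
  then temporally contiguous same-item segments merge. A non-item
  fixation between two gazes to the same item splits them into two gazes
  and its time counts toward no item.
* All "fraction of trial time" denominators are the response time, so
  non-item time dilutes every item's share.
* An item first seen at the response itself gets a remaining-time gaze
  share of 1; remaining-time shares are clamped to [0, 1].
* A GLAM trial with a single seen item takes `R = 0` (`D = ½`).
* Estimators follow the sklearn contract (`fit`, fitted attributes with
  trailing underscores, `get_params`/`set_params`), so sampler settings
  compose with sklearn model selection; the functional API
  (`fit_subject`, `psm_trial_loglik`, ...) remains the core.

## Known limitations

* Single-chain fitting: R̂ is a split-chain statistic, blind to modes the
  chain never visits; the Latin-hypercube screen mitigates but does not
  eliminate this.
* On flat γ–ζ–τ ridges the MAP wanders even when the fit is good;
  recovery correlations below ~0.95 for those parameters reflect that
  flatness, not sampler failure. For the additive bias ζ in the
  satisficing and relative-race families the 20-subject recovery
  correlation itself varies by roughly ±0.15 across realizations of the
  study, hovering around the 0.7 mark — the reproduction script's value
  at an arbitrary seed can fall on either side of it.
* The IAM's conditional structure (drifts computed from the observed
  trial's own gaze statistics) admits no fully generative account; the
  fixed-point construction makes synthetic data self-consistent but real
  data need not be.
* WAIC comparisons at 5% contamination can prefer a wrong family for
  individual subjects with few informative trials; only the aggregate
  confusion matrix is contracted.
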