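# gazechoice

Computational models of **many-alternative value-based choice**: how people
pick one snack food from grids of 9–36 items while their eyes wander over
the alternatives. The package is built for decision scientists who have
(or simulate) trial-level choices, response times and item-gaze streams
plus per-item liking ratings, and want to ask *how* gaze enters the
decision process.

Three model families span the space between satisficing search and
evidence accumulation, each in a passive-gaze variant (gaze only
determines which items are considered) and an active-gaze variant (gaze
reweights subjective value through a multiplicative bias γ ≤ 1 on
unattended items and an additive boost ζ ≥ 0 to the attended item):

* **PSM** — probabilistic satisficing: search stops with per-ms hazard
  `q(t) = min(α·C(t) + v·t, 1)` driven by the best gaze-weighted value
  seen so far, `C(t) = max_j [g_j(t)(l_j+ζ) + (1−g_j(t))γl_j]`; the
  choice is a softmax (sensitivity τ) over seen items' cached values.
* **IAM** — independent race: an accumulator per seen item starts at its
  first-gaze onset and drifts at `v·D_i` with noise σ to a boundary
  `b = 1`; first-passage times are Inverse-Gaussian with
  `μ_i = b/(v·D_i)`, `λ = b²/σ²`.
* **GLAM** — relative race: drifts are a logistic transform (sensitivity
  τ) of each item's gaze-weighted value relative to the best other item.

All fitted likelihoods carry a fixed 5% contaminant mixture (uniform
item × uniform RT in the observed range). Fitting is per subject × set
size: uniform box priors, adaptive random-walk Metropolis, split-chain
R̂/ESS convergence rules, MAP = best posterior draw, and model comparison
by WAIC on the log-score scale (larger = better). A synthetic-experiment
generator (ratings, gaze scaffolds, model-generated choices/RTs) makes
the whole pipeline testable without any data download, and
`gazechoice.metrics` implements the behavioural measures — including the
gaze-influence statistic, the residual increase in choice probability for
the longest-gazed item after regressing choice on the trial's rating
structure.

## Worked example

```python
import numpy as np
from gazechoice import GLAM, SyntheticConfig, gen_subject, summarize

params = {"v": 1e-3, "sigma": 0.01, "tau": 1.0, "gamma": 0.4, "zeta": 2.0}
cfg = SyntheticConfig(set_sizes=(9,), trials_per_cond=150,
                      contaminant_rate=0.0).with_generator("glam", "active", params)
subject, truth = gen_subject(cfg, np.random.default_rng(3))

print(summarize(subject).round(3).to_string(index=False))

est = GLAM(n_tune=1000, n_draws=1000, seed=0).fit(subject.valid_trials())
print({k: round(v, 4) for k, v in est.map_.items()})
print(f"WAIC {est.waic_.waic:.1f}  (lppd {est.waic_.lppd:.1f}, "
      f"p_waic {est.waic_.p_waic:.1f})")
```

prints

```
subject  setsize  n_trials  mean_rt_ms  p_choose_best_seen  p_choose_last_seen  frac_items_seen  gaze_influence
    s00        9       150     1294.54               0.527               0.153            0.889          22.462
{'v': 0.001, 'sigma': 0.01, 'tau': 0.6304, 'gamma': 0.7303, 'zeta': 5.7239}
WAIC -1347.0  (lppd -1343.4, p_waic 3.6)
```

The subject chooses the best-seen item 53% of the time and shows a gaze
influence of ~22 percentage points — the extra choice probability earned
by the longest-gazed item beyond what its rating predicts, the signature
of an active gaze bias. The MAP pins the accumulation scale exactly
(`v`, `σ` at their generating values) while the gaze-bias pair lands
elsewhere on the flat γ–ζ–τ trade-off ridge than the generating point
(γ 0.73/ζ 5.7 vs 0.4/2.0) — both parameterizations imply nearly the same
likelihood; see `docs/methods.md` on what is and is not identifiable at
this sample size. The estimator exposes the posterior draws, convergence
diagnostics and WAIC as fitted attributes.

A command-line pipeline wraps the same functionality:

```bash
gazechoice synth --model glam --subjects 2 --trials 50 --seed 1 --out data/
gazechoice metrics --data data/ --out behaviour_summary.csv
gazechoice fit --data data/ --model psm --variant active --out fits/
gazechoice compare --fits fits/ --out waic_comparison.csv
gazechoice simulate --data data/ --model psm --params fits/psm_active_s00_9.json --out sim.csv
```

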