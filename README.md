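# extenderopt

Closed-loop, surrogate-assisted optimization of bull-sperm cryopreservation
extender media.

Semen extenders are multi-component media (buffer, egg yolk/milk membrane
stabilizers, permeating cryoprotectants such as glycerol and ethylene glycol,
sugars, antioxidants) whose composition drives post-thaw sperm motility.
Because component effects interact and post-thaw recovery varies strongly
within and among bulls, factorial designs are hopeless (3 levels × 11
components ≈ 1.8 × 10⁵ treatments): the practical alternative is an iterative
campaign in which a small batch of candidate extenders is frozen and assayed
each generation and an optimizer proposes the next batch.

`extenderopt` implements that loop for an 11-component design space:

* **Differential evolution** (DE/rand/1/bin; mutation factor F = 0.9,
  crossover rate CR = 0.5) proposes trial formulations,
  `vᵢ = x_{r3} + F·(x_{r1} − x_{r2})` per crossed-over coordinate, with a
  late-campaign variation boost that adds `ref · U(−10 %, +10 %)` to mutated
  coordinates, pooled top-N elitist selection over parents ∪ trials, and a
  Kruskal–Wallis plateau test for convergence.
* **Surrogate models** — a 12-12-1 ReLU network (L2 = 10⁻⁴) and an
  anisotropic squared-exponential Gaussian-process regressor with an
  observation-noise term — are cross-validated (tenfold MSE), compared
  against experimental motility by rank tests, and the selected model screens
  an oversampled DE trial pool down to the 8-extender experimental batch.
* **A virtual lab** replaces the wet lab for development and testing: a
  configurable ground-truth response surface (concave per-component optima, a
  glycerol × ethylene-glycol antagonism, a detrimental growth-factor term)
  with among-bull and within-bull noise and a split-sample control, whose
  global optimum is known in closed form.
* **An equivalence-testing evaluation layer**: relative total motility
  (treatment/control per sample), Kruskal–Wallis, Dunn post-hoc and
  Fligner–Killeen tests, and the Mann–Whitney test for *equivalence* with
  margins (−0.15, 0.15): with `W⁺` the tie-weighted estimate of P(X > Y) and
  `σ̂` its U-statistic standard error, equivalence is established (REJ = 1)
  iff `|W⁺ − ½| / σ̂ < CRIT`, where `CRIT²` is the α-quantile of a noncentral
  χ²₁ with noncentrality `((ε₁+ε₂)/2σ̂)²`.

## Worked example

```python
from extenderopt import CampaignConfig, VirtualLab, default_space, run_campaign
from extenderopt.campaign import final_report

space = default_space()
cfg = CampaignConfig(seed=1)          # 8 extenders x 4 bulls x 3 straws / generation
state = run_campaign(cfg, lab=VirtualLab(space), space=space)
report = final_report(state, cfg)
```

With seed 1 this campaign runs 20 generations (surrogate coupling from
generation 7, metric switch to relative total motility at 18, growth factor
removed at 19) and selects the Gaussian-process surrogate. The trajectory
(per-generation median ± SD of the active metric, 32 formulation–bull pairs
each) climbs from a median total motility of 40.9 % at generation 1 to 68.7 %
at generation 17, then holds a relative total motility of 1.06–1.09 in the
final era — i.e. the evolved extenders outperform the split-sample control:

```
 generation  median     sd   metric
          1  40.919  9.358    total
          7  57.704  8.614    total
         14  73.417  4.276    total
         17  68.742  5.686    total
         20   1.055  0.050 relative
```

The five top media by mean relative total motility beat their paired controls
by 10.5–12.8 % each (11.6 % pooled), and the final-generation-vs-control
equivalence test reports `W⁺ = 0.94, σ̂ = 0.04, CRIT = 2.40, REJ = 0` — the
evolved media are *better* than control, not merely equivalent. All of these
numbers are printed by the code above.

The same loop runs against a real lab: `extenderopt init`, `propose`,
`ingest`, `step`, `run`, `stats` and `validate-top` drive a campaign work
directory from the shell, with all ledgers as CSV and bit-identical
reproduction under a fixed seed.

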