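# Methods

## The optimization problem

An extender formulation is a vector of 11 component concentrations over the
shipped design space (bounds in the units a bench protocol uses):

| component        | unit        | range     | role                        |
|------------------|-------------|-----------|-----------------------------|
| Tris buffer      | % v/v       | 0–50      | base medium                 |
| egg yolk         | % v/v       | 0–20      | membrane stabilizer         |
| milk             | % v/v       | 0–15      | membrane stabilizer         |
| fructose         | % w/v       | 0–1.25    | energy source / osmolyte    |
| glycerol         | % v/v       | 0–7       | permeating cryoprotectant   |
| ethylene glycol  | % v/v       | 0–6.75    | permeating cryoprotectant   |
| trehalose        | mM          | 0–100     | non-permeating cryoprotectant |
| CLC              | mg/mL       | 0.5–1     | membrane stabilizer         |
| glutathione      | mM          | 0.5 (frozen) | antioxidant              |
| melatonin        | mM          | 2–3       | antioxidant                 |
| NGF              | mg/mL       | 0–0.5     | growth factor               |

Frozen components are encoded as zero-width ranges; a component removed
mid-campaign keeps its ledger column with value 0, so schemas never change.
The split-sample control is a constant formulation modelled on a commercial
Tris/citrate/fructose egg-yolk extender (55.5 mM fructose, 20 % v/v egg
yolk, 6 % v/v glycerol); it is assayed alongside every batch and is never
touched by the optimizer.

The objective is post-thaw total motility (%, by CASA in a real campaign),
scored per (formulation, bull) as the mean over three straw replicates and
aggregated per formulation as the median across the generation's four bulls
(median rather than mean: bull effects are long-tailed; the mean is a config
option). From generation 18 the score is *relative total motility* — the
ratio of a formulation's motility to the same bull's control motility —
which cancels the shared bull effect.

## Differential evolution

Strategy DE/rand/1/bin with population 8, F = 0.9, CR = 0.5. Per target,
three distinct donors r1, r2, r3 are drawn; each mutable coordinate becomes
`r3 + F·(r1 − r2)` with probability CR, with one forced mutated coordinate
(j_rand) so a trial never equals its target. After generation 10 each
mutated coordinate also receives `ref · U(−0.10, +0.10)` where `ref` is the
component's reference value — taken to be the upper bound of its range, the
only per-component scalar available; this is an assumption and is
configurable. Out-of-bounds coordinates are clipped (concentrations cannot
be negative; reflection/resampling would complicate the exact-replay
contract for no benefit at these bounds). Frozen and deactivated components
are never mutated.

Selection is pooled top-8 over parents ∪ trials (ties prefer trials, then
lexicographic id). Parents keep the scores from the generation in which they
were assayed; only trial formulations consume assay budget, so tested
formulations per generation never exceed the population size. Classic
per-index pairwise replacement is available (`selection: pairwise`).

Initialization stratifies each mutable component's 8 values over its range
(per-component Latin hypercube), guaranteeing coverage at population size 8
in 11 dimensions.

The RNG contract is part of the module's interface: one generator per
(seed, generation), with a documented draw order (donor triple, forced
coordinate, per-coordinate crossover uniform, per-mutation jitter uniform).
Tests replay the identical stream with an independently scripted oracle and
require exact equality; campaigns are therefore bit-reproducible and
resumable from any ledger prefix.

## Surrogate models and coupling

Inputs are the 11 components min–max scaled to [0, 1] plus the water-filler
volume fraction as a twelfth coordinate (the dispensing recipes make water
the implicit filler; a twelfth input also lets the models see total
solids/liquids load). Targets are total motility in percent; the surrogate
always regresses total motility regardless of the selection metric, since
the ratio metric is derived from it.

* Network: one hidden layer of 12 ReLU units, L2 penalty 10⁻⁴, MSE loss,
  full-batch Adam (initial step 0.01, iteration cap 2000, plateau early
  stop), seeded initialization. Training-loss history is retained.
* Gaussian process: constant × anisotropic RBF + white noise kernel,
  hyperparameters by marginal-likelihood optimization (seeded), targets
  normalized. Exposes a predictive standard deviation; the network does not.

Model fitness is tenfold cross-validated MSE over a seeded disjoint
partition. Deployment-model selection, run once when the surrogate first
couples to the loop (generation 7 by default): fit both models on all but
the latest generation, predict the latest, then among models whose
predictions are not significantly different in location from the
experimental sample (Dunn post-hoc at α = 0.05), prefer the one whose
prediction spread is homoscedastic with the experimental spread
(Fligner–Killeen p ≥ α); remaining ties fall back to lower CV MSE, else the
larger homogeneity p-value. The rationale: a surrogate that collapses the
assay variance will rank candidates overconfidently, and variance fidelity
matters more than a small MSE edge for screening.

Coupling is candidate screening: DE proposes 4 × 8 trials (the
oversampling factor is a package default; any coupling that leaves the
8-extender experimental throughput unchanged must screen rather than add
assays) and the surrogate keeps the 8 with the highest predicted motility —
greedy mean, no acquisition function, ties by id. Surrogate fits use at most
the 320 most recent training pairs (10 generations): recent data covers the
current search region and bounds the cubic GP fit cost.

## The virtual lab

The synthetic assay stands in for every wet-lab step. The noiseless surface
is `baseline + Σ bumps + Σ interactions − Σ penalties`, clamped to
[0, 100] %:

* concave Gaussian bumps (optimum, width, amplitude) for Tris, egg yolk,
  milk, fructose (small amplitude: dispensable), glycerol, trehalose, CLC
  and melatonin;
* one signed product interaction on normalized concentrations:
  glycerol × ethylene glycol at −15 (the two permeating cryoprotectants are
  antagonistic in combination);
* linear penalties on normalized ethylene glycol (6) and NGF (10): both
  additives are detrimental, NGF strongly so.

Because penalized components carry no bump, every interaction coefficient is
non-positive, and each interaction involves a component whose optimum sits
at zero, the global argmax is the coordinate-wise optimum and is exposed in
closed form (75 % motility; the control sits at 66.2 %). Configurations that
break these separability conditions are rejected rather than silently
mis-reporting an optimum; a grid-search oracle over all 2-component slices
verifies the argmax in tests.

Noise has two levels: an among-bull effect shared between a bull's treatment
and control straws, and independent within-bull straw noise, both Gaussian,
with truncation to [0, 100] applied last (clamping, not resampling; the bias
is negligible at default SDs). Defaults sd_bull = 5, sd_within = 3 put the
straw-level SD at ≈ 5.8 %, consistent with the 3–7 % spread observed in
converged generations of real campaigns of this design, and put the control
median in the 60–70 % band. The generator emulates the study-shaped design —
8 formulations × 4 bulls × 3 straws plus a split-sample control per
generation — and deliberately does not model heteroscedastic measurement
error, ejaculate-to-ejaculate drift within bull, seasonal effects, or any
mechanistic cryobiology (osmotic or ice-formation physics). Passing tests
therefore demonstrate that the *loop* recovers a known optimum under
study-realistic noise, not that any particular medium is biologically
optimal.

## Statistics

`W⁺` estimates P(X > Y) with tie weight ½. Its variance uses the two
U-statistic covariance terms π̂_xxy = P(X > Y, X′ > Y) and
π̂_xyy = P(X > Y, X > Y′):

σ̂² = [W⁺(1−W⁺) + (n−1)(π̂_xyy − W⁺²) + (m−1)(π̂_xxy − W⁺²)] / (mn).

Equivalence margins default to (−0.15, 0.15) on the P(X > Y) − ½ scale at
α = 0.05; `CRIT = √(χ²₁,α(ψ²))` with ψ = (ε₁+ε₂)/(2σ̂), and REJ = 1 iff
|W⁺ − ½ − (ε₂−ε₁)/2| / σ̂ < CRIT. Completely separated samples leave σ̂ = 0
and raise a degenerate-data error instead of fabricating a decision. The
test's type-I error at the margin (P(X > Y) = 0.65, m = n = 32) is verified
by simulation to stay within α + 3·SE.

Kruskal–Wallis and Fligner–Killeen wrap scipy's tie-corrected
implementations; the test suite checks both against independently coded
textbook formulas to 10⁻¹⁰. Dunn's post-hoc z-tests (pooled-rank means with
the tie-corrected variance) are implemented here, reporting both unadjusted
and Holm-adjusted p-values with the adjustment named in the result.

Generation-vs-control comparisons are exposed in both pooling modes (32
per-pair treatment values against 4 per-bull control means by default);
which mode a real campaign should use is a protocol decision, not asserted
by the package.

## Campaign protocol events

The metric schedule (total motility for generations 1–17, relative from 18),
the surrogate start (7), and scheduled component removals (NGF at 19) are
plain configuration. Convergence is a Kruskal–Wallis plateau test (p ≥ 0.05)
over the last three generations' scores, evaluated only on windows that
share one metric and — when the schedule has a relative-motility era — only
inside that era: under raw total motility each generation's bull panel
shifts the entire score distribution, so a between-generation omnibus test
conflates bull luck with optimization progress. Re-testing of earlier top
performers is supported as a distinct protocol action (re-test generations
are tagged, not treated as DE steps). A 20-generation cap applies
regardless.

## Problem sizes used in the test suite

Property simulations use the smallest sizes at which the checked effect is
identifiable: oracle replays on populations of 4–8 in 2–11 dimensions;
U-statistic enumeration on 200 random fixtures; equivalence-test calibration
with 2,000 simulations at m = n = 32; rank-test oracle agreement on 100
random fixtures; full-loop recovery as one noiseless 20-generation campaign
plus ten default-noise campaigns.

## Known limitations

* The noisy-campaign recovery check asks every top-5 formulation to carry
  *exactly* zero ethylene glycol. The post-generation-10 jitter re-injects
  ±0.675 % v/v ethylene-glycol perturbations into mutated coordinates by
  design, and the motility deficit of such trace amounts (≲ 2 points) lies
  below the bull/straw noise floor, so campaigns routinely retain a few
  formulations with trace ethylene glycol; the corresponding test documents
  this tension and fails honestly under the default conditions (the
  beat-the-control half of the property holds in 10/10 seeded campaigns).
* The network's 12th input (water fraction) and the upper-bound jitter
  reference are interpretations of an under-specified protocol; both are
  configurable.
* Stock concentrations for µL-dispensed components (glutathione, melatonin)
  in batch recipes are configurable assumptions, not protocol facts.
* Parents are never re-assayed, so a parent's stored score can be
  optimistically biased by its generation's bull panel ("winner's curse");
  the relative-metric era mitigates but does not remove this.
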