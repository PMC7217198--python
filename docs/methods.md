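# Methods

## Model and statistics

Outcomes are binary per patient. For a pair of arms (i, j) with
cumulative counts (nᵢ, Sᵢ), (nⱼ, Sⱼ), the log-odds ratio
θᵢⱼ = log{pᵢ(1−pⱼ)/[pⱼ(1−pᵢ)]} is summarised by the efficient score
Z = (nⱼSᵢ − nᵢSⱼ)/(nᵢ+nⱼ) and Fisher information
V = nᵢnⱼ(Sᵢ+Sⱼ)(n−Sᵢ−Sⱼ)/n³, n = nᵢ+nⱼ. For small θ, E(Z) ≈ θV and
var(Z) ≈ V, and on nested data Z behaves like a Brownian motion with
drift θ observed at information times V — the basis of both the
straight-line boundaries and the analytic conditional calculations. In
stratified trials Z and V are computed within stratum and summed.

## Designs

A design is a `PairwiseBoundary` (intercept a, elimination slope
b_outer, inner slope b_inner) plus accrual rules. Symmetric
(double-triangular) rules eliminate j when Z ≥ a + b_outer·V, eliminate
i when Z ≤ −(a + b_outer·V), and declare the pair no different inside
the open interval (−(b_inner·V − a), b_inner·V − a), nonempty only once
V > a/b_inner. One-sided rules (the two-arm triangular test) stop for
efficacy at Z ≥ a + b_outer·V and for "no better" at
Z ≤ −a + b_inner·V; the boundaries meet at V = 2a/(b_inner − b_outer).
Elimination comparisons are inclusive; the no-difference interval is
open; a point with V = 0 carries no information and continues. If,
past the meeting point, both one-sided conditions hold, the efficacy
boundary takes precedence (arbitrary but fixed; only overshoot
pathologies reach it).

Three presets are shipped:

| preset | arms | a | b_outer | b_inner | per-arm/interim | cap |
|---|---|---|---|---|---|---|
| `four_arm_sepsis` | 4 | 10.90266 | 0.12380 | 0.37140 | 36 | 2772 |
| `two_arm_tri` | 2 | 10.93898 | 0.123134 | 0.369402 | 36 | 25 interims |
| `four_arm_simple` | 4 | 4.9261 | 0.2470 | 0.7411 | 32 | 640, 8 interims |

Boundary constants are configuration, not derived here: computing
(a, b_outer, b_inner) from error-rate requirements is out of scope.
The two-arm design plans 20 interim analyses (nominal information
increment 4.4419, apex 88.8380) and extends to 25 when no boundary has
been crossed.

## Trial engine

At each interim the engine adds the per-arm increment of binomial
responses for every active arm (multinomially split over centres with
equal probabilities in the stratified case), classifies every active
pair on the same cumulative data, and eliminates every arm found worse
than any other — simultaneously, so an arm can be removed by an arm
that is itself removed at that interim, since the rule quantifies over
"any other" arm with no sequencing. The trial stops with a sole winner
when one arm remains, with joint winners when every remaining pair is
no different, and unresolved either before an interim that would push
the total over the cap or past the maximum number of interims. An
eliminated arm's history is frozen at its last interim. A single seeded
`numpy` generator drives each run; the draw order (arms in index order,
centre allocation before responses) is fixed, so identical seeds give
identical histories.

Where an arm is said to be "eliminated by" another and several arms
crossed the boundary against it at the same interim, the recorded
eliminator is the one with the largest boundary overshoot; the full
pairwise decision log is what downstream consumers rely on.

## Reverse-simulation Rao-Blackwellization (RB2)

θ̂₁ = Z₁/V₁ from the first interim analysis is unbiased; its
conditional expectation given the terminal per-arm, per-stratum counts
is evaluated by Monte Carlo:

1. *Back-sampling*: per arm and stratum, from the anchor interim
   backwards, Sₖ | Sₖ₊₁ ~ Hypergeometric(nₖ₊₁, Sₖ₊₁, nₖ). Anchors are
   each arm's last interim; under Option 2 (pairwise comparisons
   restricted to data collected while both arms were in contention)
   each pairwise analysis anchors every arm at the earlier of the
   pair's comparison interim and the arm's own last interim, so a
   four-arm trial with staggered eliminations needs up to three
   separate reverse-simulation starts. Option 1 uses one start (each
   arm at its own last interim) and serves all pairs with a single
   replicate set.

2. *Consistency filtering*, at every interim before the latest anchor:
   for each pair of arms then remaining, a replicate is deleted if it
   produces an elimination that did not happen, fails to reproduce one
   that did, or (when an arm actually fell to a third arm) resolves a
   pair that stayed open; a replicate in which all remaining arms would
   have stopped as no different is also deleted. For the two-arm test
   this reduces to (Zₖ, Vₖ) strictly inside the continuation region for
   every k before the stopping analysis — boundaries are inclusive
   stopping sets, so a replicate landing exactly on one is deleted.
   Filtering always uses the plain information V, as during the trial.

3. *Moments*: θ̃ is the mean of θ̂₁ over consistent replicates,
   var(θ̂₁|data) their (unbiased-divisor) variance, and
   SE = √(E[1/V₁] − var(θ̂₁|data)), with 95% interval θ̃ ± 1.96·SE.
   Because V₁ varies across replicates, E[1/V₁] is estimated by the
   mean reciprocal first-interim information over the same replicates;
   this is the natural Monte Carlo reading of the variance
   decomposition and reduces to 1/V₁ when V₁ is constant. A negative
   radicand yields `se=None` with the diagnostic pieces reported —
   never a silent NaN. Replicates with zero first-interim information
   for a pair are excluded from that pair's moments.

In the stratified case the per-stratum information entering the
estimate and SE (only) is the small-sample adjustment
V′ = V·n/(n−1): within-centre first-interim samples are small, and
E(Z) tracks θV′ and var(Z) tracks V′ more closely than V, which keeps
the estimates nearly unbiased and the SE radicand positive.

Replicates are generated in chunks (default 250 000) to bound memory,
all chunks drawn from one seeded generator in a fixed order. Analyses
with fewer than 1000 consistent replicates (configurable) are flagged
unreliable, and the evaluation harness drops them from aggregates,
reporting the exclusion count.

## Analytic two-arm Rao-Blackwellization (RB1)

For the two-arm test the conditional law of Z₁ given the stopping
interim n and terminal score can be computed under the canonical normal
model (independent increments N(θΔV, ΔV)). With the n-th continuation
region pinched to (z_n − δz, z_n + δz), the survivor ratio
S(t) = P(Z₁ > ℓ₁ + t | stop at n near z_n) is a ratio of two
continuation probabilities in which the likelihood factor
exp(θz − θ²V/2) cancels, so everything is evaluated at θ = 0; the
conditional moments follow from E[Z₁−ℓ₁|·] = ∫S dt and
E[(Z₁−ℓ₁)²|·] = 2∫tS dt. Continuation probabilities are computed by
backward recursion of the pinch-reaching probability through the
normal increment kernel on a uniform grid per continuation interval
(default 400 points, trapezoidal quadrature; δz = 0.01; 100-point
t-grid with S(0) = 1 prepended). Doubling all grids moves the worked
estimates by < 10⁻³.

The recursion needs information values at every interim, but the
estimator should depend only on the analyses actually performed. The
default places the realized terminal information V* on an equally
spaced schedule Vₖ = k·V*/n. This choice matters: with the design's
nominal schedule the boundaries sit at the wrong information levels
relative to the data whenever accrual of information ran behind or
ahead of plan (e.g. pooled success rates far from ½), and the computed
adjustment is badly attenuated — on the stored two-arm worked cases it
disagrees with the reverse-simulation estimate by up to 0.13, whereas
with the realized schedule the two methods agree to ≤ 0.02 everywhere
and the analytic route reproduces its published behaviour. The nominal
schedule, and fully explicit schedules, remain available via arguments.
RB1 does not generalize beyond two arms (there is no scalar statistic
to recurse over); that is the role of RB2.

## Synthetic data and what the tests show

All evaluation data are generated by the trial engine itself: binomial
responses at configured success probabilities, optionally multinomially
scattered over equal-probability centres. This emulates the trials the
design targets — instantaneous binary responses, equal per-arm accrual
between analyses, exchangeable patients within stratum. It does not
emulate delayed responses, drift in recruitment, unequal per-arm
accrual, or centre-size imbalance, so passing tests demonstrate
correctness of the procedures under the design's own model, not
robustness to those complications.

Scenario probabilities follow the published design evaluations: the
four-arm designs at probabilities around ½ with odds ratios 1.5 (or
2.25 for the small design) between good and poor arms; the two-arm
test at control rate 0.6 with θ ∈ {0, log 1.5}.

## Problem sizes

Desk-scale defaults, chosen to keep the full suite and the acceptance
script to a few minutes while leaving Monte Carlo error well inside the
decision tolerances: 10 000 replicates for operating characteristics
(MC SE ≤ 0.005 on a proportion), 150 000–200 000 reverse simulations
for single worked-example analyses, 200 trial replicates × 50 000
reverse simulations for estimator sampling properties. The library
accepts full-scale values (10⁶ trial replicates, 10⁷ reverse
simulations) through the same interfaces.

## Known limitations

* RB2 confidence intervals rely on a normal pivot and on estimating
  E[var(θ̂₁|data)] by its observed value; they are conservative
  (coverage ≈ 0.97 at nominal 0.95) rather than exact.
* The SE can be undefined (negative radicand) in small-information
  analyses; the stratified V′ adjustment largely, but not entirely,
  prevents this.
* Consistency filtering can leave very few replicates when the trial
  stopped against the run of the back-sampled paths (completeness ~2%
  in one worked comparison); results below the reliability threshold
  should be rerun with more reverse simulations rather than trusted.
* The engine stops, rather than re-plans, at the sample-size cap;
  partial conclusions at an unresolved stop are recorded in the
  decision log but not adjudicated.
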