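# Methods

This note documents the model, the constrained stimulus design, the scoring
statistics, the simulator's free parameters, and the numerical choices made
where the design was genuinely open. Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The naive sampling model and its eager comparator

The simulated judge stores every presented value as a raw exemplar,
together with its presentation position, and performs no computation during
exposure. When queried, it retrieves a sample of `k` exemplars into
short-term memory and computes the requested statistic on that sample.
The model's behavioral signature follows from sampling theory alone:

* **means are unbiased** under uniform retrieval, so central-tendency
  estimates scatter around the truth;
* **dispersion is biased low**: for a sample of size `k` the expected mean
  absolute deviation is strictly below the population MAD (the suite checks
  this both by exhaustive enumeration of all C(10, 4) subsamples of a
  10-exemplar memory and by Monte Carlo through the retrieval path);
* **order is invisible**: if retrieval probability does not depend on
  encoding position, presentation order cannot reach the judgment.

Retrieval weighting is geometric: under a recency policy, the exemplar at
position `t` of `N` carries weight `decay^(N−t)`; under primacy,
`decay^(t−1)`; `decay = 1` recovers uniform retrieval for every policy.
Sampling is **without replacement** within a query — an exemplar already
active in STM is not retrieved twice; a with-replacement switch exists for
sensitivity analysis. `k` defaults to 4 (the STM estimate of 4 ± 2);
an optional jitter flag draws a per-participant `k` uniformly from 2..6.

The eager comparator maintains exponentially weighted running estimates,
`m ← m + η(x − m)` then `v ← v + η((x − m)² − v)` with the updated `m`.
With a fixed `η` the estimator is initialized at the first observation (so
constant streams are tracked exactly) and its endpoint overweights late
arrivals; with the harmonic schedule `η_t = 1/t` the final running mean
equals the exact sample mean.

### Filling a histogram from a 4-item sample

A single STM sample cannot fill a 120-count histogram. The simulant pools
`n_pools` independent retrievals (default **5**, i.e. about 20 values
feeding a shape judgment) and rescales the pooled empirical decile
proportions to the required total by largest-remainder rounding. The
pooling count is the one genuinely free "response granularity" parameter of
the simulator; it trades response noise against effective sample size and
is exposed in every simulation entry point. Five pools keeps single-judge
histograms visibly noisy (as small-sample judgments should be) while group
means of ~14–16 judges stabilize to within a few hundredths of SI.

### Task decision rules

* **Identification**: choose the prototype whose decile profile minimizes
  Euclidean distance to the pooled remembered profile; exact ties break
  toward the uniform prototype, then the lower index.
* **Sampling task**: greedy subset construction — repeatedly add the matrix
  value whose inclusion minimizes the Euclidean distance between the
  selection's decile profile and the remembered profile, until 10 values
  are chosen. The rule sees only decile membership, never whether a value
  was actually presented, so the old/new contrast is null by construction.
* **Descriptive estimates**: one fresh retrieval per queried statistic
  (mean, median, MAD), each computed directly on its own sample. Optional
  zero-mean Gaussian report noise (SD in rating units, default 0) can be
  added on top.

## Stimulus design

Two 120-value sets are drawn uniformly within each decile of [1, 1000],
without replacement, with exactly 12 values per decile — uniform at decile
resolution by construction. The withheld set `T` is drawn from the integers
not used by `E` so the two sets are disjoint (required for the old/new
manipulation to be meaningful).

The unimodal half `E_a` is built by integerizing the Beta(2.4, 2.4) decile
probabilities to 60 counts via largest-remainder rounding — yielding
(1, 4, 6, 9, 10, 10, 9, 6, 4, 1) — and drawing that many members uniformly
from `E` within each decile. `E_b` takes the complement, so the two halves'
counts sum to 12 in every decile ("reflection about uniform") and the
Shape Indices of the two halves are exact mirror images (±0.3833 on the
count profiles under the default configuration). A Beta shape so peaked
that a decile would need more than 12 values is rejected. The within-decile
membership draw is the only stochastic element of the partition; the count
structure is deterministic.

Each sampling-task matrix holds 30 values, 3 per decile; the four matrices
of one provenance partition their 120-value source set exactly. The seven
identification prototypes are a symmetric Beta(a, a) family: uniform
(a = 1), unimodal a = 2, 4, 8 (strictly decreasing variance), bimodal
a = 0.8, 0.5, 0.3 (strictly increasing variance); the constructor verifies
the variance orderings numerically and the shapes are configurable.

## The Shape Index

`SI = Σᵢ sᵢ(xᵢ − pᵢ)` over the ten decile bins — the minimal signed-sum
form with the required behavior: zero at the normative uniform profile,
positive for unimodal-leaning and negative for bimodal-leaning judgments,
and insensitive to the two excluded bins. The sign vector is derived, not
hard-coded: 0 on excluded bins, +1 where the Beta(2.4, 2.4) decile mass
exceeds 0.1, −1 elsewhere, which orients SI(E_a) positive by construction.

The default exclusions are the 301–400 and 801–900 intervals (bins 4
and 9). That pair is asymmetric about the midpoint; because a symmetric
design (bins 4 and 7, i.e. 301–400 with 601–700) is what the
shape-uninformative rationale suggests, a `SYMMETRIC_CONFIG` variant is
provided — but the asymmetric pair remains the default for fidelity to the
measure as published. Note that anti-symmetry of SI under profile
reflection (`SI(2p − x) = −SI(x)`) holds for *any* sign vector by
linearity, so the choice does not affect the mirror-image property.

Task instantiations: production divides the reported frequencies by their
required total (120); identification scores the chosen prototype's profile;
the sampling task scores the empirical profile of the selected values (per
trial, and pooled over all trials for the task-level score). Counts and
proportions give identical SI to 1e−12.

Descriptive accuracy uses signed (`e_s − n_s`) and absolute (`|e_s − n_s|`)
deviation against the normative statistics of the exposure set. Mean and
median deviations are collapsed into one central-tendency measure by
averaging the signed deviations and averaging the absolute deviations
(rather than recomputing the absolute from the collapsed signed value, which
would let opposite-signed errors masquerade as accuracy). An optional
IQR-based outlier screen exists and is **off** by default.

## Analysis layer

The split-plot ANOVA computes the classical sums-of-squares decomposition:
the between effect over the subjects-within-groups stratum, the within main
effect and interaction over the subject × within residual. Requirements and
edge cases: every subject must have exactly one observation per within
level (missing cells raise with an explicit message); group sizes may
differ slightly; a constant dependent variable yields F = 0 exactly; a
single-level within factor reduces the computation to a one-way ANOVA; and
strata with zero error degrees of freedom are omitted rather than reported
as undefined ratios. Sphericity corrections are not applied — the
within factors in scope have two or three levels and the analyses are
reported as plain F tests. The suite cross-checks the implementation
against an independent general-purpose implementation (pingouin) and a
hand-worked decomposition.

Between-subjects power uses the noncentral F distribution with
`λ = n(k−1)·RMSSE²`, where RMSSE is the root-mean-square standardized
effect across the k group means. Power conventions differ across texts
(some use `λ = nk·f²` with Cohen's f); the RMSSE convention is documented
here prominently because it is the one this package implements and tests
(k = 3, n = 16, RMSSE = .5, α = .05 → 0.686; verified against a 10⁶-draw
Monte Carlo of the noncentral F). Power at RMSSE = 0 equals α exactly.

The first/last-quarter order analysis compares each participant's mean
estimate with the mean of their own first 30, last 30, and all 120 values;
the partition size is a parameter so other splits can be examined.

## Experiment orchestration

Both experiments share materials across participants but give each
participant an independent presentation order. Randomness is organized as
one `SeedSequence` per run, spawning one child per participant, so any
participant is reproducible in isolation and identical configs produce
bit-identical output tables. Experiment 2 interrupts exposure after 60
values for a production-only intermediate test; the final test instructs
(and here simply lets) the judge sample from all 120 exemplars.

Design choices with no behavioral consequence in the simulant are recorded
but inert: task order is counterbalanced as a label only (no carry-over is
modeled), and an optional anchor-and-adjust variant blends the final
production histogram toward the intermediate one with weight `w`
(default 0, i.e. off) to make anchoring hypotheses expressible.

## Problem sizes used in the checks

The automated checks run at sizes chosen to make the Monte-Carlo error
comfortably smaller than the asserted margins: 10⁴ simulants for mean
unbiasedness (≈3 SE band), all 210 subsamples for the exact MAD-bias
enumeration, 500 replicate experiments for the null-calibration rejection
rate (3σ binomial band around .05), 150 judges per order condition for the
recency sign flip, and three independently seeded replications of the full
n = 14-per-condition Experiment 2 for the crossover pattern.

## What the generator does and does not emulate

The synthetic participants implement the lazy sampling mechanism exactly
and nothing else: no perceptual encoding noise, no forgetting, no
anchoring (unless enabled), no individual differences beyond optional k
jitter, and no strategic response policies. Passing tests therefore show
that the *mechanism* produces the qualitative pattern — order-null under
uniform retrieval, order effects under biased retrieval, unbiased means,
underestimated variability, intermediate/final crossover — not that humans
implement it. Human group means carry sources of variance this generator
deliberately omits, so quantitative agreement with any particular observed
sample is out of scope.

## Known limitations

* The Shape Index is blind to skew by design; strongly skewed judged
  profiles can score near zero.
* The greedy sampling-task rule is locally optimal per addition but not
  guaranteed globally optimal for all remembered profiles.
* The mixed ANOVA targets the balanced split-plot design; heavily
  unbalanced between-group counts are outside its intended use.
* Recency/primacy weighting is geometric in position; serial-position
  curves with both primacy and recency components are not representable by
  a single policy.
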