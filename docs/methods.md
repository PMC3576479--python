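# Methods

## The inferential model

A two-arm randomized trial is represented as outcomes *Y* (one or more
endpoint columns, continuous or binary, with explicit missing values) and an
assignment vector *Z* with labels T and C.  A permutation test conditions on
*Y = y*; the only remaining randomness is *Z*, uniform over the set of
assignment vectors consistent with the randomization scheme — the per-arm
counts, per enrollment stratum when per-arm counts were known at an interim
look.  The p-value is the fraction of consistent vectors whose statistic is
at least as favorable to treatment as the observed one (ties at the
observed value count as extreme).

The quantity the package is built around is the **conditional type I error
rate**: the probability of rejection given the information available when an
adaptation could be made.  For the permutation test at level α this is the
*attainable size* — the fraction of consistent assignments with p ≤ α —
which is ≤ α for every outcome vector, every scheme and every α, because
p-values are uniform ranks over the same finite set.  Any adaptation that is
a deterministic function of the blinded (lumped) data therefore leaves the
conditional error controlled, provided the strong null holds for everything
the rule examined.  The contrapositive is equally important and equally
implemented: when the rule effectively sees assignment information (a
drug-level endpoint, correlations with it, per-arm counts), the guarantee
degrades to "treatment affects at least one variable examined", and the
simulation laboratory quantifies the resulting inflation for the endpoint
actually tested.

## Test statistics

All statistics are pure functions of (outcome vector, boolean treated
mask), available-case on missing values, and carry a declared orientation
(whether smaller or larger values favor treatment) so that sign conventions
survive mid-analysis statistic switches:

- `diff_means` — mean(T) − mean(C);
- `diff_props` — the same on {0,1} data (validated);
- `wilcoxon` — treated-arm rank sum with mid-ranks for ties;
- `signed_rank` — paired signed-rank statistic for crossover differences;
  exact zero differences are excluded before ranking, and all-zero data
  raise a *degenerate statistic* signal (the engine converts it to p = 1
  with a flag rather than an error);
- `abs_diff_means` — two-sided testing via the direction-free magnitude.

The number of subjects excluded per arm by the available-case rule is
exposed (`available_counts`) because differential missingness is itself an
information channel: a trial with missing data examines strictly more
variables than its named endpoints.

## The engine

Exact mode has two routes, chosen automatically:

1. **Explicit enumeration** of consistent assignment vectors (per-stratum
   combinations, cartesian across strata), capped at 10⁶ vectors.  For
   *linear* statistics — those of the form "monotone function of the sum of
   a weight vector over treated subjects": mean/proportion differences
   (weights = outcomes) and the rank sum (weights = mid-ranks) — the
   statistic over all vectors is a single matrix product; other statistics
   are evaluated in a loop.  Below 10⁵ vectors this route is used even for
   linear statistics because it is faster in practice.
2. **Subset-sum convolution** for linear statistics on complete data: the
   null distribution of the treated weight sum is built per stratum by
   dynamic programming over distinct-value classes (the multivariate
   hypergeometric structure) and convolved across strata, with exact
   integer counts.  For binary outcomes this reproduces the
   product-hypergeometric distribution and has no practical size limit;
   it is what makes exact stratified Fisher-type tests on the extended
   designs of the sample-size adversary feasible.  Agreement of the two
   routes is a tested invariant.

Monte-Carlo mode samples consistent vectors uniformly (seeded shuffles
within strata; for linear statistics a vectorized uniform-subset draw via
partial sorting of i.i.d. uniforms, which is distributionally identical)
and uses the add-one estimator p = (1 + #extreme)/(1 + B), which cannot
report p = 0 and keeps the test valid at any B.

Numerical choices: ties with the observed statistic are detected with a
relative tolerance of 10⁻¹², and weight sums are rounded to 12 decimal
places before being used as distribution keys, so that the DP, matrix and
loop routes agree bitwise on their p-values.  One-sided tests are the
default; two-sided testing is a separate magnitude statistic rather than a
p-doubling rule, so the permutation distribution remains exact.

`fisher_exact_one_sided` is computed from the hypergeometric tail
(scipy) rather than through the engine, deliberately: the engine/Fisher
equivalence is then a two-route cross-check, exhaustively verified for all
2×2 tables with n ≤ 12.

## Blinded views and adaptation rules

`BlindedView` is the only access path a rule has.  It exposes pooled
outcome values (rows re-ordered by a keyed permutation whose key is a
digest of the lexicographically sorted rows — deterministic, label-free,
and destroying enrollment order as a side channel), per-endpoint missing
counts (totals, never per arm), the total n, and per-stratum totals (never
per-arm counts; when those are known, stratification in the engine — not
the view — is the remedy).  Two trials differing only by an arm relabeling
produce identical views; this is enforced by property tests over random
fixtures for every shipped rule.

Rules are deterministic mappings (view, plan) → plan.  The plan's α is
immutable under adaptation; endpoint, statistic and derived-endpoint
threshold are the only degrees of freedom.  Every rule declares which view
components it reads, and the decision record repeats the declaration so the
honest conclusion ("no effect on any of: …") is auditable.  Shipped rules:

- `min_variance` — select the candidate endpoint with the smallest lumped
  (available-case, ddof = 1) variance; ties break by candidate order.
- `outlier_switch` — switch a planned mean-difference test to the rank sum
  when any lumped value lies more than k (default 5) scaled median absolute
  deviations from the lumped median; when the MAD is zero on non-constant
  data an IQR-fence criterion is the fallback.  The outlier criterion is a
  design choice — any deterministic blinded criterion preserves validity —
  and k is exposed as a parameter.
- `threshold_feasibility` — for a binary endpoint derived as
  1[y ≥ threshold]: from the lumped event total m, the smallest attainable
  one-sided Fisher p (all m events in the unfavorable arm) is computed; if
  even that exceeds α the endpoint is re-derived at a fallback threshold.
  Per-arm design sizes enter as design knowledge, not data.
- `drug_level_adversary` (adversarial, warns on use) — reconstructs arm
  labels from a positive-in-treated-only drug level and picks the clinical
  endpoint with the more treatment-favorable statistic.
- `correlation_leak` (adversarial) — reads only the two lumped
  correlations between drug level and the clinical endpoints, a summary
  measure that nonetheless reproduces the row-level adversary's choice
  whenever the drug level separates the arms.

`run_adaptive_analysis` wires view → rule → engine (stratified whenever the
trial has more than one stratum) and emits the decision record.

## Conditional error for two-stage binary designs

`conditional_rejection_probability` takes an interim state (first-stage
per-arm counts and events, planned second-stage counts, event
probabilities, α) and enumerates **all second-stage outcome vectors**
(2^(n_T2+n_C2), capped at 2²⁰, with a seeded Monte-Carlo fallback that
reports its standard error), weighting each by its Bernoulli probability
and summing the indicator that the final unstratified Fisher-equivalent
permutation test rejects.  Enumeration rather than a closed form is
deliberate: the cube-law special case (first stage 0 T / 3 C, all events;
probability (1 − p_T)³) is then a recovered result, not an input, and the
same code covers every small design.  A count-grouped version (binomial
weights over second-stage event counts) is used by the simulation
adversary for speed; its equality with the vector enumeration is a tested
invariant, as is the law-of-total-probability identity that integrating
the conditional probability over first-stage outcomes recovers the
design's unconditional size.

`conditional_error_of_fixed_design` evaluates any test — the permutation
statistic itself, or an approximate test supplied as a p-value callable —
over the uniform distribution of consistent assignments given the lumped
outcomes.  The shipped approximate test is the pooled two-proportion
z-test, whose conditional error on small samples can reach 0.2 at nominal
0.05; `switching_adversary` formalizes the keep-if-inflated / switch-if-
deflated strategy whose no-change branch is exactly what exceeds α when
the original test was not the permutation test.

## The simulation laboratory

Scenarios couple a generator configuration, a rule, an original plan and a
null structure.  Replicates use independent RNG streams seeded by
(seed, replicate index), so results are reproducible and insensitive to
execution order.  The default is 10,000 replicates (Monte-Carlo SE ≈ 0.0022
at a rate of 0.05), enough to separate the nominal level from meaningful
inflation at desk scale.  Under a weak null (treatment affects some
endpoints but not others) a rejection counts as a type I error only when
the endpoint actually tested is truly null; branch frequencies record which
adaptation was taken.

**Sample-size adversary (per-arm counts known).**  Two-stage 3-per-arm
binary design, complete randomization in random enrollment order, interim
after three patients, strong null at event probability 0.5.  The adversary
keeps the planned design whenever its conditional rejection probability is
positive, and otherwise extends the second stage to the design maximizing
that probability, within a cap (default 150 extra patients).  The cap is
large by design: the conditional error of a small-sample Fisher test is
heavily quantized, so small extensions cannot push the zero-probability
branches anywhere near α — with a cap of 18 the plain test's overall rate
is ≈ 0.039, still below the nominal 0.05, and only around a cap of 80 does
it cross α (≈ 0.052), reaching ≈ 0.057 at the default 150.  Because the
maximizing design essentially always spends the whole budget, the search
considers every arm split but only extension totals within 8 of the cap
(plus the planned design); this matches the full search at the caps
examined and keeps the interim-state decision table cheap.  Both final
analyses are applied to the same simulated trials: the plain permutation
test, whose type I error the strategy inflates above α, and the stratified
test, which conditions on the per-arm counts the adversary used and stays
below α.  In the *unextended* design the stratified test's rate is exactly
0: with interim strata of three patients the richest consistent set has
3 × 3 = 9 assignments, so the smallest attainable p is 1/9 > 0.05.  That
degenerate-looking number is the point — conditioning on what the adversary
knew removes exactly the randomness the adversary could exploit, and with
six patients nothing is left.

**Drug-level selection study.**  Global strong null with two exchangeable
continuous clinical endpoints and a perfectly separating drug level,
5 per arm, exact rank-sum tests.  With tie-free data the rank-sum p-value
is a fixed monotone function of the statistic, so choosing the endpoint
with the more favorable statistic is identical to choosing the smaller
p-value; the study therefore reports the min(p₁, p₂) ≤ α rejection rate as
an independent oracle (computed by direct engine calls, not through the
adaptation machinery) alongside the adversary's measured rate, plus the
fixed design's rate as the baseline.

## The synthetic-trial generator

Endpoints are drawn from a Gaussian copula: a latent multivariate normal
with a configurable cross-endpoint correlation matrix (validated symmetric
PSD with unit diagonal), mapped per endpoint to its margin — Gaussian with
arm-specific means and common SD, Bernoulli via the normal CDF threshold
with arm-specific event probabilities, or a log-normal drug level that is
positive for treated subjects and exactly zero for controls.  Missingness
is independent Bernoulli per endpoint with arm-specific rates, because
arm-dependent missingness is precisely the mechanism that breaks the
two-outcome no-inflation result; the suite records (and does not bound)
the rejection rate under informative missingness.  Arm labels are shuffled
within each stratum so enrollment position carries no information.

Defaults used by the studies, chosen once as ordinary values for a
small-trial methods experiment and documented rather than tuned: unit-SD
Gaussian endpoints, a treatment effect of one SD on the affected endpoint
in weak-null scenarios (with latent correlation 0.3 between the two
candidates), event probability 0.5 in the binary design, 5 per arm for
selection studies (keeping every per-replicate test exact), 3 per arm for
the two-stage design.

What the generator does not emulate: real blood-pressure scales or event
rates from any particular trial, survival/longitudinal outcomes, more than
two arms, covariate-adaptive randomization, and structured (non-Bernoulli,
outcome-dependent) missingness.  Passing tests show the mathematical
guarantees hold under the stated sampling models; they do not certify any
specific clinical data-generating process.

## Known limitations

- Conditional error computations cover binary outcomes only; continuous
  outcomes would require distributional assumptions the framework avoids.
- The treatment-effect *estimate* after an unplanned adaptation remains
  potentially biased; the package controls error rates, not bias, and no
  adjustment is attempted.
- The stratified engine conditions on per-stratum arm counts; richer
  restricted randomization schemes (blocking, minimization) are out of
  scope.
- Confidence intervals by test inversion are not provided.
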