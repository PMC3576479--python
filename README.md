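# blindadapt

Valid inference after **unplanned, pre-unblinding adaptations** in randomized
two-arm clinical trials.

Sometimes a trial goes wrong before anyone has looked at unblinded data: the
planned primary endpoint turns out to be measured unreliably, outliers
undermine the planned *t*-test, or so few events occur that the planned test
of proportions cannot possibly reach significance.  If the change is decided
*while the treatment blind is intact*, a permutation (randomization) test of
the modified analysis still controls the type I error — and this package
implements that machinery end to end, together with the counterexamples that
mark the boundary of what it can and cannot guarantee.

## Who it is for

Biostatisticians designing or reviewing adaptive analyses, and
methodologists who want a laboratory for conditional type I error behavior
under blinded adaptation rules, including deliberately adversarial ones.

## The core idea

A permutation test conditions on the outcome data *Y = y* and treats every
treatment-assignment vector *z* consistent with the randomization scheme (a
*consistent z*) as equally likely.  The p-value refers the observed
statistic *t*(*y*, *z*) to its distribution over all consistent *z*.  Any
adaptation decided from the lumped (blinded) data *X* is a function of *X*
alone; under the strong null hypothesis — treatment affects nothing that was
examined — *X* is independent of *Z*, so the test's **conditional type I
error rate given the adaptation** never exceeds the nominal level α.  Key
consequences implemented and tested here:

- *Fisher equivalence* — with a binary outcome the permutation test of the
  proportion difference is exactly the one-sided Fisher exact test.
- *Attainable size* — the fraction of consistent assignments with p ≤ α is
  the test's conditional size given *y*; it is ≤ α for every *y*, scheme
  and α.
- *Large-sample near-identity* — on 100-per-arm Gaussian data the
  permutation p-value and the pooled-variance *t*-test p-value differ by
  less than 0.01, which justifies treating the permutation test as if it
  had been planned all along.
- *Partial blinding needs stratification* — when per-arm counts were known
  at the time of adaptation, only the **stratified** permutation test
  (restricted to assignments preserving per-stratum arm counts) keeps the
  conditional error controlled; the package includes the two-stage
  sample-size adversary that inflates the plain test above α while the
  stratified test stays below.
- *The conclusion degrades with what was examined* — an adversarial rule
  that reconstructs arm labels from a drug-level endpoint inflates the
  false positive rate for the chosen endpoint to that of min(p₁, p₂); the
  honest rejectable hypothesis is only "treatment affects at least one
  variable the rule examined", and every decision record lists those
  variables.

## Worked example

The 6-patient binary design, one-sided α = 0.05, fewer events favoring
treatment.  All three control patients had events; none of the three
treated patients did:

```python
import numpy as np
from blindadapt import (InterimState, conditional_rejection_probability,
                        get_statistic, permutation_pvalue,
                        stratified_permutation_pvalue)

y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
z = np.array(["C", "C", "C", "T", "T", "T"])
stat = get_statistic("diff_props", "smaller")

res = permutation_pvalue(y, z, stat)
print(f"observed diff in proportions: {res.observed_statistic:+.3f}")
print(f"exact p-value: {res.p_value:.3f}  ({res.n_permutations} consistent assignments)")
print(f"attainable p-values: {res.attainable_p}")
```

```
observed diff in proportions: -1.000
exact p-value: 0.050  (20 consistent assignments)
attainable p-values: (0.05, 0.5, 0.95, 1.0)
```

Exactly 1 of the C(6,3) = 20 consistent assignments puts all three events
in one arm, so the result is significant at 0.05 — and the attainable-p
grid shows 0.05 is the smallest p this data set can produce.

Now suppose the first three patients were all, by chance, assigned to
control, and this was *known* when an adaptation was contemplated.  The
plain test above ignores that knowledge; the stratified test conditions
on it:

```python
stratum = np.array([1, 1, 1, 2, 2, 2])   # enrolled before / after the look
strat = stratified_permutation_pvalue(y, z, stat, stratum)
print(f"stratified p-value: {strat.p_value:.3f}  ({strat.n_permutations} consistent assignment)")

state = InterimState(n_T1=0, n_C1=3, events_T1=0, events_C1=3,
                     n_T2=3, n_C2=0, p_T=0.5, p_C=0.5, alpha=0.05)
ce = conditional_rejection_probability(state)
print(f"conditional rejection probability: {ce.probability:.3f} ({ce.method})")
```

```
stratified p-value: 1.000  (1 consistent assignment)
conditional rejection probability: 0.125 (exact)
```

Only one assignment is consistent with 0 T / 3 C before and 3 T / 0 C
after the look, so the stratified distribution is degenerate and p = 1:
the "significant" plain result was an artifact of ignoring the per-arm
counts.  The conditional probability that the *original* design rejects,
given the interim data, is (1 − p_T)³ = 0.125 at p_T = 0.5 — far from
0.05 — which is the information an adversary could exploit and the
stratified test neutralizes.

A command-line interface mirrors the library:
`blindadapt generate`, `blindadapt permtest`, `blindadapt adapt`,
`blindadapt conderror`, `blindadapt simulate` (see `--help`).

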