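# pairmhn

Mutual Hazard Networks for the **joint progression of primary tumors and
their metastases**, learned from cross-sectional clinical sequencing
cohorts.

Clinical panels routinely produce binary event profiles (driver mutations,
copy-number gains and losses) for primary tumors and, less often, for a
matched metastasis. `pairmhn` models how these events accumulate in both
lesions at once: before the metastatic *seeding* event the two share one
genotype; after seeding they diverge and evolve independently, with the
metastasis experiencing its own environment. Clinical detection of each
tumor is part of the model, so the data's observational filter — you only
ever see a tumor at its diagnosis — is handled inside the likelihood
rather than ignored. The package is for computational biologists who want
to infer event interactions, event–seeding interactions, and the relative
timing of seeding from cohorts of paired and unpaired samples.

## Model

A system with `n` events is a continuous-time Markov chain on bit strings
`(x1P, x1M, …, xnP, xnM, xseed)` of length `2n+1`. All rates derive from a
log-parameter matrix `θ ∈ R^{(n+1)×(n+1)}` (with `Θ = exp(θ)` entrywise;
index `n+1` is the seeding event) and two observation-effect vectors
`ωP, ωM`:

- **before seeding** event `i` occurs jointly in both lesions at rate
  `Θii · ∏_{j shared} Θij`, and seeding itself at rate
  `Θss · ∏_{j shared} Θsj`;
- **after seeding** the primary gains event `i` at
  `Θii · ∏_{j∈PT} Θij` and the metastasis at
  `Θii · (∏_{j∈MT} Θij) · Θis`, where `Θis` is the environment effect of
  seeding on event `i`;
- the primary is detected at rate `∏_{j∈PT} ΩPj` (times `ΩPs` once
  seeded), the metastasis — only after seeding — at
  `ΩMs · ∏_{j∈MT} ΩMj`. The wild-type detection rate is the empty
  product, 1, which fixes the time unit.

Detection is absorbing for the whole system; the state distribution at
first observation is `UP(US−Q)⁻¹ p0` / `UM(US−Q)⁻¹ p0` for the two
channels. A later second observation is modeled by conditioning on the
first observed genotype and propagating the still-unobserved lesion with
its own restricted dynamics, `UM(UM−QM)⁻¹`. This yields exact
probabilities for the five kinds of records a cohort contains: pairs with
either observation order, pairs with unknown order, primary-only samples
(with metastasis status absent / present / unknown), and metastasis-only
samples. Parameters are estimated by maximizing the mean log-likelihood
minus `λ` times a group-sparsity penalty
`∑_{i<j} √(θij² + θji² − θij·θji) + ∑_j (|ωPj| + |ωMj|)`,
with `λ` selected by patient-level 5-fold cross-validation.

Per-sample likelihoods are computed on restricted state spaces whose cost
is exponential only in the number of events *present in that sample*, with
analytic gradients from adjoint solves; a dense full-state-space oracle
(for small `n`) backs every fast path in the test suite.

## Worked example

```python
import numpy as np
from pairmhn import EventSystem, ParameterSet, LOG_RATE_FLOOR, Sample, sample_probability

params = ParameterSet.zeros(1)          # one event, all effects neutral
params.theta[1, 1] = LOG_RATE_FLOOR     # seeding disabled
params.theta[0, 0] = np.log(3.0)        # event base rate 3x the detection rate
p = sample_probability(params, EventSystem(1),
                       Sample("demo", pt=[1], seeding_evidence="unknown"))
print(p)                                # 0.7500000000000002
```

The printed value is the probability that the event is present when the
primary tumor is detected — the classical single-tumor closed form
`Θ/(1+Θ) = 3/4`.

`examples/02_simulate_and_fit.py` simulates 3000 patients from the
package's reference sparse 4-event network (47% primary-only, 44%
metastasis-only, 9% paired samples) and re-infers it:

```
cohort composition: {'mt_only': 1310, 'pt_only': 1412, 'paired': 278}
penalized objective: -3.0405 (138 iterations)
Pearson r between true and fitted off-diagonal effects: 0.890
```

so the directed effects (including the effects into and out of the seeding
event) are recovered with the correct signs and ranking.
`examples/03_trajectories.py` reconstructs most-likely event orderings and
shows, e.g., that the high-base-rate event initiates most trajectories
while the seeding event sits mid-progression;
`examples/04_preseeding_probabilities.py` estimates, per event, the
probability that it predates seeding given that it is seen in a
metastasis (the event suppressed after seeding scores 0.77, the
late-arriving ones near 0.43).

A thin CLI mirrors the library:

```bash
pairmhn simulate truth.tsv cohort.tsv --n 1000 --seed 7
pairmhn fit cohort.tsv fitted.tsv --lambda 0.001
pairmhn cv cohort.tsv --grid 0.0001,0.001,0.01
pairmhn trajectories cohort.tsv fitted.tsv orderings.tsv
pairmhn preseed fitted.tsv --event E1 --condition observed_in_MT
```

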