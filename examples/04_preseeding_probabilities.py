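"""Estimate how often each event precedes metastatic seeding.

For every event, Gillespie simulation estimates the probability that the
event occurred before the seeding event, conditioned on the event being
present in the observed metastasis; the exact first-passage decomposition
cross-checks the Monte-Carlo answer.  In the reference network, the event
that is suppressed after seeding (E4) must almost always predate seeding
when it shows up in a metastasis, while the others split between shared
and metastasis-private origin.
"""

from pairmhn import EventSystem
from pairmhn.simulate import (
    example_sparse_network,
    pre_seeding_probability,
    pre_seeding_probability_exact,
)

truth = example_sparse_network()
sys = EventSystem(4)
print("P(event occurred before seeding | event observed in the metastasis):")
for i, name in enumerate(sys.event_names):
    est = pre_seeding_probability(truth, sys, i, "observed_in_MT", 20000, seed=7)
    exact = pre_seeding_probability_exact(truth, sys, i, "observed_in_MT")
    print(
        f"  {name}: {est.probability:.3f} +- {est.stderr:.3f} "
        f"(exact {exact:.3f}; conditioned on {est.n_conditioned} histories)"
    )
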