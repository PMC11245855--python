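"""Reconstruct most-likely event orderings and summarize relative timing.

For each simulated metastasis genotype the dynamic program finds the
chronological event order (including the seeding event) that maximizes the
embedded-jump-chain path probability under the generating network.  The
relative-position summary then shows where each event tends to fall
between the start (0) and the end (1) of progression, and trajectories are
stratified by their initiating event.
"""

from pairmhn import EventSystem, most_likely_ordering, relative_positions
from pairmhn._lattice import PipelineFactory
from pairmhn.simulate import CohortSpec, example_sparse_network, simulate_cohort
from pairmhn.trajectories import stratify_by_initial_event, to_dot

truth = example_sparse_network()
sys = EventSystem(4)
spec = CohortSpec(
    400, fractions={"pt_only": 0.0, "mt_only": 1.0, "paired": 0.0}, seed=23
)
samples, _ = simulate_cohort(truth, spec, sys)
factory = PipelineFactory(sys)
trees = [
    most_likely_ordering(truth, sys, s, factory=factory)
    for s in samples
    if s.mt.sum() > 0
]
print(f"reconstructed {len(trees)} metastasis trajectories")

summary = relative_positions(trees)
print("mean relative position per event (0 = initiating, 1 = last):")
for event in sorted(summary.positions, key=summary.mean_position):
    print(f"  {event:8s} {summary.mean_position(event):.2f} "
          f"(seen in {len(summary.positions[event])} trajectories)")

print("\nstrata by initiating event:")
for label, size, _ in stratify_by_initial_event(trees, top_k=3):
    print(f"  {label}: {size} trajectories")

demo = next(t for t in trees if t.mt_branch and len(t.shared_prefix) > 1)
print("\none branched reconstruction as DOT:\n")
print(to_dot(demo))
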