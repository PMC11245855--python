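"""Closed-form observation races in tiny systems.

Builds the smallest possible models and compares the computed
first-observation probabilities against pencil-and-paper results: with no
progression events, seeding (rate Theta_s) races the rate-1 detection of
the primary tumor, so the primary is observed unseeded with probability
1/(1+Theta_s); with a single neutral event, the event is present at
detection with probability Theta_11/(1+Theta_11).
"""

import numpy as np

from pairmhn import (
    EventSystem,
    LOG_RATE_FLOOR,
    ParameterSet,
    Sample,
    first_observation_distribution,
    sample_probability,
)

for theta_s in (0.5, 1.0, 2.0):
    params = ParameterSet.zeros(0)
    params.theta[0, 0] = np.log(theta_s)
    p_op, p_om = first_observation_distribution(params, EventSystem(0))
    print(
        f"seeding rate {theta_s:.1f}: P(primary observed before seeding) = "
        f"{p_op.values[0]:.4f} (analytic {1 / (1 + theta_s):.4f}); "
        f"P(metastasis observed first) = {p_om.total():.4f}"
    )

print()
for theta11 in (0.5, 1.0, 3.0):
    params = ParameterSet.zeros(1)
    params.theta[1, 1] = LOG_RATE_FLOOR  # seeding disabled
    params.theta[0, 0] = np.log(theta11)
    prob = sample_probability(
        params, EventSystem(1), Sample("demo", pt=[1], seeding_evidence="unknown")
    )
    print(
        f"base rate {theta11:.1f}: P(event present at detection) = {prob:.4f} "
        f"(analytic {theta11 / (1 + theta11):.4f})"
    )
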