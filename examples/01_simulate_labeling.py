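"""Simulate a heavy-water labeling experiment under the three fate paradigms.

Builds one homogeneous population per paradigm at the same median lifespan
scale, runs both the stochastic agent-based engine and its deterministic
expectation through a 9-week labeling protocol, and prints the labeled-DNA
fraction at a handful of sampling days.
"""

import numpy as np

from lymphokin import (
    EventTimeDistribution,
    PopulationSpec,
    SimulationConfig,
    expected_labeling_curve,
    median_lifespan,
    run_labeling_simulation,
)
from lymphokin.synthetic import DEFAULT_HEAVY_WATER

days = np.array([7.0, 21.0, 42.0, 63.0, 105.0, 210.0, 350.0])

populations = {
    "age-independent": PopulationSpec.homogeneous(EventTimeDistribution.exponential(200.0)),
    "cyton (gamma shape 8)": PopulationSpec.homogeneous(
        EventTimeDistribution.gamma(8.0, 150.0 / 8.0)
    ),
    "risk (gamma shape 0.3)": PopulationSpec.homogeneous(
        EventTimeDistribution.gamma(0.3, 200.0 / 0.3)
    ),
}

print("day:            " + "".join(f"{d:8.0f}" for d in days))
for name, spec in populations.items():
    det = expected_labeling_curve(spec, DEFAULT_HEAVY_WATER, days)
    sim = run_labeling_simulation(
        spec, DEFAULT_HEAVY_WATER, days, SimulationConfig(n_cells=10_000, seed=1)
    )
    print(f"\n{name}  (median lifespan {median_lifespan(spec):.0f} d)")
    print("  expectation:  " + "".join(f"{v:8.3f}" for v in det.fraction_labeled))
    print("  ABM (1 seed): " + "".join(f"{v:8.3f}" for v in sim.fraction_labeled))

print(
    "\nValues are normalized labeled-DNA fractions. All three paradigms rise "
    "during the 63-day intake;\nthe curves differ most after label withdrawal: "
    "the cyton population holds its label (recently\ndivided cells are safe) "
    "and then loses it abruptly, while the risk population sheds label\n"
    "fastest at first but keeps a long-lived tail."
)
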