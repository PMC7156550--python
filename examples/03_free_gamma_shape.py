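"""Locate the fate paradigm without model comparison: the free-gamma approach.

A single gamma distribution spans all three paradigms (shape < 1 risk,
shape = 1 age-independent, shape > 1 cyton).  Fitting it with unconstrained
shape to labeling data places the data on the age-dependence axis directly,
with a residual-bootstrap confidence interval.
"""

from lymphokin import fit_unconstrained_gamma
from lymphokin.fitting import FitBudget
from lymphokin.synthetic import (
    DEFAULT_HEAVY_WATER,
    VALIDATION_GENERATORS,
    default_schedule,
    generate_noisy_dataset,
)

budget = FitBudget(n_starts=32, n_polish=2, polish_maxfev=300)
for gen_name in ("age_independent_homogeneous_exponential", "cyton_homogeneous_gamma"):
    model, spec = next((m, s) for m, s in VALIDATION_GENERATORS if m.name == gen_name)
    data = generate_noisy_dataset(
        model, spec, DEFAULT_HEAVY_WATER, default_schedule(11), noise_sd=0.025, rng=3
    )
    res = fit_unconstrained_gamma(data, DEFAULT_HEAVY_WATER, budget=budget, rng=3, n_boot=100)
    lo, hi = res.shape_ci
    verdict = (
        "age-independent (CI covers 1)" if lo <= 1.0 <= hi
        else ("cyton" if res.shape > 1 else "risk")
    )
    print(f"data from {gen_name}:")
    print(f"  free-gamma shape = {res.shape:.2f}, 95% bootstrap CI [{lo:.2f}, {hi:.2f}]")
    print(f"  paradigm reading: {verdict}\n")

print(
    "Age-independent data yields a shape estimate near 1 with a CI that "
    "covers 1; cyton data\npushes the shape well above 1 with a CI excluding 1."
)
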