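"""In-silico approach validation: can AICc selection recover the generator?

Runs a reduced validation study (generators: exponential, gamma cyton,
gamma risk; dataset sizes 11 and 30; two noise replicates), fitting all six
gamma-family models to every dataset, and summarizes recovery and margins.
"""

from lymphokin import TABLE1_GAMMA_MODELS, run_validation_study
from lymphokin.fitting import FitBudget
from lymphokin.synthetic import VALIDATION_GENERATORS

generators = tuple(
    (m, s)
    for m, s in VALIDATION_GENERATORS
    if m.name
    in (
        "age_independent_homogeneous_exponential",
        "cyton_homogeneous_gamma",
        "risk_homogeneous_gamma",
    )
)
report = run_validation_study(
    sizes=(11, 30),
    generators=generators,
    reps=2,
    budget=FitBudget(n_starts=32, n_polish=2, polish_maxfev=300),
    seed=5,
    model_set=TABLE1_GAMMA_MODELS,
)
df = report.to_dataframe()
cols = ["generating_model", "size", "rep", "winning_model", "min_nongenerating_margin"]
print(df[cols].to_string(index=False))

cyton = df[df["generating_model"] == "cyton_homogeneous_gamma"]
exp_rows = df[df["generating_model"] == "age_independent_homogeneous_exponential"]
print(
    f"\ncyton recovered in {int(cyton['recovered'].sum())}/{len(cyton)} replicates, "
    f"smallest margin over a non-generating model: {cyton['min_nongenerating_margin'].min():.1f} AICc"
)
print(
    f"mean gamma-risk shape fitted to age-independent data: "
    f"{exp_rows['risk_shape'].mean():.3f} (near 1: the risk fit collapses onto "
    "the exponential)"
)
print(
    f"age-dependent data won by an age-independent model: "
    f"{report.n_age_dependent_won_by_age_independent()} cases"
)
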