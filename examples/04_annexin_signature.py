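"""The Annexin V / glucose-label signature: observation and model prediction.

Simulates the sorted-cell experiment (24 h glucose pulse, four subjects,
sampling at days 3/4/7/8) for a risk-paradigm population, derives the
fraction of Annexin-positive cells among labeled vs unlabeled cells, tests
the signature with an exact Wilcoxon, and then asks each of the six
reference models whether it predicts the signature.
"""

from lymphokin import derive_signature, generate_annexin_dataset, predict_signature
from lymphokin.synthetic import ANNEXIN_REFERENCE_SPECS, DEFAULT_GLUCOSE

risk_spec = ANNEXIN_REFERENCE_SPECS["risk_homogeneous_gamma"]
data = generate_annexin_dataset(risk_spec, DEFAULT_GLUCOSE, n_subjects=4, n_cells=100_000, rng=1)
sig = derive_signature(data, p_annexin=None, days=(3, 7))
print("observed signature in a risk-paradigm population (days 3 and 7):")
for _, r in sig.table.iterrows():
    print(
        f"  {r['subject']} day {int(r['day'])}: Annexin+ among labeled "
        f"{r['among_labeled']:.4f} vs among unlabeled {r['among_unlabeled']:.4f}"
    )
print(f"  exact Wilcoxon two-tailed p = {sig.p_value:.5f}\n")

print("model predictions (10 pulse simulations each):")
verdicts = predict_signature(
    ANNEXIN_REFERENCE_SPECS, DEFAULT_GLUCOSE, days=(3, 7), n_seeds=10, n_cells=100_000, seed=2
)
for name, v in verdicts.items():
    d3 = v.mean_difference.get(3, float("nan"))
    d7 = v.mean_difference.get(7, float("nan"))
    print(f"  {name:44s} predicted={str(v.predicted):5s} diff(day3)={d3:+.4f} diff(day7)={d7:+.4f}")

print(
    "\nA positive difference means Annexin-positive cells are over-represented "
    "among labeled\n(recently divided) cells.  The heterogeneous age-independent "
    "and both risk models predict\nthe signature; the homogeneous age-independent "
    "(memoryless) and both cyton models do not."
)
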