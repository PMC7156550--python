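# lymphokin

Rules of T-cell fate from stable-isotope labeling: agent-based simulation of
lymphocyte homeostasis, paradigm model selection, and the Annexin V /
glucose-label signature.

## The problem

Human T-cell turnover is measured by giving volunteers heavy water or
deuterated glucose and tracking deuterium in the DNA of sorted cell
populations: label enters DNA only when a cell divides, and leaves the pool
when labeled cells die or divide again. Interpreting such curves requires a
model of *cell fate* — and the standard assumption, that a cell's chance of
dividing or dying is independent of its age (time since its last division),
is exactly what in-vitro work on murine lymphocytes contradicts. Three
paradigms compete:

* **age-independent** — constant hazard (exponential event times);
* **cyton** — recently divided cells are *less* likely to divide or die
  (hazard increases with cell age; gamma shape > 1 or lognormal with mode
  above 7 days);
* **risk** — recently divided cells are *more* likely to divide or die
  (hazard decreases with age; gamma shape < 1 or lognormal with mode below
  2 days).

`lymphokin` implements the full computational machinery for asking which
paradigm labeling data supports: a stochastic agent-based model (ABM) of a
homeostatic, optionally heterogeneous cell population with competing
division/death clocks drawn at birth; an exact deterministic expectation of
that ABM for fast fitting; heavy-water and glucose label-availability
kinetics; paradigm-constrained least-squares fitting with model selection by
`AICc = n ln(ssr/n) + 2nk/(n−k−1)`; an unconstrained-gamma "alternative
approach" whose fitted shape locates the paradigm directly; an in-silico
validation study (generate from a known model → fit all six candidates → ask
whether the generator wins); and prediction of the Annexin V signature —
whether cells labeled by a 24 h glucose pulse are over-represented among
incipiently dying (Annexin V-positive, remaining lifetime < 24 h) cells.
A synthetic-data generator produces every input, so the whole pipeline runs
and is tested without access to subject data.

Everything is importable from `lymphokin`; a thin `lymphokin` CLI
(`simulate`, `fit`, `compare`, `validate`, `annexin`, `synth`) wraps the
same functions for shell pipelines. See `docs/methods.md` for the model,
its assumptions, and measured limits of identifiability.

## A worked example

`examples/02_model_selection.py` generates one noisy 11-point heavy-water
labeling dataset from a cyton population (gamma shape 8, mean event time
150 days, Gaussian noise sd 0.025), fits all six candidate models and ranks
them:

```
generated 11 noisy points from: cyton_homogeneous_gamma

model                                         k       ssr      AICc   dAICc
cyton_homogeneous_gamma                       2    0.0025    -86.60    0.00
cyton_heterogeneous_gamma                     5    0.0011    -79.36    7.24
age_independent_homogeneous_exponential       1    0.0549    -55.86   30.75
risk_homogeneous_gamma                        2    0.0549    -52.80   33.80
age_independent_heterogeneous_exponential     3    0.0549    -48.87   37.73
risk_heterogeneous_gamma                      5    0.0549    -36.30   50.30

winner: cyton_homogeneous_gamma
```

The generating model wins; its `ssr` (0.0025) is at the noise floor
(11 × 0.025² ≈ 0.007), while the age-independent and risk models are left
with twenty-fold larger residuals — a normalized AICc (`dAICc`) margin above
6 is decisive. The heterogeneous cyton model fits the noise slightly better
(ssr 0.0011) but pays for its five parameters.

The other examples follow the same pattern: `01` simulates labeling curves
under the three paradigms with both engines, `03` reads the paradigm off the
unconstrained gamma shape (CI [0.50, 1.73] on age-independent data — covers
1; CI [2.53, 12.85] on cyton data — excludes 1), `04` runs the simulated
Annexin V experiment and scores each model's prediction, `05` runs a reduced
validation study end to end.

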