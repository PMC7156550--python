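# Methods

## The model

`lymphokin` simulates a population of T cells in homeostasis as a critical
branching process. Every cell is created by mitosis at age 0 and draws two
independent clocks from its subpopulation's event-time distribution: a time
to divide and a time to die (or differentiate — the model does not
distinguish loss mechanisms). The first clock to ring decides the cell's
fate; the time to that first event is the cell's *lifespan*. Because the two
clocks share one distribution, divisions and deaths are equally likely and
the expected population size is constant — no external influx is modelled.

The distribution family encodes the *paradigm* of age dependence:

| paradigm        | hazard vs cell age | distributions                            |
|-----------------|--------------------|------------------------------------------|
| age-independent | constant           | exponential (gamma, shape = 1)           |
| risk            | decreasing         | gamma shape < 1; lognormal mode < 2 d    |
| cyton           | increasing         | gamma shape > 1; lognormal mode > 7 d    |

Lognormal distributions with mode between 2 and 7 days are rejected by the
classifier rather than silently assigned: they sit between the constrained
parameter spaces the fits explore, and there is no admissible lognormal
encoding of age independence.

Populations are homogeneous or a mixture of two independently homeostatic
subpopulations (kinetic heterogeneity); daughters inherit the mother's
subpopulation but nothing else — clocks are redrawn at every birth.

### Steady-state initialization

An adult's T-cell pool has been in homeostasis for years, so the simulation
must not start with newborn cells. In the stationary state the age density
is proportional to `S(a)^2` — both clocks must have stayed silent to age
`a` — and the remaining clock times are drawn conditional on exceeding the
current age. Ages are sampled by inverse CDF on a quadrature table of
`S(a)^2` (log-spaced grid to the 1−10⁻⁶ quantile, monotone PCHIP inverse);
conditional clocks use `T = isf(u · S(a))`, which is stable deep in the
tail. For exponential clocks this yields the closed-form Exp(2λ) age
distribution, which the test suite checks by Kolmogorov–Smirnov at 50,000
draws; for gamma clocks the sampler is validated against a brute-force
oracle — ages observed after a 600-day burn-in of the stochastic simulation
started from a deliberately wrong (all-newborn) state.

### Labeling

Stable-isotope label enters DNA only at division. Heavy-water availability
follows the saturating empirical curve `U(t) = f(1−e^{−δt}) + βe^{−δt}`
during intake and decays as `e^{−δ(t−τ)}` afterwards; deuterated glucose is
a square pulse. The engines consume the *normalized* availability `U(t)/f`
(unit pulse for glucose), so a fully turned-over population approaches
labeled fraction 1 and no free scaling parameter enters the fits.

Two division-labeling conventions are implemented, and the choice matters
more than any other modelling decision in the package:

* **reset** (default): daughters are labeled in proportion to the current
  availability, `label = availability`. The label marks a cell by its most
  recent division; after withdrawal the labeled fraction decays through both
  death and re-division, so the delabeling curve is the labeled cohort's
  first-event survival function. Exponential closed form:
  `M(t) = Û(1 − e^{−2λt})`.
* **semiconservative**: daughters keep one parental strand,
  `label = mother/2 + availability/2`. Strand inheritance smears cohort
  identity across generations; the labeled fraction then decays through
  death alone. Exponential closed form: `M(t) = Û(1 − e^{−λt})`.

We quantified the consequences: under strand inheritance the one-parameter
exponential model reproduces every admissible cyton labeling curve to within
about 0.015 RMS on an 11-point schedule — less than the measurement noise —
so the three paradigms become statistically indistinguishable at realistic
design sizes (the best attainable AICc margin is ≈ 2.5, and cyton-generated
data is sometimes *won* by the exponential model). Under the reset
convention the cyton delabeling shoulder survives intact and a moderate
cyton population is identified with margins above 10 AICc. Only the reset
convention reproduces the headline model-selection behaviour this package
exists to study, and the sorted-cell experiment it predicts (Annexin
sorting) also reasons about "labeled = recently divided" cells; it is
therefore the default. Both conventions are kept, each tested against its
own exponential closed form.

### Engines

The stochastic engine advances the population in fixed 1-day steps: ages
increase by one day, cells whose age has reached a clock are removed or
replaced by two daughters, and when both clocks were crossed within the same
day the smaller drawn time decides (exact ties by fair coin). It is
vectorized over cells and comfortably runs 10⁵–10⁶ cell-days per second.

The deterministic engine is the *exact expectation of that daily-stepped
process*, not a continuous-time approximation: a discrete renewal recursion
over daily birth cohorts in which a daughter cohort's effective lifespan has
mass `w[j] = S(j−1)² − S(j)²` (the probability that the minimum of two
fresh clocks falls in day j) and the pre-labeling population contributes
events through the tail integrals of `S²`. One curve evaluation costs a few
milliseconds, which is what makes the global fitting studies tractable. On
the exponential closed forms it is accurate to ~10⁻⁶ relative (reset) and
~0.25% (semiconservative, where generational label propagation feels the
day quantization); against the stochastic engine it agrees within
Monte-Carlo error on twelve parameter sets spanning all paradigms, both
families, and both heterogeneity levels.

## Fitting and model selection

The six canonical candidate models pair the paradigms with homogeneity or
two-subpopulation heterogeneity; free parameters are 1 (homogeneous
exponential), 3 (heterogeneous exponential), 2 (homogeneous gamma or
lognormal), 5 (heterogeneous gamma or lognormal). Fitting minimizes ordinary
least squares between the observed curve and the deterministic engine
(a stochastic mode using the median SSR across 5 seeds is retained and used
in the engine-equivalence tests). The global search is Latin-hypercube
seeding of the log-transformed parameter box followed by bounded
Nelder–Mead polishing of the best starts; everything is deterministic given
a seed. Default bounds: mean event time 1–5000 days, mixing proportion
0.05–0.95, gamma shape (0.02, 1) for risk and (1, 50) for cyton, lognormal
σ in (0.05, 2.5] with the mode constrained per paradigm.

Models are compared by the small-sample corrected Akaike criterion
`AICc = n ln(ssr/n) + 2nk/(n−k−1)`, reported as normalized AICc
(difference from the winner). A margin of 6 is treated as decisive,
following standard practice. The *alternative approach* fits a single gamma
with shape free over (0.02, 50), so the fitted shape locates the paradigm
without any complexity penalty; its uncertainty comes from a nonparametric
residual bootstrap (200 resamples by default), which also feeds the
hazard-trajectory ensemble plots.

## The synthetic-data generator and what it does (not) emulate

All study inputs are generated in `lymphokin.synthetic`: noisy labeling
datasets (deterministic expectation curve plus iid Gaussian noise, sd
0.025), body-water enrichment series, and sorted Annexin V datasets.
Sampling schedules are fixed nested designs of sizes 6 ⊂ 11 ⊂ 20 ⊂ 30 ⊂ 50
covering a 63-day labeling phase and follow-up to day 350. The default
heavy-water protocol is `f = 0.02, δ = 0.06/d, β = 0.015, τ = 63 d` — a
9-week intake primed to 75% of plateau.

Validation-study generating parameters sit at memory-T-cell lifespan scale:
exponential mean 200 d; heterogeneous exponential 50/500 d with 30% fast
cells; gamma cyton shape 8, mean 150 d; gamma risk shape 0.3, mean 200 d;
lognormal cyton `e^μ = 150 d, σ = 0.15`; lognormal risk `μ = 3.5, σ = 2.0`.
The cyton generator is deliberately well inside the cyton space (tightly
concentrated event times): near the shape→1 boundary the paradigms blur
by construction, and the study design questions the generator answers
presuppose a generating model that actually carries its paradigm's
signature.

The generator does **not** emulate: GC-MS measurement error structure beyond
iid Gaussian noise, between-subject parameter variation (each synthetic
subject differs only by simulation seed), cell influx from thymus or naive
compartments, or inheritance of fate times across generations. Passing
validation therefore demonstrates that the *pipeline* recovers what it
generated under its own assumptions — not that real labeling data satisfies
those assumptions.

### Findings from the validation study

Two mimicry phenomena put hard limits on model identification and are worth
knowing before interpreting any comparison table:

* **Lognormal risk ↔ heterogeneous exponential.** At every admissible σ we
  tested (1.5–2.5), a heavy-tailed lognormal produces a biphasic labeling
  curve that two exponentials fit within noise, so lognormal-risk-generated
  datasets are won by the heterogeneous age-independent model in a
  substantial minority of replicates. This is the same lognormal/biphasic
  equivalence long noted in the literature; at n = 11–30 and noise 0.025 it
  is strong enough that "age-dependent data is never misclassified as
  age-independent" holds for the gamma-risk generator but *not* for the
  lognormal-risk generator.
* **Gamma cyton ↔ lognormal cyton.** Fits of the two cyton families to each
  other's data differ by only ~0–2 AICc; recovery of the generating *model*
  is reliable at paradigm level, not family level, whenever both families
  are in the comparison set.
* **Nested superset models.** When the comparison set contains a
  heterogeneous model of the same paradigm and family as a homogeneous
  generator, the heterogeneous model *contains* the generator, so its
  normalized AICc is capped at the parameter-penalty difference minus the
  (roughly χ²₃) gain its three extra parameters extract from noise — about
  8 at n = 30 and shrinking with n. On cyton-generated data every
  different-paradigm model loses by 40–60 AICc at n = 30, but the nested
  heterogeneous cyton can come within 1–8; a "no other model within 6"
  guarantee is mathematically impossible against nested supersets at these
  sample sizes and says nothing about paradigm identification.

Median lifespan is also only weakly identified for the heavy-tailed
lognormal-risk model (and essentially unidentified for the 5-parameter
heterogeneous models) at n = 11: parameter-recovery replicates spread ±20%
around the truth, versus ±5% for the homogeneous exponential, gamma and
lognormal-cyton models.

## Annexin V / glucose signature

A 24-hour glucose pulse labels exactly the cells that divided during it.
Annexin V status is approximated by remaining lifetime below 24 h — by
default time to *first event*, per the lifespan definition; a death-only
switch is provided. The sorting experiment measures the labeled fraction in
each Annexin class; the quantity of interest — the Annexin-positive fraction
among labeled vs unlabeled cells — follows by Bayes' rule with the overall
Annexin-positive proportion `p` as an explicit argument (default 0.1). The
direction of the signature is provably invariant to `p`, so the unreported
experimental proportion cannot change any qualitative conclusion; absolute
levels are not scored (ex-vivo Annexin binding overestimates in-vivo death
many-fold).

Because subject-level fits to real memory-cell data are not available, the
prediction test scores six paradigm-representative parameter sets at the
fitted lifespan scale (`ANNEXIN_REFERENCE_SPECS`). These reproduce the
expected pattern: the heterogeneous age-independent and both risk models
predict a significantly higher Annexin-positive fraction among labeled cells
at days 3 and 7; the homogeneous age-independent (memoryless — label and
remaining lifetime are independent) and both cyton models (recently divided
cells are the *safer* ones) do not. Fitting the candidate models to a
synthetic memory-like dataset and predicting from those fits is supported in
the library, but note two traps we measured: a heterogeneous-cyton fit to
exponential-like data collapses to near-exponential shapes and then behaves
like the heterogeneous exponential, and an extreme risk fit (shape ≈ 0.1)
loses the day-7 signature because its few labeled survivors are no longer at
elevated hazard.

The signature's significance uses an exact two-tailed Wilcoxon signed-rank
test, enumerated over all 2ⁿ sign assignments for n ≤ 12 pairs (midranks for
ties; normal approximation beyond n = 12). Eight uniformly positive pairs
give p = 2/2⁸ = 0.0078125.

## Numerical choices and problem sizes

* Simulation step fixed at 1 day (the deterministic engine matches this
  exactly); curve values at fractional days are linear interpolations.
* Stationary-age tables: 6000-point log grid, trapezoid quadrature, PCHIP
  inverse; tail integrals for the deterministic engine use a 0.25-day grid
  extended log-spaced to the 10⁻⁹ survival quantile.
* Optimizer budget is a configuration knob; the studies in the test suite
  and acceptance script use 32 Latin-hypercube starts with 2 polished,
  which recovery experiments showed indistinguishable from larger budgets
  on these problems. Validation studies run sizes {11, 30} with 3 noise
  replicates; the Annexin prediction uses 20 seeds of 2×10⁵ cells.
* Ties between division and death clocks within a day: smaller drawn time
  wins; exact ties (probability zero) by fair coin. `ssr = 0` maps AICc to
  −∞ with a warning (occurs only in noiseless self-fits). Infeasible
  optimizer points and failed simulations receive a large finite penalty
  cost and are logged, never silently dropped.

## Known limitations

* The reset labeling convention treats a dividing labeled mother's daughters
  as unlabeled once availability is zero; physically, strands persist. The
  semiconservative mode is the physically faithful bookkeeping but erases
  paradigm identifiability (see above). Real GC-MS enrichment data lies
  between the two idealizations.
* No influx, no death/division asymmetry, no inheritance of fate times;
  single-step (not staged) apoptosis with a sharp 24 h Annexin window.
* The validation study's quantitative outcomes (margins, winning shapes)
  depend on the declared generating parameters; they are defaults of this
  package, not measured biology.
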