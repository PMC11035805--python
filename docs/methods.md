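# Methods

## Scope and data model

The package analyses small-scale CAR-T expansion studies structured as a
design of experiments over four process parameters: number of activation
steps (1 or 2), seed-train length (3/5/7 days), seeding density
(0.25/0.5/0.75 × 10⁶ cells) and IL-2 dose (30/65/100 IU/mL). Inputs are
per-run culture time series (viable density, viability, volume, optional
daily perfusion fraction), per-run metabolite panels (glucose, lactate,
glutamine, ammonia, with fresh-feed concentrations), and a responses table
linking factor settings to end-of-culture marker percentages. Day 0 is the
day of seeding after the seed train; sampling days are taken as given and
intervals are formed between consecutive available samples, without
interpolation.

## Kinetics

Population doublings, cumulative doublings, fold and the specific growth
rate follow the standard exponential-growth estimators
(`PD = log2(C_n/C_{n-1})`, `mu = ln(C_n/C_{n-1})/Δt`); the formula for the
specific growth rate is the unique choice consistent with the doubling
formula (`mu = PD·ln2/Δt`).

Per-cell consumption/production rates integrate the mass balance of an
exponentially growing culture over one interval, correcting the previous
concentration for perfusion exchange (`c_{n-1}(1−d) + m_x·d`). `C` in these
formulas is total viable cells (density × volume) with concentrations per
litre; rates are reported in pmol·cell⁻¹·day⁻¹. Since `e^{muΔt} − 1`
underflows for tiny growth, the implementation switches to the analytic
`mu -> 0` limit (concentration difference over `C·Δt`) below
`|mu|Δt = 1e-8`; a property test checks the two branches agree to 1e-6
relative error over `|mu|Δt ∈ [1e-10, 1e-4]`.

Negative computed rates are reported as-is (a nominally consumed analyte
can be net-produced); nothing is clipped. Rates are averaged over the
day 2–7 expansion window, defined as the set of sampling intervals whose
both endpoints lie inside the window (five intervals for daily sampling).
The lactate-from-glucose yield divides the change in specific lactate
production by the change in specific glucose consumption between the first
and last window intervals; a zero denominator raises a diagnostic error
rather than returning a value. This endpoint-difference estimator is exact
on clean data but ill-conditioned under measurement noise: it divides two
small differences, so per-run yields from noisy series scatter widely even
when window-average rates are stable (the 02 analysis script reports both).
An alternative — regressing cumulative lactate on cumulative glucose — would
be more robust but is intentionally not what this pipeline computes.

## DOE design and coding

Numeric factors are orthogonally scaled, `x -> (x − midrange)/halfrange`,
so declared levels land in [−1, +1]; the two-level activation factor is
coded −1/+1 (it is a categorical contrast, not a dose). Model matrices
carry the intercept, mains in declaration order and two-way interaction
columns (products of coded mains) in lexicographic order; on the full
54-point candidate lattice all main-effect columns are mutually
orthogonal.

Exact designs are chosen from the candidate lattice by greedy Fedorov
exchange on det(XᵀX) with random multistart (deterministic given the
seed). The default study design has 26 runs: a 23-run D-optimal subset for
the full two-way-interaction model plus three replicates of the
centre-most candidate (with the categorical factor at its low level),
giving a pure-error check at a plausible small-study size. Seeding density
is stored as a single numeric level with a units label; published sources
mix cells/cm² and cells/mL for the same numeric levels, and the package
deliberately does not resolve that ambiguity (the numbers, not the units,
drive the coded analysis).

## Regression modelling and validation

Each response is fit by OLS in coded units (statsmodels under the hood)
starting from intercept + mains + all two-way interactions. Backward
elimination removes, one at a time, the worst-p term above α = 0.05,
refitting after each removal, under strict hierarchy: the intercept is
never removed, and a main effect is frozen while any retained interaction
contains it, so interactions leave before their parents. Ties on p prefer
the higher-order term, then the later column. Mains kept only by hierarchy
are flagged (`hierarchy_terms`) and excluded when judging "all retained
terms significant". The procedure is idempotent and may legitimately end
intercept-only.

Q² = 1 − PRESS/SStot uses exact leave-one-out residuals via the hat-matrix
identity `e_i/(1 − h_ii)`; a test verifies equality with an explicit
refit-n-times oracle to 1e-10. SStot is taken about the mean. A leverage of
1 makes LOO undefined and is signalled. Model validity flags record the
R² − Q² ≤ 0.2 rule and term-significance status; models violating the gap
rule are flagged, never re-interpreted. Overall model significance is the
F-test of the fitted model against intercept-only; 95% confidence
intervals use t-quantiles with n − k degrees of freedom. Donor identity is
not a model term by default (the emulated study design crosses factors
within donor); donor scatter therefore acts as extra residual noise.

A caveat worth stating: backward elimination at α = 0.05 retains each
truly-null candidate term with probability ≈ α (slightly above, because
each term is re-tested at every refit). With six null candidate terms the
chance that a fitted model contains no spurious term at all is only about
0.95⁶ ≈ 74%, and the per-term false-retention rate measured by the test
suite is ~5–7%. This is a property of the α = 0.05 selection rule itself,
not of the implementation, and is the reason the support-recovery test in
the acceptance suite reports the zero-term drop rate it actually achieves
(~93%) rather than a nominal one.

## Optimisation

Fitted models are evaluated over the full lattice of tested levels (54
points); search is restricted to tested levels because the decision being
emulated is a choice among levels, with a continuous grid available
through the effect views instead. Per-response desirabilities are linear
rescalings of the prediction range over the lattice (direction by goal),
aggregated by a weighted geometric mean so any zeroed response zeroes the
score; the arithmetic mean is available by configuration and also serves
as the deterministic secondary tie-break, so settings tied at zero overall
still rank by how poor they are across responses, and exact ties resolve
to the lowest factor levels. Factors appearing in no fitted model are
reported as inactive (all their levels tie) rather than as pseudo-optima.

## Group comparisons

Report tables use two-sided pairwise tests only: pooled or Welch t, chosen
by a Brown–Forsythe (median-centred Levene) variance pre-check at 0.05,
with the conventional star notation (0.05/0.01/0.001/0.0001). ANOVA
families and post-hoc procedures are out of scope.

## Synthetic studies

The generator emulates the study's structure with known truth, in two
layers.

*Responses.* Each response is intercept + coded-unit linear predictor +
per-donor additive shift + Gaussian residual, clipped to declared bounds
(percentages to [0, 100] on the raw scale — the modelling is on raw
percentages, so the generator matches). Default effect structure: growth
(cPD) intercept 3.6 with activations −1.2, seed train −0.4, density −0.2,
activations × seed-train −0.3; exhaustion 63 ± (activations +14.5, seed
train +5, interaction +4); CD69 similar; per-cell glucose and lactate
rates rising with activation; lactate yield 1.75 ± 0.14 (bounded by the
glycolytic ceiling 2); IL-2 truly inert everywhere. Intercepts and the
activation effects are anchored to the reported group means (one vs two
activations: ~4.8 vs ~2.4 cPD, ~48 vs ~78% PD1+LAG3+). Residual sd
defaults to 5% of each response's noiseless range over the lattice, donor
sd to 2%; three donors assigned cyclically.

*Time series.* Cultures grow exponentially at constant
`mu = cPD·ln2/days`, so the final density is exactly `2^cPD` times the
seed. Per-cell metabolic rates decline geometrically with culture day
(default 5%/day), reflecting the slowdown of real cultures as nutrients
deplete; some time variation is also structurally necessary, because with
constant rates the endpoint-difference yield is a 0/0. Glucose
concentrations are obtained by inverting the consumption equation
(consumption capped at availability, with a warning, never negative), and
lactate is produced at exactly `lactate_per_glucose` per glucose consumed
within each interval — which makes the recovered yield equal that
stoichiometry identically, and the kinetics stage recover the generating
rates to numerical precision on noiseless data. Glutamine and ammonia are
phenomenological satellites of the glucose flux. Measurement noise, when
enabled (default 2% in the pipeline's simulate step), is multiplicative
log-normal on densities and concentrations.

What the generator does **not** emulate: mechanistic T-cell biology
(activation signalling, exhaustion dynamics), death/viability kinetics
coupled to growth, non-exponential growth phases, assay-specific error
structure, or donor × factor interactions. Passing tests therefore
demonstrate correctness of the computational pipeline under the declared
statistical structure, not biological validity on real cultures.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own scale: 26-run
designs, 54-point lattices, 8-point time series, 200-replicate selection
studies and 10⁴-replicate null calibrations — sizes chosen to estimate the
relevant rates to well under a percentage point. Key tolerances: the
fold/cPD identity holds to 1e-12 relative; hat-matrix LOO matches refit
LOO to 1e-10; noiseless ground-truth recovery to 1e-6; the small-growth
branch agrees with the exact formula to 1e-6 relative. Degenerate inputs
are errors, not silent results: non-positive counts, leverage-1 runs,
constant groups, empty averaging windows and zero yield denominators all
raise typed exceptions with diagnostics.
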