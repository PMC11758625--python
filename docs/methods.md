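# Methods

## Model and assumptions

Serum 3-hydroxybutyrate (3-HB) is described by a one-compartment model with
a gastrointestinal depot. State variables are the unabsorbed gut amount
X (mmol) and the serum concentration C (mM); parameters are systemic
clearance CL (L/min), basal concentration C0 (mM), first-order absorption
rate ka (1/min), half-saturation amount Km′ (mmol), distribution volume
Vd (L) and transporter capacity Vmax (mmol/min). Absorption is the sum of a
Michaelis–Menten term Vmax·X/(Km′+X) and a linear term ka·X; elimination is
linear (CL·C); endogenous production is constant at CL·C0, which makes
C = C0 the unique steady state of the undosed system. The model assumes

* complete oral bioavailability — both pathways deliver the whole dose to
  serum eventually, so the area under C−C0 equals Dose/CL regardless of the
  absorption split;
* production unaffected by the dose (no feedback on ketogenesis), defensible
  over a two-hour sampling window;
* serum and plasma concentrations treated as interchangeable for the
  0.28 mM target.

Amounts are mmol, concentrations mM, volumes L, time minutes; grams of
3-HB convert at 104.10 g/mol (C4H8O3). Reduced variants force Vmax = 0
(nonsaturable-only, 4 free parameters) or ka = 0 (saturable-only, 5 free
parameters); the full model has 6.

## Numerics

The ODE system is integrated with LSODA (automatic stiffness switching; the
MM term is mildly stiff as the gut empties) at rtol 1e-8 / atol 1e-10,
reported on a 0.1 min grid by default. The solver's continuous interpolant
is kept on the profile so Cmax/Tmax can be refined off-grid by bounded
scalar minimisation within one grid step of the discrete argmax; ties break
to the earliest time. States are clipped to zero only for reporting; an
excursion below −1e-7 mmol aborts with an integration error. The Vmax = 0
limit has the Bateman closed form and is used as the integrator's oracle
(agreement better than 1e-6 mM, typically 1e-9).

## Fitting

All dose arms are fitted simultaneously with one shared parameter set by
trust-region least squares on log-transformed parameters (positivity without
constraints). Multi-start: the log-midpoint of the search box plus
Latin-hypercube draws (seeded, deterministic); default box CL ∈ [0.1, 10]
L/min, C0 ∈ [0.01, 0.2] mM, ka ∈ [1e-6, 1] /min, Km′ ∈ [0.1, 500] mmol,
Vd ∈ [5, 500] L, Vmax ∈ [0.01, 10] mmol/min. The ka lower edge sits at
1e-6 /min — effectively zero flux — so that the bounded full-model fit can
approach its saturable-only (ka = 0) submodel; with a larger edge the SSR
nesting between full and reduced fits fails structurally. Weighting is
uniform by default (the fits consume mean profiles with no stated weights);
1/observation weighting is available and agrees on clean data.

Standard errors come from the linearised covariance σ̂²(JᵀJ)⁻¹ on the log
scale with σ̂² = SSR/(n−p), delta-method transformed to natural units; a
near-singular JᵀJ flags them unreliable rather than failing. Model variants
are compared by the least-squares AIC n·ln(SSR/n) + 2p — only differences
within one dataset are meaningful. Selection takes the lowest AIC; variants
within 2 AIC of the minimum count as comparable and the tie breaks on the
lower final SSR. `compare_variants` fits the reduced models first and
warm-starts the full model from their optima, which is what makes the
nesting ssr(full) ≤ ssr(reduced) robust in practice; because ka = 0 itself
is not representable in log space, nesting is guaranteed only up to a small
optimisation tolerance (measured worst case 2.5e-4 relative; tests allow
1e-3).

## Calibration from printed summaries

When only peak summaries are available, `calibrate_from_summary` fixes
(CL, C0, Vd) and solves for (Vmax, Km′, ka) by least squares on the relative
Cmax and Tmax errors of each constraint (equal weight). The objective is
evaluated through full simulations with peak refinement; the
finite-difference Jacobian uses a log-scale step of 1e-4 because the
refinement jitter swamps the default square-root-of-epsilon step and stalls
the optimizer. With two (dose, Cmax, Tmax) constraints the three parameters
are just-identified and noiseless self-consistency recovery is exact to
~1e-9; a single constraint is refused.

Applied to the published summaries — CL = 1.82 L/min, C0 = 0.063 mM,
Vd = 85.7 L with 2 g → (0.266 mM, 30 min) and 4 g → (0.289 mM, 45 min) —
the calibration is infeasible in a structural sense worth recording: the
model's absorption flux is non-increasing in time, so the concentration at
a fixed time is maximised by a constant (zero-order) infusion, giving
C(30 min) ≤ C0 + (D/30/CL)·(1 − e^(−k·30)) ≈ 0.229 mM for a 2 g dose —
below the printed 0.266 mM. (The published disposition values were
estimated jointly with absorption from the full seven-point profiles, which
a fit to peak summaries alone cannot reproduce.) The best compromise leaves
about 17% residual on the 2 g Cmax, and the function warns accordingly while
returning the best-found parameters. The downstream results are insensitive
to this: the calibrated model still brackets the threshold between 2 and
4 g, the 0.5 g-grid minimum dose is 3.5 g, the continuous crossing is
≈3.1 g, and Cmax(3.5 g) ≈ 0.298 mM ≥ 0.28 mM. The calibration optimum is
the same from every multi-start seed tried.

## Dose finding

Cmax is strictly increasing in dose (more gut content can only increase the
absorption flux), so the qualifying doses form an upper set. The grid scan
returns the smallest qualifying dose on a 0.0–8.0 g, 0.5 g-step grid
(granularity matching the reported answer); bisection refines to 0.01 g.
Equality with the target counts as reaching it. A target at or below C0
returns 0 g. Peaks are evaluated to 240 min — absorption is complete well
before, with observed Tmax ≤ 45 min.

## Crossover statistics

The efficacy endpoints are change scores (post − pre within a visit)
analysed with a linear mixed model: sequence, period and treatment fixed,
subject random intercept (compound symmetry), REML. Inference on the
treatment contrast uses a t reference with n_subjects − 2 degrees of
freedom, the between-within partition for a within-subject contrast in a
2×2 design; on balanced complete data the point estimate coincides with the
closed-form paired contrast (sequence-averaged mean within-subject
active − placebo difference), which the tests use as an independent oracle,
and the CI coincides with the exact crossover t interval. Deterministic
data (zero residual variance) short-circuit to the fixed-effects solution
with p = 1 for a null effect. Baseline comparisons use the pooled-variance
two-sample t-test (Welch optional); the sex ratio uses Fisher's exact test
(two-sided, by summing hypergeometric point probabilities, p = 1 for a zero
margin). No multiplicity adjustment is applied, matching the analysis it
mirrors; the TMD composite is the sum of the five negative POMS2 subscales
minus vigor-activity.

## Synthetic data

`generate_serum_profiles` draws per-subject concentrations as
prediction × (1 + ε), ε ~ N(0, CV), truncated at 0.001 mM, on the study
schedule (0, 5, 15, 30, 45, 60, 120 min), 10 subjects per arm, doses 2 and
4 g, and averages them into fitting-ready arms. The default CV of 0.30
matches the observed SD-to-mean ratio of the peak concentrations. Noise is
observation-level only: between-subject kinetic heterogeneity is not
modelled because the fitting stage consumes arm means. Consequently the
passing recovery studies certify the estimator under measurement noise, not
under population kinetic variability — an extension would draw per-subject
parameters from a log-normal population model.

`generate_crossover_trial` produces a complete, balanced 40-subject trial
(20 per sequence) with additive sequence, period and treatment effects, a
subject random intercept and residual noise. Defaults mirror the
mood-composite endpoint: effect −4.7 points on change scores, subject SD 8,
residual SD 10.5 (arm change-score SDs ≈ 13, within the observed 11.6–14.6
range), placebo-arm mean 5.3. All generators take explicit integer seeds
and are byte-reproducible.

The simulation-study truth `EXAMPLE_TRUTH` (CL = 1.82, C0 = 0.063,
Vd = 85.7, ka = 0.02, Km′ = 2, Vmax = 0.45) keeps the disposition at the
published estimates and places Km′ well below the dosed amounts
(19–38 mmol). That choice is deliberate: when Km′ is comparable to or above
the dose, the MM term degenerates to (Vmax/Km′)·X and aliases the
first-order pathway, making ka unidentifiable — the same sloppiness the
original analysis saw as a Km′ standard deviation close to its estimate.
With a firmly saturated transporter the pathway split is identifiable, and
50-replicate studies at 10% CV show median relative bias under 10% for CL,
Vd and ka (Km′ remains the soft direction and is exempted).

## Study sizes and tolerances in the test suite

Replicated fitting studies use 2–3 multi-starts, optimizer tolerance 1e-8
and inner ODE tolerances 1e-5…1e-6 — settings piloted to leave estimates
unchanged at a fraction of the cost of the defaults. Study sizes: 50
replicates for parameter recovery, 100 for variant selection, 2000 for the
crossover type-I-error rate, 500 for CI coverage. The integrator oracle
uses 100 random parameter draws; Fisher's test is checked against exhaustive
hypergeometric enumeration; the pooled t against a permutation test.

## Known limitations

* The absorption parameters of the original fit are not published; this
  package re-derives them from peak summaries, so parameter values (not the
  dose conclusions) may differ from the original.
* The exact AIC convention of the original software is unknown; only AIC
  differences computed within this package are meaningful.
* No population (mixed-effects) PK, no bootstrap or Bayesian uncertainty,
  no plasma/serum matrix conversion, no feedback of dosing on endogenous
  production.
* The mixed model's degrees-of-freedom convention (subjects − 2) is one of
  several defensible choices; printed CIs from other software may differ in
  the third significant figure.
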