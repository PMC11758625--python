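# ketopk

Pharmacokinetic modelling and trial statistics for oral 3-hydroxybutyrate
(3-HB), the major circulating ketone body. The package is aimed at
pharmacometricians and nutrition researchers who want to reproduce, probe or
extend a dose-optimization analysis in which a one-compartment model fitted
to 2 g and 4 g dosing data predicts the minimum oral dose whose peak serum
concentration (Cmax) reaches 0.28 mM — the level reported to initiate ketone
metabolism in the brain — and in which the resulting 3.5 g dose is evaluated
in a 2×2 crossover efficacy trial.

## The model

An oral dose places an amount X (mmol) of 3-HB in a gastrointestinal depot.
Absorption runs through two parallel pathways — a saturable,
transporter-mediated route with Michaelis–Menten kinetics and a non-saturable
first-order route — into a single well-stirred compartment of volume Vd (L)
holding serum 3-HB at concentration C (mM). Endogenous ketogenesis proceeds
at the constant rate CL·C0, balancing linear elimination at clearance CL so
that the system rests at the basal concentration C0 when the gut is empty:

    dX/dt      = − Vmax·X/(Km′ + X) − ka·X,            X(0) = Dose
    Vd·dC/dt   = CL·C0 + Vmax·X/(Km′ + X) + ka·X − CL·C,   C(0) = C0

with Vmax (mmol/min) the transporter capacity, Km′ (mmol) the half-saturation
amount (Michaelis constant × gut volume), and ka (1/min) the first-order
absorption rate constant. Doses in grams are converted with the molar mass
of 3-hydroxybutyric acid (104.10 g/mol).

On top of the forward model the package provides

* **`pk_fit`** — simultaneous nonlinear least-squares estimation of all six
  parameters across dose arms, with multi-start trust-region optimisation in
  log space, linearised standard errors, least-squares AIC
  (n·ln(SSR/n) + 2p) and comparison of the full model against
  saturable-only and nonsaturable-only reductions;
* **`dose_finder`** — minimum-dose search to a target Cmax by grid scan or
  bisection (Cmax is strictly increasing in dose);
* **`efficacy`** — the 2×2 crossover analysis: change scores, the POMS2
  total-mood-disturbance composite, a linear mixed model with sequence,
  period and treatment as fixed effects and a subject random intercept,
  two-sample t-tests and Fisher's exact test;
* **`synthetic`** — generators for noisy concentration–time datasets and
  crossover trials, so every stage is testable without any external data.

## Worked example

The raw concentration tables of the dosing study are not deposited, but its
printed summaries are enough to rebuild the model: fix the disposition
estimates (CL = 1.82 L/min, C0 = 0.063 mM, Vd = 85.7 L) and calibrate the
three absorption parameters so that simulated 2 g and 4 g doses reproduce
the printed peaks (0.266 mM at 30 min and 0.289 mM at 45 min):

```python
from ketopk import reference_parameters, DoseSearchSpec
from ketopk import find_min_dose_grid, find_min_dose_bisect

params = reference_parameters(seed=0)
# CalibrationInfeasibleWarning: calibration residuals up to 16.7% exceed 5%
print(params)
# PKParameters(CL=1.82, C0=0.063, ka=0.02002, Km_prime=0.1000,
#              Vd=85.7, Vmax=0.4769)

spec = DoseSearchSpec(target_cmax=0.28)
print(find_min_dose_grid(params, spec))     # 3.5
print(round(find_min_dose_bisect(params, spec), 2))  # 3.11
```

The warning is expected: with the printed clearance and distribution volume
fixed, no admissible absorption profile can push the 2 g peak as high as the
printed 0.266 mM at 30 min (see `docs/methods.md`), so the calibration
reports its residual instead of hiding it. The fitted absorption is strongly
saturated (Km′ at its lower bound — the transporter runs at capacity
throughout) plus a first-order component of ka ≈ 0.02 /min.

The dose scan then recommends **3.5 g** as the smallest 0.5 g-step dose whose
simulated Cmax reaches 0.28 mM; continuous bisection places the crossing at
about 3.1 g, consistent with the contrast between simulated 3 g and 3.5 g
doses. Simulating the recommended dose:

```python
from ketopk import DoseInput, simulate, summarize_cmax
profile = simulate(params, DoseInput(3.5), t_end=240.0)
print(summarize_cmax(profile))   # (0.2983, 43.1) — Cmax mM, Tmax min
```

i.e. a 3.5 g dose peaks at 0.298 mM about 43 min after ingestion, clearing
the 0.28 mM target, while a 2 g dose peaks at 0.222 mM and does not.

The same pipeline is exposed on the command line:

```
ketopk calibrate --fixed CL=1.82,C0=0.063,Vd=85.7 --constraints peaks.csv --out cal.json
ketopk find-dose --params cal.json --target-cmax 0.28
ketopk generate trial --out trial.csv
ketopk crossover --data trial.csv --out effect.csv
```

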