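# Methods

## Model family

Every candidate model is a regression of airway pressure on basis
functions of volume and flow,

    P(t) = a_1 f_1(t) + … + a_m f_m(t) + P0,

so that the coefficient vector A = (a_1 … a_m, P0) follows from the
normal equations A = (XᵀX)⁻¹XᵀP on the design matrix X whose columns
are the f_i evaluated on the record (intercept last). Columns that are
copies of measured channels are used verbatim; the acceleration column
is the central difference of measured flow; fractional columns apply
the Grünwald–Letnikov (GL) operator to measured volume. When the
reciprocal condition number of X falls below 1e−12 — typical for
nested-exponential columns, which are nearly collinear with the volume
column — the solve switches to the SVD pseudo-inverse and returns the
minimal-norm solution.

Parameters that enter nonlinearly (fractional orders α, β; exponential
rates x, β) cannot come out of the linear solve. They are searched:
integer polynomial exponents exhaustively over 1…11, continuous
parameters by particle swarm optimisation (PSO).

### Admissibility

A candidate coefficient vector is accepted only if every entry,
including P0, is strictly positive (zero fails). For the integer-order
family this is the Routh–Hurwitz stability condition; physically,
elastance, resistance and PEEP are positive quantities. Inadmissible
candidates receive an infinite objective score rather than being
repaired; a fit whose best candidate is inadmissible is returned as an
explicit failure result.

## Grünwald–Letnikov fractional differentiation

The GL derivative of order α at step h is the causal weighted sum
D^α f[i] = h^(−α) Σ_{j≤i} ω_j f[i−j] with ω_0 = 1 and
ω_j = (1 − (α+1)/j)·ω_{j−1}, equal to (−1)^j·binom(α, j). The signal
is taken as zero before its first sample, so no initialisation data
are needed; memory is full-length by default (a short-memory window
exists but is off, since no truncation rule is part of the method).
Orders up to 2 use the same recursion; at α = 1 the weights collapse
to (1, −1, 0, …) and the operator is exactly the backward difference.
Whole-series evaluation is a discrete convolution with a direct and an
FFT path that agree to ~1e−12 relative; the per-step split
ω_0-term + history ("memory term") feeds the implicit simulator.

## Particle swarm search

Positions start uniform in the bound box, velocities uniform in
±(UB−LB)/2; the velocity update uses inertia 0.729 and cognitive =
social = 1.49445 (standard constriction-style constants, configurable);
positions leaving the box are clamped to the boundary. Every draw comes
from one seeded generator, so runs are reproducible. Each candidate is
scored the way models are finally judged: solve the coefficients,
reject if inadmissible, forward-simulate volume from pressure, return
the SSR against measured volume. (A fast alternative objective scoring
the pressure-regression residual ‖XA − P‖² is available via
`objective="pressure"` for screening, but prediction-based scoring is
the default because the regression alone cannot predict V from P.)
Saturation swarm sizes, below which repeated runs stop improving, are
N = M = 5 for the single-fractional model, 10 for the exponential
family and 20 for the hybrid; these are the defaults per family.

Fractional-order search bounds default to α ∈ [0.01, 2]; an accepted
order above 1 is legitimate (inertance-like behaviour), hence the
upper bound above 1. Exponential rates are bounded above by
6.5/max|V| (ln 6.5/max|V| for the triple exponential) so that the
nested exponential stays finite in double precision.

## Forward simulation

Prediction of volume from a pressure program solves, at every step i,

    g(V) = Σ_terms(V; history) + P0 − P[i] = 0,

with flow ≈ (V − V[i−1])/h (fully implicit backward difference),
acceleration ≈ (V − 2V[i−1] + V[i−2])/h² (flat pre-history), and each
fractional term split into h^(−α)·(ω_0 V + memory of *previously
simulated* volumes). The simulator never reads measured volume, which
is what makes cross-validation a genuine prediction. For admissible
coefficients g is strictly increasing in V (slope ≥ E + R/h), so the
per-step root is unique. Models linear in the current sample (all
integer/fractional linear models) use the closed-form update
V = −const/slope; nonlinear terms (powers, nested exponentials) use
Newton from the previous volume with analytic derivatives, safeguarded
by doubling bracket expansion (cap 60) and bisection, to a residual
tolerance of 1e−10 mbar (configurable). The initial volume is 0 by
default and configurable, e.g. to a record's first measured volume.

### Accuracy

The backward scheme is first-order: against the analytic step response
of the single-compartment model the maximum error is ≈ V′(0⁺)·h/(2e) —
3.2e−3 L at h = 0.01 with a 12.6 mbar step through R ≈ 7.2 — and
shrinks linearly in h (empirical ratio ≈ 1.98 per halving; the O(h²)
correction has opposite sign, so the ratio approaches 2 from below).
The scheme is kept first-order deliberately: the flow discretization
must equal the α = 1 GL operator for the model family to be internally
consistent (a fractional term with α = 1 must behave exactly like
added resistance), and it must match the design matrix's
backward-difference convention so that feeding a simulated record back
through the regression reproduces the driving pressure to solver
tolerance. That conservation identity holds for every model except
`second_order`, whose design matrix uses the central difference of
flow for the acceleration column while the stepper is backward.

Two closed forms verify the simulator by substitution: the first-order
step/sinusoid responses, and the tan-form solution of the quadratic
model P = EV + RV′ + aV² + P0 (evaluated over the complex field so the
physically common tanh branch needs no special casing).

One documented oddity: the hybrid's stand-alone double exponential
b·e^{e^{βV}} is nonzero at V = 0, so driving the hybrid with constant
baseline pressure P ≡ P0 settles at the small negative root of
E·V + b·e^{e^{βV}} = 0 rather than exactly zero. The term is
implemented exactly as the model states it (the exponential-family
term a·e^{e^{xV}}·V, by contrast, multiplies V); the asymmetry is
intentional and flagged, not "fixed".

## Evaluation

SSR = Σ(V_i − V̂_i)² in L², RMSE = √(SSR/n), CV(RMSE) = RMSE / mean
measured volume, Pearson r between measured and simulated volume, and
the equivalent BIC = n·ln(SSR) + k·ln(n) (natural log; note ln(SSR),
not the classical ln(SSR/n) — the two differ only by a constant at
fixed n, so rankings agree). k counts every estimated quantity:
coefficients, offset, and each searched nonlinear parameter — the
convention validated by back-calculating reference fit tables, where
k = 3/5/5/7 for the single/fractional/double-exponential/hybrid
families reproduces the published BIC values within the ±1.5 bound
implied by 4-decimal SSR rounding (15000·Δln SSR ≈ 1.3). Rankings are
ascending in BIC with SSR as tie-break. A perfect fit (SSR = 0)
reports BIC = −∞ as a sentinel rather than raising.

## Synthetic data generator

The generator emulates ventilator records: 150 s at h = 10 ms (15 000
rows, ≈ 50 breaths) by default, written in the package's three-column
TSV dialect.

- **PC mode** — pressure is a periodic trapezoid: baseline PEEP
  3 mbar, linear rise (0.1 s) to the 15 mbar plateau, hold through the
  inspiratory third of a 3 s cycle, linear fall back to PEEP. Volume
  comes from forward simulation of the ground-truth model.
- **VC mode** — constant inspiratory flow sized to deliver the 0.3 L
  tidal volume, passive exponential expiration (τ = one fifth of the
  expiratory window) scaled so each cycle's *discrete* net volume is
  exactly zero; volume is the running integral of flow and pressure is
  the ground-truth model applied to (V, V′).

After construction, the three channels are made mutually consistent
with the fitting pipeline's discretization (flow is the grid backward
difference of volume; pressure is the truth model evaluated on the
stored channels), so a zero-noise fixture is recovered *exactly* by
the estimator — the round trip is an identity, not an approximation.
Independent zero-mean Gaussian noise is then added per channel
(defaults 0.05 mbar, 0.005 L/s, 0.001 L); the flow channel gets its
own noise rather than a derivative of noisy volume, mirroring a
ventilator's independent flow sensor. The noiseless record and true
parameters are returned alongside, and a fixed seed gives
byte-identical files. The default truth is the single-compartment
model at a physiological porcine regime (E = 26.1130 cmH2O/L,
R = 7.1716 cmH2O·s/L, P0 = 3.3972 mbar). Pressure is treated as mbar
throughout while elastance/resistance are conventionally quoted in
cmH2O units; the ~2% unit difference (1 mbar = 1.0197 cmH2O) is
deliberately not converted, matching field practice.

What the generator does **not** emulate: spontaneous breathing effort,
leaks, valve-governed expiratory dynamics, SIMV trigger logic, or
correlated/quantization noise. Passing recovery tests therefore show
correctness of the estimation machinery on generator-matched data, not
clinical validity on real recordings.

## Identifiability and the noise model

The fractional column D^α V of a smooth quasi-periodic volume signal
is nearly collinear with the V and V′ columns, and the GL operator
amplifies white noise by h^(−α). Plain least squares is therefore
acutely sensitive to noise on the *regressor* channels: with white
noise of SD 0.003 L (1% of tidal volume) on the volume channel the
fractional coefficient collapses toward zero and the SSR-optimal α
drops by ~0.3 — the term becomes unidentifiable. This is a genuine
limitation of the method (no regularisation or errors-in-variables
correction is part of it), not of the implementation.

Real ventilators integrate volume digitally from flow, so the
kinematic channels are far smoother than white millilitre-scale noise;
the measurement noise lives mainly in the pressure transducer.
Parameter-recovery experiments therefore use 1% measurement noise on
pressure (SD 0.15 mbar = 1% of the plateau) with instrument-scale
noise on flow (5e−4 L/s) and volume (5e−5 L). Under these conditions a
5-particle, 5-iteration swarm recovers a generating α = 0.6 within
±0.05 in 2 of 3 seeds (the SSR basin in α is flat near the optimum, so
single-seed misses are expected and the criterion is a 2-of-3 one).

In the 7-parameter hybrid model the pair (a, α) trades off along a
flat SSR valley and is not point-identified even with clean
regressors; E, R, the exponential amplitude b and P0 recover within
10%, and prediction quality is unaffected. Recovery claims for the
hybrid are therefore made for the well-identified parameters and the
predicted volume, not for (a, α) individually.

## Numerical choices and edge cases

- Root tolerance 1e−10 mbar residual; Newton cap 100 iterations;
  bracket doubling cap 60; bisection cap 200.
- Full GL memory (J = series length); no per-breath memory reset — a
  record has a single time origin.
- Records require n ≥ 1, finite values, h > 0; the sampling interval
  is a reader argument (default 0.01 s), not stored in files.
- Blank lines in waveform files are skipped; any other malformation is
  a parse error naming the 1-based line number. Decimal separator is
  "." only.
- Design-matrix columns with non-finite entries (exponential overflow)
  raise an error naming the offending term; inside a swarm search the
  candidate simply scores +∞.
- Problem sizes in the test suite and acceptance script: recovery
  experiments use the full 150 s/15 000-sample records; the hybrid
  ranking experiment uses 30 s records, where the ranking is already
  unambiguous (BIC gap > 50 to the runner-up).

## Known limitations

- First-order simulator accuracy (see above); step-response errors at
  h = 0.01 are a few mL for sharp pressure steps.
- Fractional and hybrid fits are O(n²) in record length because of the
  full GL memory inside the per-step simulation.
- No uncertainty quantification: the method reports point estimates
  and per-seed spread only.
- The `second_order` acceleration column's central-difference
  convention breaks the exact regression/simulation conservation
  identity for that one model.
- Cross-validation assumes equal sampling intervals between periods
  and starts from V0 = 0 unless configured otherwise.
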