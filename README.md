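# ventmech

Lumped-parameter respiratory mechanics modelling for mechanical
ventilation: fit, simulate and compare lung models on ventilator
pressure/flow/volume recordings, including fractional-order
(Grünwald–Letnikov) and double-exponential elastance terms and a hybrid
model combining both.

## Who it is for

Researchers and engineers working with mechanical-ventilation waveforms
who want to estimate respiratory-system parameters (elastance,
resistance, PEEP offset), predict the volume curve from an airway
pressure program, and select among candidate models with an
information criterion — without hand-rolling the numerics each time.

## The models

All candidates relate airway pressure P(t) [mbar] to volume V(t) [L]
and flow V′(t) [L/s] as a linear combination of basis terms plus an
offset. The catalogue (`predefined_specs()`) covers:

| name           | equation                                                        | k |
|----------------|-----------------------------------------------------------------|---|
| `single`       | P = E·V + R·V′ + P0                                             | 3 |
| `second_order` | P = E·V + R·V′ + I·V″ + P0                                      | 4 |
| `fractional`   | P = E·V + R·V′ + a·D^α V + P0                                   | 5 |
| `fractional2`  | P = E·V + R·V′ + a·D^α V + b·D^β V + P0                         | 7 |
| `poly_v` / `poly_f` / `poly_vv` | polynomial elastance/resistance, e.g. P = E·V + R·V′ + a·Vˣ + P0 | 5–7 |
| `exp1`–`exp3`  | nested-exponential elastance, e.g. P = E·V + a·e^{e^{xV}}·V + R·V′ + P0 | 5 |
| `hybrid`       | P = E·V + R·V′ + a·D^α V + b·e^{e^{βV}} + P0                    | 7 |

Here E is the respiratory-system elastance (cmH2O/L, compliance
C = 1/E), R the airway resistance (cmH2O·s/L), P0 the positive
end-expiratory pressure offset, and D^α the Grünwald–Letnikov
fractional derivative

    D^α f[i] = h^(−α) Σ_{j=0..i} ω_j f[i−j],   ω_0 = 1,
    ω_j = (1 − (α+1)/j) ω_{j−1},

which captures the memory-dependent viscoelasticity of lung tissue.
The fractional order α and the exponential rates x, β enter nonlinearly
("non-coefficient parameters") and are searched by a seeded particle
swarm; everything else comes from a least-squares solve with a
pseudo-inverse fallback for near-singular designs. Fits are accepted
only if every coefficient is strictly positive (Routh–Hurwitz
stability / physical plausibility), and volume prediction is done by a
fully-implicit per-step solver so that cross-validation — fitting on
one time period, predicting another from its pressure alone — is a
genuine prediction. Models are compared with the equivalent Bayesian
information criterion

    BIC = n·ln(SSR) + k·ln(n),

where k counts all estimated quantities including the swarm-searched
parameters.

## Worked example

```python
from ventmech import SyntheticConfig, fit_model, generate_record, get_spec

truth = (26.1130, 7.1716, 3.3972)   # E, R, P0
config = SyntheticConfig(duration=60.0, truth_coefficients=truth, seed=0)
record, _ = generate_record(config)  # 60 s PC-mode record, noisy channels
fit = fit_model(record, get_spec("single"))
```

Running `python examples/01_generate_and_fit.py` prints:

```
record: 6000 samples at h = 0.01 s (60 s, ~20 breaths)
fitted : E = 26.1104 cmH2O/L, R = 7.1703 cmH2O*s/L, P0 = 3.3969 mbar
truth  : E = 26.1130, R = 7.1716, P0 = 3.3972
scores : SSR = 0.0064 L^2, RMSE = 0.0010 L, CV(RMSE) = 0.0076, r = 1.0000
```

i.e. the generating mechanics are recovered to a fraction of a percent
through realistic measurement noise, and the simulated volume curve
tracks the measured one to ~1 mL RMS. Model comparison
(`python examples/03_model_comparison.py`) fits four candidates on
hybrid-generated volume-controlled data and ranks them:

```
 rank      model         BIC    SSR   RMSE  CV_RMSE      r  k  time_s
    1     hybrid -17103.2214 0.0033 0.0010   0.0118 0.9999  7  3.5563
    2       exp2 -17052.9176 0.0034 0.0011   0.0120 0.9999  5  0.8013
    3 fractional  -6202.2304 0.1248 0.0065   0.0730 0.9976  5  0.0847
    4     single  -5847.6988 0.1412 0.0069   0.0777 0.9972  3  0.0032
```

The other examples demonstrate fractional-order recovery by particle
swarm (`02`) and simulator accuracy plus cross-period validation
(`04`).

## Command line

The same workflow is available as a thin CLI:

```sh
ventmech synth --mode PC --duration 150 --seed 1 --out case.txt
ventmech fit --model fractional --input case.txt --seed 1 --out fit.json
ventmech simulate --input case.txt --params fit.json --out sim.txt
ventmech compare --model single --model hybrid --input case.txt --out-csv cmp.csv
ventmech crossval --model single --fit-input a.txt --validate-input b.txt
```

Records are plain UTF-8 text, one sample per line, three tab-separated
columns — pressure (mbar), flow (L/s), volume (L) — sampled every
10 ms by default.

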