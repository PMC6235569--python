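# epishear

Analysis of how an epithelial monolayer responds to localized in-plane
shear. When a 100 µm shear step is applied at the midline of an MDCK
monolayer suspended on two microfabricated planks, the tissue shows two
distinct responses: a short-lived passive deformation of the 2–3 cell layers
(<50 µm) beside the shear plane, moving opposite the shear, and a long-term
collective oscillation perpendicular to it — an inward wave that launches
from the shear plane roughly 10× faster than the cells themselves move and
then reverses direction every few hours with decaying magnitude, like a
damped oscillator. `epishear` implements the full data path for this
system, for researchers in tissue mechanobiology working with PIV-derived
velocity fields and on-chip force sensors:

- **Kymographs** — horizontal averaging of 18×15-gridded velocity frames,
  "folding" of the two planks over the shear plane, 15-min binning,
  cumulative trapezoidal integration to displacement traces, and an
  onset-threshold estimator of the inward-front propagation speed.
- **Force relaxation** — conversion of sensing-plank deflection to force via
  the calibrated spring (k_s = 0.93 N/m) and a three-parameter exponential
  fit F(t) = F_∞ + (F_MAX − F_∞)e^(−t/τ), where τ is the 63.2% decay time.
- **Damped oscillation** — nonlinear fit of
  v(t) = v₀ + A·e^(−t/2D)·sin(2π(t − t₀)/P) to the mean y-velocity,
  reversal detection, and the rank-based two-stage condition comparison
  (Kruskal–Wallis gate, then pairwise Mann–Whitney U).
- **Mechanical model** — a Maxwell branch (spring k, damper c) in parallel
  with an inerter b, driven by an inward step force; c = kD,
  b = kP²/(4π²), damping ratio ζ = √(kb)/(2c). Fixed-step RK4 simulation
  with an exact pole-decomposition oracle.
- **Synthetic data** — a seeded generator reproducing the statistical
  structure of the measurements per experimental condition (`+Shear`,
  `-Shear`, `+Blebb`, `+Jasp`, `T151`), so the whole pipeline runs and is
  tested without any microscopy data.

The package follows the statsmodels idiom: build a model object from data,
call `fit()`, get a results object with estimates, diagnostics and a
`summary()`; simulation and plotting hang off those objects.

## Worked example

```python
from epishear import *
from epishear.kymo import fold_fields

preset = make_condition_preset("+Shear", noise_sd=0.0)   # noiseless fixture
fields, truth = generate_velocity_series(preset, seed=1)

kymo = fold_fields(fields, "y")                  # folded y-velocity kymograph
front = estimate_propagation_speed(kymo)
print(f"front speed: {front.speed:.1f} um/h (R^2 = {front.r_squared:.3f})")

fit = fit_damped_sinusoid(mean_velocity_series(kymo), t_min=10.0)
print(fit.summary())

trace, _ = generate_sensing_trace(preset, f_max=1.0, noise_sd_um=0.0)
relax = fit_exponential_decay(displacement_to_force(trace, k_s=0.93))
print(relax.summary())

circuit = ShearCircuit(k=1.0, c=1.0 * fit.damping_time,
                       b=inertance_for_period(1.0, fit.period))
rev = circuit.simulate_step_response(t_end=20.0).detrended().reversal_times()
print(f"zeta = {circuit.zeta:.3f}; simulated reversals (h):",
      ", ".join(f"{t:.2f}" for t in rev))
```

Output:

```
front speed: 288.9 um/h (R^2 = 0.990)
Damped sinusoid  v(t) = v0 + A exp(-t/2D) sin(2pi (t - t0)/P)
------------------------------------------------------------
A (amplitude)            16.28  um/h
P (period)                   8  h
D (damping time)             5  h
t0 (phase)               7.019  h
v0 (offset)         -8.663e-15  um/h
RSS                  3.342e-24
n obs                      160
Force relaxation (3-parameter exponential decay)
------------------------------------------------
F_MAX                  1  uN
F_inf                0.2  uN
tau                  3.7  min  (63.2% decay time)
RSS            1.099e-21
n obs                 61
zeta = 0.127; simulated reversals (h): 0.33, 4.36, 8.39, 12.43, 16.46
```

Reading it: the inward wave front crosses the plank at ~290 µm/h, an order
of magnitude faster than the ~30 µm/h cell speed; the collective y-velocity
oscillates with an 8 h period and a 5 h damping time, first reversing ~7 h
after shear; the sensed force relaxes with τ = 3.7 min toward a 20%
residual plateau; and the circuit built from those fits (ζ ≈ 0.13) reverses
direction every damped half-period ≈ 4 h, mirroring the measured reversals.

There is also a CLI for shell use — `epishear generate | kymo | force |
fit | simulate | run` — where `run` executes the whole pipeline (three
seeded replicates per condition, stage CSVs, JSON report):

```sh
epishear run --condition +Shear --condition +Blebb --seed 7 --out out/
```

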