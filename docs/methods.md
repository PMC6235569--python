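# Methods

`epishear` reimplements, as a tested pipeline, the analysis of how an
epithelial monolayer (MDCK cells grown across two suspended silicon planks)
responds to a 100 µm in-plane shear applied at its midline: construction and
integration of PIV-derived velocity kymographs, force-relaxation analysis
from the on-chip spring sensor, damped-oscillation fitting of the collective
y-velocity, and simulation of a lumped spring–damper–inerter circuit of the
tissue. A synthetic-data generator stands in for the microscopy-derived
inputs so every stage is exercisable and testable offline.

## Coordinate and sign conventions

x is the shear direction (positive = direction of actuation), y the in-plane
axis perpendicular to the shear plane. Distances are row-center distances
from the shear plane: the 300 × 250 µm field per plank is divided into an
18 × 15 (width × height) PIV grid, so rows are 250/15 ≈ 16.7 µm tall with
centers at 8.33 … 241.67 µm (the labels "8 µm" and "242 µm" refer to the
first and last row centers). After folding, positive y-velocity means
outward (away from the shear plane) on both planks; the passive
deformation-zone x-motion is negative (opposite the applied shear). Time is
hours relative to the moment of shear; frames run from −1 h to +23.25 h at
5 min, the sensing plank is sampled at 30 s from −5 to +30 min.

## Kymographs

Each frame is averaged horizontally (18 columns → 1) giving one 15-position
profile per time point. Folding sign-flips the bottom plank's y-velocity and
averages rows equidistant from the shear plane (x-velocities average without
the flip); folding an exactly antisymmetric pair reproduces the top plank
bit-for-bit, which the tests assert at zero noise. Binning averages
non-overlapping blocks of 3 frames (15-min bins), averaging a trailing
partial block over its actual count. Displacement traces are cumulative
trapezoidal integrals of velocity over time, zeroed at the first post-shear
bin; requested positions snap to the nearest row center and error beyond
half a row. The mean velocity series is the unweighted vertical average of
the unbinned folded y-kymograph.

**Front-speed estimator.** Per row, the onset of the inward wave is the
first post-shear time the inward (negative) velocity exceeds 0.25 × the
global post-shear |v| maximum; a least-squares line of position against
onset time gives the speed, with R² reported. The threshold fraction is
exposed in the configuration. Simultaneous onsets return an infinite-speed
sentinel with a warning; fewer than three detected rows is an error. On
noiseless synthetic kymographs the estimator recovers generating wave speeds
in [50, 500] µm/h within 5%; the residual bias (≲1%) comes from the 5-min
frame quantisation of onset times.

## Force relaxation

The sensing plank is a calibrated spring, k_s = 0.93 N/m; deflection × k_s
gives force (1 µm × 1 N/m = 1 µN). The post-shear force is fitted over
0–30 min with the three-parameter model F(t) = F_inf + (F_MAX − F_inf)
e^(−t/τ) by nonlinear least squares (all parameters bounded below by zero).
The free plateau F_inf reflects the observed incomplete relaxation; τ is
therefore defined against the decaying span F_MAX − F_inf and is the
63.2% (1 − 1/e) decay time of that span. Initialisation: F_MAX from the
first post-shear sample, F_inf from the last, τ from the linearly
interpolated 63.2% crossing. A direct crossing read of τ is kept as a
cross-check (`ForceRelaxationResults.crossing_tau`). Pre-shear samples only
verify a near-zero baseline (warning above 5% of the peak). Because the
model is scale-equivariant, τ is independent of the (arbitrary) force scale.

## Damped-oscillation fit

The mean y-velocity is fitted with
v(t) = v0 + A e^(−t/(2D)) sin(2π(t − t0)/P).
The envelope is parameterised as e^(−t/(2D)) deliberately: the circuit map
c = kD then agrees exactly with the circuit's pole real part −k/(2c), so the
fitted D and the simulated envelope are the same quantity. Initialisation:
P from the dominant FFT peak of the detrended series, A from max |v − v̄|,
the decay rate from a log-envelope regression on successive extrema, t0 from
the first upward zero crossing. The decay rate is bounded at zero; a fit
whose envelope decays by less than 5% over the window reports D = ∞
(undamped), and an exactly flat series short-circuits to a flagged
degenerate A = 0 result. Amplitude is referenced to t = 0, so shifting the
time axis rescales A by the envelope factor while leaving P and D unchanged.

Reversals are zero crossings of the 3-bin moving-average-smoothed series,
linearly interpolated between bracketing samples; crossings in the first
30 min (deformation transient) are excluded, and exact-zero samples are
handled by placing the crossing mid-run.

**Fit window.** The fit itself uses t ≥ 0, but on synthetic data the first
~10 h contain the inward transient (see below), which is deliberately not a
sinusoid; recovery tests and the pipeline therefore fit from t = 10 h, after
every row has passed its first reversal, where the generated mean series is
an exact damped sinusoid. On that window the noiseless round-trip is exact
and the noisy median parameter errors are ~1%.

**Condition comparison.** Replicate-level fitted A, P, D are compared with a
Kruskal–Wallis omnibus test (tie-corrected); pairwise Mann–Whitney U tests
run only when the omnibus p < α = 0.05. The exact permutation null is used
when both samples have n ≤ 8 and no ties, the tie-corrected normal
approximation otherwise; the test suite checks the exact path against a full
enumeration of rank assignments. Identical samples in all groups return
p = 1 with no pairwise tests.

## Mechanical circuit

A Maxwell branch (spring k in series with damper c) in parallel with an
inerter b, driven by an inward step force: F_INT alone (unsheared) or
F_INT + F_EXT with F_EXT = 4 F_INT (sheared). State equations

    b dv/dt = F(t) − F_m,    dF_m/dt = k v − (k/c) F_m

give s² + (k/c)s + k/b = 0, ω0 = √(k/b), ζ = √(kb)/(2c), intrinsic period
P = 2π√(b/k). This topology is the unique reading of "k and c in series,
in parallel with b" consistent with both b = kP²/(4π²) (undamped period) and
c = kD under the e^(−t/(2D)) envelope convention. Parameter maps: k is held
at 1 across conditions (only normalized output is compared); c = kD;
b = kP²/(4π²) when the mechanical signal propagates, and an overdamped
sentinel 10⁴ × that value when the propagation rate is zero (myosin
inhibition, E-cadherin truncation) — a finite sentinel avoids a
special-cased degenerate integrator while guaranteeing ζ ≫ 1 and no
velocity reversals. An undamped oscillation fit combined with finite
propagation (actin stabilisation) sets c from a configurable damping-ratio
floor ζ = 0.05, with a warning.

Simulation is fixed-step RK4 from rest (deterministic, bit-reproducible);
the default step is the minimum of P/1000, t_end/2000 and 0.1/|s|_max, and
explicit steps are validated against both the period (dt ≤ P/100) and RK4
stability (|s|_max·dt ≤ 2.5). The analytic oracle solves the same system by
pole decomposition, with a critically-damped formula inside a 10⁻⁹
relative repeated-root window; the suite checks sup-norm agreement < 10⁻⁶
(normalized) across 20 random parameter draws spanning ζ ∈ [0.05, 3].

**Drift and reversals.** Under a sustained step the Maxwell branch makes the
node drift at the terminal velocity F/c, which offsets the simulated zero
crossings alternately by ±asin(offset/envelope)/ω_d — an artifact of the
sustained-step idealisation, not of the oscillation. Reversal analysis of
simulations therefore uses the drift-removed (detrended) velocity, whose
crossings are spaced by exactly the damped half-period π/(ω0√(1−ζ²));
both raw and detrended series are reported in the pipeline output.

## Synthetic-data generator

The generator's defaults are the study conditions; they are not tuning
knobs. Per condition it emulates: the initial inward y-wave front
propagating at `wave_speed_initial` (290 µm/h sheared, 80 µm/h
actin-stabilised); the damped collective oscillation (period 8 h, first
mean-series reversal at 7 h); the amplitude gradient across the plank
(linear ramp from 0.3× at the innermost row to 1× at the outermost, stated
only qualitatively in the source data, "cells furthest from the shear plane
move most"); later reversal fronts staggered across rows at
`wave_speed_reversal` (90 µm/h, the midpoint of the reported 80–100 µm/h);
the <50 µm passive deformation zone with x-motion opposite the shear,
decaying with a 0.75 h constant and ceasing by 3 h; and, for the
actin-stabilised condition, a low-amplitude x oscillation in an extended
100 µm zone. The bottom plank carries the antisymmetric y-signal; noise is
i.i.d. Gaussian per grid cell (default sd 3 µm/h, a convention — the PIV
noise level is not characterised in the source).

Per row (distance y, time t): nothing before the front arrives at
t_on = y/c_init; a quarter-cosine inward lobe at full amplitude from front
arrival, releasing to zero at the row's first reversal R1(y); then the
shared damped sinusoid with sign flips every half period. R1(y) is staggered
as first_reversal + (y − y_ref)/c_rev with y_ref the amplitude-weighted mean
row distance, so the preset's `first_reversal` is the *mean-series* first
reversal — matching how the reversal times were read off the data. The
sharp-edged front matches the kymographs and keeps the onset estimator
faithful; a slow rise would lag the threshold crossing in a row-dependent
way. Because all rows share frequency and envelope, the mean series past the
transient is an exact damped sinusoid whose amplitude and delay follow from
the phasor sum of the row signals; both are recorded in the `GroundTruth`
sidecar and are the reference for recovery tests.

Choices the printed record does not fix, made once: damping time D = 5 h for
the oscillating untreated conditions (reversal magnitudes visibly decay over
~3 cycles); force plateau fraction 0.2 (relaxation is visibly incomplete,
no printed asymptote); myosin-inhibited deformation peak 15 µm/h ("less
than" the untreated 30 µm/h); sensing noise 2% of peak deflection. The
generator does not model cell division, extrusion, density changes, image
formation, or PIV estimation error structure (correlated noise, outlier
vectors); passing tests therefore demonstrate correctness of the analysis
chain, not robustness to every artifact of real microscopy data.

## Problem sizes and determinism

Default runs use the full study geometry: 292 frames × 2 planks × 15 × 18
cells per replicate, 3 replicates per condition (matching the three
independent experiments), 71-sample sensing traces, and 2 000–2 500-step
simulations. All randomness flows through `numpy.random.default_rng` seeded
from the preset or the pipeline master seed (replicate seeds are
`seed + 1000·condition_index + replicate`), so a run's configuration plus
seed reproduces its outputs byte-for-byte; the configuration hash in the
report is the SHA-256 of the canonical config JSON.

## Known limitations

- The lumped circuit is a single y-direction mode; it has no spatial
  resolution and cannot describe the deformation zone or the x-response.
- The generator's transient lobe is a convention; only its onset sharpness,
  reversal staggering and post-transient sinusoid are constrained by the
  study's printed numbers.
- With three replicates per condition the exact Mann–Whitney floor is
  p = 0.1 two-sided, so single pairwise comparisons cannot reach 0.05;
  the omnibus gate across ≥3 conditions can.
- `load_external_fields` accepts the package's long CSV layout only; the
  study's deposited `.mat` PIV exports must be converted to that layout
  first.
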