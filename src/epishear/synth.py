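"""Synthetic velocity-field series and sensing-plank displacement traces.

The generator emulates the statistical structure of the study's PIV output so
every downstream stage (kymograph folding, front estimation, oscillation and
force fitting, model simulation) can be exercised without the deposited data.

y-velocity model (top plank, row center at distance ``y`` from the shear
plane, time ``t`` in hours after shear):

* nothing before the inward front arrives at ``t_on(y) = y / wave_speed_initial``;
* from front arrival to the row's first reversal ``R1(y)``, a sustained
  inward lobe ``-A r(y) E(t) cos(pi/2 * (t - t_on)/(R1 - t_on))`` — full
  amplitude at front arrival, smoothly releasing to zero at the reversal;
* from ``R1(y)`` on, the damped sinusoid
  ``+A r(y) E(t) sin(2 pi (t - R1)/P)``, so sign flips occur every half
  period, staggered across rows.

Here ``E(t) = exp(-t / (2 D))`` is the shared envelope, ``r(y)`` a linear
amplitude ramp from 0.3 at the innermost row to 1 at the outermost row (cells
furthest from the shear plane move most), and
``R1(y) = first_reversal + (y - y_ref)/wave_speed_reversal`` with ``y_ref``
the ramp-weighted mean row distance, so the *mean* velocity series reverses
first at ``first_reversal``.  Because all rows share frequency and envelope,
the vertical mean is an exact damped sinusoid once every row has passed its
first reversal.

x-velocity: a passive deformation-zone transient confined to
``deform_zone_width`` of the shear plane, opposite the shear direction,
decaying with ``deform_decay`` and ceasing by 3 h; plus (actin-stabilised
condition only) a low-amplitude x oscillation in an extended zone.

The bottom plank carries the antisymmetric y-signal (``v_bottom = -v_top``
before noise) and the same x-signal.  Noise is i.i.d. Gaussian per grid cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, VelocityField
from .presets import ConditionPreset

DEFAULT_SPRING_CONSTANT = 0.93  # N/m, sensing-plank spring
X_TRANSIENT_STOP = 3.0          # h, x-deformation ceases by here


# ---------------------------------------------------------------------------
# ground truth bookkeeping


@dataclass
class GroundTruth:
    """All generating parameters of a realized dataset, for recovery tests."""

    kind: str                       # "velocity" | "sensing"
    preset: dict
    seed: int
    grid: Optional[dict] = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "preset": self.preset, "seed": self.seed,
                "grid": self.grid, "params": self.params}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# closed-form signal components


def amplitude_ramp(grid: GridSpec, inner_frac: float = 0.3) -> np.ndarray:
    """Linear amplitude ramp across rows: inner_frac at row 0 up to 1."""
    y = grid.row_centers
    if len(y) == 1:
        return np.array([1.0])
    return inner_frac + (1.0 - inner_frac) * (y - y[0]) / (y[-1] - y[0])


def _reversal_reference(grid: GridSpec, ramp: np.ndarray) -> float:
    """Ramp-weighted mean row distance; centres the reversal stagger."""
    y = grid.row_centers
    return float(np.sum(ramp * y) / np.sum(ramp))


def envelope(t: np.ndarray, damping_D: float) -> np.ndarray:
    """Shared oscillation envelope exp(-t/(2D)); 1 everywhere if undamped."""
    if math.isinf(damping_D):
        return np.ones_like(np.asarray(t, dtype=float))
    return np.exp(-np.asarray(t, dtype=float) / (2.0 * damping_D))


def v_signal(times: np.ndarray, grid: GridSpec, preset: ConditionPreset) -> np.ndarray:
    """Noiseless top-plank y-velocity, shape (n_times, n_rows), um/h."""
    times = np.asarray(times, dtype=float)
    out = np.zeros((len(times), grid.n_rows))
    if not preset.oscillates:
        return out
    ramp = amplitude_ramp(grid)
    y_ref = _reversal_reference(grid, ramp)
    env = envelope(times, preset.osc_damping_D)
    P = preset.osc_period
    for j, y in enumerate(grid.row_centers):
        t_on = y / preset.wave_speed_initial
        r1 = preset.first_reversal + (y - y_ref) / preset.wave_speed_reversal
        amp = preset.osc_amplitude * ramp[j]
        lobe = times >= t_on
        inward = lobe & (times < r1)
        osc = times >= r1
        if r1 > t_on:
            out[inward, j] = -amp * env[inward] * np.cos(
                0.5 * np.pi * (times[inward] - t_on) / (r1 - t_on))
        out[osc, j] = amp * env[osc] * np.sin(2.0 * np.pi * (times[osc] - r1) / P)
    return out


def u_signal(times: np.ndarray, grid: GridSpec, preset: ConditionPreset) -> np.ndarray:
    """Noiseless x-velocity (same on both planks), shape (n_times, n_rows)."""
    times = np.asarray(times, dtype=float)
    out = np.zeros((len(times), grid.n_rows))
    post = times >= 0.0
    y = grid.row_centers
    if preset.deform_peak_speed > 0 and preset.deform_zone_width > 0:
        zone = np.clip(1.0 - y / preset.deform_zone_width, 0.0, None)
        taper = np.clip(1.0 - times[post] / X_TRANSIENT_STOP, 0.0, None)
        decay = np.exp(-times[post] / preset.deform_decay) * taper
        out[np.ix_(post, np.arange(grid.n_rows))] += (
            -preset.deform_peak_speed * decay[:, None] * zone[None, :])
    if preset.x_osc_amplitude > 0 and preset.x_osc_zone > 0:
        zone = np.clip(1.0 - y / preset.x_osc_zone, 0.0, None)
        env = envelope(times[post], preset.osc_damping_D)
        osc = np.sin(2.0 * np.pi * times[post] / preset.osc_period)
        out[np.ix_(post, np.arange(grid.n_rows))] += (
            -preset.x_osc_amplitude * (env * osc)[:, None] * zone[None, :])
    return out


# ---------------------------------------------------------------------------
# generators


def generate_velocity_series(
    preset: ConditionPreset,
    grid: Optional[GridSpec] = None,
    seed: Optional[int] = None,
) -> tuple[list[VelocityField], GroundTruth]:
    """Generate the two-plank velocity-field series for one condition.

    Returns the fields ordered by time (top then bottom plank per frame) and
    the :class:`GroundTruth` sidecar holding every generating parameter,
    including the per-row front-onset and first-reversal times and the exact
    amplitude/delay of the post-transient mean velocity series.
    """
    grid = grid or GridSpec()
    if seed is None:
        seed = preset.seed
    rng = np.random.default_rng(seed)
    times = grid.frame_times()
    vs = v_signal(times, grid, preset)
    us = u_signal(times, grid, preset)

    fields: list[VelocityField] = []
    shape = (grid.n_rows, grid.n_cols)
    for i, t in enumerate(times):
        for plank, v_sig in (("top", vs[i]), ("bottom", -vs[i])):
            u = us[i][:, None] + _noise(rng, preset.noise_sd, shape)
            v = v_sig[:, None] + _noise(rng, preset.noise_sd, shape)
            fields.append(VelocityField(time=float(t), plank=plank, u=u, v=v, grid=grid))

    ramp = amplitude_ramp(grid)
    y_ref = _reversal_reference(grid, ramp)
    y = grid.row_centers
    if preset.oscillates:
        onsets = (y / preset.wave_speed_initial).tolist()
        r1 = preset.first_reversal + (y - y_ref) / preset.wave_speed_reversal
        # phasor sum: the mean series past the transient is exactly
        # A_eff * E(t) * sin(2 pi (t - delay_eff)/P)
        z = np.sum(ramp * np.exp(-2j * np.pi * r1 / preset.osc_period))
        a_eff = preset.osc_amplitude * abs(z) / grid.n_rows
        delay_eff = float((-np.angle(z) * preset.osc_period / (2 * np.pi))
                          % preset.osc_period)
        r1_list = r1.tolist()
    else:
        onsets, r1_list, a_eff, delay_eff = [], [], 0.0, 0.0
    truth = GroundTruth(
        kind="velocity", preset=preset.to_dict(), seed=int(seed),
        grid=grid.to_dict(),
        params=dict(
            row_centers=y.tolist(), amplitude_ramp=ramp.tolist(),
            reversal_reference_um=y_ref, onset_times_h=onsets,
            first_reversal_times_h=r1_list,
            mean_series_amplitude=a_eff, mean_series_delay_h=delay_eff,
        ),
    )
    return fields, truth


def _noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    # draw even at sd=0 so noiseless/noisy runs consume the same stream
    if sd == 0:
        return np.zeros(shape)
    return rng.normal(0.0, sd, shape)


@dataclass
class SensingDisplacementTrace:
    """Sensing-plank deflection (um) at 30-s cadence around the shear step."""

    times: np.ndarray        # s relative to shear
    displacement: np.ndarray  # um
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.shape != self.displacement.shape:
            raise ValueError("times and displacement must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "displacement_um": self.displacement})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensingDisplacementTrace":
        df = pd.read_csv(path)
        missing = {"time_s", "displacement_um"} - set(df.columns)
        if missing:
            raise ValueError(f"sensing CSV missing column(s): {sorted(missing)}")
        return cls(times=df["time_s"].to_numpy(), displacement=df["displacement_um"].to_numpy())


def generate_sensing_trace(
    preset: ConditionPreset,
    f_max: float = 1.0,
    seed: Optional[int] = None,
    k_s: float = DEFAULT_SPRING_CONSTANT,
    plateau: float = 0.2,
    noise_sd_um: Optional[float] = None,
    t_start_min: float = -5.0,
    t_end_min: float = 30.0,
    sample_interval_s: float = 30.0,
) -> tuple[SensingDisplacementTrace, GroundTruth]:
    """Generate a sensing-plank displacement trace for the force stage.

    The noiseless displacement is zero before shear and
    ``(f_max/k_s) * [(1 - plateau) * exp(-t/tau) + plateau]`` after, with
    ``tau`` the preset's force-relaxation constant in minutes.  1 um deflection
    at 1 N/m is 1 uN, so ``f_max`` is in uN.  Default noise is 2% of the peak
    displacement; pass ``noise_sd_um=0`` for a noiseless trace.
    """
    if preset.tau_force is None:
        raise ValueError(
            f"condition {preset.name!r} has no force-relaxation data "
            "(no tau_force); skip the force stage for this condition"
        )
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    if k_s <= 0:
        raise ValueError("spring constant k_s must be positive")
    if not 0 <= plateau < 1:
        raise ValueError("plateau fraction must be in [0, 1)")
    if seed is None:
        seed = preset.seed
    rng = np.random.default_rng(seed)
    times_s = np.arange(t_start_min * 60.0, t_end_min * 60.0 + sample_interval_s / 2,
                        sample_interval_s)
    t_min = times_s / 60.0
    peak = f_max / k_s
    disp = np.where(
        t_min < 0, 0.0,
        peak * ((1.0 - plateau) * np.exp(-np.clip(t_min, 0, None) / preset.tau_force)
                + plateau))
    if noise_sd_um is None:
        noise_sd_um = 0.02 * peak
    if noise_sd_um < 0:
        raise ValueError("noise_sd_um must be non-negative")
    if noise_sd_um > 0:
        disp = disp + rng.normal(0.0, noise_sd_um, disp.shape)
    trace = SensingDisplacementTrace(times=times_s, displacement=disp, seed=int(seed))
    truth = GroundTruth(
        kind="sensing", preset=preset.to_dict(), seed=int(seed),
        params=dict(f_max_uN=f_max, k_s_N_per_m=k_s, plateau=plateau,
                    tau_min=preset.tau_force, noise_sd_um=noise_sd_um,
                    peak_displacement_um=peak),
    )
    return trace, truth


# ---------------------------------------------------------------------------
# long-format CSV I/O for velocity series


VELOCITY_COLUMNS = ["time_h", "plank", "row", "col", "y_um", "u_um_per_h", "v_um_per_h"]


def velocity_series_to_frame(fields: Sequence[VelocityField]) -> pd.DataFrame:
    """Long-format table of a velocity-field series (one row per grid cell)."""
    if not fields:
        raise ValueError("empty velocity-field sequence")
    grid = fields[0].grid
    rows, cols = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    y_um = grid.row_centers[rows]
    parts = []
    for f in fields:
        parts.append(pd.DataFrame({
            "time_h": f.time, "plank": f.plank,
            "row": rows.ravel(), "col": cols.ravel(), "y_um": y_um.ravel(),
            "u_um_per_h": f.u.ravel(), "v_um_per_h": f.v.ravel(),
        }))
    return pd.concat(parts, ignore_index=True)


def write_velocity_csv(fields: Sequence[VelocityField], path) -> None:
    velocity_series_to_frame(fields).to_csv(path, index=False)
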