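"""Kymograph construction, folding, binning, integration and front fitting.

A kymograph is a time x distance-from-shear-plane matrix of one velocity
component, obtained by averaging each PIV frame horizontally (18 columns ->
1) so the default grid yields 15 positions per time point.  The two planks
are "folded" over the shear plane: the bottom plank's y-velocity is sign
flipped so positive means outward on both planks, then rows equidistant from
the plane are averaged (x-velocities average without the flip).

Sign conventions: folded y — positive = outward, negative = inward;
x — positive = shear direction, so passive deformation-zone motion is
negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from .grid import VelocityField

DEFAULT_POSITIONS = (8.0, 50.0, 100.0, 150.0, 200.0, 242.0)


@dataclass
class Kymograph:
    component: str            # "x" | "y"
    times: np.ndarray         # h, bin centers
    y_positions: np.ndarray   # um from shear plane, row centers
    values: np.ndarray        # um/h, (n_times, n_positions)
    folded: bool = False
    bin_width: int = 1        # frames per time bin
    plank: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y_positions = np.asarray(self.y_positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.times), len(self.y_positions)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.times)} times x {len(self.y_positions)} positions")
        if np.any(np.diff(self.y_positions) <= 0):
            raise ValueError("y_positions must be strictly increasing")
        if self.folded and np.any(self.y_positions < 0):
            raise ValueError("folded kymograph positions must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{y:.2f}" for y in self.y_positions])
        df.insert(0, "time_h", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DisplacementTraces:
    """Cumulative displacement (um) at selected distances from the shear plane."""

    times: np.ndarray          # h, >= 0
    y_positions: np.ndarray    # um, snapped row centers
    displacement: np.ndarray   # um, (n_times, n_positions), zero at first time
    requested: np.ndarray      # um, positions as requested
    component: str = "y"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.displacement,
                          columns=[f"{y:.2f}" for y in self.y_positions])
        df.insert(0, "time_h", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class MeanVelocitySeries:
    """Vertical (over-position) average of a folded kymograph."""

    times: np.ndarray   # h
    mean_v: np.ndarray  # um/h
    component: str = "y"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_v = np.asarray(self.mean_v, dtype=float)
        if self.times.shape != self.mean_v.shape:
            raise ValueError("times and mean_v must have equal length")


@dataclass
class PropagationFit:
    """Front speed from the onset-time regression, with diagnostics."""

    speed: float              # um/h, slope of position vs onset time
    intercept: float          # um
    r_squared: float
    threshold: float          # um/h used for onset detection
    onset_times: np.ndarray   # h, per detected row
    positions: np.ndarray     # um, rows with a detected onset


# ---------------------------------------------------------------------------


def build_kymograph(fields: Sequence[VelocityField], component: str) -> Kymograph:
    """Horizontally average one plank's velocity frames into a kymograph."""
    if component not in ("x", "y"):
        raise ValueError("component must be 'x' or 'y'")
    fields = list(fields)
    if not fields:
        raise ValueError("empty velocity-field sequence")
    grid = fields[0].grid
    plank = fields[0].plank
    for f in fields:
        if f.grid != grid:
            raise ValueError("all fields must share one GridSpec")
        if f.plank != plank:
            raise ValueError(
                "fields mix planks; build one kymograph per plank "
                "(see build_plank_kymographs)")
    times = np.array([f.time for f in fields])
    if np.any(np.diff(times) <= 0):
        raise ValueError("field times must be strictly increasing")
    values = np.stack([f.component(component).mean(axis=1) for f in fields])
    return Kymograph(component=component, times=times,
                     y_positions=grid.row_centers, values=values,
                     folded=False, plank=plank)


def build_plank_kymographs(fields: Sequence[VelocityField], component: str) -> dict:
    """Split a mixed-plank series and build one unfolded kymograph per plank."""
    by_plank: dict[str, list[VelocityField]] = {}
    for f in fields:
        by_plank.setdefault(f.plank, []).append(f)
    return {plank: build_kymograph(fs, component) for plank, fs in by_plank.items()}


def fold_kymograph(top: Kymograph, bottom: Kymograph) -> Kymograph:
    """Average the two planks over the shear plane.

    y-component: the bottom plank's sign is flipped first so that positive
    means outward on both planks; x-component averages without a flip.
    """
    if top.folded or bottom.folded:
        raise ValueError("fold_kymograph expects unfolded per-plank kymographs")
    if top.component != bottom.component:
        raise ValueError("cannot fold kymographs of different components")
    if top.values.shape != bottom.values.shape:
        raise ValueError(
            f"shape mismatch: top {top.values.shape} vs bottom {bottom.values.shape}")
    if not np.allclose(top.times, bottom.times):
        raise ValueError("plank kymographs must share time axes")
    if top.component == "y":
        values = 0.5 * (top.values - bottom.values)
    else:
        values = 0.5 * (top.values + bottom.values)
    return Kymograph(component=top.component, times=top.times.copy(),
                     y_positions=top.y_positions.copy(), values=values,
                     folded=True, bin_width=top.bin_width, plank=None)


def fold_fields(fields: Sequence[VelocityField], component: str) -> Kymograph:
    """Convenience: build both plank kymographs from a mixed series and fold."""
    per_plank = build_plank_kymographs(fields, component)
    missing = {"top", "bottom"} - set(per_plank)
    if missing:
        raise ValueError(f"series is missing plank(s): {sorted(missing)}")
    return fold_kymograph(per_plank["top"], per_plank["bottom"])


def bin_kymograph(k: Kymograph, n: int = 3) -> Kymograph:
    """Average non-overlapping blocks of ``n`` consecutive time rows.

    The default n=3 turns 5-min PIV frames into 15-min bins.  A trailing
    partial block is averaged over its actual count; n larger than the series
    collapses it to a single bin.
    """
    if n < 1 or int(n) != n:
        raise ValueError("bin size n must be a positive integer")
    n = int(n)
    if n == 1:
        return replace(k, times=k.times.copy(), values=k.values.copy(),
                       y_positions=k.y_positions.copy())
    n_t = len(k.times)
    edges = np.arange(0, n_t, n)
    times = np.array([k.times[s:s + n].mean() for s in edges])
    values = np.stack([k.values[s:s + n].mean(axis=0) for s in edges])
    return Kymograph(component=k.component, times=times,
                     y_positions=k.y_positions.copy(), values=values,
                     folded=k.folded, bin_width=k.bin_width * n, plank=k.plank)


def snap_position(k: Kymograph, position: float) -> int:
    """Index of the row center nearest ``position``; errors beyond half a row."""
    diffs = np.abs(k.y_positions - position)
    idx = int(np.argmin(diffs))
    row_height = float(np.median(np.diff(k.y_positions))) if len(k.y_positions) > 1 else np.inf
    if diffs[idx] > row_height / 2 + 1e-9:
        raise ValueError(
            f"position {position} um is outside the plank; valid positions lie "
            f"within half a row of [{k.y_positions[0]:.2f}, {k.y_positions[-1]:.2f}] um")
    return idx


def integrate_displacement(
    k: Kymograph, positions: Sequence[float] = DEFAULT_POSITIONS
) -> DisplacementTraces:
    """Cumulative trapezoidal time integral of velocity at selected rows.

    Positions snap to the nearest row center; integration starts at the first
    post-shear bin, where displacement is zero.
    """
    idxs = [snap_position(k, p) for p in positions]
    post = k.times >= 0.0
    if not np.any(post):
        raise ValueError("kymograph has no post-shear time points")
    t = k.times[post]
    disp = np.stack(
        [cumulative_trapezoid(k.values[post, i], t, initial=0.0) for i in idxs],
        axis=1)
    return DisplacementTraces(times=t, y_positions=k.y_positions[idxs],
                              displacement=disp,
                              requested=np.asarray(positions, dtype=float),
                              component=k.component)


def mean_velocity_series(k: Kymograph) -> MeanVelocitySeries:
    """Unweighted mean across positions per time point (folded kymograph)."""
    if not k.folded:
        raise ValueError("mean_velocity_series expects a folded kymograph")
    if k.bin_width != 1:
        warnings.warn("mean velocity series is normally taken from the unbinned "
                      f"kymograph; got bin_width={k.bin_width}", stacklevel=2)
    return MeanVelocitySeries(times=k.times.copy(),
                              mean_v=k.values.mean(axis=1),
                              component=k.component)


def estimate_propagation_speed(
    k: Kymograph, threshold_frac: float = 0.25
) -> PropagationFit:
    """Estimate the inward-front propagation speed from onset times.

    Per row, the onset is the first post-shear time the *inward* (negative)
    velocity exceeds ``threshold_frac`` x the global post-shear |v| maximum;
    a least-squares line of position against onset time gives the speed.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    post = k.times >= 0.0
    t = k.times[post]
    vals = k.values[post]
    vmax = np.max(np.abs(vals)) if vals.size else 0.0
    if vmax == 0:
        raise ValueError("no propagating front: kymograph is identically zero")
    threshold = threshold_frac * vmax
    onsets, positions = [], []
    for j, y in enumerate(k.y_positions):
        hits = np.nonzero(vals[:, j] < -threshold)[0]
        if len(hits):
            onsets.append(t[hits[0]])
            positions.append(y)
    if len(onsets) < 3:
        raise ValueError(
            f"no propagating front: inward onset detected in only "
            f"{len(onsets)} row(s); need at least 3")
    onsets = np.asarray(onsets)
    positions = np.asarray(positions)
    if np.ptp(onsets) == 0:
        warnings.warn("simultaneous onset at all rows; front speed unresolvably "
                      "fast, returning inf", stacklevel=2)
        return PropagationFit(speed=np.inf, intercept=float(positions.mean()),
                              r_squared=1.0, threshold=threshold,
                              onset_times=onsets, positions=positions)
    fit = linregress(onsets, positions)
    return PropagationFit(speed=float(fit.slope), intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue ** 2), threshold=threshold,
                          onset_times=onsets, positions=positions)
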