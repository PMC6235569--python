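"""Spatial/temporal calibration of the PIV grid and the velocity-field container.

The shear device holds two parallel planks (top = actuating, bottom = sensing),
each imaged over a 300 um x 250 um field that the PIV step divides into an
18 x 15 (width x height) grid.  Row 0 is the row nearest the shear plane; row
centers sit at (i + 1/2) * plank_height / n_rows from the plane, i.e. ~8.3 um
to ~241.7 um for the default grid.  Frames are 5 min apart from 1 h before
shear (t = 0) to 23.25 h after.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Layout of one plank's PIV grid and the imaging cadence."""

    n_cols: int = 18
    n_rows: int = 15
    field_width: float = 300.0      # um
    plank_height: float = 250.0     # um
    frame_interval: float = 5.0     # min between velocity frames
    sensing_interval: float = 30.0  # s between sensing-plank images
    t_start: float = -1.0           # h relative to shear
    t_end: float = 23.25            # h relative to shear

    def __post_init__(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.plank_height <= 0 or self.field_width <= 0:
            raise ValueError("field dimensions must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def row_height(self) -> float:
        """Height of one PIV row in um."""
        return self.plank_height / self.n_rows

    @property
    def row_centers(self) -> np.ndarray:
        """Distance of each row center from the shear plane, um, increasing."""
        return (np.arange(self.n_rows) + 0.5) * self.row_height

    def frame_times(self) -> np.ndarray:
        """Frame times in hours relative to shear, strictly increasing."""
        dt = self.frame_interval / 60.0
        n = int(round((self.t_end - self.t_start) / dt)) + 1
        return self.t_start + dt * np.arange(n)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


PLANKS = ("top", "bottom")


@dataclass
class VelocityField:
    """One PIV frame for one plank.

    ``u`` is the x-velocity (positive = shear direction) and ``v`` the
    y-velocity, both in um/h on an (n_rows, n_cols) grid.  On the top plank
    positive v points away from the shear plane; the bottom plank carries the
    globally signed value, so outward motion on the bottom plank is negative
    (folding flips it back, see :mod:`epishear.kymo`).
    """

    time: float                 # h relative to shear
    plank: str                  # "top" | "bottom"
    u: np.ndarray               # um/h, (n_rows, n_cols)
    v: np.ndarray               # um/h, (n_rows, n_cols)
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if self.plank not in PLANKS:
            raise ValueError(f"plank must be one of {PLANKS}, got {self.plank!r}")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        expected = (self.grid.n_rows, self.grid.n_cols)
        if self.u.shape != expected or self.v.shape != expected:
            raise ValueError(
                f"velocity grids must have shape {expected}, "
                f"got u{self.u.shape}, v{self.v.shape}"
            )
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("velocity fields must be finite")

    def component(self, name: str) -> np.ndarray:
        if name == "x":
            return self.u
        if name == "y":
            return self.v
        raise ValueError("component must be 'x' or 'y'")
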