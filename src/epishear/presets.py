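"""Per-condition parameter presets for the synthetic generator.

Each experimental condition of the shear study maps to one preset:

* ``+Shear``   — exogenous shear on wild-type MDCK: fast inward front
  (290 um/h), damped 8-h oscillation at ~30 um/h cell speed, force relaxation
  tau = 3.7 min.
* ``-Shear``   — no applied shear: spontaneous oscillation at ~9 um/h, same
  period/damping class, no deformation zone, no force-relaxation data.
* ``+Blebb``   — myosin II inhibited: no oscillation, no propagation, fast
  force relaxation (tau = 1.3 min), weaker passive x-deformation.
* ``+Jasp``    — actin filaments stabilised: slower cells (10 um/h),
  propagation 80 um/h, effectively undamped oscillation, slow force
  relaxation (tau = 6.2 min), extra x-direction oscillation.
* ``T151``     — E-cadherin extracellular truncation: no oscillation, no
  propagation, force response indistinguishable from +Shear (tau = 3.7 min).

Speeds are um/h, times hours unless noted; ``tau_force`` is minutes.  A
damping time of ``math.inf`` means undamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, fields as dc_fields
from typing import Optional


@dataclass(frozen=True)
class ConditionPreset:
    name: str
    osc_amplitude: float        # um/h, outermost-row oscillation amplitude
    osc_period: float           # h
    osc_damping_D: float        # h, envelope exp(-t/(2D)); inf = undamped
    first_reversal: float       # h, mean-series first sign change
    wave_speed_initial: float   # um/h, initial inward front; 0 = no propagation
    wave_speed_reversal: float  # um/h, later reversal fronts
    deform_zone_width: float    # um, passive x-deformation zone
    deform_peak_speed: float    # um/h, peak x-speed at the shear plane
    deform_decay: float         # h, x-transient decay constant
    x_osc_amplitude: float      # um/h, x-direction oscillation (Jasp only)
    x_osc_zone: float           # um, zone of the x oscillation
    tau_force: Optional[float]  # min, force-relaxation constant; None = no data
    f_ext_to_f_int: float       # F_EXT / F_INT ratio (0 when unsheared)
    noise_sd: float             # um/h, additive PIV noise per grid cell
    seed: int = 0

    def __post_init__(self) -> None:
        if self.osc_amplitude < 0 or self.osc_period <= 0:
            raise ValueError("oscillation amplitude must be >= 0 and period > 0")
        if not (self.osc_damping_D > 0):  # inf passes
            raise ValueError("osc_damping_D must be positive or inf")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for f in ("wave_speed_initial", "wave_speed_reversal",
                  "deform_zone_width", "deform_peak_speed", "deform_decay"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.tau_force is not None and self.tau_force <= 0:
            raise ValueError("tau_force must be positive when present")

    @property
    def oscillates(self) -> bool:
        return self.osc_amplitude > 0 and self.wave_speed_initial > 0

    def replace(self, **overrides) -> "ConditionPreset":
        d = asdict(self)
        d.update(overrides)
        return ConditionPreset(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["osc_damping_D"]):
            d["osc_damping_D"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionPreset":
        d = dict(d)
        if d.get("osc_damping_D") == "inf":
            d["osc_damping_D"] = math.inf
        return cls(**d)


_PRESETS: dict[str, dict] = {
    "+Shear": dict(
        osc_amplitude=30.0, osc_period=8.0, osc_damping_D=5.0,
        first_reversal=7.0, wave_speed_initial=290.0, wave_speed_reversal=90.0,
        deform_zone_width=50.0, deform_peak_speed=30.0, deform_decay=0.75,
        x_osc_amplitude=0.0, x_osc_zone=0.0,
        tau_force=3.7, f_ext_to_f_int=4.0, noise_sd=3.0,
    ),
    "-Shear": dict(
        osc_amplitude=9.0, osc_period=8.0, osc_damping_D=5.0,
        first_reversal=7.0, wave_speed_initial=90.0, wave_speed_reversal=90.0,
        deform_zone_width=0.0, deform_peak_speed=0.0, deform_decay=0.75,
        x_osc_amplitude=0.0, x_osc_zone=0.0,
        tau_force=None, f_ext_to_f_int=0.0, noise_sd=3.0,
    ),
    "+Blebb": dict(
        osc_amplitude=0.0, osc_period=8.0, osc_damping_D=math.inf,
        first_reversal=7.0, wave_speed_initial=0.0, wave_speed_reversal=0.0,
        deform_zone_width=50.0, deform_peak_speed=15.0, deform_decay=0.75,
        x_osc_amplitude=0.0, x_osc_zone=0.0,
        tau_force=1.3, f_ext_to_f_int=4.0, noise_sd=3.0,
    ),
    "+Jasp": dict(
        osc_amplitude=10.0, osc_period=8.0, osc_damping_D=math.inf,
        first_reversal=7.0, wave_speed_initial=80.0, wave_speed_reversal=90.0,
        deform_zone_width=100.0, deform_peak_speed=30.0, deform_decay=0.75,
        x_osc_amplitude=3.0, x_osc_zone=100.0,
        tau_force=6.2, f_ext_to_f_int=4.0, noise_sd=3.0,
    ),
    "T151": dict(
        osc_amplitude=0.0, osc_period=8.0, osc_damping_D=math.inf,
        first_reversal=7.0, wave_speed_initial=0.0, wave_speed_reversal=0.0,
        deform_zone_width=50.0, deform_peak_speed=30.0, deform_decay=0.75,
        x_osc_amplitude=0.0, x_osc_zone=0.0,
        tau_force=3.7, f_ext_to_f_int=4.0, noise_sd=3.0,
    ),
}

CONDITION_NAMES = tuple(_PRESETS)

# Accept the obvious spelling variants ("+shear", "Shear", "-shear" ...).
_ALIASES = {name.lstrip("+").lower(): name for name in _PRESETS}
_ALIASES.update({name.lower(): name for name in _PRESETS})


def make_condition_preset(name: str, **overrides) -> ConditionPreset:
    """Return the parameter preset for one experimental condition.

    Parameters
    ----------
    name
        One of ``+Shear, -Shear, +Blebb, +Jasp, T151`` (case-insensitive,
        leading ``+`` optional except where ambiguous).
    **overrides
        Any preset field, e.g. ``noise_sd=0`` for noiseless fixtures.
    """
    key = _ALIASES.get(str(name).strip().lower())
    if key is None:
        raise ValueError(
            f"unknown condition {name!r}; supported conditions are "
            f"{', '.join(CONDITION_NAMES)}"
        )
    params = dict(_PRESETS[key])
    valid = {f.name for f in dc_fields(ConditionPreset)} - {"name"}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown preset override(s): {sorted(unknown)}")
    params.update(overrides)
    return ConditionPreset(name=key, **params)
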