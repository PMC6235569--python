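"""Lumped spring-damper-inerter circuit of the sheared epithelium.

Topology: a Maxwell branch (spring k in series with damper c) in parallel
with an inerter of inertance b, between the driven node and ground.  The
node velocity v and the Maxwell branch force F_m obey

    b dv/dt   = F(t) - F_m
    dF_m/dt   = k v - (k/c) F_m

which gives the characteristic polynomial s^2 + (k/c) s + k/b = 0, natural
frequency omega0 = sqrt(k/b), damping ratio zeta = sqrt(k b) / (2 c) and
intrinsic period P = 2 pi sqrt(b / k).  The shear input is an inward
(negative) step of magnitude F_INT (unsheared) or F_INT + F_EXT (sheared,
F_EXT = 4 F_INT by default).

Parameter maps from measurements: c = k D with D the fitted envelope damping
time (envelope exp(-t/(2D)) matches the pole real part -k/(2c) exactly);
b = k P^2 / (4 pi^2) when the mechanical signal propagates, and an
effectively infinite sentinel (1e4 x the oscillatory value, deep in the
overdamped regime) when the propagation rate is zero.

Under a sustained step the Maxwell branch drifts at the terminal velocity
F/c; `StepResponse.detrended()` removes that drift, leaving the pure damped
oscillation that is compared with the measured mean cell velocity.

`simulate_step_response` uses fixed-step RK4 (deterministic, bit
reproducible); `closed_form_response` is the analytic oracle via the exact
pole decomposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

B_SENTINEL_FACTOR = 1e4  # overdamped stand-in for an infinite inerter


@dataclass(frozen=True)
class ShearCircuit:
    """Mechanical circuit parameters (arbitrary consistent force units)."""

    k: float                 # stiffness, force/length
    c: float                 # damping, force*time/length (inf = rigid branch)
    b: float                 # inertance, force*time^2/length (inf allowed)
    f_int: float = 1.0       # intrinsic step force magnitude
    f_ratio: float = 4.0     # F_EXT / F_INT
    sheared: bool = True

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("stiffness k must be positive")
        if not self.c > 0:
            raise ValueError("damping c must be positive (inf allowed)")
        if not self.b > 0:
            raise ValueError("inertance b must be positive (inf allowed)")

    # -- derived quantities ------------------------------------------------

    @property
    def omega0(self) -> float:
        """Undamped natural frequency sqrt(k/b) (0 when b = inf)."""
        return 0.0 if math.isinf(self.b) else math.sqrt(self.k / self.b)

    @property
    def zeta(self) -> float:
        """Damping ratio sqrt(k b) / (2 c)."""
        if math.isinf(self.b):
            return math.inf
        if math.isinf(self.c):
            return 0.0
        return math.sqrt(self.k * self.b) / (2.0 * self.c)

    def natural_period(self) -> float:
        """Intrinsic period P = 2 pi sqrt(b/k); inf when b = inf."""
        if math.isinf(self.b):
            return math.inf
        return 2.0 * math.pi * math.sqrt(self.b / self.k)

    def damped_period(self) -> float:
        """Period of the damped oscillation, 2 pi / (omega0 sqrt(1 - zeta^2))."""
        z = self.zeta
        if z >= 1.0 or math.isinf(self.b):
            return math.inf
        return 2.0 * math.pi / (self.omega0 * math.sqrt(1.0 - z * z))

    @property
    def f_total(self) -> float:
        """Total step magnitude: F_INT alone, or F_INT + F_EXT when sheared."""
        return self.f_int * (1.0 + self.f_ratio) if self.sheared else self.f_int

    def poles(self) -> tuple[complex, complex]:
        """Roots of s^2 + (k/c) s + k/b (requires finite b)."""
        if math.isinf(self.b):
            raise ValueError("poles undefined for infinite inertance")
        kc = 0.0 if math.isinf(self.c) else self.k / self.c
        disc = complex(kc * kc - 4.0 * self.k / self.b)
        root = np.sqrt(disc)
        return ((-kc + root) / 2.0, (-kc - root) / 2.0)

    # -- construction from measurements -------------------------------------

    @classmethod
    def from_measurements(cls, k: float, oscillation, propagation_speed: float,
                          sheared: bool = True, f_int: float = 1.0,
                          f_ratio: float = 4.0, zeta_floor: float = 0.05,
                          fallback_period: float = 8.0,
                          b_sentinel_factor: float = B_SENTINEL_FACTOR
                          ) -> "ShearCircuit":
        """Map fitted oscillation parameters to circuit elements.

        ``c = k D`` from the fitted damping time; ``b = k P^2/(4 pi^2)`` from
        the fitted period when the mechanical signal propagates
        (propagation_speed > 0), else the overdamped sentinel
        ``b_sentinel_factor x k P_ref^2/(4 pi^2)``.  An undamped fit
        (D = inf) with finite propagation gets c from the ``zeta_floor``.

        ``oscillation`` is a fitted :class:`DampedOscillationResults` (or any
        object with ``period`` and ``damping_time`` attributes).
        """
        if not k > 0:
            raise ValueError("stiffness k must be positive")
        period = getattr(oscillation, "period", None)
        damping = getattr(oscillation, "damping_time", None)
        degenerate = bool(getattr(oscillation, "degenerate", False))
        if degenerate or period is None or not period > 0:
            period = fallback_period
        if propagation_speed > 0:
            b = k * period ** 2 / (4.0 * math.pi ** 2)
        else:
            b = b_sentinel_factor * k * fallback_period ** 2 / (4.0 * math.pi ** 2)
        if damping is None or degenerate:
            damping = fallback_period  # nominal; overdamped regardless via b
        if math.isinf(damping):
            if propagation_speed > 0:
                c = math.sqrt(k * b) / (2.0 * zeta_floor)
                warnings.warn(
                    "undamped oscillation fit with finite propagation; damping "
                    f"set from the zeta floor {zeta_floor}", stacklevel=2)
            else:
                c = k * fallback_period
        else:
            c = k * damping
        return cls(k=k, c=c, b=b, f_int=f_int, f_ratio=f_ratio, sheared=sheared)

    # -- state space --------------------------------------------------------

    def state_space(self) -> "StateSpace":
        """Linear system x' = A x + B u with x = (v, F_m), u = F(t).

        With b = inf the node cannot move and the system reduces to the
        first-order Maxwell branch relaxation F_m' = -(k/c) F_m.
        """
        if math.isinf(self.b):
            kc = 0.0 if math.isinf(self.c) else self.k / self.c
            return StateSpace(A=np.array([[-kc]]), B=np.array([0.0]),
                              omega0=0.0, zeta=math.inf, poles=(complex(-kc),),
                              reduced=True)
        kc = 0.0 if math.isinf(self.c) else self.k / self.c
        A = np.array([[0.0, -1.0 / self.b], [self.k, -kc]])
        B = np.array([1.0 / self.b, 0.0])
        return StateSpace(A=A, B=B, omega0=self.omega0, zeta=self.zeta,
                          poles=self.poles(), reduced=False)

    # -- simulation ----------------------------------------------------------

    def default_dt(self, t_end: float) -> float:
        """Fixed RK4 step: fine against both the period and the fastest pole."""
        candidates = [t_end / 2000.0]
        P = self.natural_period()
        if math.isfinite(P):
            candidates.append(P / 1000.0)
        if math.isfinite(self.b):
            smax = max(abs(p) for p in self.poles())
            if smax > 0:
                candidates.append(0.1 / smax)
        return min(candidates)

    def simulate_step_response(self, t_end: float = 20.0,
                               dt: Optional[float] = None) -> "StepResponse":
        """Fixed-step RK4 integration of the inward step response from rest."""
        if t_end <= 0:
            raise ValueError("t_end must be positive")
        if dt is None:
            dt = self.default_dt(t_end)
        if dt <= 0:
            raise ValueError("dt must be positive")
        P = self.natural_period()
        if math.isfinite(P) and dt > P / 100.0:
            raise ValueError(
                f"dt={dt:g} h is too coarse for the natural period {P:g} h; "
                f"use dt <= {P / 100.0:g}")
        if math.isfinite(self.b):
            smax = max(abs(p) for p in self.poles())
            if smax * dt > 2.5:
                raise ValueError(
                    f"unstable step size dt={dt:g} for the fastest pole "
                    f"|s|={smax:g} 1/h; use dt <= {2.5 / smax:g}")
        n = int(math.ceil(t_end / dt))
        times = dt * np.arange(n + 1)
        force = -self.f_total  # inward = negative y
        if math.isinf(self.b):
            # no node motion: v = 0, F_m relaxes from rest (stays 0)
            zeros = np.zeros(n + 1)
            return StepResponse(times=times, velocity=zeros.copy(),
                                displacement=zeros.copy(), circuit=self, dt=dt)
        kc = 0.0 if math.isinf(self.c) else self.k / self.c

        def deriv(x):
            v, fm, _ = x
            return np.array([(force - fm) / self.b, self.k * v - kc * fm, v])

        x = np.zeros(3)
        vel = np.empty(n + 1)
        disp = np.empty(n + 1)
        vel[0], disp[0] = 0.0, 0.0
        for i in range(n):
            k1 = deriv(x)
            k2 = deriv(x + 0.5 * dt * k1)
            k3 = deriv(x + 0.5 * dt * k2)
            k4 = deriv(x + dt * k3)
            x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            vel[i + 1] = x[0]
            disp[i + 1] = x[2]
        return StepResponse(times=times, velocity=vel, displacement=disp,
                            circuit=self, dt=dt)

    def closed_form_response(self, times) -> "StepResponse":
        """Exact step response via the pole decomposition (analytic oracle).

        Handles the under-, over- and critically damped branches; a
        near-repeated-root pair (within 1e-9 relative) uses the critically
        damped formula.
        """
        if math.isinf(self.b):
            raise ValueError("closed form requires finite inertance")
        times = np.asarray(times, dtype=float)
        force = -self.f_total
        v_drift = 0.0 if math.isinf(self.c) else force / self.c
        s1, s2 = self.poles()
        scale = max(abs(s1), abs(s2), 1e-300)
        if abs(s1 - s2) <= 1e-9 * scale:
            s = 0.5 * (s1 + s2)
            # v = v_drift + (a1 + a2 t) e^{st}; v(0)=0, v'(0)=F/b
            a1 = -v_drift
            a2 = force / self.b - s * a1
            e = np.exp(s.real * times)
            v = v_drift + (a1.real + a2.real * times) * e
            x = (v_drift * times
                 + _crit_integral(a1.real, a2.real, s.real, times))
        else:
            # v = v_drift + A1 e^{s1 t} + A2 e^{s2 t}
            a2 = (force / self.b + s1 * v_drift) / (s2 - s1)
            a1 = -v_drift - a2
            v = (v_drift + a1 * np.exp(s1 * times) + a2 * np.exp(s2 * times)).real
            x = (v_drift * times
                 + (a1 / s1) * (np.exp(s1 * times) - 1.0)
                 + (a2 / s2) * (np.exp(s2 * times) - 1.0)).real
        return StepResponse(times=times, velocity=np.asarray(v, dtype=float),
                            displacement=np.asarray(x, dtype=float),
                            circuit=self, dt=float(np.median(np.diff(times)))
                            if len(times) > 1 else 0.0)


def _crit_integral(a1: float, a2: float, s: float, t: np.ndarray) -> np.ndarray:
    """Integral of (a1 + a2 t) e^{st} from 0 to t (s < 0 at critical damping)."""
    if s == 0:
        return a1 * t + 0.5 * a2 * t * t
    e = np.exp(s * t)
    return (a1 / s) * (e - 1.0) + a2 * ((t / s) * e - (e - 1.0) / (s * s))


@dataclass
class StateSpace:
    A: np.ndarray
    B: np.ndarray
    omega0: float
    zeta: float
    poles: tuple
    reduced: bool = False


@dataclass
class StepResponse:
    """Simulated or analytic step response of the circuit."""

    times: np.ndarray        # h
    velocity: np.ndarray     # response units/h
    displacement: np.ndarray
    circuit: ShearCircuit = field(repr=False)
    dt: float = 0.0
    normalized: bool = False
    detrend_applied: bool = False
    scale: float = 1.0   # cumulative scaling applied by normalize()

    def detrended(self) -> "StepResponse":
        """Remove the Maxwell terminal drift F/c from the velocity."""
        if self.detrend_applied:
            return self
        c = self.circuit.c
        drift = 0.0 if math.isinf(c) else -self.circuit.f_total / c
        drift *= self.scale  # drift shrinks with any normalization applied
        return replace(self, velocity=self.velocity - drift,
                       displacement=self.displacement - drift * self.times,
                       detrend_applied=True)

    def normalize(self) -> "StepResponse":
        """Scale so that max |velocity| = 1 (displacement scaled alike)."""
        peak = float(np.max(np.abs(self.velocity)))
        if peak == 0:
            raise ValueError("cannot normalize an identically zero response")
        return replace(self, velocity=self.velocity / peak,
                       displacement=self.displacement / peak,
                       scale=self.scale / peak, normalized=True)

    def reversal_times(self) -> np.ndarray:
        """Zero crossings of the velocity after the initial departure from rest."""
        v = self.velocity
        t = self.times
        nz = np.nonzero(v != 0)[0]
        if len(nz) == 0:
            return np.asarray([])
        out = []
        prev = nz[0]
        for i in range(nz[0], len(v) - 1):
            if v[i + 1] == 0:
                continue
            j = i + 1
            if np.sign(v[prev]) != np.sign(v[j]):
                frac = -v[prev] / (v[j] - v[prev])
                out.append(float(t[prev] + frac * (t[j] - t[prev])))
            prev = j
        return np.asarray(out)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_h": self.times, "velocity": self.velocity,
                             "displacement": self.displacement})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, detrend: bool = False):
        import matplotlib.pyplot as plt

        r = self.detrended() if detrend else self
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(r.times, r.velocity, label="velocity")
        ax.axhline(0.0, ls=":", lw=0.8)
        ax.set_xlabel("time after shear (h)")
        ax.set_ylabel("normalized velocity" if self.normalized else "velocity")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# module-level operation surface


def equations_of_motion(m: ShearCircuit) -> StateSpace:
    return m.state_space()


def simulate_step_response(m: ShearCircuit, t_end: float = 20.0,
                           dt: Optional[float] = None) -> StepResponse:
    return m.simulate_step_response(t_end=t_end, dt=dt)


def closed_form_response(m: ShearCircuit, times) -> StepResponse:
    return m.closed_form_response(times)


def natural_period(m: ShearCircuit) -> float:
    return m.natural_period()


def params_from_fit(k: float, fit, propagation: float, **kw) -> ShearCircuit:
    return ShearCircuit.from_measurements(k, fit, propagation, **kw)


def normalize_response(r: StepResponse) -> StepResponse:
    return r.normalize()


def inertance_for_period(k: float, period: float) -> float:
    """b = k P^2 / (4 pi^2): the inertance giving intrinsic period P."""
    if k <= 0 or period <= 0:
        raise ValueError("k and period must be positive")
    return k * period ** 2 / (4.0 * math.pi ** 2)
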