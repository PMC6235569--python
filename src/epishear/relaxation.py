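"""Force sensing: spring conversion and viscoelastic relaxation fitting.

The sensing plank is a calibrated cantilever spring (k_s = 0.93 N/m); its
deflection times k_s gives the force across the monolayer (1 um x 1 N/m =
1 uN).  After the shear step the force peaks (F_MAX) and relaxes like a
viscoelastic material:

    F(t) = F_inf + (F_MAX - F_inf) * exp(-t / tau)

where tau is the 63.2% (1 - 1/e) decay time of the decaying span
F_MAX - F_inf.  `ForceRelaxation` is the model object; `fit()` runs the
three-parameter nonlinear least squares and returns a
`ForceRelaxationResults` with the estimates, residual and a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .synth import SensingDisplacementTrace, DEFAULT_SPRING_CONSTANT


@dataclass
class ForceTrace:
    """Force across the monolayer versus time (minutes relative to shear)."""

    times: np.ndarray   # min
    force: np.ndarray   # uN
    k_s: float = DEFAULT_SPRING_CONSTANT

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.times.shape != self.force.shape:
            raise ValueError("times and force must have equal length")


def displacement_to_force(
    trace: SensingDisplacementTrace, k_s: float = DEFAULT_SPRING_CONSTANT
) -> ForceTrace:
    """Convert plank deflection (um) to force (uN) via the spring constant."""
    if k_s <= 0:
        raise ValueError("spring constant k_s must be positive")
    return ForceTrace(times=trace.times / 60.0, force=k_s * trace.displacement, k_s=k_s)


@dataclass
class FMax:
    """Peak post-shear force and when it occurred."""

    value: float  # uN
    time: float   # min


def extract_fmax(trace: ForceTrace) -> FMax:
    """Maximum force over t >= 0 (the first post-shear sample when relaxing)."""
    post = trace.times >= 0.0
    if not np.any(post):
        raise ValueError("trace has no post-shear samples")
    i = int(np.argmax(trace.force[post]))
    return FMax(value=float(trace.force[post][i]), time=float(trace.times[post][i]))


def _decay_model(t, f_max, f_inf, tau):
    return f_inf + (f_max - f_inf) * np.exp(-t / tau)


class ForceRelaxation:
    """Exponential force-relaxation model for a post-shear force trace.

    Parameters
    ----------
    trace
        Force trace spanning the shear step (t = 0).
    fit_window
        (t_min, t_max) in minutes for the fit; default 0-30 min.
    """

    def __init__(self, trace: ForceTrace, fit_window: tuple[float, float] = (0.0, 30.0)):
        self.trace = trace
        self.fit_window = fit_window
        lo, hi = fit_window
        mask = (trace.times >= lo) & (trace.times <= hi)
        self.t = trace.times[mask]
        self.f = trace.force[mask]
        if len(self.t) < 10:
            raise ValueError("need at least 10 post-shear samples to fit")
        if np.ptp(self.f) == 0:
            raise ValueError("constant force trace; relaxation fit is undefined")
        self._check_baseline()

    def _check_baseline(self) -> None:
        pre = self.trace.times < 0
        if np.any(pre):
            baseline = float(np.mean(np.abs(self.trace.force[pre])))
            fmax = float(np.max(np.abs(self.f)))
            if fmax > 0 and baseline > 0.05 * fmax:
                warnings.warn(
                    f"pre-shear force baseline ({baseline:.3g} uN) exceeds 5% of "
                    f"the post-shear peak ({fmax:.3g} uN)", stacklevel=3)

    def initial_params(self) -> tuple[float, float, float]:
        """(F_MAX, F_inf, tau) start values.

        F_MAX from the first post-shear sample, F_inf from the last, tau from
        the linearly interpolated 63.2% crossing of the span.
        """
        f0 = float(self.f[0])
        finf = float(self.f[-1])
        tau0 = crossing_tau(self.t, self.f, f0, finf)
        return f0, finf, tau0

    def fit(self) -> "ForceRelaxationResults":
        p0 = self.initial_params()
        p0 = (max(p0[0], 1e-12), max(p0[1], 0.0), max(p0[2], 1e-6))
        try:
            popt, pcov = curve_fit(
                _decay_model, self.t, self.f, p0=p0,
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=10000)
        except RuntimeError as err:
            raise RuntimeError(
                f"force-relaxation fit did not converge (start values "
                f"F_MAX={p0[0]:.4g}, F_inf={p0[1]:.4g}, tau={p0[2]:.4g} min): {err}"
            ) from err
        resid = self.f - _decay_model(self.t, *popt)
        return ForceRelaxationResults(
            model=self, f_max=float(popt[0]), f_inf=float(popt[1]),
            tau=float(popt[2]), rss=float(np.sum(resid ** 2)),
            cov=pcov, nobs=len(self.t))


@dataclass
class ForceRelaxationResults:
    """Fitted exponential relaxation: peak, plateau, and 63.2% decay time."""

    model: ForceRelaxation = field(repr=False)
    f_max: float   # uN
    f_inf: float   # uN
    tau: float     # min
    rss: float
    cov: np.ndarray = field(repr=False)
    nobs: int = 0

    def predict(self, t) -> np.ndarray:
        return _decay_model(np.asarray(t, dtype=float), self.f_max, self.f_inf, self.tau)

    def decayed_fraction(self, t: float) -> float:
        """Fraction of the decaying span lost by time t (0.632 at t = tau)."""
        span = self.f_max - self.f_inf
        if span == 0:
            return 0.0
        return float((self.f_max - self.predict(t)) / span)

    def crossing_tau(self) -> float:
        """Direct 63.2%-crossing read of tau from the data (cross-check)."""
        return crossing_tau(self.model.t, self.model.f, self.f_max, self.f_inf)

    def to_dict(self) -> dict:
        return {"f_max_uN": self.f_max, "f_inf_uN": self.f_inf,
                "tau_min": self.tau, "rss": self.rss}

    def summary(self) -> str:
        lines = [
            "Force relaxation (3-parameter exponential decay)",
            "-" * 48,
            f"{'F_MAX':<12}{self.f_max:>12.4g}  uN",
            f"{'F_inf':<12}{self.f_inf:>12.4g}  uN",
            f"{'tau':<12}{self.tau:>12.4g}  min  (63.2% decay time)",
            f"{'RSS':<12}{self.rss:>12.4g}",
            f"{'n obs':<12}{self.nobs:>12d}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.trace.times, self.model.trace.force, ".", label="measured")
        tt = np.linspace(self.model.t[0], self.model.t[-1], 300)
        ax.plot(tt, self.predict(tt), "-", label="fit")
        ax.axvline(self.tau, ls="--", lw=0.8)
        ax.set_xlabel("time after shear (min)")
        ax.set_ylabel("force (uN)")
        ax.legend()
        return ax


def crossing_tau(t: np.ndarray, f: np.ndarray, f_max: float, f_inf: float) -> float:
    """Time where the trace first crosses 63.2% decay of (f_max - f_inf)."""
    target = f_max - (1.0 - np.exp(-1.0)) * (f_max - f_inf)
    below = np.nonzero(f <= target)[0]
    if len(below) == 0:
        return float(t[-1] - t[0])
    i = below[0]
    if i == 0:
        return float(max(t[0], 1e-6))
    # linear interpolation between the bracketing samples
    t_cross = t[i - 1] + (t[i] - t[i - 1]) * (f[i - 1] - target) / (f[i - 1] - f[i])
    return float(max(t_cross, 1e-6))


def fit_exponential_decay(
    trace: ForceTrace, fit_window: tuple[float, float] = (0.0, 30.0)
) -> ForceRelaxationResults:
    """Fit the 3-parameter exponential relaxation to a force trace."""
    return ForceRelaxation(trace, fit_window=fit_window).fit()
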