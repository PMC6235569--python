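"""Damped-sinusoid fitting, reversal detection and condition comparison.

The collective y-velocity of the monolayer behaves as a damped oscillator:

    v(t) = v0 + A * exp(-t / (2 D)) * sin(2 pi (t - t0) / P)

with amplitude A (um/h), period P (h), damping time D (h; infinity =
undamped) and phase reference t0.  The envelope is parameterised as
exp(-t/(2D)) so that the mechanical-circuit map c = k D is exactly
consistent with the circuit's pole real part -k/(2c)
(see :mod:`epishear.mech`).

`DampedOscillation` is the model object over a mean-velocity series;
`fit()` returns a `DampedOscillationResults`.  `find_reversals` locates the
sign changes of the (smoothed) series, and `compare_conditions` runs the
rank-based two-stage comparison: a Kruskal-Wallis omnibus gate followed, only
when significant, by pairwise Mann-Whitney U tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy import stats

from .kymo import MeanVelocitySeries

UNDAMPED = math.inf


def _model(t, a, period, lam, t0, v0):
    return v0 + a * np.exp(-lam * t) * np.sin(2.0 * np.pi * (t - t0) / period)


class DampedOscillation:
    """Damped-sinusoid model of a mean y-velocity series.

    Only post-shear data (t >= t_min, default 0) enter the fit.  The fit is
    a 5-parameter nonlinear least squares (A, P, decay rate, t0, v0) with the
    decay rate bounded at zero so the undamped limit is reachable.
    """

    def __init__(self, series: MeanVelocitySeries,
                 t_min: float = 0.0, t_max: Optional[float] = None):
        self.series = series
        mask = series.times >= t_min
        if t_max is not None:
            mask &= series.times <= t_max
        self.t = np.asarray(series.times[mask], dtype=float)
        self.v = np.asarray(series.mean_v[mask], dtype=float)
        if len(self.t) < 10:
            raise ValueError("need at least 10 post-shear samples to fit")

    @classmethod
    def from_arrays(cls, times, velocity, **kw) -> "DampedOscillation":
        return cls(MeanVelocitySeries(times=np.asarray(times),
                                      mean_v=np.asarray(velocity)), **kw)

    # -- initialisation ----------------------------------------------------

    def initial_params(self) -> tuple[float, float, float, float, float]:
        """(A, P, lambda, t0, v0) start values.

        P from the dominant FFT peak of the detrended series, A from max |v|,
        lambda from a log-envelope regression on successive extrema, t0 from
        the first upward zero crossing.
        """
        t, v = self.t, self.v
        v0 = float(np.mean(v))
        dv = v - v0
        a0 = float(np.max(np.abs(dv))) or 1.0
        period = self._fft_period(t, dv)
        window = t[-1] - t[0]
        if len(t) >= 4 and window < 1.5 * period:
            warnings.warn(
                f"fit window ({window:.2f} h) spans less than 1.5 expected "
                f"periods ({period:.2f} h); fit may be poorly constrained",
                stacklevel=3)
        lam0 = self._envelope_rate(t, dv)
        t0 = self._first_up_crossing(t, dv, period)
        return a0, period, lam0, t0, v0

    @staticmethod
    def _fft_period(t: np.ndarray, dv: np.ndarray) -> float:
        dt = float(np.median(np.diff(t)))
        n = max(len(dv) * 8, 256)  # zero padding for peak resolution
        spec = np.abs(np.fft.rfft(dv, n=n))
        freqs = np.fft.rfftfreq(n, d=dt)
        spec[0] = 0.0
        k = int(np.argmax(spec))
        if freqs[k] == 0:
            return max(t[-1] - t[0], 1.0)
        return float(1.0 / freqs[k])

    @staticmethod
    def _envelope_rate(t: np.ndarray, dv: np.ndarray) -> float:
        mag = np.abs(dv)
        # local maxima of |dv| approximate the envelope
        peaks = np.nonzero((mag[1:-1] >= mag[:-2]) & (mag[1:-1] > mag[2:]))[0] + 1
        peaks = peaks[mag[peaks] > 0.05 * mag.max()]
        if len(peaks) < 2:
            return 0.0
        slope = np.polyfit(t[peaks], np.log(mag[peaks]), 1)[0]
        return float(max(-slope, 0.0))

    @staticmethod
    def _first_up_crossing(t: np.ndarray, dv: np.ndarray, period: float) -> float:
        sign = np.sign(dv)
        ups = np.nonzero((sign[:-1] <= 0) & (sign[1:] > 0))[0]
        if len(ups) == 0:
            return float(t[0])
        i = ups[0]
        if dv[i + 1] == dv[i]:
            return float(t[i])
        frac = -dv[i] / (dv[i + 1] - dv[i])
        return float(t[i] + frac * (t[i + 1] - t[i]))

    # -- fitting -----------------------------------------------------------

    def fit(self, undamped_threshold: float = 0.05) -> "DampedOscillationResults":
        """Nonlinear least squares; D reported as inf when the fitted envelope
        decays by less than ``undamped_threshold`` over the window."""
        if np.ptp(self.v) == 0:
            warnings.warn("flat series: degenerate A = 0 fit", stacklevel=2)
            return DampedOscillationResults(
                model=self, amplitude=0.0, period=float(self.t[-1] - self.t[0]),
                damping_time=UNDAMPED, t0=0.0, offset=float(self.v[0]),
                rss=0.0, cov=np.zeros((5, 5)), nobs=len(self.t),
                degenerate=True)
        p0 = list(self.initial_params())
        p0[0] = max(p0[0], 1e-9)
        p0[1] = max(p0[1], 1e-3)
        bounds = ([0.0, 1e-3, 0.0, -np.inf, -np.inf],
                  [np.inf, np.inf, np.inf, np.inf, np.inf])
        try:
            popt, pcov = curve_fit(_model, self.t, self.v, p0=p0, bounds=bounds,
                                   maxfev=20000)
        except RuntimeError as err:
            raise RuntimeError(
                f"damped-sinusoid fit did not converge (start values "
                f"A={p0[0]:.3g}, P={p0[1]:.3g}, lambda={p0[2]:.3g}): {err}"
            ) from err
        a, period, lam, t0, v0 = (float(x) for x in popt)
        t0 = t0 % period
        window = float(self.t[-1] - self.t[0])
        damping = UNDAMPED if lam * window < -math.log1p(-undamped_threshold) \
            else 1.0 / (2.0 * lam)
        resid = self.v - _model(self.t, *popt)
        scale = max(float(np.std(self.v)), 1e-12)
        degenerate = a < 1e-6 * scale or a < 1e-12
        if degenerate:
            warnings.warn("flat series: degenerate A = 0 fit", stacklevel=2)
        return DampedOscillationResults(
            model=self, amplitude=a, period=period, damping_time=damping,
            t0=t0, offset=v0, rss=float(np.sum(resid ** 2)), cov=pcov,
            nobs=len(self.t), degenerate=degenerate)


@dataclass
class DampedOscillationResults:
    """Fitted damped sinusoid: A, P, D (inf = undamped), phase and offset."""

    model: DampedOscillation = field(repr=False)
    amplitude: float      # um/h
    period: float         # h
    damping_time: float   # h; inf sentinel = undamped
    t0: float             # h, phase reference in [0, P)
    offset: float         # um/h
    rss: float
    cov: np.ndarray = field(repr=False)
    nobs: int = 0
    degenerate: bool = False

    @property
    def decay_rate(self) -> float:
        return 0.0 if math.isinf(self.damping_time) else 1.0 / (2.0 * self.damping_time)

    def predict(self, t) -> np.ndarray:
        return _model(np.asarray(t, dtype=float), self.amplitude, self.period,
                      self.decay_rate, self.t0, self.offset)

    def envelope(self, t) -> np.ndarray:
        return self.amplitude * np.exp(-self.decay_rate * np.asarray(t, dtype=float))

    def to_dict(self) -> dict:
        d = self.damping_time
        return {"amplitude_um_per_h": self.amplitude, "period_h": self.period,
                "damping_time_h": (None if math.isinf(d) else d),
                "t0_h": self.t0, "offset_um_per_h": self.offset,
                "rss": self.rss, "degenerate": self.degenerate}

    def summary(self) -> str:
        d = "inf (undamped)" if math.isinf(self.damping_time) \
            else f"{self.damping_time:.4g}"
        lines = [
            "Damped sinusoid  v(t) = v0 + A exp(-t/2D) sin(2pi (t - t0)/P)",
            "-" * 60,
            f"{'A (amplitude)':<18}{self.amplitude:>12.4g}  um/h",
            f"{'P (period)':<18}{self.period:>12.4g}  h",
            f"{'D (damping time)':<18}{d:>12}  h",
            f"{'t0 (phase)':<18}{self.t0:>12.4g}  h",
            f"{'v0 (offset)':<18}{self.offset:>12.4g}  um/h",
            f"{'RSS':<18}{self.rss:>12.4g}",
            f"{'n obs':<18}{self.nobs:>12d}",
        ]
        if self.degenerate:
            lines.append("NOTE: flat series; amplitude degenerate at zero")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.t, self.model.v, ".", ms=3, label="mean y-velocity")
        tt = np.linspace(self.model.t[0], self.model.t[-1], 600)
        ax.plot(tt, self.predict(tt), "r-", lw=1.2, label="damped-sine fit")
        ax.axhline(self.offset, ls=":", lw=0.8)
        ax.set_xlabel("time after shear (h)")
        ax.set_ylabel("velocity (um/h)")
        ax.legend()
        return ax


def fit_damped_sinusoid(series: MeanVelocitySeries, t_min: float = 0.0,
                        t_max: Optional[float] = None) -> DampedOscillationResults:
    """Fit the damped sinusoid to a mean-velocity series (post-shear only)."""
    return DampedOscillation(series, t_min=t_min, t_max=t_max).fit()


# ---------------------------------------------------------------------------
# reversal detection


@dataclass
class ReversalSet:
    """Sign changes of the smoothed mean velocity after shear."""

    times: np.ndarray       # h, strictly increasing
    directions: np.ndarray  # +1 turning outward, -1 turning inward

    def __len__(self) -> int:
        return len(self.times)


def find_reversals(series: MeanVelocitySeries, smooth_window: int = 3,
                   t_min: float = 0.5) -> ReversalSet:
    """Zero crossings of the moving-average-smoothed post-shear series.

    Crossings are located by linear interpolation between bracketing samples;
    crossings within the first 30 min (the deformation transient) are
    excluded by default.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    t = series.times
    v = series.mean_v
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        vs = np.convolve(v, kernel, mode="same")
        # fix shortened averages at the edges
        counts = np.convolve(np.ones_like(v), kernel, mode="same")
        vs = vs / counts
    else:
        vs = v.copy()
    times, dirs = [], []
    sign = np.sign(vs)
    nz = np.nonzero(sign != 0)[0]
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] == sign[b]:
            continue
        if b == a + 1:
            frac = -vs[a] / (vs[b] - vs[a])
            tc = t[a] + frac * (t[b] - t[a])
        else:
            # the series touches zero exactly; place the crossing mid-run
            tc = 0.5 * (t[a + 1] + t[b - 1])
        if tc < t_min:
            continue
        times.append(float(tc))
        dirs.append(1 if sign[b] > 0 else -1)
    return ReversalSet(times=np.asarray(times), directions=np.asarray(dirs, dtype=int))


# ---------------------------------------------------------------------------
# condition comparison (Kruskal-Wallis gate, then Mann-Whitney U)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with the exact null when both samples are small.

    Uses the exact permutation null when both n <= 8 and there are no ties
    across the pooled sample, and the tie-corrected normal approximation
    otherwise.  Returns (U statistic of the first sample, p value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_value: float


@dataclass
class ConditionComparison:
    """Two-stage nonparametric comparison of one fitted parameter."""

    parameter: str
    groups: dict
    omnibus_statistic: float
    omnibus_p: float
    alpha: float
    pairwise: Optional[list[PairwiseResult]]  # None when the gate fails

    @property
    def significant(self) -> bool:
        return self.omnibus_p < self.alpha

    def to_rows(self) -> list[dict]:
        rows = [{"parameter": self.parameter, "pair": "omnibus",
                 "statistic": self.omnibus_statistic, "p_value": self.omnibus_p}]
        for pw in self.pairwise or []:
            rows.append({"parameter": self.parameter,
                         "pair": f"{pw.pair[0]} vs {pw.pair[1]}",
                         "statistic": pw.statistic, "p_value": pw.p_value})
        return rows


def compare_conditions(values: Mapping[str, Sequence[float]],
                       alpha: float = 0.05,
                       parameter: str = "") -> ConditionComparison:
    """Kruskal-Wallis omnibus test, gating pairwise Mann-Whitney U tests.

    Pairwise tests run only when the omnibus p < alpha.  Identical samples in
    all groups yield p = 1 with no pairwise tests.
    """
    names = list(values)
    if len(names) < 2:
        raise ValueError("need at least 2 conditions to compare")
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    for k, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"condition {k!r} has no replicate values")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        return ConditionComparison(parameter=parameter, groups=groups,
                                   omnibus_statistic=0.0, omnibus_p=1.0,
                                   alpha=alpha, pairwise=None)
    stat, p = stats.kruskal(*groups.values())
    pairwise = None
    if p < alpha:
        pairwise = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                u, pp = mann_whitney_u(groups[a], groups[b])
                pairwise.append(PairwiseResult(pair=(a, b), statistic=u, p_value=pp))
    return ConditionComparison(parameter=parameter, groups=groups,
                               omnibus_statistic=float(stat), omnibus_p=float(p),
                               alpha=alpha, pairwise=pairwise)
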