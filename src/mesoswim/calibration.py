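"""Micropipette force sensor (MFS) calibration.

A micropipette force sensor is a long thin glass cantilever whose tip
deflection x reports the force applied to it through

    F = k x + b xdot + m_eff xddot,

with spring constant k, drag coefficient b and effective mass m_eff.
Quasi-static calibration hangs an ellipsoidal water drop of known weight on
the tip and reads k from the static deflection.  Dynamic calibration deflects
the cantilever, releases it, and fits the free ringdown with an underdamped
harmonic oscillator to obtain the damping ratio xi and undamped angular
frequency omega0, from which b = 2 k xi / omega0 and m_eff = k / omega0**2.

All quantities are SI (m, s, kg, N) unless a name says otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import argrelextrema

logger = logging.getLogger(__name__)

#: Damping ratio above which the resonant frequency omega0*sqrt(1-2 xi^2)
#: ceases to be real.
XI_RESONANCE_LIMIT = 1.0 / math.sqrt(2.0)

#: Default characteristic swimming-stroke time used for the drag/inertia
#: contribution diagnostics (s).
DEFAULT_T_C = 0.1

#: Default swimming-frequency band (Hz) checked for resonance overlap.
DEFAULT_SWIM_BAND = (5.0, 10.0)


class InvalidInputError(ValueError):
    """An input field violates its physical domain."""


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best attempt."""

    def __init__(self, message: str, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class NotUnderdampedError(ValueError):
    """Trace shows no oscillation; the underdamped model does not apply."""


@dataclass(frozen=True)
class DropObservation:
    """One water-drop loading of the cantilever tip.

    The drop is treated as an ellipsoid of revolution with minor axis
    ``l_min`` and major axis ``l_max`` (volume pi*l_min**2*l_max/6) whose
    weight statically deflects the tip by ``deflection``.
    """

    l_min: float
    l_max: float
    deflection: float
    fluid_density: float = 1000.0
    g: float = 9.81

    def __post_init__(self):
        if not self.l_min > 0:
            raise InvalidInputError(f"l_min must be positive, got {self.l_min}")
        if self.l_max < self.l_min:
            raise InvalidInputError(
                f"l_max ({self.l_max}) must be >= l_min ({self.l_min})"
            )
        if not self.deflection > 0:
            raise InvalidInputError(
                f"deflection must be positive, got {self.deflection}"
            )

    @property
    def volume(self) -> float:
        """Ellipsoidal drop volume (m^3)."""
        return math.pi * self.l_min**2 * self.l_max / 6.0


@dataclass(frozen=True)
class SpringCalibration:
    """Aggregated quasi-static spring-constant calibration."""

    k: float
    k_sd: float
    n_repeats: int

    def __post_init__(self):
        if not self.k > 0:
            raise InvalidInputError(f"k must be positive, got {self.k}")
        if self.k_sd < 0 or self.n_repeats < 1:
            raise InvalidInputError("k_sd must be >= 0 and n_repeats >= 1")


@dataclass(frozen=True)
class RingdownFit:
    """Underdamped ringdown fit x(t) = A exp(-xi w0 t) sin(sqrt(1-xi^2) w0 t + phi)."""

    amplitude: float
    phase: float
    damping_ratio: float
    omega0: float
    rss: float = 0.0

    def __post_init__(self):
        if not self.amplitude > 0:
            raise InvalidInputError(f"amplitude must be positive, got {self.amplitude}")
        if not 0.0 < self.damping_ratio < 1.0:
            raise InvalidInputError(
                f"damping_ratio must be in (0, 1), got {self.damping_ratio}"
            )
        if not self.omega0 > 0:
            raise InvalidInputError(f"omega0 must be positive, got {self.omega0}")

    def __call__(self, t):
        """Evaluate the fitted model at times ``t`` (s)."""
        xi, w0 = self.damping_ratio, self.omega0
        wd = w0 * math.sqrt(1.0 - xi * xi)
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(-xi * w0 * t) * np.sin(wd * t + self.phase)


@dataclass(frozen=True)
class CantileverModel:
    """Calibrated cantilever: elastic, viscous and inertial coefficients."""

    k: float
    b: float
    m_eff: float
    k_sd: float = 0.0
    label: str = ""

    def __post_init__(self):
        if not self.k > 0:
            raise InvalidInputError(f"k must be positive, got {self.k}")
        if self.b < 0:
            raise InvalidInputError(f"b must be non-negative, got {self.b}")
        if not self.m_eff > 0:
            raise InvalidInputError(f"m_eff must be positive, got {self.m_eff}")

    @property
    def omega0(self) -> float:
        """Undamped angular frequency sqrt(k / m_eff) (rad/s)."""
        return math.sqrt(self.k / self.m_eff)

    @property
    def xi(self) -> float:
        """Damping ratio b / (2 sqrt(m_eff k))."""
        return self.b / (2.0 * math.sqrt(self.m_eff * self.k))

    @property
    def resonant_frequency(self) -> float | None:
        """Resonant frequency omega0*sqrt(1-2 xi^2)/(2 pi) (Hz), or None.

        A driven-amplitude resonance peak exists only for xi < 1/sqrt(2);
        above that the response is monotone and ``None`` is returned.
        """
        return resonant_frequency(self)

    def resonance_in_band(self, band: tuple[float, float] = DEFAULT_SWIM_BAND) -> bool:
        """True when the resonant frequency falls inside ``band`` (Hz)."""
        f_r = self.resonant_frequency
        return f_r is not None and band[0] <= f_r <= band[1]


def drop_spring_constant(obs: DropObservation) -> float:
    """Spring constant from one drop observation: k = rho*V*g/x (N/m)."""
    weight = obs.fluid_density * obs.volume * obs.g
    return weight / obs.deflection


def aggregate_spring_constant(observations) -> SpringCalibration:
    """Mean and sample SD of per-drop spring constants.

    Logs a warning when fewer than 4 repeats are supplied, the minimum the
    calibration protocol calls for.
    """
    observations = list(observations)
    if not observations:
        raise InvalidInputError("at least one drop observation is required")
    ks = np.array([drop_spring_constant(o) for o in observations])
    n = len(ks)
    if n < 4:
        logger.warning(
            "spring calibration from only %d drop(s); protocol asks for >= 4", n
        )
    sd = float(np.std(ks, ddof=1)) if n > 1 else 0.0
    return SpringCalibration(k=float(np.mean(ks)), k_sd=sd, n_repeats=n)


def _ringdown_residuals(params, t, x):
    a, phi, xi, w0 = params
    wd = w0 * np.sqrt(max(1.0 - xi * xi, 1e-12))
    return a * np.exp(-xi * w0 * t) * np.sin(wd * t + phi) - x


def _initial_guess(t, x, dt):
    """Self-initialization: spectrum peak, log decrement, first extremum."""
    # no taper: the signal is a decaying transient at the trace start and a
    # window would suppress it; the raw spectrum peaks at the damped frequency
    n = len(x)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, dt)
    spec[0] = 0.0
    wd0 = 2.0 * math.pi * freqs[int(np.argmax(spec))]

    # log decrement from successive same-sign extrema
    imax = argrelextrema(x, np.greater)[0]
    imin = argrelextrema(x, np.less)[0]
    xi0 = 0.1
    for idx in (imax, imin):
        if len(idx) >= 2:
            peaks = np.abs(x[idx])
            good = peaks > 0
            if good.sum() >= 2:
                p = peaks[good]
                ratios = p[:-1] / p[1:]
                ratios = ratios[ratios > 0]
                if len(ratios):
                    delta = float(np.median(np.log(ratios)))
                    xi0 = delta / math.sqrt(4.0 * math.pi**2 + delta**2)
                    break
    xi0 = min(max(xi0, 1e-4), 0.95)
    w0_0 = wd0 / math.sqrt(1.0 - xi0 * xi0) if wd0 > 0 else 2.0 * math.pi / (t[-1] + dt)

    ext = np.concatenate([imax, imin])
    if len(ext):
        i0 = int(np.min(ext))
        a0 = abs(x[i0]) * math.exp(xi0 * w0_0 * t[i0])
    else:
        a0 = float(np.max(np.abs(x)))
    a0 = max(a0, 1e-30)
    phi0 = math.asin(min(max(x[0] / a0, -1.0), 1.0))
    return a0, phi0, xi0, w0_0


def fit_ringdown(trace, initial_guess: RingdownFit | None = None) -> RingdownFit:
    """Fit an underdamped harmonic-oscillator ringdown to a deflection trace.

    ``trace`` is any object with ``sample_rate`` (Hz) and ``deflection`` (m,
    equilibrium offset already removed).  The fit minimizes the sum of squared
    residuals of the four-parameter model over (A, phi, xi, omega0); when
    ``initial_guess`` is absent the starting point is derived from the trace
    (spectral peak, logarithmic decrement, first extremum) and up to 5
    multi-start restarts with jittered damping ratio are attempted.

    Raises
    ------
    NotUnderdampedError
        If the trace never changes sign (no oscillation to fit).
    FitFailureError
        If no restart converges; carries the best attempt.
    """
    x = np.asarray(trace.deflection, dtype=float)
    dt = 1.0 / trace.sample_rate
    t = np.arange(len(x)) * dt

    if np.all(x >= 0) or np.all(x <= 0):
        raise NotUnderdampedError(
            "deflection trace never crosses zero; not an underdamped ringdown"
        )

    if initial_guess is not None:
        starts = [(initial_guess.amplitude, initial_guess.phase,
                   initial_guess.damping_ratio, initial_guess.omega0)]
    else:
        a0, phi0, xi0, w0_0 = _initial_guess(t, x, dt)
        wd0 = w0_0 * math.sqrt(1.0 - xi0 * xi0)
        # jittered restarts around the log-decrement estimate plus a coarse
        # grid: heavily damped traces (< 1 visible period) defeat the
        # decrement estimate entirely
        xis = [min(xi0 * j, 0.95) for j in (1.0, 0.5, 2.0)]
        xis += [0.2, 0.45, 0.65, 0.85]
        starts = [
            (a0, phi0, xi, wd0 / math.sqrt(1.0 - xi * xi)) for xi in xis
        ]

    scale = max(float(np.max(np.abs(x))), 1e-30)
    lb = [1e-12 * scale, -2.0 * math.pi, 1e-8, 1e-8]
    ub = [1e6 * scale, 2.0 * math.pi, 1.0 - 1e-8, np.inf]
    best = None
    for a0, phi0, xi0, w0_0 in starts:
        p0 = [min(max(a0, lb[0]), ub[0]), phi0, xi0, w0_0]
        try:
            res = least_squares(
                _ringdown_residuals, p0, args=(t, x), bounds=(lb, ub),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:  # singular starting point; try next restart
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and res.cost <= 1.05 * best.cost and best is res:
            # good enough; still try the remaining starts only if poor fit
            rel = math.sqrt(2.0 * res.cost / len(x)) / scale
            if rel < 1e-8:
                break
    if best is None or not np.isfinite(best.cost):
        raise FitFailureError("ringdown fit did not converge", best_attempt=best)

    a, phi, xi, w0 = best.x
    if a < 0:
        a, phi = -a, phi + math.pi
    phi = phi % (2.0 * math.pi)
    return RingdownFit(
        amplitude=float(a), phase=float(phi), damping_ratio=float(xi),
        omega0=float(w0), rss=float(2.0 * best.cost),
    )


def dynamic_coefficients(k: float, fit: RingdownFit) -> tuple[float, float]:
    """Drag coefficient and effective mass from k and a ringdown fit.

    b = 2 k xi / omega0 (N*s/m), m_eff = k / omega0**2 (kg).
    """
    if not k > 0:
        raise InvalidInputError(f"k must be positive, got {k}")
    b = 2.0 * k * fit.damping_ratio / fit.omega0
    m_eff = k / fit.omega0**2
    return b, m_eff


def relative_contributions(
    model: CantileverModel, t_c: float = DEFAULT_T_C, threshold: float = 0.01
) -> tuple[float, float, bool, bool]:
    """Drag and inertia contributions relative to elasticity on a stroke.

    For a stroke of characteristic time t_c, drag contributes ~b/(k*t_c) and
    inertia ~m_eff/(k*t_c^2) relative to the elastic term.  Each flag is True
    when its ratio reaches ``threshold`` (default 1%), i.e. when the term
    should not be neglected in force reconstruction.
    """
    if not t_c > 0:
        raise InvalidInputError(f"t_c must be positive, got {t_c}")
    drag_ratio = model.b / (model.k * t_c)
    inertia_ratio = model.m_eff / (model.k * t_c**2)
    return drag_ratio, inertia_ratio, drag_ratio >= threshold, inertia_ratio >= threshold


def resonant_frequency(model: CantileverModel) -> float | None:
    """f_r = omega0*sqrt(1 - 2 xi^2)/(2 pi) (Hz); None when xi >= 1/sqrt(2)."""
    xi = model.xi
    if xi >= XI_RESONANCE_LIMIT:
        return None
    return model.omega0 * math.sqrt(1.0 - 2.0 * xi * xi) / (2.0 * math.pi)


def calibrate_dynamic(
    trace, k: float, k_sd: float = 0.0, label: str = ""
) -> tuple[CantileverModel, RingdownFit]:
    """Full dynamic calibration: fit the ringdown, derive (b, m_eff)."""
    fit = fit_ringdown(trace)
    b, m_eff = dynamic_coefficients(k, fit)
    return CantileverModel(k=k, b=b, m_eff=m_eff, k_sd=k_sd, label=label), fit
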