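"""Swimming-force reconstruction from cantilever deflection traces.

The tethered swimmer drives the cantilever tip; the instantaneous force
balance F_swim = k x + b xdot + m_eff xddot inverts the measured deflection
into the swimming force.  For the stiffness range used in practice the
inertial term is negligible and either F = k x (stiff cantilevers,
k >= 25 nN/um) or F = k x + b xdot (soft ones) is used.  Cycle segmentation
then yields the mean propulsive force F_p, the mean peak-to-peak force
F_peak, and the stroke frequency f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .calibration import CantileverModel, InvalidInputError

#: Stiffness (N/m) above which the drag term is neglected: 25 nN/um.
K_DRAG_THRESHOLD = 25e-9 / 1e-6

#: Settling window (s) discarded after release before baseline averaging.
SETTLING_WINDOW_S = 0.2


class NoPeriodicityError(ValueError):
    """No spectral peak rises above the noise floor."""


@dataclass(frozen=True)
class DeflectionTrace:
    """Uniformly sampled cantilever tip deflection (m).

    ``release_index``, when present, marks the sample at which the organism
    was released; the subsequent samples show the force-free pipette and
    define the zero-force baseline.
    """

    sample_rate: float
    deflection: np.ndarray
    release_index: int | None = None
    overdamped: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "deflection", np.asarray(self.deflection, dtype=float)
        )
        if not self.sample_rate > 0:
            raise InvalidInputError(f"sample_rate must be positive, got {self.sample_rate}")
        if len(self.deflection) < 3:
            raise InvalidInputError("trace needs at least 3 samples")
        if self.release_index is not None:
            n = len(self.deflection)
            if not 0 <= self.release_index < n:
                raise InvalidInputError(
                    f"release_index {self.release_index} outside [0, {n})"
                )
            post = (n - self.release_index) / self.sample_rate
            if post < 0.5:
                raise InvalidInputError(
                    f"only {post:.3f} s of post-release data; >= 0.5 s required"
                )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.deflection)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.deflection) / self.sample_rate


@dataclass(frozen=True)
class ForceTrace:
    """Reconstructed swimming force (N), same sampling as the source trace.

    ``mode`` records which force-balance terms were included; the first and
    last samples use one-sided differences and are listed in
    ``endpoint_indices``.
    """

    sample_rate: float
    force: np.ndarray
    mode: str
    endpoint_indices: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.force)) / self.sample_rate


@dataclass(frozen=True)
class SwimmingSummary:
    """Cycle-averaged swimming-force summary for one individual."""

    F_p: float
    F_peak: float
    f: float
    n_cycles: int
    se_Fp: float
    se_Fpeak: float
    se_f: float

    def __post_init__(self):
        if self.F_peak < 0 or self.n_cycles < 1:
            raise InvalidInputError("F_peak must be >= 0 and n_cycles >= 1")
        if min(self.se_Fp, self.se_Fpeak, self.se_f) < 0:
            raise InvalidInputError("standard errors must be >= 0")


def zero_baseline(
    trace: DeflectionTrace,
    baseline: float | None = None,
    settling_window: float = SETTLING_WINDOW_S,
) -> DeflectionTrace:
    """Subtract the zero-force baseline from a deflection trace.

    The baseline is the mean of the post-release segment after discarding a
    settling window (the pipette rings down briefly once the swimmer is
    released).  Without a release event an explicit ``baseline`` value must
    be supplied.
    """
    if baseline is None:
        if trace.release_index is None:
            raise InvalidInputError(
                "trace has no release_index; pass an explicit baseline value"
            )
        start = trace.release_index + int(round(settling_window * trace.sample_rate))
        if start >= len(trace.deflection):
            start = trace.release_index
        baseline = float(np.mean(trace.deflection[start:]))
    return replace(trace, deflection=trace.deflection - baseline)


def _second_derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """3-point central second difference, one-sided (copied) at the ends."""
    d2 = np.empty_like(x)
    d2[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt**2
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def reconstruct_force(
    trace: DeflectionTrace,
    model: CantileverModel,
    mode: str = "auto",
    k_drag_threshold: float = K_DRAG_THRESHOLD,
) -> ForceTrace:
    """Invert a (baseline-corrected) deflection trace into swimming force.

    Modes: ``static`` F = kx; ``drag`` F = kx + b*xdot; ``full`` adds
    m_eff*xddot.  ``auto`` selects drag below the stiffness threshold
    (25 nN/um by default) and static above it, never full — on these
    cantilevers the inertial contribution is negligible on stroke timescales.
    Velocities use 3-point central differences with first-order one-sided
    differences at the two endpoints.
    """
    x = trace.deflection
    if len(x) < 3:
        raise InvalidInputError("need at least 3 samples to differentiate")
    if mode == "auto":
        mode = "drag" if model.k < k_drag_threshold else "static"
    if mode not in ("static", "drag", "full"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    if mode in ("drag", "full") and model.b is None:
        raise InvalidInputError("drag mode requires a calibrated b")

    dt = 1.0 / trace.sample_rate
    force = model.k * x
    endpoints: tuple[int, ...] = ()
    if mode in ("drag", "full"):
        force = force + model.b * np.gradient(x, dt)
        endpoints = (0, len(x) - 1)
    if mode == "full":
        force = force + model.m_eff * _second_derivative(x, dt)
    return ForceTrace(
        sample_rate=trace.sample_rate, force=force, mode=mode,
        endpoint_indices=endpoints,
    )


def _cycle_durations(y: np.ndarray, sample_rate: float, f_est: float) -> np.ndarray:
    """Durations between interpolated upward zero crossings near frequency f_est."""
    idx = _upward_crossings(y, sample_rate, f_est)
    if len(idx) < 2:
        return np.array([])
    # refine crossing position by linear interpolation
    pos = []
    for i in idx:
        if i > 0 and y[i - 1] < 0 <= y[i]:
            frac = -y[i - 1] / (y[i] - y[i - 1])
            pos.append((i - 1) + frac)
        else:
            pos.append(float(i))
    return np.diff(pos) / sample_rate


def estimate_frequency(
    trace_or_force, min_cycles: int = 5, rel_floor_db: float = 20.0
) -> tuple[float, float]:
    """Dominant stroke frequency of a deflection or force trace.

    The point estimate is the fundamental of the detrended periodogram:
    among peaks within ``rel_floor_db`` of the strongest one, the lowest
    frequency whose integer multiples explain the others (+-5%) is chosen,
    then refined by quadratic interpolation around its bin.  The standard
    error comes from the spread of individual cycle durations measured at
    upward zero crossings.
    """
    y = np.asarray(trace_or_force.force if hasattr(trace_or_force, "force")
                   else trace_or_force.deflection, dtype=float)
    fs = trace_or_force.sample_rate
    y = signal.detrend(y)
    freqs, pxx = signal.periodogram(y, fs, window="hann")
    pxx[0] = 0.0
    if not np.any(pxx > 0):
        raise NoPeriodicityError("flat trace; no periodicity")

    peak_idx = signal.argrelextrema(pxx, np.greater)[0]
    if len(peak_idx) == 0:
        peak_idx = np.array([int(np.argmax(pxx))])
    pmax = pxx[peak_idx].max()
    noise_floor = np.median(pxx[pxx > 0])
    if pmax < 10.0 * noise_floor:
        raise NoPeriodicityError("no spectral peak above the noise floor")
    cand = peak_idx[pxx[peak_idx] >= pmax * 10 ** (-rel_floor_db / 10.0)]
    cand_f = freqs[cand]

    # harmonic grouping: pick the lowest candidate whose multiples explain
    # every other candidate within 5%
    best_i = int(cand[np.argmax(pxx[cand])])
    fundamental = None
    for i, f0 in sorted(zip(cand, cand_f), key=lambda p: p[1]):
        if f0 <= 0:
            continue
        ratios = cand_f / f0
        if np.all(np.abs(ratios - np.round(ratios)) <= 0.05 * np.round(ratios)):
            fundamental = int(i)
            break
    i = fundamental if fundamental is not None else best_i

    # quadratic interpolation around the peak bin
    if 0 < i < len(pxx) - 1 and pxx[i] > 0:
        with np.errstate(divide="ignore"):
            la, lb, lc = np.log(pxx[i - 1] + 1e-300), np.log(pxx[i]), np.log(pxx[i + 1] + 1e-300)
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = freqs[1] - freqs[0]
    f_hat = float(freqs[i] + delta * df)

    durations = _cycle_durations(y, fs, f_hat)
    if len(durations) >= 2:
        f_cyc = 1.0 / durations
        se = float(np.std(f_cyc, ddof=1) / math.sqrt(len(f_cyc)))
    else:
        se = 0.0
    return f_hat, se


def _upward_crossings(y: np.ndarray, sample_rate: float, f: float) -> np.ndarray:
    """Upward zero-crossing indices of y, deduplicated to >= 0.5/f spacing."""
    up = np.nonzero((y[:-1] < 0) & (y[1:] >= 0))[0] + 1
    if len(up) == 0:
        return up
    min_gap = 0.5 / f * sample_rate
    keep = [up[0]]
    for i in up[1:]:
        if i - keep[-1] >= min_gap:
            keep.append(i)
    return np.asarray(keep)


def segment_cycles(force: ForceTrace, f: float) -> np.ndarray:
    """Cycle boundary indices of a periodic force trace.

    Boundaries are upward zero crossings of the mean-subtracted, low-pass
    filtered force (cutoff 3f) with a minimum spacing of half a period; only
    complete cycles (pairs of consecutive boundaries) are retained.
    """
    if not f > 0:
        raise InvalidInputError(f"f must be positive, got {f}")
    y = force.force - np.mean(force.force)
    nyq = force.sample_rate / 2.0
    cutoff = 3.0 * f
    if cutoff < nyq:
        sos = signal.butter(4, cutoff / nyq, output="sos")
        y = signal.sosfiltfilt(sos, y)
    bounds = _upward_crossings(y, force.sample_rate, f)
    # a trace starting exactly on a rising zero crossing begins a complete cycle
    if (len(bounds) and bounds[0] >= 0.75 * force.sample_rate / f
            and y[0] >= 0 and y[1] > y[0]):
        bounds = np.concatenate([[0], bounds])
    if len(bounds) < 2:
        raise InvalidInputError("fewer than one complete cycle in trace")
    return bounds


def summarize(force: ForceTrace, cycles: Sequence[int]) -> SwimmingSummary:
    """Cycle-averaged F_p, F_peak and frequency with standard errors.

    F_p is the mean of per-cycle mean forces; F_peak the mean of per-cycle
    (max - min); standard errors are over cycles; f comes from the mean
    cycle duration.
    """
    cycles = np.asarray(cycles)
    if len(cycles) < 2:
        raise InvalidInputError("need at least one complete cycle")
    means, ptps = [], []
    for a, b in zip(cycles[:-1], cycles[1:]):
        seg = force.force[a:b]
        means.append(float(np.mean(seg)))
        ptps.append(float(np.ptp(seg)))
    means, ptps = np.asarray(means), np.asarray(ptps)
    durations = np.diff(cycles) / force.sample_rate
    n = len(means)

    def se(v):
        return float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    f_per = 1.0 / durations
    return SwimmingSummary(
        F_p=float(np.mean(means)), F_peak=float(np.mean(ptps)),
        f=float(1.0 / np.mean(durations)), n_cycles=n,
        se_Fp=se(means), se_Fpeak=se(ptps), se_f=se(f_per),
    )


def analyze_trace(
    trace: DeflectionTrace,
    model: CantileverModel,
    mode: str = "auto",
    baseline: float | None = None,
) -> tuple[ForceTrace, SwimmingSummary]:
    """Baseline-correct, reconstruct, segment and summarize in one call.

    Only the pre-release portion of the trace enters the cycle summary.
    """
    zeroed = zero_baseline(trace, baseline=baseline) if (
        trace.release_index is not None or baseline is not None
    ) else trace
    if zeroed.release_index is not None:
        swim = DeflectionTrace(
            sample_rate=zeroed.sample_rate,
            deflection=zeroed.deflection[: zeroed.release_index],
        )
    else:
        swim = zeroed
    force = reconstruct_force(swim, model, mode=mode)
    f, _ = estimate_frequency(force)
    cycles = segment_cycles(force, f)
    return force, summarize(force, cycles)
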