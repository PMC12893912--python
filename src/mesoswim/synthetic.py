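"""Synthetic-data generator for the whole pipeline.

Every input the analysis consumes can be generated here with known ground
truth: damped-oscillator ringdowns, tethered deflection traces produced by
driving the cantilever ODE with an *Artemia*-like periodic force waveform,
two-segment antenna pose tracks with a commanded non-reciprocity ratio,
allometric populations, chi-versus-Re ensembles, and cross-taxa Th-Sw
ensembles.  Generator defaults are the study conditions: the frequency law
f = 6.6 * L^-0.35 (L in mm), force allometry F_p = 0.031 * L^2 (uN), the
peak-to-peak ratio F_peak = 16 * F_p, the non-reciprocity force constant
F_p/(eta f L^2) = 13 * chi, the Th-Sw prefactors 12 (Stokes) and 0.011
(inertial), and the breakpoint Re_c = 4.

Boundary units follow the printed laws (mm, Hz, uN); everything returned in
data containers is SI.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .calibration import CantileverModel, InvalidInputError
from .force import DeflectionTrace
from .kinematics import (
    PoseTrack,
    body_frame,
    joint_angles,
    nonreciprocity,
    segment_stroke_cycles,
)
from .scaling import SwimmerRecord


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions used by every generator.

    Scaling-law constants are in the boundary units of the printed laws
    (mm, Hz, uN); fluid and cantilever properties are SI.
    """

    c_f: float = 6.6          # frequency prefactor, Hz * mm^0.35
    beta_f: float = -0.35     # frequency exponent
    c_F: float = 0.031        # force allometry prefactor, uN / mm^2
    r_pp: float = 16.0        # peak-to-peak / mean force ratio
    c_nr: float = 13.0        # non-reciprocity force constant, dimensionless
    c_stokes: float = 12.0    # Th = c_stokes * Sw on the Stokes branch
    c_inertial: float = 0.011  # Th = c_inertial * Sw^2 on the inertial branch
    Re_c: float = 4.0         # breakpoint Reynolds number
    chi_slope: float = 0.05   # chi per unit Re below Re_c (free parameter)
    b_default: float = 35.5e-6  # cantilever drag coefficient, N*s/m
    t_c: float = 0.1          # characteristic stroke time, s
    eta: float = 1.0e-3       # fluid viscosity, Pa*s
    rho: float = 1000.0       # fluid density, kg/m^3
    deflection_noise: float = 0.1e-6  # additive trace noise SD, m
    keypoint_noise: float = 2.0e-6    # pose keypoint noise SD, m
    sigma_log: float = 0.1    # lognormal scatter of population laws

    def __post_init__(self):
        if self.r_pp <= 2.0:
            raise InvalidInputError(
                "r_pp must exceed 2 so the recovery-stroke force can be negative"
            )
        for name in ("c_f", "c_F", "c_nr", "c_stokes", "c_inertial", "Re_c",
                     "chi_slope", "b_default", "t_c", "eta", "rho"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")


DEFAULT_CONFIG = GeneratorConfig()

#: Calibrated cantilever length range (m).
L_MFS_RANGE = (0.013, 0.033)

#: Reference stiffness anchor of the cube law: k(1.3 cm) = 25 nN/um.
K_REF = 25e-3  # N/m
L_REF = 0.013  # m

#: Product m_eff * k (kg * N/m) setting the effective-mass default; keeps the
#: damping ratio below 1/sqrt(2) for b_default and the undamped frequency well
#: above the stroke band at swim-force stiffnesses.
MK_PRODUCT = 7.5e-10

#: Body-length range probed by the study (mm).
L_RANGE_MM = (0.42, 1.5)

#: Default stroke geometry of the synthetic two-segment antenna.
THETA_A_MEAN = 90.0   # deg
THETA_A_AMP = 40.0    # deg
THETA_E_MEAN = 130.0  # deg
THETA_E_AMP = 45.0    # deg
THETA_E_AMP2 = 0.25   # second-harmonic fraction of the elbow amplitude
L_A_FRACTION = 0.55   # antenna length as a fraction of body length


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# cantilevers and ringdowns


def make_cantilever(
    l_MFS: float, config: GeneratorConfig = DEFAULT_CONFIG,
    b: float | None = None, m_eff: float | None = None,
) -> CantileverModel:
    """Synthetic cantilever for a pipette of length ``l_MFS`` (m).

    Stiffness follows the beam-like cube law k = K_REF * (l/L_REF)^-3
    anchored at 25 nN/um for the shortest calibrated pipette; the drag
    coefficient defaults to the study-wide average and the effective mass to
    MK_PRODUCT / k (longer, softer pipettes are heavier).  Out-of-range
    lengths are extrapolated with a warning.
    """
    import warnings

    if not L_MFS_RANGE[0] <= l_MFS <= L_MFS_RANGE[1]:
        warnings.warn(
            f"l_MFS = {l_MFS} m outside the calibrated range {L_MFS_RANGE}; "
            "extrapolating", stacklevel=2,
        )
    k = K_REF * (l_MFS / L_REF) ** -3
    if b is None:
        b = config.b_default
    if m_eff is None:
        m_eff = MK_PRODUCT / k
    return CantileverModel(k=k, b=b, m_eff=m_eff, label=f"l_MFS={l_MFS:g}m")


def simulate_ringdown(
    model: CantileverModel,
    x0: float,
    sample_rate: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DeflectionTrace:
    """Exact free-ringdown trace from initial displacement ``x0`` at rest.

    Underdamped models use the closed-form damped cosine; overdamped ones
    (xi >= 1) use the bi-exponential closed form and the returned trace is
    tagged ``overdamped`` so fitters can exercise their rejection path.
    """
    import warnings

    if not 50e-6 <= abs(x0) <= 450e-6:
        warnings.warn(
            f"x0 = {x0} m outside the calibrated release range 50-450 um",
            stacklevel=2,
        )
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    xi, w0 = model.xi, model.omega0
    overdamped = xi >= 1.0
    if not overdamped:
        wd = w0 * math.sqrt(1.0 - xi * xi)
        x = x0 * np.exp(-xi * w0 * t) * (
            np.cos(wd * t) + (xi * w0 / wd) * np.sin(wd * t)
        )
    elif xi == 1.0:
        x = x0 * (1.0 + w0 * t) * np.exp(-w0 * t)
    else:
        s = w0 * math.sqrt(xi * xi - 1.0)
        r1, r2 = -xi * w0 + s, -xi * w0 - s
        x = x0 * (-r2 * np.exp(r1 * t) + r1 * np.exp(r2 * t)) / (r1 - r2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=len(x))
    return DeflectionTrace(sample_rate=sample_rate, deflection=x,
                           overdamped=overdamped)


# ---------------------------------------------------------------------------
# force waveform and tethered traces


@dataclass(frozen=True)
class ForceWaveform:
    """Periodic swimming-force waveform F(t) = F_p*(1 + a1 sin(wt) + a2 sin(2wt+psi)).

    ``F_p`` (N) is the cycle mean; the harmonic coefficients are solved so
    the per-cycle peak-to-peak equals ``r_pp * F_p`` with a negative
    recovery-stroke minimum.  Callable with time in seconds.
    """

    F_p: float
    f: float
    a1: float
    a2: float
    psi: float
    achieved_ptp_ratio: float
    achieved_min: float

    def __call__(self, t):
        th = 2.0 * math.pi * self.f * np.asarray(t, dtype=float)
        return self.F_p * (
            1.0 + self.a1 * np.sin(th) + self.a2 * np.sin(2.0 * th + self.psi)
        )


def _shape_extrema(a2_over_a1: float, psi: float) -> tuple[float, float]:
    """Accurate max and min of s(th) = sin(th) + (a2/a1) sin(2 th + psi)."""
    th = np.linspace(0.0, 2.0 * math.pi, 4096, endpoint=False)
    s = np.sin(th) + a2_over_a1 * np.sin(2.0 * th + psi)

    def val(x):
        return math.sin(x) + a2_over_a1 * math.sin(2.0 * x + psi)

    h = th[1] - th[0]
    i_max, i_min = int(np.argmax(s)), int(np.argmin(s))
    hi = minimize_scalar(lambda x: -val(x),
                         bounds=(th[i_max] - h, th[i_max] + h), method="bounded",
                         options={"xatol": 1e-12})
    lo = minimize_scalar(val,
                         bounds=(th[i_min] - h, th[i_min] + h), method="bounded",
                         options={"xatol": 1e-12})
    return -hi.fun, lo.fun


def make_force_waveform(
    L_mm: float, config: GeneratorConfig = DEFAULT_CONFIG,
    shape_ratio: float = 0.4, psi: float = 1.0,
) -> ForceWaveform:
    """Butterfly-stroke force waveform for a swimmer of body length ``L_mm``.

    F_p = c_F * L^2 (uN -> N) and f = c_f * L^beta_f (Hz) per the population
    laws; the two-harmonic template is scaled so the peak-to-peak force is
    exactly r_pp * F_p while keeping the recovery-stroke minimum negative.
    """
    if not L_mm > 0:
        raise InvalidInputError(f"L_mm must be positive, got {L_mm}")
    if config.r_pp <= 2.0:
        raise InvalidInputError("r_pp <= 2 cannot produce a negative minimum")
    F_p = config.c_F * L_mm**2 * 1e-6  # uN -> N
    f = config.c_f * L_mm**config.beta_f
    s_max, s_min = _shape_extrema(shape_ratio, psi)
    a1 = config.r_pp / (s_max - s_min)
    a2 = shape_ratio * a1
    achieved_min = F_p * (1.0 + a1 * s_min)
    if achieved_min >= 0:
        raise InvalidInputError("waveform minimum is not negative; increase r_pp")
    return ForceWaveform(
        F_p=F_p, f=f, a1=a1, a2=a2, psi=psi,
        achieved_ptp_ratio=a1 * (s_max - s_min),
        achieved_min=achieved_min,
    )


def simulate_tethered_trace(
    waveform: ForceWaveform,
    model: CantileverModel,
    sample_rate: float,
    n_cycles: int,
    release_after: int | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    baseline_offset: float = 0.0,
    post_release_s: float = 2.0,
    oversample: int = 10,
) -> DeflectionTrace:
    """Integrate the driven cantilever ODE into a deflection trace.

    m_eff xddot + b xdot + k x = F(t) is stepped with classical 4th-order
    Runge-Kutta at ``oversample`` times the output rate and downsampled.
    With ``release_after`` set, the forcing stops after that many cycles
    (the swimmer is released), the trace rings down to equilibrium for
    ``post_release_s`` seconds and the release sample index is recorded.
    The integration starts at the quasi-static state to suppress the
    start-up transient.  ``baseline_offset`` shifts the whole trace (an
    uncorrected zero), and Gaussian noise is added last.
    """
    f = waveform.f
    if sample_rate < 20.0 * f:
        raise InvalidInputError(
            f"sample_rate {sample_rate} Hz undersamples a {f:.3g} Hz stroke; "
            "need >= 20 samples per cycle"
        )
    if n_cycles < 5:
        raise InvalidInputError("need at least 5 stroke cycles")
    forcing_cycles = n_cycles if release_after is None else release_after
    t_release = forcing_cycles / f
    duration = t_release + (post_release_s if release_after is not None else 0.0)

    n_out = int(round(duration * sample_rate))
    n_fine = n_out * oversample
    h = 1.0 / (sample_rate * oversample)
    t_half = np.arange(2 * n_fine + 1) * (h / 2.0)
    F = waveform(t_half)
    F[t_half >= t_release] = 0.0

    k, b, m = model.k, model.b, model.m_eff
    # quasi-static initial state
    x = waveform(0.0) / k
    eps = 1e-6 / f
    v = (waveform(eps) - waveform(-eps)) / (2.0 * eps) / k

    out = np.empty(n_out + 1)
    out[0] = x

    def acc(xx, vv, FF):
        return (FF - b * vv - k * xx) / m

    for i in range(n_fine):
        F1, F2, F3 = F[2 * i], F[2 * i + 1], F[2 * i + 2]
        k1x = v
        k1v = acc(x, v, F1)
        k2x = v + 0.5 * h * k1v
        k2v = acc(x + 0.5 * h * k1x, k2x, F2)
        k3x = v + 0.5 * h * k2v
        k3v = acc(x + 0.5 * h * k2x, k3x, F2)
        k4x = v + h * k3v
        k4v = acc(x + h * k3x, k4x, F3)
        x += h / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
        v += h / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        if (i + 1) % oversample == 0:
            out[(i + 1) // oversample] = x

    out = out[:n_out] + baseline_offset
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=n_out)
    release_index = (
        int(round(t_release * sample_rate)) if release_after is not None else None
    )
    return DeflectionTrace(
        sample_rate=sample_rate, deflection=out, release_index=release_index
    )


# ---------------------------------------------------------------------------
# pose tracks


def _pose_coords(
    n_frames: int,
    sample_rate: float,
    L: float,
    f: float,
    delta: float,
    theta_a_amp: float,
    theta_e_amp: float,
    l_a: float,
) -> dict:
    """Noiseless body-frame keypoint coordinates of the two-segment stroke."""
    t = np.arange(n_frames) / sample_rate
    th = 2.0 * math.pi * f * t
    theta_a = np.radians(THETA_A_MEAN + theta_a_amp * np.sin(th))
    # the cos(2*) term is a function of sin(th + delta), so at delta = 0 both
    # joints follow one oscillating coordinate and the tip path retraces
    theta_e = np.radians(
        THETA_E_MEAN
        + theta_e_amp * np.sin(th + delta)
        - THETA_E_AMP2 * theta_e_amp * np.cos(2.0 * (th + delta))
    )
    r1 = r2 = 0.5 * l_a
    coords = {
        "head": np.zeros((n_frames, 2)),
        "tail": np.tile([0.0, -L], (n_frames, 1)),
    }
    for side, sgn in (("right", 1.0), ("left", -1.0)):
        sh = np.tile([sgn * 0.08 * L, -0.15 * L], (n_frames, 1))
        # proximal segment at theta_a from the body axis (0, -1)
        u = np.stack([sgn * np.sin(theta_a), -np.cos(theta_a)], axis=1)
        el = sh + r1 * u
        # distal segment at interior angle theta_e from elbow->shoulder,
        # opening toward the tail so theta_e = 180 deg is a straight antenna
        ang_u = np.arctan2(u[:, 1], u[:, 0])
        ang_w = ang_u + math.pi + sgn * theta_e
        w = np.stack([np.cos(ang_w), np.sin(ang_w)], axis=1)
        tp = el + r2 * w
        coords[f"shoulder_{side}"] = sh
        coords[f"elbow_{side}"] = el
        coords[f"tip_{side}"] = tp
    return coords


def _realized_chi(
    L: float, f: float, delta: float,
    theta_a_amp: float, theta_e_amp: float, l_a: float,
    samples_per_cycle: int = 256, n_cycles: int = 2,
) -> float:
    """chi of the noiseless stroke, measured by the kinematics module itself."""
    sample_rate = samples_per_cycle * f
    n = samples_per_cycle * n_cycles + 1
    coords = _pose_coords(n, sample_rate, L, f, delta, theta_a_amp,
                          theta_e_amp, l_a)
    track = PoseTrack(sample_rate=sample_rate, coords=coords, confidence={},
                      tether_mode="head", body_frame=True)
    return nonreciprocity(track)["chi"]


def make_pose_track(
    L_mm: float,
    chi_target: float,
    f: float | None = None,
    sample_rate: float | None = None,
    n_cycles: int = 30,
    noise_sd: float = 0.0,
    seed: int | None = None,
    tether_mode: str = "head",
    config: GeneratorConfig = DEFAULT_CONFIG,
    theta_a_amp: float = THETA_A_AMP,
    theta_e_amp: float = THETA_E_AMP,
    l_a: float | None = None,
) -> tuple[PoseTrack, dict]:
    """Synthetic 8-keypoint pose track with a commanded non-reciprocity ratio.

    The two joint angles oscillate at the stroke frequency with an
    elbow-to-armpit phase lag delta; delta = 0 retraces the same path
    (reciprocal stroke, chi = 0) and the lag is calibrated by bounded scalar
    search until the chi measured by the kinematics module's own operations
    matches ``chi_target`` to 1%.  Free-mode tracks additionally drift at
    the predicted net speed 2*chi*f*L.  Keypoint noise is added last.
    Returns the track and a truth record.
    """
    if not 0.0 <= chi_target <= 0.5:
        raise InvalidInputError(f"chi_target must be in [0, 0.5], got {chi_target}")
    L = L_mm * 1e-3
    if f is None:
        f = config.c_f * L_mm**config.beta_f
    if sample_rate is None:
        sample_rate = 80.0 * f
    if l_a is None:
        l_a = L_A_FRACTION * L

    if chi_target == 0.0:
        delta = 0.0
    else:
        chi_max = _realized_chi(L, f, math.pi / 2.0, theta_a_amp, theta_e_amp, l_a)
        if chi_target > chi_max:
            raise InvalidInputError(
                f"chi_target {chi_target} unattainable; maximum with these "
                f"amplitudes is {chi_max:.3f}"
            )
        delta = brentq(
            lambda d: _realized_chi(L, f, d, theta_a_amp, theta_e_amp, l_a)
            - chi_target,
            1e-6, math.pi / 2.0, xtol=1e-6, rtol=1e-4,
        )

    n_frames = int(round(n_cycles * sample_rate / f)) + 1
    coords = _pose_coords(n_frames, sample_rate, L, f, delta, theta_a_amp,
                          theta_e_amp, l_a)

    if tether_mode == "free":
        # drift head-first (+y) at the predicted net speed, in the lab frame
        U = 2.0 * chi_target * f * L
        drift = np.stack(
            [np.zeros(n_frames), U * np.arange(n_frames) / sample_rate], axis=1
        )
        coords = {p: xy + drift for p, xy in coords.items()}
    else:
        U = None

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = {
            p: xy + rng.normal(0.0, noise_sd, size=xy.shape)
            for p, xy in coords.items()
        }

    track = PoseTrack(
        sample_rate=sample_rate, coords=coords, confidence={},
        tether_mode=tether_mode, body_frame=False,
    )
    truth = {
        "chi": chi_target, "delta": delta, "f": f, "L": L, "l_a": l_a,
        "U": U, "theta_a_amp": theta_a_amp, "theta_e_amp": theta_e_amp,
        "n_cycles": n_cycles, "noise_sd": noise_sd, "seed": seed,
    }
    return track, truth


# ---------------------------------------------------------------------------
# populations and ensembles


def mean_tip_speed(f: float, l_a: float, theta_a_amp_deg: float = THETA_A_AMP) -> float:
    """Mean antenna-tip speed (m/s) of a sinusoidal sweep of given amplitude."""
    return 4.0 * f * math.radians(theta_a_amp_deg) * l_a


def make_population(
    n: int,
    L_range_mm: tuple[float, float] = L_RANGE_MM,
    mode: str = "allometric",
    sigma_log: float | None = None,
    seed: int | None = None,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> tuple[list[SwimmerRecord], dict]:
    """Synthetic swimmer population with known generating laws.

    Body lengths are log-uniform over ``L_range_mm``; frequencies follow
    f = c_f * L^beta_f.  ``allometric`` mode sets F_p = c_F * L^2 (uN);
    ``nonreciprocity`` mode first assigns each individual its stroke
    Reynolds number (antenna length and mean tip speed), takes chi from the
    linear-then-plateau chi-Re law and sets F_p = c_nr * chi * eta * f * L^2.
    Either way F_peak = r_pp * F_p and U = 2*chi*f*L where defined.  Each
    law carries independent lognormal scatter exp(N(0, sigma_log)).
    Returns (records, truth).
    """
    import warnings

    if n < 3:
        raise InvalidInputError("need at least 3 individuals")
    if mode not in ("allometric", "nonreciprocity"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    if sigma_log is None:
        sigma_log = config.sigma_log
    if L_range_mm[0] < L_RANGE_MM[0] or L_range_mm[1] > L_RANGE_MM[1]:
        warnings.warn(
            f"L range {L_range_mm} mm extends beyond the probed "
            f"{L_RANGE_MM} mm", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    L_mm = np.exp(rng.uniform(np.log(L_range_mm[0]), np.log(L_range_mm[1]), n))

    def scatter():
        return np.exp(rng.normal(0.0, sigma_log, n)) if sigma_log > 0 else np.ones(n)

    f = config.c_f * L_mm**config.beta_f * scatter()
    L = L_mm * 1e-3
    l_a = L_A_FRACTION * L

    if mode == "allometric":
        F_p = config.c_F * L_mm**2 * 1e-6 * scatter()  # uN -> N
        v_tip = mean_tip_speed(f, l_a)
        Re = config.rho * v_tip * l_a / config.eta
        chi = config.chi_slope * np.minimum(Re, config.Re_c)
    else:
        v_tip = mean_tip_speed(f, l_a)
        Re = config.rho * v_tip * l_a / config.eta
        chi = config.chi_slope * np.minimum(Re, config.Re_c)
        F_p = config.c_nr * chi * config.eta * f * L**2 * scatter()
    F_peak = config.r_pp * F_p
    U = 2.0 * chi * f * L

    records = [
        SwimmerRecord(
            L=float(L[i]), f=float(f[i]), rho=config.rho, eta=config.eta,
            l_a=float(l_a[i]), F_p=float(F_p[i]), F_peak=float(F_peak[i]),
            U=float(U[i]), chi=float(chi[i]), taxon_label="Artemia (synthetic)",
        )
        for i in range(n)
    ]
    truth = {
        "mode": mode, "n": n, "sigma_log": sigma_log, "seed": seed,
        "c_f": config.c_f, "beta_f": config.beta_f, "c_F": config.c_F,
        "r_pp": config.r_pp, "c_nr": config.c_nr, "Re_c": config.Re_c,
        "chi_slope": config.chi_slope, "L_mm": L_mm, "Re": Re, "chi": chi,
    }
    return records, truth


def make_chi_vs_Re(
    n: int,
    Re_range: tuple[float, float] = (0.5, 12.0),
    sigma: float = 0.1,
    seed: int | None = None,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """(Re, chi) ensemble following chi = chi_slope * min(Re, Re_c).

    Re is log-uniform over ``Re_range`` (which must span the breakpoint) and
    chi carries multiplicative Gaussian noise of relative SD ``sigma``.
    """
    if not Re_range[0] < config.Re_c < Re_range[1]:
        raise InvalidInputError(
            f"Re_range {Re_range} must span the breakpoint Re_c = {config.Re_c}"
        )
    rng = np.random.default_rng(seed)
    Re = np.exp(rng.uniform(np.log(Re_range[0]), np.log(Re_range[1]), n))
    chi = config.chi_slope * np.minimum(Re, config.Re_c)
    if sigma > 0:
        chi = chi * (1.0 + rng.normal(0.0, sigma, n))
    truth = {"Re_c": config.Re_c, "chi_slope": config.chi_slope,
             "sigma": sigma, "seed": seed, "n": n}
    return Re, chi, truth


def make_cross_taxa(
    n_per_regime: int = 60,
    Sw_range_stokes: tuple[float, float] = (1e-2, 1e3),
    Sw_range_inertial: tuple[float, float] = (1e4, 1e9),
    sigma_log: float = 0.2,
    seed: int | None = None,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> tuple[list[SwimmerRecord], dict]:
    """Cross-taxa ensemble on the two Th-Sw branches.

    Swimming numbers are log-uniform per regime; thrust numbers follow
    Th = c_stokes * Sw (Stokes) or Th = c_inertial * Sw^2 (inertial) with
    lognormal scatter.  Records are back-solved to (L, f, F_peak) in water:
    frequency log-uniform in 1-50 Hz, L = sqrt(Sw*eta/(rho*f)), and
    F_peak = Th * eta^2 / rho.
    """
    rng = np.random.default_rng(seed)
    records: list[SwimmerRecord] = []
    truth_sw, truth_th, labels = [], [], []
    for label, (lo, hi), c, p in (
        ("stokes", Sw_range_stokes, config.c_stokes, 1),
        ("inertial", Sw_range_inertial, config.c_inertial, 2),
    ):
        Sw = np.exp(rng.uniform(np.log(lo), np.log(hi), n_per_regime))
        eps = np.exp(rng.normal(0.0, sigma_log, n_per_regime)) if sigma_log > 0 \
            else np.ones(n_per_regime)
        Th = c * Sw**p * eps
        f = np.exp(rng.uniform(np.log(1.0), np.log(50.0), n_per_regime))
        L = np.sqrt(Sw * config.eta / (config.rho * f))
        F_peak = Th * config.eta**2 / config.rho
        for i in range(n_per_regime):
            records.append(SwimmerRecord(
                L=float(L[i]), f=float(f[i]), rho=config.rho, eta=config.eta,
                F_peak=float(F_peak[i]), taxon_label=f"{label} (synthetic)",
            ))
        truth_sw.append(Sw)
        truth_th.append(Th)
        labels += [label] * n_per_regime
    truth = {
        "c_stokes": config.c_stokes, "c_inertial": config.c_inertial,
        "sw_star": config.c_stokes / config.c_inertial,
        "Sw": np.concatenate(truth_sw), "Th": np.concatenate(truth_th),
        "regime": labels, "sigma_log": sigma_log, "seed": seed,
    }
    return records, truth
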