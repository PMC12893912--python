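"""End-to-end parameter-recovery protocols.

Each function runs one complete study protocol on synthetic data — generate
the inputs with the default study conditions, push them through the analysis
chain, and fit the resulting scaling relation — returning the fitted object.
They are the package's reproducibility surface: with the generator defaults,
each protocol should recover the corresponding generating constant.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .calibration import CantileverModel
from .force import analyze_trace
from .kinematics import analyze_track
from .scaling import (
    BreakpointFit,
    PowerLawFit,
    ProportionalFit,
    dimensionless_numbers,
    fit_breakpoint,
    fit_power_law,
    fit_proportionality,
)
from .synthetic import (
    DEFAULT_CONFIG,
    MK_PRODUCT,
    GeneratorConfig,
    make_chi_vs_Re,
    make_cross_taxa,
    make_force_waveform,
    make_population,
    make_pose_track,
    simulate_tethered_trace,
    spawn_seeds,
)


def frequency_law(
    seed: int, n: int = 40, sigma_log: float = 0.1,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> PowerLawFit:
    """Free power-law fit of stroke frequency (Hz) vs body length (mm)."""
    records, _ = make_population(n, sigma_log=sigma_log, seed=seed,
                                 config=config)
    L_mm = np.array([r.L for r in records]) * 1e3
    f = np.array([r.f for r in records])
    return fit_power_law(L_mm, f)


def force_allometry(
    seed: int, n: int = 60, sigma_log: float = 0.15,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> ProportionalFit:
    """Fixed-exponent-2 fit of mean propulsive force (uN) vs body length (mm)."""
    records, _ = make_population(n, mode="allometric", sigma_log=sigma_log,
                                 seed=seed, config=config)
    L_mm = np.array([r.L for r in records]) * 1e3
    Fp_uN = np.array([r.F_p for r in records]) * 1e6
    return fit_proportionality(L_mm, Fp_uN, exponent=2.0)


def peak_force_ratio(
    seed: int, n: int = 40, sigma_log: float = 0.1,
    sample_rate: float = 1000.0, n_cycles: int = 40,
    k: float = 0.01,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> ProportionalFit:
    """F_peak vs F_p prefactor through the full force-measurement chain.

    Each individual's waveform drives the cantilever ODE; the deflection
    trace is baseline-corrected, reconstructed (auto mode), segmented into
    cycles and summarized, and the per-individual (F_p, F_peak) pairs are
    fitted with the exponent fixed at 1.
    """
    model = CantileverModel(k=k, b=config.b_default, m_eff=MK_PRODUCT / k)
    records, _ = make_population(n, mode="allometric", sigma_log=sigma_log,
                                 seed=seed, config=config)
    trace_seeds = spawn_seeds(seed, n)
    Fp, Fpeak = [], []
    for i, rec in enumerate(records):
        wf = make_force_waveform(rec.L * 1e3, config)
        # carry the individual's scattered F_p and f into the waveform
        wf = dataclasses.replace(wf, F_p=rec.F_p, f=rec.f)
        trace = simulate_tethered_trace(
            wf, model, sample_rate=sample_rate, n_cycles=n_cycles,
            release_after=n_cycles, noise_sd=config.deflection_noise,
            seed=trace_seeds[i], baseline_offset=20e-6, post_release_s=1.0,
        )
        _, summary = analyze_trace(trace, model)
        Fp.append(summary.F_p)
        Fpeak.append(summary.F_peak)
    return fit_proportionality(np.array(Fp), np.array(Fpeak), exponent=1.0)


def nonreciprocity_force_law(
    seed: int, n: int = 40, sigma_log: float = 0.15, n_cycles: int = 15,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> ProportionalFit:
    """F_p/(eta f L^2) vs chi prefactor, chi re-measured from pose tracks."""
    records, truth = make_population(n, mode="nonreciprocity",
                                     sigma_log=sigma_log, seed=seed,
                                     config=config)
    track_seeds = spawn_seeds(seed, n)
    chi_meas = []
    for i, rec in enumerate(records):
        track, _ = make_pose_track(
            rec.L * 1e3, float(truth["chi"][i]), f=rec.f, n_cycles=n_cycles,
            noise_sd=config.keypoint_noise, seed=track_seeds[i], config=config,
        )
        chi_meas.append(analyze_track(track).chi)
    y = np.array([r.F_p / (r.eta * r.f * r.L**2) for r in records])
    return fit_proportionality(np.array(chi_meas), y, exponent=1.0)


def universal_scaling(
    seed: int, n_per_regime: int = 60, sigma_log: float = 0.2,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> tuple[ProportionalFit, ProportionalFit]:
    """Th-Sw prefactors on the Stokes (exponent 1) and inertial (2) branches."""
    records, truth = make_cross_taxa(n_per_regime=n_per_regime,
                                     sigma_log=sigma_log, seed=seed,
                                     config=config)
    Sw = np.array([dimensionless_numbers(r)["Sw"] for r in records])
    Th = np.array([dimensionless_numbers(r)["Th"] for r in records])
    stokes = np.array(truth["regime"]) == "stokes"
    return (
        fit_proportionality(Sw[stokes], Th[stokes], exponent=1.0),
        fit_proportionality(Sw[~stokes], Th[~stokes], exponent=2.0),
    )


def breakpoint_recovery(
    seed: int, n: int = 50, sigma: float = 0.10,
    Re_range: tuple[float, float] = (0.5, 12.0),
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> BreakpointFit:
    """Linear-then-plateau breakpoint fit on a synthetic chi-Re ensemble."""
    Re, chi, _ = make_chi_vs_Re(n, Re_range=Re_range, sigma=sigma, seed=seed,
                                config=config)
    return fit_breakpoint(Re, chi, seed=seed)
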