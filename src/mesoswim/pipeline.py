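"""End-to-end pipeline: simulate -> calibrate -> extract -> kinematics -> scaling.

``full_run`` chains every stage on synthetic data and writes per-stage
outputs, a report of all six fitted scaling relations (f-L, F_p-L^2,
F_peak-F_p, F_p/(eta f L^2)-chi, Th-Sw, chi-Re) with confidence intervals,
and a manifest recording configuration, seeds and output paths.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from pathlib import Path

import numpy as np

from . import io as mio
from .calibration import calibrate_dynamic, relative_contributions
from .force import analyze_trace
from .kinematics import analyze_track
from .scaling import (
    SwimmerRecord,
    dimensionless_numbers,
    fit_breakpoint,
    fit_power_law,
    fit_proportionality,
)
from .synthetic import (
    DEFAULT_CONFIG,
    GeneratorConfig,
    make_cantilever,
    make_chi_vs_Re,
    make_cross_taxa,
    make_force_waveform,
    make_population,
    make_pose_track,
    simulate_ringdown,
    simulate_tethered_trace,
    spawn_seeds,
)

logger = logging.getLogger(__name__)


def _fit_dict(fit) -> dict:
    return dataclasses.asdict(fit)


def full_run(
    out_dir,
    seed: int = 0,
    config: GeneratorConfig = DEFAULT_CONFIG,
    n_population: int = 40,
    n_traces: int = 12,
    n_tracks: int = 10,
    n_chi_re: int = 50,
    trace_sample_rate: float = 500.0,
    trace_cycles: int = 25,
    track_cycles: int = 12,
) -> dict:
    """Run the five-stage chain on generated data; returns the manifest.

    Problem sizes are deliberately modest defaults; every count is a
    parameter.  All randomness derives from ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(seed, 8)
    warnings_log: list[str] = []
    report: dict = {}

    # --- stage 1: cantilever calibration from a synthetic ringdown -----------
    logger.info("stage 1: dynamic calibration")
    cant_true = make_cantilever(0.020, config)
    ring = simulate_ringdown(cant_true, x0=200e-6, sample_rate=2000.0,
                             duration=1.5, noise_sd=0.2e-6, seed=seeds[0])
    mio.write_deflection_csv(out / "ringdown.csv", ring)
    model, ringfit = calibrate_dynamic(ring, k=cant_true.k)
    mio.write_calibration_json(out / "cantilever.json", model)
    drag_ratio, inertia_ratio, drag_flag, _ = relative_contributions(model, config.t_c)
    report["calibration"] = {
        "k": model.k, "b": model.b, "m_eff": model.m_eff,
        "xi": model.xi, "omega0": model.omega0,
        "f_r": model.resonant_frequency,
        "drag_ratio": drag_ratio, "inertia_ratio": inertia_ratio,
        "true": {"b": cant_true.b, "m_eff": cant_true.m_eff},
    }

    # --- stage 2: population laws (f-L, F_p-L^2) ------------------------------
    logger.info("stage 2: allometric population")
    records, _ = make_population(n_population, mode="allometric",
                                 sigma_log=config.sigma_log, seed=seeds[1],
                                 config=config)
    mio.write_records_csv(out / "population.csv", records)
    L_mm = np.array([r.L for r in records]) * 1e3
    f_hz = np.array([r.f for r in records])
    Fp_un = np.array([r.F_p for r in records]) * 1e6
    report["f_vs_L"] = _fit_dict(fit_power_law(L_mm, f_hz))
    report["Fp_vs_L2"] = _fit_dict(fit_proportionality(L_mm, Fp_un, exponent=2.0))

    # --- stage 3: force-extraction chain (F_peak vs F_p) ----------------------
    logger.info("stage 3: tethered traces for %d individuals", n_traces)
    swim_model = make_cantilever(0.0176, config)  # ~10 nN/um
    sub = spawn_seeds(seeds[2], n_traces)
    Fp_meas, Fpeak_meas = [], []
    rng = np.random.default_rng(seeds[2])
    for i in range(n_traces):
        L = float(np.exp(rng.uniform(*np.log([0.42, 1.5]))))
        wf = make_force_waveform(L, config)
        trace = simulate_tethered_trace(
            wf, swim_model, sample_rate=trace_sample_rate, n_cycles=trace_cycles,
            release_after=trace_cycles, noise_sd=config.deflection_noise,
            seed=sub[i], baseline_offset=20e-6, post_release_s=1.0,
        )
        _, summary = analyze_trace(trace, swim_model)
        Fp_meas.append(summary.F_p)
        Fpeak_meas.append(summary.F_peak)
    report["Fpeak_vs_Fp"] = _fit_dict(
        fit_proportionality(np.array(Fp_meas), np.array(Fpeak_meas), exponent=1.0)
    )

    # --- stage 4: kinematics (chi) and the non-reciprocity force law ----------
    logger.info("stage 4: pose tracks for %d individuals", n_tracks)
    nr_records, nr_truth = make_population(
        max(n_tracks, 3), mode="nonreciprocity", sigma_log=config.sigma_log,
        seed=seeds[3], config=config)
    sub = spawn_seeds(seeds[3], len(nr_records))
    chi_meas = []
    for i, rec in enumerate(nr_records):
        track, _ = make_pose_track(
            rec.L * 1e3, chi_target=float(nr_truth["chi"][i]), f=rec.f,
            n_cycles=track_cycles, noise_sd=config.keypoint_noise, seed=sub[i],
            config=config)
        chi_meas.append(analyze_track(track).chi)
    x = np.array(chi_meas)
    y = np.array([r.F_p / (r.eta * r.f * r.L**2) for r in nr_records])
    report["Fp_norm_vs_chi"] = _fit_dict(fit_proportionality(x, y, exponent=1.0))

    # --- stage 5: scaling ensembles ------------------------------------------
    logger.info("stage 5: cross-taxa and chi-Re ensembles")
    taxa, taxa_truth = make_cross_taxa(sigma_log=0.2, seed=seeds[4], config=config)
    mio.write_records_csv(out / "cross_taxa.csv", taxa)
    sw_star = taxa_truth["sw_star"]
    Sw = np.array([dimensionless_numbers(r)["Sw"] for r in taxa])
    Th = np.array([dimensionless_numbers(r)["Th"] for r in taxa])
    stokes = Sw < sw_star
    report["Th_vs_Sw_stokes"] = _fit_dict(
        fit_proportionality(Sw[stokes], Th[stokes], exponent=1.0))
    report["Th_vs_Sw_inertial"] = _fit_dict(
        fit_proportionality(Sw[~stokes], Th[~stokes], exponent=2.0))

    Re, chi, _ = make_chi_vs_Re(n_chi_re, sigma=0.1, seed=seeds[5], config=config)
    bp = fit_breakpoint(Re, chi, seed=seeds[6])
    report["chi_vs_Re"] = _fit_dict(bp)

    manifest = {
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "seed": seed,
        "stage_seeds": seeds,
        "config": dataclasses.asdict(config),
        "sizes": {
            "n_population": n_population, "n_traces": n_traces,
            "n_tracks": n_tracks, "n_chi_re": n_chi_re,
        },
        "outputs": {
            "ringdown": str(out / "ringdown.csv"),
            "cantilever": str(out / "cantilever.json"),
            "population": str(out / "population.csv"),
            "cross_taxa": str(out / "cross_taxa.csv"),
            "report": str(out / "report.json"),
        },
        "warnings": warnings_log,
    }
    report["manifest"] = manifest
    mio.write_json(out / "report.json", report)
    mio.write_json(out / "manifest.json", manifest)
    return report
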