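"""Readers and writers for every file dialect the pipeline touches.

Files use laboratory units (um for deflections and keypoints, mm for body
lengths, nN for forces, mPa*s for viscosity); in-memory containers are SI.
Pose tracks are accepted both in the three-header-row dialect written by
markerless pose estimators (scorer / bodyparts / coords rows, x-y-likelihood
column triples per part) and in a plain long format
(frame, part, x, y, confidence).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CantileverModel, DropObservation, InvalidInputError
from .force import DeflectionTrace, ForceTrace, SwimmingSummary
from .kinematics import BODY_PARTS, PoseTrack
from .scaling import SwimmerRecord

UM = 1e-6
MM = 1e-3
NN = 1e-9
MPAS = 1e-3


# ---------------------------------------------------------------------------
# deflection and drop CSVs


def read_deflection_csv(
    path, release_time_s: float | None = None
) -> DeflectionTrace:
    """Read a two-column time_s / deflection_um trace (uniform rate)."""
    df = pd.read_csv(path)
    for col in ("time_s", "deflection_um"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 3:
        raise InvalidInputError(f"{path}: fewer than 3 samples")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0] + 1e-12:
        raise InvalidInputError(f"{path}: time column is not uniformly sampled")
    sample_rate = 1.0 / float(dt[0])
    release_index = (
        int(round((release_time_s - t[0]) * sample_rate))
        if release_time_s is not None else None
    )
    return DeflectionTrace(
        sample_rate=sample_rate,
        deflection=df["deflection_um"].to_numpy(float) * UM,
        release_index=release_index,
    )


def write_deflection_csv(path, trace: DeflectionTrace) -> None:
    pd.DataFrame({
        "time_s": trace.times,
        "deflection_um": trace.deflection / UM,
    }).to_csv(path, index=False)


def read_drops_csv(path) -> list[DropObservation]:
    """Read drop-calibration observations (l_min_um, l_max_um, deflection_um)."""
    df = pd.read_csv(path)
    for col in ("l_min_um", "l_max_um", "deflection_um"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col!r}")
    rho = df["rho"] if "rho" in df.columns else pd.Series(1000.0, index=df.index)
    return [
        DropObservation(
            l_min=row.l_min_um * UM, l_max=row.l_max_um * UM,
            deflection=row.deflection_um * UM, fluid_density=float(r),
        )
        for (_, row), r in zip(df.iterrows(), rho)
    ]


def write_force_csv(path, force: ForceTrace) -> None:
    pd.DataFrame({
        "time_s": force.times,
        "force_nN": force.force / NN,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pose CSVs


def write_pose_csv(path, track: PoseTrack, scorer: str = "mesoswim") -> None:
    """Write the three-header-row pose dialect (coordinates in um)."""
    cols = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part in BODY_PARTS
         for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    n = track.n_frames
    data = np.empty((n, len(cols)))
    for j, part in enumerate(BODY_PARTS):
        data[:, 3 * j] = track.coords[part][:, 0] / UM
        data[:, 3 * j + 1] = track.coords[part][:, 1] / UM
        data[:, 3 * j + 2] = track.confidence[part]
    pd.DataFrame(data, columns=cols).to_csv(path, index_label="frame")


def write_pose_long_csv(path, track: PoseTrack) -> None:
    """Write the long pose dialect: frame, part, x, y, confidence (um)."""
    rows = []
    for part in BODY_PARTS:
        xy = track.coords[part]
        for i in range(track.n_frames):
            rows.append((i, part, xy[i, 0] / UM, xy[i, 1] / UM,
                         track.confidence[part][i]))
    pd.DataFrame(rows, columns=["frame", "part", "x", "y", "confidence"]) \
        .to_csv(path, index=False)


def _detect_dialect(path) -> str:
    with open(path) as fh:
        first = fh.readline()
        second = fh.readline()
    if "bodyparts" in second or "scorer" in first:
        return "dlc"
    return "long"


def read_pose_csv(
    path,
    sample_rate: float,
    tether_mode: str = "head",
    dialect: str = "auto",
    part_map: dict | None = None,
) -> PoseTrack:
    """Read a pose track in either dialect; coordinates are um on disk.

    ``part_map`` renames file body parts to the canonical names.  A missing
    likelihood/confidence column yields confidence 1 everywhere.
    """
    if dialect == "auto":
        dialect = _detect_dialect(path)
    part_map = part_map or {}
    coords: dict = {}
    confidence: dict = {}
    if dialect == "dlc":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        parts_in_file = list(dict.fromkeys(c[1] for c in df.columns))
        for part in parts_in_file:
            name = part_map.get(part, part)
            sub = df.xs(part, axis=1, level=1)
            sub.columns = sub.columns.get_level_values(-1)
            coords[name] = np.stack(
                [sub["x"].to_numpy(float), sub["y"].to_numpy(float)], axis=1
            ) * UM
            if "likelihood" in sub.columns:
                confidence[name] = sub["likelihood"].to_numpy(float)
    elif dialect == "long":
        df = pd.read_csv(path)
        need = {"frame", "part", "x", "y"}
        if not need.issubset(df.columns):
            raise InvalidInputError(f"{path}: long dialect needs columns {need}")
        for part, sub in df.groupby("part"):
            name = part_map.get(part, part)
            sub = sub.sort_values("frame")
            coords[name] = np.stack(
                [sub["x"].to_numpy(float), sub["y"].to_numpy(float)], axis=1
            ) * UM
            if "confidence" in sub.columns:
                confidence[name] = sub["confidence"].to_numpy(float)
    else:
        raise InvalidInputError(f"unknown pose dialect {dialect!r}")

    missing = [p for p in BODY_PARTS if p not in coords]
    if missing:
        raise InvalidInputError(
            f"{path}: missing body parts {missing}; expected {list(BODY_PARTS)}"
        )
    return PoseTrack(
        sample_rate=sample_rate, coords=coords, confidence=confidence,
        tether_mode=tether_mode,
    )


# ---------------------------------------------------------------------------
# swimmer records


RECORD_COLUMNS = ["L_mm", "la_mm", "f_Hz", "Fp_nN", "Fpeak_nN", "U_mm_s",
                  "chi", "rho", "eta_mPas", "taxon"]


def write_records_csv(path, records: list[SwimmerRecord]) -> None:
    rows = []
    for r in records:
        rows.append({
            "L_mm": r.L / MM,
            "la_mm": r.l_a / MM if r.l_a is not None else np.nan,
            "f_Hz": r.f,
            "Fp_nN": r.F_p / NN if r.F_p is not None else np.nan,
            "Fpeak_nN": r.F_peak / NN if r.F_peak is not None else np.nan,
            "U_mm_s": r.U / MM if r.U is not None else np.nan,
            "chi": r.chi if r.chi is not None else np.nan,
            "rho": r.rho,
            "eta_mPas": r.eta / MPAS,
            "taxon": r.taxon_label,
        })
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records_csv(path) -> list[SwimmerRecord]:
    df = pd.read_csv(path)
    for col in ("L_mm", "f_Hz"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col!r}")

    def opt(row, col, scale):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col]) * scale

    return [
        SwimmerRecord(
            L=float(row["L_mm"]) * MM,
            f=float(row["f_Hz"]),
            rho=float(row.get("rho", 1000.0)),
            eta=float(row.get("eta_mPas", 1.0)) * MPAS,
            l_a=opt(row, "la_mm", MM),
            F_p=opt(row, "Fp_nN", NN),
            F_peak=opt(row, "Fpeak_nN", NN),
            U=opt(row, "U_mm_s", MM),
            chi=opt(row, "chi", 1.0),
            taxon_label=str(row.get("taxon", "")),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# JSON / YAML


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(path, obj) -> None:
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_calibration_json(path, model: CantileverModel) -> None:
    """Calibration record with derived oscillator quantities and flags."""
    f_r = model.resonant_frequency
    write_json(path, {
        "k": model.k, "k_sd": model.k_sd, "b": model.b, "m_eff": model.m_eff,
        "xi": model.xi, "omega0": model.omega0, "f_r": f_r,
        "flags": {
            "resonance_defined": f_r is not None,
            "resonance_in_swim_band": model.resonance_in_band(),
        },
        "label": model.label,
    })


def read_calibration_json(path) -> CantileverModel:
    d = read_json(path)
    return CantileverModel(
        k=d["k"], b=d["b"], m_eff=d["m_eff"],
        k_sd=d.get("k_sd", 0.0), label=d.get("label", ""),
    )


def write_summary_json(path, summary: SwimmingSummary) -> None:
    write_json(path, {
        "F_p_nN": summary.F_p / NN, "F_peak_nN": summary.F_peak / NN,
        "f_Hz": summary.f, "n_cycles": summary.n_cycles,
        "se_Fp_nN": summary.se_Fp / NN, "se_Fpeak_nN": summary.se_Fpeak / NN,
        "se_f_Hz": summary.se_f,
    })


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
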