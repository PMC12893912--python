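"""Stroke kinematics from 8-keypoint pose tracks.

A markerless pose tracker marks 8 body parts of a swimming *Artemia* larva:
head, tail, one shoulder/elbow/antenna-tip triple per side.  This module
rotates each frame into the body frame (anchor at the origin, body axis
vertical), derives armpit and elbow joint angles, and quantifies the
time-reversal symmetry breaking of the stroke: over one cycle the antenna
tip traces a closed, usually figure-eight-shaped loop whose enclosed area
A_sb is zero for reciprocal (time-symmetric) motion.  Normalizing by the
sector area A_sector = pi*l_a^2*Theta_a/360 that a rigid antenna of length
l_a sweeping reciprocally through Theta_a would cover gives the
dimensionless non-reciprocity ratio chi = A_sb / A_sector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.ops import polygonize, unary_union

from .calibration import InvalidInputError

BODY_PARTS = (
    "head", "tail",
    "shoulder_left", "shoulder_right",
    "elbow_left", "elbow_right",
    "tip_left", "tip_right",
)

SIDES = ("left", "right")

#: Keypoints below this confidence are interpolated from neighboring frames.
DEFAULT_MIN_CONFIDENCE = 0.6


@dataclass(frozen=True)
class PoseTrack:
    """Timestamped 2-D coordinates (+ confidence) of the 8 tracked parts.

    ``coords`` maps part name to an (n_frames, 2) array in consistent length
    units (typically um or m); ``confidence`` maps part name to an
    (n_frames,) array in [0, 1].  ``tether_mode`` is ``head`` or ``tail``
    for tethered experiments (naming the anchored part) or ``free``.
    """

    sample_rate: float
    coords: dict
    confidence: dict
    tether_mode: str = "head"
    body_frame: bool = False

    def __post_init__(self):
        missing = [p for p in BODY_PARTS if p not in self.coords]
        if missing:
            raise InvalidInputError(f"missing body parts: {missing}")
        n = self.n_frames
        coords = {p: np.asarray(self.coords[p], dtype=float) for p in BODY_PARTS}
        conf = {
            p: np.asarray(
                self.confidence.get(p, np.ones(n)) if self.confidence else np.ones(n),
                dtype=float,
            )
            for p in BODY_PARTS
        }
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "confidence", conf)
        for p in BODY_PARTS:
            if coords[p].shape != (n, 2):
                raise InvalidInputError(f"part {p!r} has shape {coords[p].shape}")
            if np.any((conf[p] < 0) | (conf[p] > 1)):
                raise InvalidInputError(f"confidences for {p!r} outside [0, 1]")
        if self.tether_mode not in ("head", "tail", "free"):
            raise InvalidInputError(f"unknown tether_mode {self.tether_mode!r}")

    @property
    def n_frames(self) -> int:
        first = next(iter(self.coords.values()))
        return len(first)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate

    @property
    def anchor_part(self) -> str:
        return "tail" if self.tether_mode == "tail" else "head"


@dataclass(frozen=True)
class AngleSeries:
    """Armpit and elbow joint angles per frame per side (degrees)."""

    sample_rate: float
    theta_a: dict  # side -> (n_frames,) degrees
    theta_e: dict

    @property
    def n_frames(self) -> int:
        return len(self.theta_a["left"])


@dataclass(frozen=True)
class KinematicsSummary:
    """Per-individual kinematic summary, SI areas and lengths."""

    theta_a_amplitude: float
    theta_e_amplitude: float
    l_a: float
    Theta_a: float
    A_sb: float
    A_sector: float
    chi: float
    f: float
    n_cycles: int
    U: float | None = None
    se_theta_a: float = 0.0
    se_theta_e: float = 0.0
    se_A_sb: float = 0.0
    se_chi: float = 0.0
    se_f: float = 0.0
    se_U: float = 0.0

    def __post_init__(self):
        if self.A_sb < 0 or not self.A_sector > 0 or self.chi < 0:
            raise InvalidInputError("areas must be non-negative, A_sector > 0")


def interpolate_low_confidence(
    track: PoseTrack, min_confidence: float = DEFAULT_MIN_CONFIDENCE
) -> PoseTrack:
    """Linearly interpolate keypoints whose confidence falls below threshold."""
    coords = {}
    n = track.n_frames
    frames = np.arange(n)
    for p in BODY_PARTS:
        xy = track.coords[p].copy()
        good = track.confidence[p] >= min_confidence
        if good.sum() == 0:
            raise InvalidInputError(f"no confident frames for part {p!r}")
        if not good.all():
            for d in range(2):
                xy[:, d] = np.interp(frames, frames[good], xy[good, d])
        coords[p] = xy
    conf = {p: np.ones(n) for p in BODY_PARTS}
    return replace(track, coords=coords, confidence=conf)


def body_frame(track: PoseTrack) -> PoseTrack:
    """Rotate and translate each frame into the body frame.

    The anchor part (head for head-catch and free swimmers, tail for
    tail-catch) goes to the origin and the head-to-tail vector is rotated
    onto the -y axis, so the body axis is vertical and the antennae beat in
    the +-x direction.  The rotation is proper (determinant +1).  Frames in
    which head and tail coincide are interpolated from their neighbors.
    """
    n = track.n_frames
    head, tail = track.coords["head"], track.coords["tail"]
    axis = tail - head
    norm = np.hypot(axis[:, 0], axis[:, 1])
    degenerate = norm < 1e-12 * max(float(norm.max()), 1.0)
    if degenerate.all():
        raise InvalidInputError("head and tail coincide in every frame")

    # angle that rotates the head->tail vector onto (0, -1)
    ang = -math.pi / 2.0 - np.arctan2(axis[:, 1], axis[:, 0])
    if degenerate.any():
        frames = np.arange(n)
        good = ~degenerate
        uw = np.unwrap(ang[good])
        ang[good] = uw
        ang[degenerate] = np.interp(frames[degenerate], frames[good], uw)

    c, s = np.cos(ang), np.sin(ang)
    anchor = track.coords[track.anchor_part]
    coords = {}
    for p in BODY_PARTS:
        rel = track.coords[p] - anchor
        coords[p] = np.stack(
            [c * rel[:, 0] - s * rel[:, 1], s * rel[:, 0] + c * rel[:, 1]], axis=1
        )
    return replace(track, coords=coords, body_frame=True)


def _interior_angle(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Interior angle (deg) between per-frame vectors v1 and v2."""
    n1 = np.hypot(v1[:, 0], v1[:, 1])
    n2 = np.hypot(v2[:, 0], v2[:, 1])
    bad = (n1 < 1e-300) | (n2 < 1e-300)
    n1 = np.where(bad, 1.0, n1)
    n2 = np.where(bad, 1.0, n2)
    cosang = np.clip(
        (v1[:, 0] * v2[:, 0] + v1[:, 1] * v2[:, 1]) / (n1 * n2), -1.0, 1.0
    )
    ang = np.degrees(np.arccos(cosang))
    if bad.any():
        frames = np.arange(len(ang))
        ang[bad] = np.interp(frames[bad], frames[~bad], ang[~bad])
    return ang


def joint_angles(track: PoseTrack) -> AngleSeries:
    """Armpit and elbow angles per side from a body-frame track.

    theta_e is the interior angle at the elbow between the elbow->shoulder
    and elbow->tip vectors (180 deg for a straight antenna); theta_a is the
    angle at the shoulder between the shoulder->elbow vector and the body
    axis (the head->tail direction), 90 deg when the proximal segment is
    perpendicular to the body.
    """
    if not track.body_frame:
        track = body_frame(track)
    theta_a, theta_e = {}, {}
    n = track.n_frames
    body_axis = np.tile(np.array([0.0, -1.0]), (n, 1))
    for side in SIDES:
        sh = track.coords[f"shoulder_{side}"]
        el = track.coords[f"elbow_{side}"]
        tp = track.coords[f"tip_{side}"]
        theta_a[side] = _interior_angle(el - sh, body_axis)
        theta_e[side] = _interior_angle(sh - el, tp - el)
    return AngleSeries(sample_rate=track.sample_rate, theta_a=theta_a, theta_e=theta_e)


def antenna_length(track: PoseTrack) -> tuple[float, float]:
    """Mean antenna length |shoulder->elbow| + |elbow->tip| and its SD.

    Averaged over frames and sides; the SD is over frames (pooled sides).
    """
    if not track.body_frame:
        track = body_frame(track)
    lengths = []
    for side in SIDES:
        sh = track.coords[f"shoulder_{side}"]
        el = track.coords[f"elbow_{side}"]
        tp = track.coords[f"tip_{side}"]
        seg1 = np.hypot(*(el - sh).T)
        seg2 = np.hypot(*(tp - el).T)
        lengths.append(seg1 + seg2)
    lengths = np.concatenate(lengths)
    return float(np.mean(lengths)), float(np.std(lengths))


def loop_area(tip_xy: np.ndarray) -> tuple[float, bool]:
    """Symmetry-breaking area of one closed tip trajectory.

    The polygon is closed by joining the last point to the first.  A
    self-intersecting loop (the usual figure-eight) is decomposed at its
    crossing points into simple lobes and the absolute lobe areas are
    summed, so a figure-eight counts both lobes instead of cancelling.  A
    retraced (reciprocal) path encloses no area.  Returns (area, degenerate)
    where the flag marks an all-collinear input.
    """
    pts = np.asarray(tip_xy, dtype=float)
    if len(pts) < 3:
        return 0.0, True
    closed = np.vstack([pts, pts[:1]])
    line = LineString(closed)
    merged = unary_union(line)
    area = float(sum(poly.area for poly in polygonize(merged)))
    if area == 0.0:
        # distinguish a retraced path (legitimate zero) from collinear input
        centered = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] <= 1e-12 * max(sv[0], 1e-300):
            return 0.0, True
    return area, False


def sector_area(l_a: float, Theta_a: float) -> float:
    """Sector area pi * l_a**2 * Theta_a / 360 swept by a rigid antenna."""
    if not l_a > 0:
        raise InvalidInputError(f"l_a must be positive, got {l_a}")
    if not 0.0 < Theta_a <= 360.0:
        raise InvalidInputError(f"Theta_a must be in (0, 360], got {Theta_a}")
    return math.pi * l_a**2 * Theta_a / 360.0


def segment_stroke_cycles(angles: AngleSeries, min_cycles: int = 1) -> np.ndarray:
    """Cycle boundaries at upward zero crossings of the mean-subtracted armpit angle.

    The left and right armpit series are averaged first (they are in phase
    for the breaststroke gait).
    """
    y = 0.5 * (angles.theta_a["left"] + angles.theta_a["right"])
    y = y - np.mean(y)
    up = np.nonzero((y[:-1] < 0) & (y[1:] >= 0))[0] + 1
    # a track starting on a rising crossing begins a complete cycle
    if len(up) and up[0] > 2 and abs(y[0]) <= 0.02 * np.ptp(y) and y[2] > y[0]:
        up = np.concatenate([[0], up])
    if len(up) >= 3:
        # deduplicate to half the median spacing
        min_gap = 0.5 * float(np.median(np.diff(up)))
        keep = [up[0]]
        for i in up[1:]:
            if i - keep[-1] >= min_gap:
                keep.append(i)
        up = np.asarray(keep)
    if len(up) < min_cycles + 1:
        raise InvalidInputError("not enough complete stroke cycles")
    return up


def nonreciprocity(
    track: PoseTrack,
    cycles: np.ndarray | None = None,
    l_a: float | None = None,
) -> dict:
    """Per-cycle and mean non-reciprocity ratio chi = A_sb / A_sector.

    For each cycle and each side the tip trajectory (body frame) is closed
    into a loop whose decomposed area gives A_sb; the armpit excursion
    Theta_a = max - min of theta_a over the cycle and the per-individual
    antenna length give A_sector.  chi is averaged over sides and cycles.
    chi is dimensionless and invariant under uniform scaling of the track.
    """
    if not track.body_frame:
        track = body_frame(track)
    angles = joint_angles(track)
    if cycles is None:
        cycles = segment_stroke_cycles(angles)
    if l_a is None:
        l_a, _ = antenna_length(track)

    per_cycle_chi, per_cycle_asb, per_cycle_theta = [], [], []
    for a, b in zip(cycles[:-1], cycles[1:]):
        chis = []
        asbs = []
        thetas = []
        for side in SIDES:
            tip = track.coords[f"tip_{side}"][a:b]
            asb, degen = loop_area(tip)
            theta = float(np.ptp(angles.theta_a[side][a:b]))
            if theta <= 0:
                continue
            asector = sector_area(l_a, theta)
            chis.append(asb / asector)
            asbs.append(asb)
            thetas.append(theta)
        if chis:
            per_cycle_chi.append(float(np.mean(chis)))
            per_cycle_asb.append(float(np.mean(asbs)))
            per_cycle_theta.append(float(np.mean(thetas)))
    if not per_cycle_chi:
        raise InvalidInputError("no usable stroke cycles")
    chi_arr = np.asarray(per_cycle_chi)
    n = len(chi_arr)
    se = float(np.std(chi_arr, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return {
        "chi": float(np.mean(chi_arr)),
        "se_chi": se,
        "per_cycle_chi": chi_arr,
        "A_sb": float(np.mean(per_cycle_asb)),
        "se_A_sb": float(np.std(per_cycle_asb, ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        "Theta_a": float(np.mean(per_cycle_theta)),
        "l_a": float(l_a),
        "n_cycles": n,
        "cycles": np.asarray(cycles),
    }


def free_swimming_speed(track: PoseTrack) -> tuple[float, float]:
    """Net swimming speed of a free swimmer from the lab-frame anchor drift.

    The magnitude of the velocity vector obtained by linear least squares of
    the raw anchor-point x(t) and y(t) over an integer number of stroke
    cycles.  Tethered tracks are rejected.
    """
    if track.tether_mode != "free":
        raise InvalidInputError("free_swimming_speed requires tether_mode='free'")
    if track.body_frame:
        raise InvalidInputError("speed must be measured on the raw lab-frame track")
    angles = joint_angles(body_frame(track))
    cycles = segment_stroke_cycles(angles, min_cycles=2)
    a, b = cycles[0], cycles[-1]
    t = track.times[a:b]
    pos = track.coords[track.anchor_part][a:b]
    n = len(t)
    vx, cov_x = np.polyfit(t, pos[:, 0], 1, cov=True)
    vy, cov_y = np.polyfit(t, pos[:, 1], 1, cov=True)
    speed = math.hypot(vx[0], vy[0])
    if speed > 0:
        se = math.sqrt(
            (vx[0] ** 2 * cov_x[0, 0] + vy[0] ** 2 * cov_y[0, 0])
        ) / speed
    else:
        se = math.sqrt(cov_x[0, 0] + cov_y[0, 0])
    return float(speed), float(se)


def stroke_frequency(angles: AngleSeries, cycles: np.ndarray) -> tuple[float, float]:
    """Stroke frequency and SE from cycle durations of the armpit angle."""
    durations = np.diff(cycles) / angles.sample_rate
    f_per = 1.0 / durations
    n = len(f_per)
    se = float(np.std(f_per, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(1.0 / np.mean(durations)), se


def analyze_track(
    track: PoseTrack, min_confidence: float = DEFAULT_MIN_CONFIDENCE
) -> KinematicsSummary:
    """Full kinematic analysis of one pose track.

    Interpolates low-confidence keypoints, moves to the body frame, segments
    stroke cycles on the armpit angle, and assembles amplitudes, antenna
    length, symmetry-breaking and sector areas, chi, stroke frequency, and
    (for free swimmers) net speed.
    """
    clean = interpolate_low_confidence(track, min_confidence)
    bf = body_frame(clean)
    angles = joint_angles(bf)
    cycles = segment_stroke_cycles(angles)
    l_a, _ = antenna_length(bf)
    nr = nonreciprocity(bf, cycles=cycles, l_a=l_a)
    f, se_f = stroke_frequency(angles, cycles)

    amp_a, amp_e = [], []
    for a, b in zip(cycles[:-1], cycles[1:]):
        for side in SIDES:
            amp_a.append(np.ptp(angles.theta_a[side][a:b]))
            amp_e.append(np.ptp(angles.theta_e[side][a:b]))
    n = len(amp_a)

    U = se_U = None
    if track.tether_mode == "free":
        U, se_U = free_swimming_speed(clean)

    def se(v):
        return float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0

    return KinematicsSummary(
        theta_a_amplitude=float(np.mean(amp_a)),
        theta_e_amplitude=float(np.mean(amp_e)),
        l_a=l_a,
        Theta_a=nr["Theta_a"],
        A_sb=nr["A_sb"],
        A_sector=sector_area(l_a, nr["Theta_a"]),
        chi=nr["chi"],
        f=f,
        n_cycles=nr["n_cycles"],
        U=U,
        se_theta_a=se(amp_a),
        se_theta_e=se(amp_e),
        se_A_sb=nr["se_A_sb"],
        se_chi=nr["se_chi"],
        se_f=se_f,
        se_U=se_U if se_U is not None else 0.0,
    )
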