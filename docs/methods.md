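# Methods

## Force sensor model

The micropipette force sensor is modelled as a damped harmonic oscillator:
a point force `F` applied at the tip balances `F = kx + bẋ + m_eff ẍ` with
spring constant `k` (N/m), drag coefficient `b` (N·s/m) and effective mass
`m_eff` (kg). Three derived quantities follow: the undamped angular
frequency `ω₀ = √(k/m_eff)`, the damping ratio `ξ = b/(2√(m_eff·k))`, and
the resonant frequency `f_r = ω₀√(1−2ξ²)/2π`, which exists only for
`ξ < 1/√2` (above that the driven response is monotone and `f_r` is
reported as undefined). A cantilever whose `f_r` falls inside the 5–10 Hz
stroke band of the swimmers is flagged, since driving near resonance
amplifies the apparent force.

**Quasi-static calibration.** A water drop of minor axis `l_min` and major
axis `l_max` is treated as an ellipsoid of revolution,
`V = π·l_min²·l_max/6`; its weight over the static deflection gives
`k = ρVg/x`. Repeats are aggregated by mean and sample standard deviation,
with a logged warning below the protocol minimum of 4 repeats.

**Dynamic calibration.** Released from an initial deflection, the tip rings
down as `x(t) = A e^{−ξω₀t} sin(√(1−ξ²)·ω₀t + φ)`. The four parameters are
fitted by bounded nonlinear least squares. Self-initialization uses the
dominant peak of the (untapered) discrete spectrum for the damped
frequency, the logarithmic decrement of successive extrema for ξ, the first
extremum for A and the first sample for φ. Because the decrement estimate
collapses when fewer than one full period is visible (heavily damped
pipettes), the jittered restarts around it are supplemented by a fixed
ξ-grid {0.2, 0.45, 0.65, 0.85}; the lowest-residual solution wins.
Amplitude sign and phase are normalized to `A > 0`, `φ ∈ [0, 2π)`. Traces
that never change sign are rejected as not underdamped rather than fitted
with a different model; the fit domain is `0 < ξ < 1`. The equilibrium
offset is taken as the mean of the trailing 10% of samples. Finally
`b = 2kξ/ω₀` and `m_eff = k/ω₀²`.

**Contribution diagnostics.** For a stroke of characteristic time
`t_c` (default 0.1 s), drag and inertia contribute `~b/(k·t_c)` and
`~m_eff/(k·t_c²)` relative to elasticity; each is flagged when it reaches
1%.

## Force reconstruction

Deflection traces are zeroed against the post-release baseline (mean of the
post-release segment after discarding a 0.2 s settling window, during which
the freed pipette rings down; the decay time `1/ξω₀` of the default
cantilevers is a few milliseconds, so this window is generous). Velocity
uses 3-point central differences, first-order one-sided at the two ends
(flagged in the trace metadata); acceleration, when requested, uses the
central second difference. No smoothing is applied before differentiation
by default.

Mode selection: `static` (F = kx) for k ≥ 25 nN/µm, `drag` (F = kx + bẋ)
below, never `full` automatically — the inertial term is negligible on
stroke timescales for the sensors in range. Full mode exists for round-trip
verification and unusually heavy cantilevers.

Frequency estimation takes the dominant periodogram peak of the detrended
trace, with a harmonic-grouping rule (among peaks within 20 dB of the
strongest, the lowest frequency whose integer multiples explain the others
within ±5% is the fundamental — butterfly-stroke forces carry strong
harmonics) and quadratic interpolation around the winning bin. Cycle
boundaries are upward zero crossings of the mean-subtracted force after a
low-pass at 3f, deduplicated to half-period spacing; a trace that starts
exactly on a rising crossing starts a complete cycle. `F_p` is the mean of
per-cycle means, `F_peak` the mean of per-cycle (max − min) of the
unfiltered reconstructed force; standard errors are over cycles.

## Kinematics and symmetry breaking

Pose tracks carry 8 named parts per frame. Keypoints below a confidence
threshold (default 0.6) are linearly interpolated from neighboring frames.
Each frame is translated so the anchor (head for head-catch and free
swimmers, tail for tail-catch) sits at the origin and rotated (proper
rotation) so the head→tail vector points along −y; antennae then beat in
±x. The armpit angle θ_a is measured at the shoulder between the
shoulder→elbow vector and the body axis (the head→tail direction; the
shoulder–shoulder line is a possible alternative convention not used here),
and the elbow angle θ_e is the interior angle at the elbow. Both are
interior angles in (0°, 180°], so no unwrapping ambiguity arises for
physiological strokes.

The per-cycle antenna-tip trajectory, closed last-to-first, is generally a
self-intersecting figure-eight. Its symmetry-breaking area `A_sb` is the
sum of the absolute areas of the simple lobes obtained by splitting the
polygon at its self-intersections (a signed shoelace sum would cancel the
two lobes of an ∞-shape); splitting and lobe areas use planar-geometry
noding (shapely `unary_union` + `polygonize`). A retraced path has zero
area; an all-collinear cycle is flagged degenerate. The sector area is
`A_sector = π·l_a²·Θ_a/360°` with `l_a` the mean two-segment antenna length
over frames and sides, and `Θ_a` the per-cycle excursion (max − min) of
θ_a averaged over cycles — identified with the reported armpit amplitude.
χ = A_sb/A_sector is computed per cycle per side and averaged; it is
dimensionless and invariant under rigid motions and uniform scaling of the
track. Kinematic cycles are segmented at upward zero crossings of the
mean-subtracted armpit angle. Free-swimming speed is the magnitude of the
velocity vector fitted by linear least squares to the lab-frame anchor
position over an integer number of cycles.

## Scaling fits

All power-law and proportionality fits run in log space (multiplicative,
lognormal error model), appropriate to data spanning decades; points are
weighted equally. Free power laws use ordinary least squares of log y on
log x with t-based 95% intervals on slope and intercept (the prefactor
interval by exponentiation). Fixed-exponent fits average
`log y − m·log x`. The χ–Re breakpoint uses the continuous one-knot model
`χ(Re) = s·min(Re, Re_c)` — a flat plateau above the knot, matching the
observed constant non-reciprocity beyond the transition, rather than a
free second slope. `Re_c` is found by grid search (data-adjacent candidates
plus a 200-point uniform refinement between the 2nd and (n−1)th sorted Re)
with the closed-form slope at each candidate; its 95% interval comes from a
seeded residual bootstrap (500 resamples), since breakpoint estimators are
non-regular and t-intervals do not apply. Two Reynolds conventions are
exposed: body length with net speed for organism-scale maps, antenna length
with mean tip speed for stroke-regime classification.

## Synthetic data generator

The generator's defaults are the study conditions; every dataset returns a
sidecar truth record.

- **Population laws** (boundary units mm, Hz, µN): `f = 6.6·L^−0.35`,
  `F_p = 0.031·L²`, `F_peak = 16·F_p`, `F_p = 13·χ·ηfL²`
  (non-reciprocity mode), `Th = 12·Sw` and `Th = 0.011·Sw²`,
  breakpoint `Re_c = 4`. Body lengths are log-uniform over 0.42–1.5 mm;
  each law carries independent lognormal scatter.
- **χ–Re law**: `χ = 0.05·min(Re, Re_c)`. The slope (and hence the plateau
  level 0.2) is a free parameter of the generator — no quantitative value
  is established for it, so no recovery target depends on it, only on
  `Re_c`. An individual's stroke Reynolds number uses the antenna
  convention with the mean tip speed of a sinusoidal sweep,
  `v̄ = 4·f·Δθ_a·l_a`; over the default population this spans Re ≈ 1.2–12,
  crossing the breakpoint.
- **Cantilevers**: stiffness follows a beam-like cube law
  `k = 25 nN/µm · (l/1.3 cm)^−3` over the calibrated length range
  1.3–3.3 cm. The cube law cannot span the full 0.7–25 nN/µm experimental
  range over that length ratio (2.54³ ≈ 16); the default family covers
  ≈1.5–25 nN/µm. Drag defaults to the study-average 35.5 µN·s/m. The
  effective-mass default keeps `m_eff·k = 7.5×10⁻¹⁰ kg·N/m`, so heavier
  pipettes are softer, every model stays underdamped and resonance-capable
  (ξ ≈ 0.65 < 1/√2), and the undamped frequency at swim-force stiffnesses
  (≈58 Hz at 10 nN/µm) keeps the stroke band and its first harmonics
  quasi-static. Real pipettes are tapered and their mass distribution is
  not modelled; only the effective point mass is.
- **Force waveform**: `F(t) = F_p(1 + a₁sin(2πft) + a₂sin(4πft+ψ))` with
  `a₂/a₁ = 0.4`, `ψ = 1.0` fixed as shape defaults and `a₁` solved so the
  peak-to-peak equals `16·F_p` exactly; the recovery-stroke minimum is then
  necessarily negative. This is the minimal two-harmonic form satisfying
  the mean, peak-to-peak and sign constraints; no further realism is
  claimed.
- **Tethered traces**: the driven cantilever ODE is integrated by classical
  4th-order Runge–Kutta at 10× the output rate from the quasi-static
  initial state (suppressing the start-up transient), then downsampled;
  release zeroes the forcing and records the release index. Additive
  Gaussian deflection noise defaults to 0.1 µm, typical of sub-pixel image
  tracking of a high-contrast pipette tip.
- **Pose tracks**: two-segment antennae (each segment `0.275·L`,
  `l_a = 0.55·L`) driven by `θ_a = 90° + 40°·sin(2πft)` and
  `θ_e = 130° + 45°·[sin(2πft+δ) − 0.25·cos(2(2πft+δ))]`. The cos-2 term
  is a function of `sin(2πft+δ)`, so at δ = 0 both joints follow a single
  oscillating coordinate and the tip retraces its path (χ = 0); the lag δ
  is calibrated by bounded root search until the χ measured by the
  kinematics module itself matches the commanded value (attainable up to
  χ ≈ 0.40 with the default amplitudes). Free-mode tracks drift head-first
  at the predicted `U = 2χfL`. Keypoint noise (default 2 µm) is added
  last; left/right are mirror-symmetric.

## Known estimator biases and limitations

- Drag-mode reconstruction omits `m_eff·ẍ`; below resonance this inflates
  harmonic amplitudes by roughly `(ω/ω₀)²`, and per-cycle extrema of the
  unfiltered force pick up extreme-value noise. With the default
  conditions the recovered peak-to-mean ratio runs ≈16.5–17.0 against a
  generating 16 — inside the quoted ±1 band but systematically high. Full
  mode removes the inertial part of the bias.
- The synthetic stroke is strictly periodic and mirror-symmetric; real
  swimmers show cycle-to-cycle variability, left–right asymmetry, body
  roll out of the image plane and antenna bending, none of which are
  emulated. Passing recovery tests therefore validates the estimator
  chain, not robustness to those effects.
- The breakpoint fit assumes an exactly flat plateau; a slowly declining
  plateau would bias `Re_c` upward.
- Problem sizes in the test-suite and acceptance protocols (populations of
  40–60, 40 stroke cycles per trace, 500 bootstrap resamples) are the
  package's defaults for routine verification; all are parameters.
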