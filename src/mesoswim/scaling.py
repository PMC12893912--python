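"""Dimensionless numbers and scaling-law fits for swimming data.

Each swimmer is reduced to a record (body length L, stroke frequency f,
mean propulsive force F_p, peak-to-peak force F_peak, speed U, fluid
density rho and viscosity eta) from which the dimensionless groups

    Re = rho U L / eta        (Reynolds number)
    Sw = rho f L**2 / eta     (swimming number)
    Th = rho F_peak / eta**2  (thrust number)

are formed.  Fits cover free power laws y = c x**m, fixed-exponent
proportionalities, and the continuous linear-then-plateau ("hockey stick")
dependence of the non-reciprocity ratio chi on Re.  All power-law fits are
performed in log space (multiplicative, lognormal errors), appropriate to
data spanning several decades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import InvalidInputError


@dataclass(frozen=True)
class SwimmerRecord:
    """One individual's morphology, gait, forces and fluid, SI units."""

    L: float
    f: float
    rho: float = 1000.0
    eta: float = 1.0e-3
    l_a: float | None = None
    F_p: float | None = None
    F_peak: float | None = None
    U: float | None = None
    chi: float | None = None
    taxon_label: str = ""

    def __post_init__(self):
        for name in ("L", "f", "rho", "eta"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")
        for name in ("F_p", "F_peak", "U", "chi"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidInputError(f"{name} must be >= 0 when provided")


@dataclass(frozen=True)
class PowerLawFit:
    """Free power law y = prefactor * x**exponent fitted in log space."""

    prefactor: float
    prefactor_ci: tuple[float, float]
    exponent: float
    exponent_ci: tuple[float, float]
    r_squared: float
    n: int


@dataclass(frozen=True)
class ProportionalFit:
    """Fixed-exponent proportionality y = prefactor * x**fixed_exponent."""

    fixed_exponent: float
    prefactor: float
    prefactor_ci: tuple[float, float]
    n: int


@dataclass(frozen=True)
class BreakpointFit:
    """Continuous linear-then-plateau fit chi(Re) = slope * min(Re, Re_c)."""

    slope: float
    Re_c: float
    Re_c_ci: tuple[float, float]
    plateau: float
    rss: float
    n: int
    degenerate: bool = False


def dimensionless_numbers(
    record: SwimmerRecord, length_choice: str = "body"
) -> dict:
    """Re, Sw and Th of a swimmer record; missing inputs yield None.

    ``length_choice='antenna'`` builds Re from the antenna length l_a and the
    mean antenna-tip speed stored in ``U`` (the stroke-regime convention);
    ``'body'`` uses body length and net swimming speed.
    """
    if length_choice not in ("body", "antenna"):
        raise InvalidInputError(f"unknown length_choice {length_choice!r}")
    L = record.L if length_choice == "body" else record.l_a
    out = {"Re": None, "Sw": None, "Th": None}
    if record.U is not None and L is not None:
        out["Re"] = record.rho * record.U * L / record.eta
    out["Sw"] = record.rho * record.f * record.L**2 / record.eta
    if record.F_peak is not None:
        out["Th"] = record.rho * record.F_peak / record.eta**2
    return out


def _check_positive(x: np.ndarray, y: np.ndarray):
    bad = np.nonzero((x <= 0) | (y <= 0))[0]
    if len(bad):
        raise InvalidInputError(
            f"power-law fitting needs positive data; offending indices: {bad.tolist()}"
        )


def fit_power_law(x, y, conf: float = 0.95) -> PowerLawFit:
    """OLS of log y on log x; prefactor = exp(intercept).

    Confidence intervals are t-based on slope and intercept; the prefactor
    CI is the exponentiated intercept CI.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise InvalidInputError("need at least 3 points for a free power law")
    _check_positive(x, y)
    lx, ly = np.log(x), np.log(y)
    n = len(x)
    res = stats.linregress(lx, ly)
    dof = n - 2
    tval = stats.t.ppf(0.5 + conf / 2.0, dof) if dof > 0 else math.inf
    slope_half = tval * res.stderr
    inter_half = tval * res.intercept_stderr
    if not np.isfinite(slope_half):
        slope_half = inter_half = 0.0
    return PowerLawFit(
        prefactor=float(np.exp(res.intercept)),
        prefactor_ci=(
            float(np.exp(res.intercept - inter_half)),
            float(np.exp(res.intercept + inter_half)),
        ),
        exponent=float(res.slope),
        exponent_ci=(float(res.slope - slope_half), float(res.slope + slope_half)),
        r_squared=float(res.rvalue**2),
        n=n,
    )


def fit_proportionality(x, y, exponent: float, conf: float = 0.95) -> ProportionalFit:
    """Fixed-exponent fit: log y - exponent*log x averaged for the prefactor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise InvalidInputError("need at least 2 points")
    _check_positive(x, y)
    resid = np.log(y) - exponent * np.log(x)
    n = len(resid)
    mean = float(np.mean(resid))
    sd = float(np.std(resid, ddof=1))
    half = stats.t.ppf(0.5 + conf / 2.0, n - 1) * sd / math.sqrt(n)
    if not np.isfinite(half):
        half = 0.0
    return ProportionalFit(
        fixed_exponent=exponent,
        prefactor=float(np.exp(mean)),
        prefactor_ci=(float(np.exp(mean - half)), float(np.exp(mean + half))),
        n=n,
    )


def _breakpoint_rss(Re: np.ndarray, chi: np.ndarray, c: float) -> tuple[float, float]:
    """Closed-form slope and RSS of chi = s*min(Re, c) at candidate breakpoint c."""
    m = np.minimum(Re, c)
    denom = float(m @ m)
    if denom == 0:
        return 0.0, float(chi @ chi)
    s = float(chi @ m) / denom
    r = chi - s * m
    return s, float(r @ r)


def fit_breakpoint(
    Re_values,
    chi_values,
    n_boot: int = 500,
    seed: int | None = 0,
    n_grid: int = 200,
) -> BreakpointFit:
    """Fit the continuous linear-then-plateau model chi(Re) = slope*min(Re, Re_c).

    The breakpoint is found by grid search over candidate Re_c values
    between the 2nd and (n-1)th sorted Re (sorted data points plus a uniform
    refinement grid), with the slope closed-form at each candidate; the
    95% CI on Re_c comes from a seeded residual bootstrap.  Data lying
    entirely in one regime set the ``degenerate`` flag with Re_c pinned at
    the corresponding range boundary.
    """
    Re = np.asarray(Re_values, dtype=float)
    chi = np.asarray(chi_values, dtype=float)
    n = len(Re)
    if n < 6:
        raise InvalidInputError("need at least 6 points spanning both regimes")

    order = np.argsort(Re)
    lo, hi = Re[order][1], Re[order][-2]
    grid = np.unique(
        np.concatenate([Re[(Re >= lo) & (Re <= hi)], np.linspace(lo, hi, n_grid)])
    )

    def best_fit(chi_vec):
        rss = np.empty(len(grid))
        slopes = np.empty(len(grid))
        for i, c in enumerate(grid):
            slopes[i], rss[i] = _breakpoint_rss(Re, chi_vec, c)
        i = int(np.argmin(rss))
        return slopes[i], float(grid[i]), float(rss[i])

    slope, Re_c, rss = best_fit(chi)

    degenerate = bool(Re_c <= lo * (1 + 1e-9) or Re_c >= hi * (1 - 1e-9))

    # residual bootstrap for the Re_c confidence interval
    fitted = slope * np.minimum(Re, Re_c)
    resid = chi - fitted
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        chi_b = fitted + rng.choice(resid, size=n, replace=True)
        _, boot[b], _ = best_fit(chi_b)
    ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))

    return BreakpointFit(
        slope=float(slope), Re_c=float(Re_c), Re_c_ci=ci,
        plateau=float(slope * Re_c), rss=rss, n=n, degenerate=degenerate,
    )


def predicted_speed(chi: float, f: float, L: float) -> float:
    """Predicted net speed U = 2 * chi * f * L of a non-reciprocal swimmer."""
    return 2.0 * chi * f * L


#: Default Th-Sw branch prefactors: Stokes Th = 12*Sw, inertial Th = 0.011*Sw^2.
STOKES_PREFACTOR = 12.0
INERTIAL_PREFACTOR = 0.011


def regime_classify(
    Sw: float,
    c_stokes: float = STOKES_PREFACTOR,
    c_inertial: float = INERTIAL_PREFACTOR,
    crossover_width: float = 10.0,
) -> str:
    """Classify a swimming number as stokes / crossover / inertial.

    The two branches Th = c_stokes*Sw and Th = c_inertial*Sw**2 intersect at
    Sw* = c_stokes / c_inertial (~1091 with the defaults); below Sw* is
    stokes, above crossover_width*Sw* is inertial, in between crossover.
    """
    if not Sw > 0:
        raise InvalidInputError(f"Sw must be positive, got {Sw}")
    sw_star = c_stokes / c_inertial
    if Sw < sw_star:
        return "stokes"
    if Sw > crossover_width * sw_star:
        return "inertial"
    return "crossover"
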