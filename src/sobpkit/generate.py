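"""Synthetic pristine Bragg peaks, lateral profiles and measurement noise.

The pristine-peak model is a Bragg–Kleeman stopping-power shape,

    D0(d) ∝ (R - d)^(1/p - 1),   d < R,  p = 1.77,

plus a linear nuclear-background ramp and a constant entrance pedestal,
convolved with a Gaussian of width ``distal_spread_sigma`` (cm).  The
Gaussian width is a depth-space proxy for the beam's energy spread: a
larger sigma smears the narrow stopping-power peak down while leaving
the entrance dose untouched, so the *normalized* entrance dose PDD(0.5)
and the distal 80–20 falloff distance both grow with sigma — the
qualitative behaviour commissioning tuning relies on.  (A rough
documentation-only mapping is sigma ≈ 2.5 · (ΔE/E) · R.)

The convolution runs on an internal 0.01 cm supersampled grid; the
stopping-power singularity at d = R is handled by exact cell averaging
of its antiderivative, so the fine-grid samples are well defined.  The
generator then calibrates an internal shift of R so the distal 90%
crossing of the finished peak lands on the requested ``range_d90``
within 0.02 cm, and finally resamples linearly to the requested grid.

Lateral profiles are flat-topped fields with error-function edges,

    P(x) = [Φ((x + L/2)/σp) - Φ((x - L/2)/σp)] · (1 + ripple),

giving an exact analytic per-side 80–20 penumbra of 1.6832·σp for wide
fields.  The optional cosine ripple has one full period across the
middle-80% evaluation window so its amplitude (in %) is directly the
profile's flatness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .curves import DepthDoseCurve, LateralProfile, _Curve1D
from .metrics import _falling_crossings

__all__ = [
    "PristinePeakParams",
    "ProfileParams",
    "GeneratorError",
    "generate_pristine_peak",
    "generate_lateral_profile",
    "add_measurement_noise",
    "depth_grid",
    "position_grid",
]

#: Bragg–Kleeman range-energy exponent for protons in water
BRAGG_KLEEMAN_P = 1.77
#: internal supersampling pitch, cm
FINE_SPACING = 0.01
#: Gaussian kernel half-width in sigmas
KERNEL_NSIGMA = 6.0
#: calibration tolerance on the distal-90% crossing, cm
RANGE_TOL = 0.02


class GeneratorError(ValueError):
    """Raised for invalid generator parameters or insufficient grids."""


@dataclass(frozen=True)
class PristinePeakParams:
    """Knobs of the synthetic pristine-peak model.

    range_d90
        target depth (cm) of the distal 90% crossing.
    distal_spread_sigma
        Gaussian smearing width (cm); energy-spread proxy.
    entrance_fraction
        constant pedestal on [0, R) relative to the pre-convolution peak;
        raises PDD(0.5) without touching the falloff.
    background_fraction
        amplitude of a linear ramp background (1 - d/R), emulating the
        nuclear-interaction buildup of real peaks.
    fluence
        protons delivered by one wheel step; scales the (arbitrary-unit)
        dose linearly.
    """

    range_d90: float
    distal_spread_sigma: float = 0.3
    entrance_fraction: float = 0.0075
    background_fraction: float = 0.0075
    fluence: float = 3e6

    def __post_init__(self) -> None:
        if self.range_d90 <= 0:
            raise GeneratorError("range_d90 must be positive")
        if self.distal_spread_sigma <= 0:
            raise GeneratorError("distal_spread_sigma must be positive")
        if not 0 <= self.entrance_fraction < 1:
            raise GeneratorError("entrance_fraction must be in [0, 1)")
        if not 0 <= self.background_fraction < 0.2:
            raise GeneratorError("background_fraction must be in [0, 0.2)")
        if self.fluence <= 0:
            raise GeneratorError("fluence must be positive")


@dataclass(frozen=True)
class ProfileParams:
    """Knobs of the synthetic flat-field lateral profile."""

    field_width: float
    penumbra_sigma: float = 0.3
    ripple_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.field_width <= 0:
            raise GeneratorError("field_width must be positive")
        if self.penumbra_sigma <= 0:
            raise GeneratorError("penumbra_sigma must be positive")
        if not 0 <= self.ripple_amplitude <= 5:
            raise GeneratorError("ripple_amplitude must be in [0, 5] %")


def depth_grid(stop: float, spacing: float = 0.1, start: float = 0.0) -> np.ndarray:
    """Uniform depth grid [start, stop] (cm), endpoint included."""
    n = int(round((stop - start) / spacing))
    return start + spacing * np.arange(n + 1)


def position_grid(half_span: float, spacing: float = 0.1) -> np.ndarray:
    """Uniform symmetric position grid [-half_span, half_span] (cm)."""
    n = int(round(half_span / spacing))
    return spacing * np.arange(-n, n + 1)


# ---------------------------------------------------------------------------
# pristine peak

def _bk_cell_average(R: float, x: np.ndarray, h: float) -> np.ndarray:
    """Cell-averaged Bragg–Kleeman dose (R - d)^(1/p - 1) over cells of width h.

    Uses the exact antiderivative so the integrable singularity at d = R
    contributes its true cell mass instead of a grid-dependent sample.
    """
    q = 1.0 / BRAGG_KLEEMAN_P  # exponent of the antiderivative
    lo = np.clip(R - (x + h / 2.0), 0.0, None)
    hi = np.clip(R - (x - h / 2.0), 0.0, None)
    return (hi**q - lo**q) / (q * h)


def _fine_peak(R: float, params: PristinePeakParams, xmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized peak on the supersampled grid for shifted range R.

    The stopping-power shape is evaluated on a domain extended upstream of
    the water surface (the curve continues smoothly into d < 0, where the
    beam traverses nozzle material), so the Gaussian convolution has no
    artificial truncation dip at d = 0; the result is cropped to d >= 0.
    """
    h = FINE_SPACING
    sigma = params.distal_spread_sigma
    pad = int(np.ceil(KERNEL_NSIGMA * sigma / h)) + 1
    x = h * np.arange(-pad, int(np.ceil(xmax / h)) + 1)
    bk = _bk_cell_average(R, x, h)
    # normalize by the analytic average over an aligned peak cell [R-h, R]
    # rather than the grid's max cell, which jitters with frac(R/h)
    q = 1.0 / BRAGG_KLEEMAN_P
    bk /= h ** (q - 1.0) / q
    in_range = x < R
    shape = (
        bk
        + params.background_fraction * np.clip(1.0 - x / R, 0.0, None) * in_range
        + params.entrance_fraction * in_range
    )
    m = int(np.ceil(KERNEL_NSIGMA * sigma / h))
    k = np.exp(-0.5 * ((h * np.arange(-m, m + 1)) / sigma) ** 2)
    k /= k.sum()
    y = np.convolve(shape, k, mode="same")
    keep = x >= -0.5 * h
    return x[keep], y[keep]


def _distal_d90(x: np.ndarray, y: np.ndarray) -> float:
    hits = _falling_crossings(x, y * (100.0 / y.max()), 90.0)
    if not hits:
        raise GeneratorError("generated peak has no distal 90% crossing")
    return hits[-1]


def generate_pristine_peak(
    params: PristinePeakParams, grid: np.ndarray | None = None
) -> DepthDoseCurve:
    """Generate a pristine Bragg peak calibrated to ``params.range_d90``.

    The requested grid must extend at least to range + 5 sigma so the
    distal falloff is contained (dose at the last depth above 1% of the
    maximum is rejected).  Default grid: [0, range + 5 sigma] at 0.1 cm,
    rounded up.
    """
    sigma = params.distal_spread_sigma
    target = params.range_d90
    if grid is None:
        grid = depth_grid(np.ceil((target + 5.0 * sigma) / 0.1) * 0.1)
    grid = np.asarray(grid, dtype=float)

    xmax = max(float(grid[-1]), target + KERNEL_NSIGMA * sigma) + 2.0 * sigma + 0.5

    def miss(R: float) -> float:
        x, y = _fine_peak(R, params, xmax)
        return _distal_d90(x, y) - target

    # d90 grows monotonically with the internal range parameter; bracket
    # the root and polish it with Brent's method
    lo, hi = target - 2.0 * sigma, target + 2.0 * sigma
    lo = max(lo, 2.0 * FINE_SPACING)
    for _ in range(8):
        if miss(lo) < 0 < miss(hi):
            break
        lo = max(lo - 2.0 * sigma, 0.5 * lo)
        hi += 2.0 * sigma
    else:  # pragma: no cover - bracket always found for valid params
        raise GeneratorError("range calibration failed to bracket the target")
    R = brentq(miss, lo, hi, xtol=0.1 * RANGE_TOL)

    x, y = _fine_peak(R, params, xmax)
    dose = np.interp(grid, x, y) * (params.fluence / 3e6)
    if dose[-1] > 0.01 * dose.max():
        raise GeneratorError(
            f"grid too short: dose at last depth {grid[-1]:.2f} cm exceeds 1% of max"
        )
    meta = {
        "role": "simulated",
        "kind": "pristine",
        "range_d90": target,
        "distal_spread_sigma": sigma,
    }
    return DepthDoseCurve(grid, dose, meta)


# ---------------------------------------------------------------------------
# lateral profile

def generate_lateral_profile(
    params: ProfileParams, grid: np.ndarray | None = None
) -> LateralProfile:
    """Generate a flat-field lateral profile with erf-shaped edges."""
    L, sp, A = params.field_width, params.penumbra_sigma, params.ripple_amplitude
    if grid is None:
        grid = position_grid(np.ceil((L / 2.0 + 5.0 * sp) / 0.1) * 0.1)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > -(L + 8.0 * sp) / 2.0 or grid[-1] < (L + 8.0 * sp) / 2.0:
        raise GeneratorError(
            f"grid [{grid[0]:.2f}, {grid[-1]:.2f}] narrower than field + 8 sigma"
        )
    edges = ndtr((grid + L / 2.0) / sp) - ndtr((grid - L / 2.0) / sp)
    # one full cosine period across the middle-80% window (0.8 L wide),
    # so the ripple amplitude in % equals the resulting flatness
    ripple = 1.0 + (A / 100.0) * np.cos(2.0 * np.pi * grid / (0.8 * L))
    dose = 100.0 * edges * ripple
    meta = {"role": "simulated", "kind": "profile", "field_width": L}
    return LateralProfile(grid, dose, meta)


# ---------------------------------------------------------------------------
# measurement noise

def add_measurement_noise(curve: _Curve1D, relative_sd: float, seed: int) -> _Curve1D:
    """Apply per-point multiplicative Gaussian noise, clipped at zero.

    Emulates the point-by-point statistical scatter of detector scans.
    Deterministic for a given seed; ``relative_sd = 0`` returns an
    unchanged copy.  The result is re-flagged as un-normalized measured
    data.
    """
    if relative_sd < 0:
        raise GeneratorError("relative_sd must be non-negative")
    if relative_sd == 0:
        out = curve.copy()
        out.meta.update(role="measured", seed=seed)
        return out
    rng = np.random.default_rng(seed)
    factors = 1.0 + rng.normal(0.0, relative_sd, size=curve.dose.size)
    noisy = np.clip(curve.dose * factors, 0.0, None)
    return curve.with_dose(noisy, role="measured", normalized=False, seed=seed)
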