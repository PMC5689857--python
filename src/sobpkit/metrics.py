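"""Scalar beam metrics for commissioning QA.

Depth-dose metrics: distal D90/D20, proximal 95% depth, entrance dose
PDD(0.5), SOBP modulation width (distal 90% minus proximal 95%), peak
depth.  Lateral-profile metrics: per-side 80–20 penumbra, FWHM, field
centre, flatness and symmetry.

Flatness and symmetry follow the usual QA definitions

    F = |Dmax - Dmin| / (Dmax + Dmin) * 100
    S = |DL - DR| / (DL + DR) * 100

with Dmin/Dmax taken over the middle 80% of the field (field size taken
as the FWHM) and DL/DR the trapezoidal dose integrals over the left and
right halves of that middle-80% window.  Both are reported as absolute
percentages.

All level crossings are located by linear interpolation between grid
samples.  Distal (falling) crossings take the *deepest* crossing,
proximal (rising) crossings the *shallowest*, which resolves the
ambiguity noisy scans can create; an optional window-3 median prefilter
is available for rough data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import medfilt

from .curves import DepthDoseCurve, LateralProfile, _Curve1D

__all__ = [
    "PDDMetrics",
    "ProfileMetrics",
    "MetricError",
    "normalize",
    "depth_at_level",
    "pdd_metrics",
    "profile_metrics",
    "plateau_flatness",
]


class MetricError(ValueError):
    """Raised when a requested metric is undefined for the given curve."""


# ---------------------------------------------------------------------------
# crossing search

def _falling_crossings(x: np.ndarray, y: np.ndarray, level: float) -> list[float]:
    """Positions where y crosses from >= level to < level (linear interp)."""
    yi, yj = y[:-1], y[1:]
    i = np.nonzero((yi >= level) & (yj < level))[0]
    pos = x[i] + (level - y[i]) * (x[i + 1] - x[i]) / (y[i + 1] - y[i])
    return [float(p) for p in pos]


def _rising_crossings(x: np.ndarray, y: np.ndarray, level: float) -> list[float]:
    """Positions where y crosses from < level to >= level (linear interp)."""
    yi, yj = y[:-1], y[1:]
    i = np.nonzero((yi < level) & (yj >= level))[0]
    pos = x[i] + (level - y[i]) * (x[i + 1] - x[i]) / (y[i + 1] - y[i])
    return [float(p) for p in pos]


def _as_percent_of_max(curve: _Curve1D) -> np.ndarray:
    m = float(np.max(curve.dose))
    if m <= 0:
        raise MetricError("curve has no positive dose")
    return curve.dose * (100.0 / m)


def depth_at_level(
    curve: DepthDoseCurve,
    level: float,
    side: str = "distal",
    median_filter: bool = False,
) -> float | None:
    """Depth (cm) where the normalized curve crosses ``level`` percent.

    ``side='distal'`` returns the deepest falling crossing, ``'proximal'``
    the shallowest rising crossing.  Returns ``None`` when the curve never
    crosses the level on that side.  The curve is normalized to max = 100
    internally, so pre-normalization is allowed but not required.
    """
    if not 0.0 < level < 100.0:
        raise MetricError(f"level must be in (0, 100), got {level}")
    if side not in ("distal", "proximal"):
        raise MetricError(f"side must be 'distal' or 'proximal', got {side!r}")
    y = _as_percent_of_max(curve)
    if median_filter:
        y = medfilt(y, kernel_size=3)
    x = curve.axis
    if side == "distal":
        hits = _falling_crossings(x, y, level)
        return hits[-1] if hits else None
    if y[0] >= level:
        # curve already at/above the level at the first sample: the
        # proximal depth is the start of the scan (full-modulation case)
        return float(x[0])
    hits = _rising_crossings(x, y, level)
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# normalization

def normalize(curve: _Curve1D) -> _Curve1D:
    """Rescale a curve to the percent convention used for comparisons.

    Depth-dose curves are scaled so the global maximum is 100.  Lateral
    profiles are scaled so the dose at the field centre (midpoint of the
    50% crossings) is 100; with in-field ripple the maximum may then
    slightly exceed 100.  Idempotent; the result's meta records
    ``normalized=True``.
    """
    m = float(np.max(curve.dose))
    if m <= 0:
        raise MetricError("cannot normalize an all-zero curve")
    if isinstance(curve, LateralProfile):
        center = _field_center(curve)
        ref = float(np.interp(center, curve.positions, curve.dose))
        if ref <= 0:
            raise MetricError("zero dose at field centre")
        return curve.with_dose(curve.dose * (100.0 / ref), normalized=True)
    return curve.with_dose(curve.dose * (100.0 / m), normalized=True)


def _field_center(profile: LateralProfile) -> float:
    """Midpoint of the two 50%-of-max crossings."""
    y = _as_percent_of_max(profile)
    x = profile.positions
    rising = _rising_crossings(x, y, 50.0)
    falling = _falling_crossings(x, y, 50.0)
    if not rising or not falling:
        raise MetricError("profile lacks two 50% crossings; cannot locate field")
    return 0.5 * (rising[0] + falling[-1])


# ---------------------------------------------------------------------------
# depth-dose metrics

@dataclass
class PDDMetrics:
    """Depth-dose scalars; all depths cm, doses percent of max."""

    d90: float
    d20: float
    prox95: float | None
    pdd05: float
    sobp_width: float | None
    peak_depth: float
    pristine: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def pdd_metrics(curve: DepthDoseCurve, pristine: bool = False) -> PDDMetrics:
    """Extract D90/D20/prox95/PDD(0.5)/width/peak depth from a depth curve.

    ``pristine=True`` flags that the proximal-95% depth sits on the rising
    edge of a single Bragg peak, so ``sobp_width`` is not a modulation
    width in the clinical sense (it is still reported).
    """
    y = _as_percent_of_max(curve)
    x = curve.depths
    d90 = depth_at_level(curve, 90.0, "distal")
    if d90 is None:
        raise MetricError("no distal 90% crossing; cannot define range")
    d20 = depth_at_level(curve, 20.0, "distal")
    prox95 = depth_at_level(curve, 95.0, "proximal")
    pdd05 = float(np.interp(0.5, x, y))
    width = None if prox95 is None else d90 - prox95
    peak_depth = float(x[int(np.argmax(y))])
    return PDDMetrics(
        d90=float(d90),
        d20=float(d20) if d20 is not None else None,
        prox95=float(prox95) if prox95 is not None else None,
        pdd05=pdd05,
        sobp_width=float(width) if width is not None else None,
        peak_depth=peak_depth,
        pristine=pristine,
    )


def plateau_flatness(curve: DepthDoseCurve, d_lo: float, d_hi: float) -> float:
    """Flatness (%) of a depth-dose curve over the window [d_lo, d_hi].

    Applies the lateral-profile flatness definition in depth — used to
    grade the uniformity of a synthesized SOBP plateau.
    """
    if d_hi <= d_lo:
        raise MetricError("empty plateau window")
    y = _as_percent_of_max(curve)
    x = curve.depths
    sel = (x >= d_lo) & (x <= d_hi)
    if not np.any(sel):
        raise MetricError("plateau window contains no grid points")
    dmax, dmin = float(np.max(y[sel])), float(np.min(y[sel]))
    return abs(dmax - dmin) / (dmax + dmin) * 100.0


# ---------------------------------------------------------------------------
# profile metrics

def _trapz_between(x: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal integral of the piecewise-linear curve over [a, b]."""
    inner = x[(x > a) & (x < b)]
    xs = np.concatenate(([a], inner, [b]))
    ys = np.interp(xs, x, y)
    return float(np.trapezoid(ys, xs))


@dataclass
class ProfileMetrics:
    """Lateral-profile scalars; distances cm, doses percent."""

    penumbra_left: float
    penumbra_right: float
    penumbra_mean: float
    fwhm: float
    field_center: float
    flatness: float
    symmetry: float
    dmin: float
    dmax: float
    dl: float
    dr: float

    def to_dict(self) -> dict:
        return asdict(self)


def profile_metrics(profile: LateralProfile) -> ProfileMetrics:
    """Compute penumbra, FWHM, flatness and symmetry of a lateral profile.

    Field edges are the 50% crossings of the centre-normalized profile;
    FWHM is their separation and the field centre their midpoint.  The
    middle-80% window is centre +/- 0.4*FWHM.
    """
    prof = normalize(profile)
    x = prof.positions
    y = prof.dose
    rising50 = _rising_crossings(x, y, 50.0)
    falling50 = _falling_crossings(x, y, 50.0)
    if not rising50 or not falling50:
        raise MetricError("profile lacks two 50% crossings")
    left_edge, right_edge = rising50[0], falling50[-1]
    fwhm = right_edge - left_edge
    center = 0.5 * (left_edge + right_edge)

    def _left(level: float) -> float:
        hits = [c for c in _rising_crossings(x, y, level) if c <= center]
        if not hits:
            raise MetricError(f"no left-side {level}% crossing")
        return hits[-1]

    def _right(level: float) -> float:
        hits = [c for c in _falling_crossings(x, y, level) if c >= center]
        if not hits:
            raise MetricError(f"no right-side {level}% crossing")
        return hits[0]

    pen_l = _left(80.0) - _left(20.0)
    pen_r = _right(20.0) - _right(80.0)

    half = 0.4 * fwhm
    sel = (x >= center - half) & (x <= center + half)
    if not np.any(sel):
        raise MetricError("middle-80% window contains no grid points")
    dmax, dmin = float(np.max(y[sel])), float(np.min(y[sel]))
    flatness = abs(dmax - dmin) / (dmax + dmin) * 100.0

    dl = _trapz_between(x, y, center - half, center)
    dr = _trapz_between(x, y, center, center + half)
    symmetry = abs(dl - dr) / (dl + dr) * 100.0

    return ProfileMetrics(
        penumbra_left=float(pen_l),
        penumbra_right=float(pen_r),
        penumbra_mean=float(0.5 * (pen_l + pen_r)),
        fwhm=float(fwhm),
        field_center=float(center),
        flatness=float(flatness),
        symmetry=float(symmetry),
        dmin=dmin,
        dmax=dmax,
        dl=dl,
        dr=dr,
    )
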