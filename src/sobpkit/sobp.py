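"""Spread-out Bragg peak composition, weight fitting and width adjustment.

An SOBP is a weighted sum of range-pulled-back pristine peaks,

    D(d) = sum_i w_i * p_i(d),  w_i >= 0,

and the weights that best reproduce a target depth-dose curve minimize
the sum of squared errors over a fit window [d1, d2] sampled at 0.1 cm
depth increments,

    SSE = sum_{d=d1..d2} (D_target(d) - D(d))^2,

a convex non-negative least-squares problem solved deterministically
with ``scipy.optimize.nnls``.

Modulation-width adjustment follows the stop-pulse procedure: pulses
are removed one at a time from the fully modulated beam, shallowest
peaks first, and the resulting curve of SOBP width versus stop-pulse
count is interpolated linearly to find the (generally fractional) stop
pulse achieving a requested width; the fractional part scales the
fluence of a single pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .curves import DepthDoseCurve
from .generate import PristinePeakParams
from .metrics import MetricError, pdd_metrics
from .rmw import PristinePeakSet, PulseWeights, StepFluenceMap

__all__ = [
    "WeightVector",
    "FitResult",
    "StopPulseCurve",
    "AdjustedWeights",
    "SOBPError",
    "compose_sobp",
    "flat_target",
    "fit_weights",
    "SynthesisResult",
    "synthesize_sobp",
    "stop_pulse_curve",
    "adjust_modulation",
]

#: fit lattice pitch, cm
FIT_SPACING = 0.1

#: per-peak weights are plain non-negative float arrays
WeightVector = np.ndarray


class SOBPError(ValueError):
    """Raised for invalid compositions, fits or width requests."""


def _check_weights(weights, n_peaks: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n_peaks,):
        raise SOBPError(f"expected {n_peaks} weights, got shape {w.shape}")
    if np.any(w < 0):
        raise SOBPError("weights must be non-negative")
    return w


def compose_sobp(peaks: PristinePeakSet, weights) -> DepthDoseCurve:
    """Pointwise weighted sum of the library peaks (linear in weights)."""
    w = _check_weights(weights, len(peaks))
    dose = peaks.as_matrix() @ w
    return DepthDoseCurve(
        np.array(peaks.depths),
        dose,
        {"role": "simulated", "kind": "sobp", "n_peaks": len(peaks)},
    )


def flat_target(
    range_d90: float,
    modulation: float,
    plateau_dose: float = 100.0,
    grid: np.ndarray | None = None,
    distal_taper: float = 0.3,
    proximal_taper: float = 0.0,
    proximal_level: float = 0.0,
) -> DepthDoseCurve:
    """Idealized flat SOBP target for weight fitting.

    The plateau holds ``plateau_dose`` from ``range_d90 - modulation`` up
    to a cosine distal roll-off of length ``distal_taper`` placed so the
    curve's own distal 90% crossing equals ``range_d90`` exactly.  The
    sub-plateau region defaults to a flat ``proximal_level`` (fraction of
    plateau, default zero); a positive ``proximal_taper`` instead rolls
    the proximal edge on with a cosine of that length, positioned so the
    target's proximal 95% crossing equals ``range_d90 - modulation`` —
    matching the edge sharpness a finite peak library can deliver.
    """
    if modulation > range_d90:
        raise SOBPError("modulation cannot exceed range")
    if modulation <= 0 or range_d90 <= 0:
        raise SOBPError("range and modulation must be positive")
    # taper offset so the 90% point of (1+cos)/2 lands on range_d90
    u90 = distal_taper / np.pi * np.arccos(2 * 0.9 - 1.0)
    taper_start = range_d90 - u90
    if grid is None:
        stop = np.ceil((range_d90 + distal_taper + 0.5) / FIT_SPACING) * FIT_SPACING
        grid = FIT_SPACING * np.arange(int(round(stop / FIT_SPACING)) + 1)
    grid = np.asarray(grid, dtype=float)
    plateau_start = range_d90 - modulation
    dose = np.full_like(grid, proximal_level * plateau_dose)
    dose[grid >= plateau_start] = plateau_dose
    if proximal_taper > 0:
        # cosine rise whose 95% point lands on the plateau start
        u95 = proximal_taper / np.pi * np.arccos(1.0 - 2 * 0.95)
        rise_start = plateau_start - u95
        if rise_start > float(grid[0]):
            v = grid - rise_start
            in_rise = (v > 0) & (v < proximal_taper)
            dose[in_rise] = plateau_dose * 0.5 * (
                1.0 - np.cos(np.pi * v[in_rise] / proximal_taper)
            )
            dose[v <= 0] = proximal_level * plateau_dose
    u = grid - taper_start
    in_taper = (u > 0) & (u < distal_taper)
    dose[in_taper] = plateau_dose * 0.5 * (1.0 + np.cos(np.pi * u[in_taper] / distal_taper))
    dose[u >= distal_taper] = 0.0
    return DepthDoseCurve(
        grid,
        dose,
        {
            "role": "target",
            "kind": "flat_target",
            "range_d90": range_d90,
            "modulation": modulation,
        },
    )


@dataclass
class FitResult:
    """Fitted per-peak weights with the SSE and fit window that produced them."""

    weights: WeightVector
    sse: float
    fit_window: tuple[float, float]
    n_points: int


def _auto_window(target: DepthDoseCurve) -> tuple[float, float]:
    """Default fit window: 0.5 cm to the distal depth where the target
    first drops below 1% of its maximum beyond the peak."""
    y = target.dose
    x = target.depths
    i_peak = int(np.argmax(y))
    thresh = 0.01 * float(np.max(y))
    beyond = np.nonzero(y[i_peak:] < thresh)[0]
    d2 = float(x[i_peak + beyond[0]]) if beyond.size else float(x[-1])
    return (max(0.5, float(x[0])), d2)


def fit_weights(
    peaks: PristinePeakSet,
    target: DepthDoseCurve,
    window: tuple[float, float] | str = "auto",
) -> FitResult:
    """Non-negative least-squares weights reproducing ``target``.

    Both target and peaks are resampled by linear interpolation onto the
    0.1 cm lattice spanning the fit window.  The problem is convex, so
    the solution is deterministic and globally optimal.
    """
    if float(np.max(target.dose)) == 0.0:
        w = np.zeros(len(peaks))
        d1, d2 = (float(target.depths[0]), float(target.depths[-1]))
        n = int(np.floor((d2 - d1) / FIT_SPACING + 1e-9)) + 1
        return FitResult(weights=w, sse=0.0, fit_window=(d1, d2), n_points=n)
    if window == "auto":
        d1, d2 = _auto_window(target)
    else:
        d1, d2 = float(window[0]), float(window[1])
    if d2 <= d1:
        raise SOBPError(f"empty fit window [{d1}, {d2}]")
    lo = min(float(target.depths[0]), float(peaks.depths[0]))
    hi = max(float(target.depths[-1]), float(peaks.depths[-1]))
    if d1 < lo - 1e-9 or d2 > hi + 1e-9:
        raise SOBPError(f"fit window [{d1}, {d2}] outside curve grids")
    n = int(np.floor((d2 - d1) / FIT_SPACING + 1e-9)) + 1
    if n < len(peaks):
        raise SOBPError(
            f"{n} lattice points cannot constrain {len(peaks)} peak weights"
        )
    lattice = d1 + FIT_SPACING * np.arange(n)
    A = np.column_stack(
        [np.interp(lattice, peaks.depths, p.dose) for p in peaks.peaks]
    )
    b = np.interp(lattice, target.depths, target.dose)
    w, rnorm = nnls(A, b)
    return FitResult(weights=w, sse=float(rnorm**2), fit_window=(d1, d2), n_points=n)


# ---------------------------------------------------------------------------
# end-to-end synthesis

@dataclass
class SynthesisResult:
    """Everything produced while synthesizing a flat SOBP."""

    peaks: PristinePeakSet
    target: DepthDoseCurve
    fit: FitResult
    sobp: DepthDoseCurve


def synthesize_sobp(
    range_d90: float,
    modulation: float,
    base: "PristinePeakParams | None" = None,
    pitch_factor: float = 1.2,
    proximal_taper: float = 1.6,
    sigma_growth_per_cm: float = 0.0,
) -> SynthesisResult:
    """Build a peak library and fit it to a flat SOBP target.

    The library's pullback pitch is ``pitch_factor`` times the distal
    Gaussian sigma — fine enough that the inter-peak scalloping of the
    summed plateau stays below about 1%.  The pullback span covers the
    modulation but stops 0.5 cm short of zero range, where the peak model
    degenerates.  The target's distal taper is 3.3 sigma (matching the
    falloff the deepest peak can deliver) and its proximal edge rolls on
    over ``proximal_taper`` cm with the 95% point pinned to
    ``range - modulation``, so the fitted curve's modulation width lands
    on the request.  The fit window is the plateau plus distal taper;
    sub-plateau depths are left to the library's natural entrance dose.
    """
    from .rmw import build_step_peak_library, uniform_wheel

    if base is None:
        base = PristinePeakParams(range_d90=range_d90, distal_spread_sigma=0.2)
    sigma = base.distal_spread_sigma
    span = min(modulation, range_d90 - 0.5)
    n_steps = int(np.ceil(span / (pitch_factor * sigma))) + 1
    wheel = uniform_wheel(n_steps=n_steps, pullback_per_step=span / (n_steps - 1))
    peaks = build_step_peak_library(
        wheel, base, sigma_growth_per_cm=sigma_growth_per_cm
    )
    distal_taper = max(0.3, 3.3 * sigma)
    target = flat_target(
        range_d90,
        modulation,
        grid=np.array(peaks.depths),
        distal_taper=distal_taper,
        proximal_taper=proximal_taper,
    )
    window = (
        max(0.0, range_d90 - modulation),
        min(range_d90 + distal_taper, float(peaks.depths[-1])),
    )
    fit = fit_weights(peaks, target, window=window)
    sobp = compose_sobp(peaks, fit.weights)
    sobp.meta.update(range_d90=range_d90, modulation=modulation)
    return SynthesisResult(peaks=peaks, target=target, fit=fit, sobp=sobp)


# ---------------------------------------------------------------------------
# stop pulses

@dataclass
class StopPulseCurve:
    """SOBP width as a function of how many pulses have been removed.

    ``entries[k] = (k, width_cm)``; entry 0 is the fully modulated beam.
    ``removal_order`` lists pulse indices sorted shallowest-landing-peak
    first (largest pullback), ties broken by descending pulse index.
    """

    entries: list[tuple[int, float]]
    removal_order: list[int]

    @property
    def widths(self) -> np.ndarray:
        return np.array([w for _, w in self.entries])

    @property
    def max_width(self) -> float:
        return float(self.entries[0][1])

    @property
    def min_width(self) -> float:
        return float(self.entries[-1][1])


def _effective_step_weights(
    peaks: PristinePeakSet,
    fmap: StepFluenceMap,
    pulse_weights: PulseWeights,
    step_weights,
    removed: dict[int, float],
) -> np.ndarray:
    """Per-peak weights after scaling each pulse k by removed.get(k, 1)."""
    sw = (
        np.ones(len(peaks))
        if step_weights is None
        else _check_weights(step_weights, len(peaks))
    )
    col = {s: i for i, s in enumerate(peaks.step_indices)}
    full = np.zeros(len(peaks))
    active = np.zeros(len(peaks))
    for k, contribs in enumerate(fmap.pulse_fractions):
        keep = removed.get(k, 1.0)
        for s, f in contribs:
            if s in col:
                flu = pulse_weights.weights[k] * f
                full[col[s]] += flu
                active[col[s]] += keep * flu
    ratio = np.divide(active, full, out=np.zeros(len(peaks)), where=full > 0)
    return sw * ratio


def _removal_order(peaks: PristinePeakSet, fmap: StepFluenceMap) -> list[int]:
    pb = dict(zip(peaks.step_indices, peaks.pullbacks))
    removable = [
        k
        for k, s in enumerate(fmap.landing_step)
        if s is not None and s in pb
    ]
    return sorted(removable, key=lambda k: (pb[fmap.landing_step[k]], k), reverse=True)


def stop_pulse_curve(
    peaks: PristinePeakSet,
    fmap: StepFluenceMap,
    pulse_weights: PulseWeights,
    step_weights=None,
) -> StopPulseCurve:
    """Tabulate SOBP width against the number of removed pulses.

    ``step_weights`` are the fitted per-peak weights of the fully
    modulated beam (default uniform).  Pulses are zeroed cumulatively in
    removal order; tabulation stops when the width becomes undefined
    (the plateau has vanished).
    """
    order = _removal_order(peaks, fmap)
    entries: list[tuple[int, float]] = []
    for k in range(len(order) + 1):
        removed = {p: 0.0 for p in order[:k]}
        eff = _effective_step_weights(peaks, fmap, pulse_weights, step_weights, removed)
        if not np.any(eff > 0):
            break
        curve = compose_sobp(peaks, eff)
        try:
            m = pdd_metrics(curve)
        except MetricError:
            break
        if m.sobp_width is None:
            break
        if entries and m.sobp_width > entries[-1][1] + 1e-12:
            # width can only shrink as pulses are removed; an increase
            # signals the plateau has degenerated past the point where
            # the width metric is meaningful — stop tabulating
            break
        entries.append((k, float(m.sobp_width)))
    if not entries:
        raise SOBPError("no defined SOBP width even for the fully modulated beam")
    return StopPulseCurve(entries=entries, removal_order=order)


@dataclass
class AdjustedWeights:
    """Recomposed per-peak weights after a (fractional) stop-pulse cut."""

    weights: WeightVector
    fractional_stop_pulse: float
    achieved_width: float


def adjust_modulation(
    curve: StopPulseCurve,
    desired_width: float,
    peaks: PristinePeakSet,
    fmap: StepFluenceMap,
    pulse_weights: PulseWeights,
    step_weights=None,
) -> AdjustedWeights:
    """Scale pulse fluences so the SOBP width matches ``desired_width``.

    Brackets the request between integer stop pulses (k, k+1), linearly
    interpolates the fractional stop pulse, and scales the (k+1)-th
    removed pulse's fluence by one minus the fraction.  The achieved
    width is recomputed from the recomposed curve.
    """
    widths = curve.widths
    wmax, wmin = float(widths.max()), float(widths.min())
    if not (wmin - 1e-9 <= desired_width <= wmax + 1e-9):
        raise SOBPError(
            f"desired width {desired_width:.2f} cm outside achievable "
            f"[{wmin:.2f}, {wmax:.2f}] cm"
        )
    # exact tabulated match
    exact = np.nonzero(np.abs(widths - desired_width) <= 1e-12)[0]
    if exact.size:
        k = int(curve.entries[int(exact[0])][0])
        frac = 0.0
    else:
        k = None
        for i in range(len(widths) - 1):
            if widths[i] >= desired_width >= widths[i + 1]:
                k = int(curve.entries[i][0])
                wk, wk1 = float(widths[i]), float(widths[i + 1])
                break
        if k is None:
            raise SOBPError(
                f"desired width {desired_width:.2f} cm not bracketed by the "
                "stop-pulse curve (non-monotone tabulation?)"
            )
        frac = 0.0 if wk == wk1 else (wk - desired_width) / (wk - wk1)
    removed = {p: 0.0 for p in curve.removal_order[:k]}
    if frac > 0:
        removed[curve.removal_order[k]] = 1.0 - frac
    eff = _effective_step_weights(peaks, fmap, pulse_weights, step_weights, removed)
    composed = compose_sobp(peaks, eff)
    m = pdd_metrics(composed)
    if m.sobp_width is None:
        raise SOBPError("adjusted beam has no defined SOBP width")
    return AdjustedWeights(
        weights=eff,
        fractional_stop_pulse=float(k + frac),
        achieved_width=float(m.sobp_width),
    )
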