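"""Pulsed beam on a rotating range-modulator wheel (RMW).

A synchrocyclotron delivers the beam as discrete pulses while the RMW
spins at constant speed (600 rpm nominally), so each pulse lands on
whichever step of the stepped wheel happens to be in the beam path.
This module maps pulses to steps, splits a finite-width pulse that
straddles a step boundary ("partial shining") proportionally to angular
overlap, equalizes per-step proton fluence the way the machine's beam
current modulation does, and builds the per-step library of
range-pulled-back pristine Bragg peaks that SOBP synthesis weights.

Conventions: wheel angles are degrees in [0, 360) increasing in the
rotation direction; pulse k fires at t = k * period with the wheel at
``phase`` degrees at t = 0, so its centre angle is

    angle_k = (phase + 360 * (rpm / 60) * k * period) mod 360.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curves import DepthDoseCurve
from .generate import PristinePeakParams, generate_pristine_peak, depth_grid
from .metrics import depth_at_level

__all__ = [
    "RMWStep",
    "RMW",
    "PulseTrain",
    "StepFluenceMap",
    "PulseWeights",
    "PristinePeakSet",
    "RMWError",
    "uniform_wheel",
    "map_pulses_to_steps",
    "equalize_step_fluence",
    "build_step_peak_library",
]

_ANG_TOL = 1e-9


class RMWError(ValueError):
    """Raised for inconsistent wheel/pulse-train definitions."""


@dataclass(frozen=True)
class RMWStep:
    """One step of the modulator wheel.

    ``pullback`` is the water-equivalent range reduction (cm) relative to
    the thinnest step (index 0).  ``blocked`` marks the beam-stopping step
    (the brass wedge on the real wheel).
    """

    index: int
    angle_start: float
    angle_width: float
    pullback: float
    blocked: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.angle_start < 360:
            raise RMWError(f"angle_start {self.angle_start} outside [0, 360)")
        if self.angle_width <= 0:
            raise RMWError("angle_width must be positive")
        if self.pullback < 0:
            raise RMWError("pullback must be non-negative")


@dataclass(frozen=True)
class RMW:
    """A modulator wheel: ordered steps plus rotation speed (rpm)."""

    steps: tuple[RMWStep, ...]
    rpm: float = 600.0

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise RMWError("wheel needs at least one step")
        if self.rpm <= 0:
            raise RMWError("rpm must be positive")
        if steps[0].pullback != 0:
            raise RMWError("step 0 must have zero pullback")
        pb = [s.pullback for s in steps]
        if any(b < a for a, b in zip(pb, pb[1:])):
            raise RMWError("pullback must be non-decreasing with step index")
        if sum(s.angle_width for s in steps) > 360 + _ANG_TOL:
            raise RMWError("step angular widths exceed 360 degrees")
        ivals = sorted(
            ((s.angle_start, s.angle_start + s.angle_width) for s in steps)
        )
        for (a0, a1), (b0, _) in zip(ivals, ivals[1:]):
            if b0 < a1 - _ANG_TOL:
                raise RMWError("step angular intervals overlap")
        # wraparound overlap: last interval spilling past 360 into the first
        if ivals and ivals[-1][1] - 360 > ivals[0][0] + _ANG_TOL:
            raise RMWError("step angular intervals overlap across 0/360")

    @property
    def rotation_period(self) -> float:
        """Seconds per full rotation."""
        return 60.0 / self.rpm

    def unblocked(self) -> tuple[RMWStep, ...]:
        return tuple(s for s in self.steps if not s.blocked)


def uniform_wheel(
    n_steps: int = 14,
    pullback_per_step: float = 0.7,
    rpm: float = 600.0,
    blocked_last: bool = False,
) -> RMW:
    """Wheel with equal angular sectors and uniform pullback increments.

    ``blocked_last=True`` makes the final sector a beam stop (it keeps the
    previous step's pullback so the non-decreasing invariant holds while
    contributing no peak).
    """
    if n_steps < 1:
        raise RMWError("n_steps must be >= 1")
    width = 360.0 / n_steps
    steps = []
    for i in range(n_steps):
        blocked = blocked_last and i == n_steps - 1
        pb = pullback_per_step * (i - 1 if blocked and i > 0 else i)
        steps.append(
            RMWStep(
                index=i,
                angle_start=i * width,
                angle_width=width,
                pullback=pb,
                blocked=blocked,
            )
        )
    return RMW(steps=tuple(steps), rpm=rpm)


@dataclass(frozen=True)
class PulseTrain:
    """Regular pulse train: ``period`` s between pulses, finite angular
    footprint ``pulse_angular_width`` (deg), wheel at ``phase`` deg at t=0."""

    period: float = 0.002
    phase: float = 0.0
    pulse_angular_width: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise RMWError("period must be positive")
        if not 0 <= self.phase < 360:
            raise RMWError("phase must be in [0, 360)")
        if self.pulse_angular_width < 0:
            raise RMWError("pulse_angular_width must be non-negative")

    def pulses_per_rotation(self, rpm: float = 600.0) -> int:
        """Number of pulses fired during one full rotation at ``rpm``."""
        x = (60.0 / rpm) / self.period
        return int(np.ceil(x - 1e-9))


@dataclass
class StepFluenceMap:
    """Which pulses hit which steps, in unit-pulse fluence fractions.

    ``pulse_fractions[k]`` lists ``(step_index, fraction)`` for the
    unblocked steps pulse k touches; fractions over *all* steps (blocked
    included) sum to 1, so a pulse entirely on the beam stop has an empty
    list.  ``totals`` accumulates unweighted fractions per step.
    """

    pulse_fractions: list[list[tuple[int, float]]]
    totals: dict[int, float]
    landing_step: list[int | None]
    n_pulses: int
    rotations: int

    def per_step(self) -> dict[int, list[tuple[int, float]]]:
        """Per-step view: step index -> list of (pulse index, fraction)."""
        out: dict[int, list[tuple[int, float]]] = {s: [] for s in self.totals}
        for k, contribs in enumerate(self.pulse_fractions):
            for s, f in contribs:
                out[s].append((k, f))
        return out


def _overlap(lo: float, hi: float, a: float, b: float) -> float:
    """Length of [lo, hi] ∩ [a, b] on the circle, all in [0, 720)."""
    return max(0.0, min(hi, b) - max(lo, a))


def map_pulses_to_steps(rmw: RMW, train: PulseTrain, rotations: int = 1) -> StepFluenceMap:
    """Assign each pulse of ``rotations`` full turns to wheel steps.

    Point pulses land wholly on the step containing their centre angle; a
    finite-width pulse overlapping a boundary is split proportionally to
    angular overlap.  Overlap with blocked steps is dropped (zero dose).
    A pulse reaching an angle not covered by any step is an error: the
    wheel must be fully specified where pulses can land.
    """
    if rotations < 1:
        raise RMWError("rotations must be >= 1")
    n_pulses = rotations * train.pulses_per_rotation(rmw.rpm)
    deg_per_sec = 360.0 * rmw.rpm / 60.0

    # unrolled step intervals [start, end) plus 360-shifted copies to make
    # wraparound overlap arithmetic linear
    ivals = []
    for s in rmw.steps:
        for shift in (0.0, 360.0):
            ivals.append((s.angle_start + shift, s.angle_start + s.angle_width + shift, s))

    pulse_fractions: list[list[tuple[int, float]]] = []
    landing: list[int | None] = []
    totals: dict[int, float] = {s.index: 0.0 for s in rmw.unblocked()}
    w = train.pulse_angular_width
    for k in range(n_pulses):
        center = (train.phase + deg_per_sec * k * train.period) % 360.0
        contribs: list[tuple[int, float]] = []
        if w == 0.0:
            hit = None
            for a, b, s in ivals:
                if a - _ANG_TOL <= center < b - _ANG_TOL:
                    hit = s
                    break
            if hit is None:
                raise RMWError(f"pulse {k} at {center:.3f} deg lands in an angular gap")
            if not hit.blocked:
                contribs.append((hit.index, 1.0))
        else:
            lo, hi = center - w / 2.0, center + w / 2.0
            if lo < 0:
                lo, hi = lo + 360.0, hi + 360.0
            covered = 0.0
            for a, b, s in ivals:
                ov = _overlap(lo, hi, a, b)
                if ov > 0:
                    covered += ov
                    if not s.blocked:
                        contribs.append((s.index, ov / w))
            if covered < w - 1e-6:
                raise RMWError(
                    f"pulse {k} footprint [{lo % 360:.2f}, {hi % 360:.2f}] deg "
                    "partly lands in an angular gap"
                )
        # merge duplicate step entries (possible when footprint wraps)
        merged: dict[int, float] = {}
        for s_idx, f in contribs:
            merged[s_idx] = merged.get(s_idx, 0.0) + f
        contribs = sorted(merged.items())
        pulse_fractions.append(contribs)
        for s_idx, f in contribs:
            totals[s_idx] += f
        landing.append(
            max(contribs, key=lambda t: (t[1], t[0]))[0] if contribs else None
        )
    return StepFluenceMap(
        pulse_fractions=pulse_fractions,
        totals=totals,
        landing_step=landing,
        n_pulses=n_pulses,
        rotations=rotations,
    )


@dataclass
class PulseWeights:
    """Per-pulse proton weights plus steps that received no fluence."""

    weights: np.ndarray
    excluded_steps: list[int]
    protons_per_step: float

    def step_totals(self, fmap: StepFluenceMap) -> dict[int, float]:
        """Weighted proton fluence per step implied by these weights."""
        out = {s: 0.0 for s in fmap.totals}
        for k, contribs in enumerate(fmap.pulse_fractions):
            for s, f in contribs:
                out[s] += self.weights[k] * f
        return out


def equalize_step_fluence(
    fmap: StepFluenceMap, protons_per_step: float = 3e6
) -> PulseWeights:
    """Per-pulse proton weights giving every hit step the same fluence.

    Mirrors the machine's beam current modulation: each step the beam
    passes through receives ``protons_per_step`` protons regardless of how
    many pulses land on it.  For pulses confined to single steps the
    weights are exact closed forms; boundary-split pulses are handled by a
    non-negative least-squares solve, with a warning if exact equality is
    unattainable.  Unblocked steps hit by no pulse are warned about and
    listed in ``excluded_steps``.
    """
    excluded = [s for s, tot in fmap.totals.items() if tot <= 0]
    if excluded:
        warnings.warn(
            f"steps {excluded} received no pulse fluence and are excluded",
            stacklevel=2,
        )
    hit_steps = sorted(s for s, tot in fmap.totals.items() if tot > 0)
    row = {s: i for i, s in enumerate(hit_steps)}
    n = fmap.n_pulses
    weights = np.zeros(n)
    split = any(len(c) > 1 for c in fmap.pulse_fractions)
    if not split:
        for k, contribs in enumerate(fmap.pulse_fractions):
            if contribs:
                s, f = contribs[0]
                weights[k] = protons_per_step / fmap.totals[s]
    else:
        # every pulse carries positive weight (the BCM scales pulses, it
        # does not switch most of them off), so solve the underdetermined
        # equalization by iterative proportional scaling: each sweep
        # multiplies a pulse's weight by the fraction-weighted mean of its
        # steps' deficit ratios; converges geometrically to positive
        # weights satisfying all step totals
        A = np.zeros((len(hit_steps), n))
        for k, contribs in enumerate(fmap.pulse_fractions):
            for s, f in contribs:
                A[row[s], k] = f
        fsum = A.sum(axis=0)
        active = fsum > 0
        weights[active] = 1.0
        converged = False
        for _ in range(2000):
            totals = A @ weights
            if np.max(np.abs(totals - protons_per_step)) <= 1e-9 * protons_per_step:
                converged = True
                break
            ratio = protons_per_step / totals
            weights[active] *= (A.T @ ratio)[active] / fsum[active]
        if not converged:
            warnings.warn(
                "per-pulse weights could not equalize split pulses to "
                "1e-9 relative; returning best iterate",
                stacklevel=2,
            )
    return PulseWeights(
        weights=weights, excluded_steps=excluded, protons_per_step=protons_per_step
    )


@dataclass
class PristinePeakSet:
    """Ordered per-step pristine-peak library on one shared depth grid."""

    peaks: list[DepthDoseCurve]
    pullbacks: np.ndarray
    step_indices: list[int]

    def __post_init__(self) -> None:
        self.pullbacks = np.asarray(self.pullbacks, dtype=float)
        if not (len(self.peaks) == self.pullbacks.size == len(self.step_indices)):
            raise RMWError("peaks, pullbacks and step indices must align")
        g0 = self.peaks[0]
        for p in self.peaks[1:]:
            if not g0.same_grid(p):
                raise RMWError("all peaks must share one depth grid")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def depths(self) -> np.ndarray:
        return self.peaks[0].depths

    def as_matrix(self) -> np.ndarray:
        """(n_depths, n_peaks) dose matrix."""
        return np.column_stack([p.dose for p in self.peaks])


def build_step_peak_library(
    rmw: RMW,
    base: PristinePeakParams,
    grid: np.ndarray | None = None,
    sigma_growth_per_cm: float = 0.0,
) -> PristinePeakSet:
    """Generate one pristine peak per unblocked step of the wheel.

    Step i's peak has range ``base.range_d90 - pullback[i]``; its Gaussian
    width optionally grows linearly with pullback (shallower peaks have
    traversed more modulator material, so extra straggling is physical).
    All peaks share a grid covering the deepest peak's falloff.
    """
    steps = rmw.unblocked()
    max_pb = max(s.pullback for s in steps)
    if max_pb >= base.range_d90:
        raise RMWError(
            f"max pullback {max_pb} cm >= base range {base.range_d90} cm"
        )
    max_sigma = base.distal_spread_sigma + sigma_growth_per_cm * max_pb
    if grid is None:
        grid = depth_grid(
            np.ceil((base.range_d90 + 5.0 * max_sigma) / 0.1) * 0.1
        )
    peaks, pullbacks, indices = [], [], []
    for s in steps:
        params = PristinePeakParams(
            range_d90=base.range_d90 - s.pullback,
            distal_spread_sigma=base.distal_spread_sigma
            + sigma_growth_per_cm * s.pullback,
            entrance_fraction=base.entrance_fraction,
            background_fraction=base.background_fraction,
            fluence=base.fluence,
        )
        peak = generate_pristine_peak(params, grid=grid)
        peak.meta.update(step_index=s.index, pullback=s.pullback)
        d90 = depth_at_level(peak, 90.0, "distal")
        if d90 is None or abs(d90 - params.range_d90) > 0.05:
            raise RMWError(
                f"step {s.index} peak range {d90} deviates from "
                f"{params.range_d90} by more than 0.05 cm"
            )
        peaks.append(peak)
        pullbacks.append(s.pullback)
        indices.append(s.index)
    return PristinePeakSet(peaks=peaks, pullbacks=np.array(pullbacks), step_indices=indices)
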