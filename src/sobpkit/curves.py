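"""One-dimensional dose curves: depth-dose curves and lateral beam profiles.

Both are samples of a non-negative dose on a uniform, strictly ascending
grid.  Depths and positions are in centimetres of water; dose is in
arbitrary units until :func:`sobpkit.metrics.normalize` rescales it to
percent.  A free-form ``meta`` mapping carries provenance tags
(``role``, ``config``, ``normalized``, ``seed`` ...) that the CSV
readers/writers round-trip.
"""

from __future__ import annotations

from typing import Any

import numpy as np

__all__ = ["DepthDoseCurve", "LateralProfile", "CurveError", "GRID_TOL"]

#: absolute tolerance on grid-spacing uniformity, cm
GRID_TOL = 1e-9


class CurveError(ValueError):
    """Raised for malformed curves (grid, length or sign violations)."""


def _validate_axis(x: np.ndarray, name: str) -> None:
    if x.ndim != 1 or x.size < 2:
        raise CurveError(f"{name} must be a 1-D array with at least 2 points")
    dx = np.diff(x)
    if np.any(dx <= 0):
        raise CurveError(f"{name} must be strictly increasing")
    if np.max(dx) - np.min(dx) > GRID_TOL:
        raise CurveError(
            f"{name} must be uniformly spaced (spread {np.max(dx) - np.min(dx):.3g} cm)"
        )


class _Curve1D:
    """Shared behaviour for depth curves and lateral profiles."""

    _axis_attr = "x"

    def __init__(self, x, dose, meta: dict[str, Any] | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(dose, dtype=float)
        _validate_axis(x, self._axis_attr)
        if y.shape != x.shape:
            raise CurveError(f"dose length {y.size} != {self._axis_attr} length {x.size}")
        if np.any(y < 0):
            raise CurveError("dose values must be non-negative")
        self.dose = y
        self.meta: dict[str, Any] = {} if meta is None else dict(meta)
        setattr(self, self._axis_attr, x)
        if self.meta.get("normalized") and isinstance(self, DepthDoseCurve):
            if abs(float(np.max(y)) - 100.0) > 1e-6:
                raise CurveError("curve flagged normalized but max(dose) != 100")

    @property
    def axis(self) -> np.ndarray:
        return getattr(self, self._axis_attr)

    @property
    def spacing(self) -> float:
        x = self.axis
        return float((x[-1] - x[0]) / (x.size - 1))

    def with_dose(self, dose, **meta_updates: Any):
        """Copy of this curve with new dose values and updated meta."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return type(self)(np.array(self.axis), np.asarray(dose, dtype=float), meta)

    def copy(self):
        return type(self)(np.array(self.axis), np.array(self.dose), dict(self.meta))

    def same_grid(self, other: "_Curve1D", tol: float = 1e-9) -> bool:
        a, b = self.axis, other.axis
        return a.size == b.size and bool(np.allclose(a, b, atol=tol, rtol=0.0))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        x = self.axis
        return (
            f"{type(self).__name__}(n={x.size}, "
            f"{self._axis_attr}=[{x[0]:.3g}..{x[-1]:.3g}] cm, "
            f"max_dose={float(np.max(self.dose)):.4g}, meta={self.meta})"
        )


class DepthDoseCurve(_Curve1D):
    """Dose versus depth in water on a uniform grid (default pitch 0.1 cm)."""

    _axis_attr = "depths"

    def __init__(self, depths, dose, meta: dict[str, Any] | None = None):
        super().__init__(depths, dose, meta)


class LateralProfile(_Curve1D):
    """Dose versus lateral position at a fixed depth, grid centred near 0."""

    _axis_attr = "positions"

    def __init__(self, positions, dose, meta: dict[str, Any] | None = None):
        super().__init__(positions, dose, meta)
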