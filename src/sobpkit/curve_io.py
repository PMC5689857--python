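"""CSV / JSON readers and writers for curves, peak libraries and weights.

Curve files are two-column CSV (``depth_cm,dose`` for depth-dose curves,
``position_cm,dose`` for lateral profiles) with ``#``-prefixed metadata
lines before the header, e.g.::

    # role=measured
    # config=13
    depth_cm,dose
    0.000000,12.3456

Values are written with 6 significant digits; reading a written file and
re-writing it reproduces the bytes, and metadata round-trips.  Peak
libraries are a single CSV whose columns are ``depth_cm`` plus one dose
column per step; weights, wheels and pulse trains are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .curves import CurveError, DepthDoseCurve, LateralProfile
from .rmw import RMW, PristinePeakSet, PulseTrain, RMWStep

__all__ = [
    "read_curve",
    "write_curve",
    "read_peakset",
    "write_peakset",
    "read_weights",
    "write_weights",
    "rmw_from_json",
    "rmw_to_json",
    "train_from_json",
    "train_to_json",
]

_FMT = "{:.6g}"


def _parse_meta_value(raw: str) -> Any:
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    if raw in ("True", "False"):
        return raw == "True"
    return raw


def _read_header(path: Path) -> tuple[dict[str, Any], list[str], int]:
    """Metadata dict, header columns, and line number of the header row."""
    meta: dict[str, Any] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, raw = body.partition("=")
                    meta[key.strip()] = _parse_meta_value(raw.strip())
                continue
            cols = [c.strip() for c in line.split(",")]
            return meta, cols, lineno
    raise CurveError(f"{path}: no header row found")


def read_curve(path: str | Path) -> DepthDoseCurve | LateralProfile:
    """Read a curve CSV; the header column decides the curve type."""
    path = Path(path)
    meta, cols, header_line = _read_header(path)
    if cols == ["depth_cm", "dose"]:
        cls: type = DepthDoseCurve
    elif cols == ["position_cm", "dose"]:
        cls = LateralProfile
    else:
        raise CurveError(
            f"{path}:{header_line}: expected 'depth_cm,dose' or "
            f"'position_cm,dose' header, got {','.join(cols)!r}"
        )
    df = pd.read_csv(path, comment="#")
    x = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(x) <= 0):
        bad = int(np.nonzero(np.diff(x) <= 0)[0][0])
        raise CurveError(
            f"{path}:{header_line + bad + 2}: grid not strictly increasing"
        )
    if np.any(y < 0):
        bad = int(np.nonzero(y < 0)[0][0])
        raise CurveError(f"{path}:{header_line + bad + 1}: negative dose")
    try:
        return cls(x, y, meta)
    except CurveError as err:
        raise CurveError(f"{path}: {err}") from err


def write_curve(curve: DepthDoseCurve | LateralProfile, path: str | Path) -> None:
    """Write a curve CSV with its metadata; round-trips through read_curve."""
    path = Path(path)
    col = "depth_cm" if isinstance(curve, DepthDoseCurve) else "position_cm"
    lines = [f"# {k}={v}" for k, v in sorted(curve.meta.items())]
    lines.append(f"{col},dose")
    for x, y in zip(curve.axis, curve.dose):
        lines.append(f"{_FMT.format(x)},{_FMT.format(y)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# peak libraries

def write_peakset(peaks: PristinePeakSet, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# pullbacks={','.join(_FMT.format(p) for p in peaks.pullbacks)}"]
    lines.append(f"# step_indices={','.join(str(i) for i in peaks.step_indices)}")
    header = ["depth_cm"] + [f"peak_{i:02d}" for i in range(len(peaks))]
    lines.append(",".join(header))
    M = peaks.as_matrix()
    for j, d in enumerate(peaks.depths):
        lines.append(
            ",".join([_FMT.format(d)] + [_FMT.format(v) for v in M[j]])
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_peakset(path: str | Path) -> PristinePeakSet:
    path = Path(path)
    meta, cols, _ = _read_header(path)
    if "pullbacks" not in meta:
        raise CurveError(f"{path}: peak library lacks '# pullbacks=' metadata")
    pullbacks = np.array([float(v) for v in str(meta["pullbacks"]).split(",")])
    if "step_indices" in meta:
        indices = [int(v) for v in str(meta["step_indices"]).split(",")]
    else:
        indices = list(range(pullbacks.size))
    df = pd.read_csv(path, comment="#")
    depths = df.iloc[:, 0].to_numpy(dtype=float)
    peaks = [
        DepthDoseCurve(
            depths,
            df.iloc[:, 1 + i].to_numpy(dtype=float),
            {"pullback": float(pullbacks[i]), "step_index": indices[i]},
        )
        for i in range(df.shape[1] - 1)
    ]
    return PristinePeakSet(peaks=peaks, pullbacks=pullbacks, step_indices=indices)


# ---------------------------------------------------------------------------
# weights / wheel / train JSON

def write_weights(
    weights,
    path: str | Path,
    fractional_stop_pulse: float = 0.0,
    extra: dict[str, Any] | None = None,
) -> None:
    payload: dict[str, Any] = {
        "step_weights": [float(w) for w in np.asarray(weights, dtype=float)],
        "fractional_stop_pulse": float(fractional_stop_pulse),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_weights(path: str | Path) -> dict[str, Any]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    payload["step_weights"] = np.asarray(payload["step_weights"], dtype=float)
    return payload


def rmw_to_json(rmw: RMW, path: str | Path) -> None:
    payload = {
        "rpm": rmw.rpm,
        "steps": [
            {
                "index": s.index,
                "angle_start": s.angle_start,
                "angle_width": s.angle_width,
                "pullback_cm": s.pullback,
                "blocked": s.blocked,
            }
            for s in rmw.steps
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def rmw_from_json(path: str | Path) -> RMW:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    steps = tuple(
        RMWStep(
            index=s["index"],
            angle_start=s["angle_start"],
            angle_width=s["angle_width"],
            pullback=s["pullback_cm"],
            blocked=s.get("blocked", False),
        )
        for s in payload["steps"]
    )
    return RMW(steps=steps, rpm=payload.get("rpm", 600.0))


def train_to_json(train: PulseTrain, path: str | Path) -> None:
    payload = {
        "period_s": train.period,
        "phase_deg": train.phase,
        "pulse_angular_width_deg": train.pulse_angular_width,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def train_from_json(path: str | Path) -> PulseTrain:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return PulseTrain(
        period=payload["period_s"],
        phase=payload.get("phase_deg", 0.0),
        pulse_angular_width=payload.get("pulse_angular_width_deg", 0.0),
    )
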