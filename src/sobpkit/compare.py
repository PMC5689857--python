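"""Measured-versus-simulated comparison rows and group summaries.

These are the QA report rows a commissioning study tabulates: per
configuration, the entrance-dose and range agreement of pristine Bragg
peaks; modulation width / D90 / D20 agreement of SOBPs; and penumbra,
flatness, symmetry and FWHM agreement of lateral profiles.  Signed
differences follow the measured-minus-simulated convention; entrance
dose, penumbra and FWHM differences are reported as absolute values.

Group summaries average the *absolute* per-configuration differences.
Rendering to fixed table precision (1 decimal for percentages, 2 for
centimetres) happens only at output time; full precision is retained
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .curves import DepthDoseCurve, LateralProfile
from .metrics import normalize, pdd_metrics, profile_metrics

__all__ = [
    "PDDComparisonRow",
    "SOBPComparisonRow",
    "ProfileComparisonRow",
    "GroupSummary",
    "compare_pdd",
    "compare_sobp",
    "compare_profile",
    "group_summary",
    "rows_to_frame",
]


def _resample_to(simulated: DepthDoseCurve, measured: DepthDoseCurve) -> DepthDoseCurve:
    if measured.same_grid(simulated):
        return simulated
    dose = np.interp(measured.depths, simulated.depths, simulated.dose)
    return DepthDoseCurve(np.array(measured.depths), dose, dict(simulated.meta))


@dataclass
class PDDComparisonRow:
    """Pristine-peak agreement: entrance dose and range."""

    config: int | str | None
    pdd05_diff: float  # absolute, %
    d90_measured: float
    d90_simulated: float
    d90_diff: float  # signed, measured - simulated, cm

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SOBPComparisonRow:
    """SOBP agreement: modulation width, range, distal 20% depth."""

    config: int | str | None
    measured_width: float
    simulated_width: float
    width_diff: float  # signed, measured - simulated, cm
    d90_diff: float
    d20_diff: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProfileComparisonRow:
    """Lateral-profile agreement at one scan depth."""

    config: int | str | None
    depth: float | None
    penumbra_diff: float  # absolute, cm
    flatness_sim: float
    flatness_meas: float
    symmetry_sim: float
    symmetry_meas: float
    fwhm_diff: float  # absolute, cm

    def to_dict(self) -> dict:
        return asdict(self)


def compare_pdd(
    measured: DepthDoseCurve,
    simulated: DepthDoseCurve,
    config: int | str | None = None,
) -> PDDComparisonRow:
    """Entrance-dose and range agreement of two pristine peaks."""
    simulated = _resample_to(simulated, measured)
    mm = pdd_metrics(normalize(measured), pristine=True)
    ms = pdd_metrics(normalize(simulated), pristine=True)
    return PDDComparisonRow(
        config=config,
        pdd05_diff=abs(mm.pdd05 - ms.pdd05),
        d90_measured=mm.d90,
        d90_simulated=ms.d90,
        d90_diff=mm.d90 - ms.d90,
    )


def compare_sobp(
    measured: DepthDoseCurve,
    simulated: DepthDoseCurve,
    config: int | str | None = None,
) -> SOBPComparisonRow:
    """Modulation-width / D90 / D20 agreement of two SOBPs."""
    simulated = _resample_to(simulated, measured)
    mm = pdd_metrics(normalize(measured))
    ms = pdd_metrics(normalize(simulated))
    if mm.sobp_width is None or ms.sobp_width is None:
        raise ValueError("both curves need a defined modulation width")
    return SOBPComparisonRow(
        config=config,
        measured_width=mm.sobp_width,
        simulated_width=ms.sobp_width,
        width_diff=mm.sobp_width - ms.sobp_width,
        d90_diff=mm.d90 - ms.d90,
        d20_diff=mm.d20 - ms.d20,
    )


def compare_profile(
    measured: LateralProfile,
    simulated: LateralProfile,
    config: int | str | None = None,
    depth: float | None = None,
) -> ProfileComparisonRow:
    """Penumbra / flatness / symmetry / FWHM agreement of two profiles.

    Penumbra agreement uses the mean of the left and right penumbras;
    flatness and symmetry are reported per curve rather than differenced.
    """
    mm = profile_metrics(measured)
    ms = profile_metrics(simulated)
    if depth is None:
        depth = measured.meta.get("depth_cm")
    return ProfileComparisonRow(
        config=config,
        depth=depth,
        penumbra_diff=abs(mm.penumbra_mean - ms.penumbra_mean),
        flatness_sim=ms.flatness,
        flatness_meas=mm.flatness,
        symmetry_sim=ms.symmetry,
        symmetry_meas=mm.symmetry,
        fwhm_diff=abs(mm.fwhm - ms.fwhm),
    )


@dataclass
class GroupSummary:
    """Per-group averages of absolute pristine-peak differences."""

    group: str
    n: int
    mean_abs_pdd05_diff: float
    mean_abs_d90_diff: float
    pdd05_range: tuple[float, float]
    d90_range: tuple[float, float]
    rows: list[PDDComparisonRow]

    def rounded(self) -> dict:
        """Table-precision view: 1 dp for %, 2 dp for cm."""
        return {
            "group": self.group,
            "n": self.n,
            "mean_abs_pdd05_diff": round(self.mean_abs_pdd05_diff, 1),
            "mean_abs_d90_diff": round(self.mean_abs_d90_diff, 2),
        }


def group_summary(rows: list[PDDComparisonRow], group: str = "") -> GroupSummary:
    """Average the absolute per-configuration differences of a group."""
    if not rows:
        raise ValueError("group summary needs at least one row")
    pdd = np.array([abs(r.pdd05_diff) for r in rows])
    d90 = np.array([abs(r.d90_diff) for r in rows])
    return GroupSummary(
        group=group,
        n=len(rows),
        mean_abs_pdd05_diff=float(pdd.mean()),
        mean_abs_d90_diff=float(d90.mean()),
        pdd05_range=(float(pdd.min()), float(pdd.max())),
        d90_range=(float(d90.min()), float(d90.max())),
        rows=list(rows),
    )


_RENDER_DECIMALS = {
    "pdd05_diff": 1,
    "d90_measured": 2,
    "d90_simulated": 2,
    "d90_diff": 2,
    "measured_width": 2,
    "simulated_width": 2,
    "width_diff": 2,
    "d20_diff": 2,
    "penumbra_diff": 2,
    "flatness_sim": 1,
    "flatness_meas": 1,
    "symmetry_sim": 1,
    "symmetry_meas": 1,
    "fwhm_diff": 2,
}


def rows_to_frame(rows: list, rounded: bool = False) -> pd.DataFrame:
    """Comparison rows as a DataFrame, optionally at table precision."""
    df = pd.DataFrame([r.to_dict() for r in rows])
    if rounded:
        for col, nd in _RENDER_DECIMALS.items():
            if col in df.columns:
                df[col] = df[col].round(nd)
    return df
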