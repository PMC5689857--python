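import numpy as np
import pytest

from sobpkit import (
    PristinePeakParams,
    PulseTrain,
    build_step_peak_library,
    equalize_step_fluence,
    fit_weights,
    flat_target,
    map_pulses_to_steps,
    stop_pulse_curve,
    uniform_wheel,
)


@pytest.fixture(scope="session")
def lib14():
    """14-step library, 0.7 cm pullback pitch, sigma 0.15 — pitch is more
    than 3 sigma, so fitted weights are individually identifiable."""
    wheel = uniform_wheel(n_steps=14, pullback_per_step=0.7)
    base = PristinePeakParams(range_d90=25.0, distal_spread_sigma=0.15)
    return build_step_peak_library(wheel, base)


@pytest.fixture(scope="session")
def sweep_rig():
    """Full stop-pulse rig: 57 material steps + blocked wedge spanning
    20 cm of pullback, a precessing pulse train (~51 pulses/rotation over
    5 rotations), equalized pulse weights, flat-SOBP step weights, and
    the tabulated stop-pulse curve."""
    r, m, sigma = 25.0, 20.0, 0.3
    n = 58
    wheel = uniform_wheel(
        n_steps=n, pullback_per_step=m / (n - 2), blocked_last=True
    )
    lib = build_step_peak_library(
        wheel,
        PristinePeakParams(range_d90=r, distal_spread_sigma=sigma),
    )
    fmap = map_pulses_to_steps(
        wheel, PulseTrain(period=0.00199, pulse_angular_width=6.0), rotations=5
    )
    pw = equalize_step_fluence(fmap)
    taper = 3.3 * sigma
    target = flat_target(
        r, m, grid=np.array(lib.depths), distal_taper=taper, proximal_taper=1.6
    )
    fit = fit_weights(lib, target, window=(r - m, r + taper))
    curve = stop_pulse_curve(lib, fmap, pw, step_weights=fit.weights)
    return {
        "wheel": wheel,
        "lib": lib,
        "fmap": fmap,
        "pulse_weights": pw,
        "step_weights": fit.weights,
        "curve": curve,
        "range": r,
        "modulation": m,
    }
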