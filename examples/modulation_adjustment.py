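"""Shrink the modulation width of an SOBP with the stop-pulse procedure.

The pulsed beam puts ~50 pulses on each wheel rotation.  Removing pulses
shallowest-peak-first tabulates SOBP width versus stop-pulse count; a
request between tabulated widths is met by linearly interpolating a
fractional stop pulse that scales a single pulse's fluence.
"""

import numpy as np

from sobpkit import (
    PristinePeakParams,
    PulseTrain,
    adjust_modulation,
    build_step_peak_library,
    equalize_step_fluence,
    fit_weights,
    flat_target,
    map_pulses_to_steps,
    stop_pulse_curve,
    uniform_wheel,
)

r, m, sigma = 25.0, 20.0, 0.3
wheel = uniform_wheel(n_steps=58, pullback_per_step=m / 56, blocked_last=True)
lib = build_step_peak_library(
    wheel, PristinePeakParams(range_d90=r, distal_spread_sigma=sigma)
)
fmap = map_pulses_to_steps(
    wheel, PulseTrain(period=0.00199, pulse_angular_width=6.0), rotations=5
)
pulse_w = equalize_step_fluence(fmap)  # 3e6 protons per step, like the BCM
target = flat_target(r, m, grid=np.array(lib.depths),
                     distal_taper=3.3 * sigma, proximal_taper=1.6)
step_w = fit_weights(lib, target, window=(r - m, r + 3.3 * sigma)).weights
curve = stop_pulse_curve(lib, fmap, pulse_w, step_weights=step_w)

print(f"pulses mapped      : {fmap.n_pulses} over {fmap.rotations} rotations")
print(f"fully modulated    : {curve.max_width:.2f} cm")
for desired in (15.0, 10.0, 5.0):
    adj = adjust_modulation(curve, desired, lib, fmap, pulse_w, step_weights=step_w)
    print(f"request {desired:5.1f} cm -> stop pulse {adj.fractional_stop_pulse:7.2f}, "
          f"achieved {adj.achieved_width:.2f} cm")
print("\nthe fractional stop pulse says how many pulses (and what fraction "
      "of the last one) the beam current modulation cuts per rotation.")
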