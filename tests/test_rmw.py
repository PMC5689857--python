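"""Pulse-to-step mapping, fluence equalization and peak libraries."""

import numpy as np
import pytest

from sobpkit import (
    PristinePeakParams,
    PulseTrain,
    RMW,
    RMWError,
    RMWStep,
    build_step_peak_library,
    depth_at_level,
    equalize_step_fluence,
    map_pulses_to_steps,
    uniform_wheel,
)


def two_step_wheel():
    return RMW(
        steps=(
            RMWStep(index=0, angle_start=0.0, angle_width=180.0, pullback=0.0),
            RMWStep(index=1, angle_start=180.0, angle_width=180.0, pullback=1.0),
        )
    )


class TestWheelValidation:
    def test_nonzero_first_pullback_rejected(self):
        with pytest.raises(RMWError):
            RMW(steps=(RMWStep(index=0, angle_start=0, angle_width=360, pullback=1.0),))

    def test_overlapping_sectors_rejected(self):
        with pytest.raises(RMWError, match="overlap"):
            RMW(
                steps=(
                    RMWStep(index=0, angle_start=0, angle_width=200, pullback=0.0),
                    RMWStep(index=1, angle_start=180, angle_width=140, pullback=1.0),
                )
            )

    def test_decreasing_pullback_rejected(self):
        with pytest.raises(RMWError, match="non-decreasing"):
            RMW(
                steps=(
                    RMWStep(index=0, angle_start=0, angle_width=100, pullback=0.0),
                    RMWStep(index=1, angle_start=100, angle_width=100, pullback=2.0),
                    RMWStep(index=2, angle_start=200, angle_width=100, pullback=1.0),
                )
            )


class TestPulseMapping:
    def test_fifty_pulses_per_rotation(self):
        """600 rpm with a 2 ms pulse period puts exactly 50 pulses on one
        wheel rotation."""
        train = PulseTrain(period=0.002)
        assert train.pulses_per_rotation(600.0) == 50
        fmap = map_pulses_to_steps(uniform_wheel(), train, rotations=1)
        assert fmap.n_pulses == 50

    def test_single_step_wheel_collects_everything(self):
        wheel = RMW(
            steps=(RMWStep(index=0, angle_start=0, angle_width=360, pullback=0.0),)
        )
        fmap = map_pulses_to_steps(wheel, PulseTrain(period=0.002), rotations=1)
        assert fmap.totals[0] == pytest.approx(50.0)

    def test_quarter_rotation_period_landing_sequence(self):
        """Four point pulses at quarter-rotation spacing land at 0, 90,
        180 and 270 degrees: the first two on the front step, the last
        two on the back step."""
        fmap = map_pulses_to_steps(
            two_step_wheel(), PulseTrain(period=0.025), rotations=1
        )
        assert fmap.n_pulses == 4
        assert fmap.landing_step == [0, 0, 1, 1]

    def test_boundary_pulse_splits_half_and_half(self):
        wheel = two_step_wheel()
        train = PulseTrain(period=0.05, phase=180.0, pulse_angular_width=10.0)
        fmap = map_pulses_to_steps(wheel, train, rotations=1)
        assert dict(fmap.pulse_fractions[0]) == pytest.approx({0: 0.5, 1: 0.5})

    def test_gap_in_wheel_rejected(self):
        wheel = RMW(
            steps=(RMWStep(index=0, angle_start=0, angle_width=300, pullback=0.0),)
        )
        with pytest.raises(RMWError, match="gap"):
            map_pulses_to_steps(wheel, PulseTrain(period=0.002), rotations=1)

    def test_fluence_conservation(self):
        """Total fractional fluence equals the number of pulses landing on
        unblocked material."""
        wheel = uniform_wheel(n_steps=10, pullback_per_step=0.5, blocked_last=True)
        train = PulseTrain(period=0.00213, pulse_angular_width=5.0)
        fmap = map_pulses_to_steps(wheel, train, rotations=3)
        total = sum(fmap.totals.values())
        blocked_share = sum(
            1.0 - sum(f for _, f in contribs) for contribs in fmap.pulse_fractions
        )
        assert total + blocked_share == pytest.approx(fmap.n_pulses, abs=1e-9)

    def test_rotation_periodicity(self):
        wheel = uniform_wheel(n_steps=8, pullback_per_step=0.5)
        train = PulseTrain(period=0.002, pulse_angular_width=4.0)
        one = map_pulses_to_steps(wheel, train, rotations=1)
        four = map_pulses_to_steps(wheel, train, rotations=4)
        for s in one.totals:
            assert four.totals[s] == pytest.approx(4.0 * one.totals[s], abs=1e-9)

    def test_edge_split_continuity(self):
        """As a finite pulse footprint crosses a step boundary its two
        fractions vary continuously and always sum to one."""
        wheel = two_step_wheel()
        prev = None
        for phase in np.arange(172.0, 188.0, 0.25):
            train = PulseTrain(period=0.05, phase=float(phase), pulse_angular_width=10.0)
            fmap = map_pulses_to_steps(wheel, train, rotations=1)
            f = dict(fmap.pulse_fractions[0])
            f0 = f.get(0, 0.0)
            assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)
            if prev is not None:
                assert abs(f0 - prev) <= 0.25 / 10.0 + 1e-9
            prev = f0


class TestEqualization:
    def test_unequal_pulse_counts_rebalanced(self):
        """Two pulses on one step and five on the other: per-pulse weights
        are in ratio 5:2 and both step totals equal the proton budget."""
        steps = (
            RMWStep(index=0, angle_start=0.0, angle_width=2 / 7 * 360, pullback=0.0),
            RMWStep(index=1, angle_start=2 / 7 * 360, angle_width=5 / 7 * 360, pullback=1.0),
        )
        wheel = RMW(steps=steps)
        # 7 pulses equally spaced: 2 land on step 0, 5 on step 1
        fmap = map_pulses_to_steps(wheel, PulseTrain(period=0.1 / 7), rotations=1)
        assert fmap.totals == pytest.approx({0: 2.0, 1: 5.0})
        pw = equalize_step_fluence(fmap, protons_per_step=3e6)
        w_a = pw.weights[fmap.landing_step.index(0)]
        w_b = pw.weights[fmap.landing_step.index(1)]
        assert w_a / w_b == pytest.approx(2.5)
        assert pw.step_totals(fmap) == pytest.approx({0: 3e6, 1: 3e6})

    def test_equal_pulse_counts_equal_weights(self):
        wheel = uniform_wheel(n_steps=5, pullback_per_step=0.5)
        fmap = map_pulses_to_steps(wheel, PulseTrain(period=0.1 / 5), rotations=1)
        pw = equalize_step_fluence(fmap)
        assert np.ptp(pw.weights) == pytest.approx(0.0, abs=1e-9)

    def test_randomized_split_pulses_equalize(self):
        """With boundary-splitting pulses the solved weights still give
        every step the same proton total to high relative precision."""
        wheel = uniform_wheel(n_steps=11, pullback_per_step=0.4)
        train = PulseTrain(period=0.00197, pulse_angular_width=9.0, phase=13.0)
        fmap = map_pulses_to_steps(wheel, train, rotations=4)
        pw = equalize_step_fluence(fmap, protons_per_step=3e6)
        for total in pw.step_totals(fmap).values():
            assert total == pytest.approx(3e6, rel=1e-6)

    def test_unhit_step_warned_and_excluded(self):
        # 4 pulses on an 8-sector wheel leave half the steps unhit
        wheel = uniform_wheel(n_steps=8, pullback_per_step=0.5)
        fmap = map_pulses_to_steps(wheel, PulseTrain(period=0.025), rotations=1)
        with pytest.warns(UserWarning, match="no pulse fluence"):
            pw = equalize_step_fluence(fmap)
        assert len(pw.excluded_steps) == 4


class TestPeakLibrary:
    def test_pullback_shifts_ranges(self):
        steps = tuple(
            RMWStep(index=i, angle_start=120.0 * i, angle_width=120.0, pullback=0.5 * i)
            for i in range(3)
        )
        lib = build_step_peak_library(
            RMW(steps=steps), PristinePeakParams(range_d90=25.0, distal_spread_sigma=0.15)
        )
        d90s = [depth_at_level(p, 90.0, "distal") for p in lib.peaks]
        assert d90s == pytest.approx([25.0, 24.5, 24.0], abs=0.02)

    def test_blocked_step_excluded(self, lib14):
        wheel = uniform_wheel(n_steps=14, pullback_per_step=0.7, blocked_last=True)
        lib = build_step_peak_library(
            wheel, PristinePeakParams(range_d90=25.0, distal_spread_sigma=0.15)
        )
        assert len(lib) == 13
        assert 13 not in lib.step_indices

    def test_fourteen_step_shallowest_range(self):
        """A 14-step wheel with uniform 0.7 cm pullback from a 20 cm base
        reaches 20 - 13*0.7 = 10.9 cm at the shallowest step."""
        wheel = uniform_wheel(n_steps=14, pullback_per_step=0.7)
        lib = build_step_peak_library(
            wheel, PristinePeakParams(range_d90=20.0, distal_spread_sigma=0.15)
        )
        shallowest = depth_at_level(lib.peaks[-1], 90.0, "distal")
        assert shallowest == pytest.approx(10.9, abs=0.05)

    def test_excessive_pullback_rejected(self):
        wheel = uniform_wheel(n_steps=14, pullback_per_step=1.0)
        with pytest.raises(RMWError, match="pullback"):
            build_step_peak_library(wheel, PristinePeakParams(range_d90=10.0))
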