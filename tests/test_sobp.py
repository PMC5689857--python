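"""SOBP composition, weight fitting and stop-pulse width adjustment."""

import numpy as np
import pytest

from sobpkit import (
    PristinePeakSet,
    SOBPError,
    adjust_modulation,
    compose_sobp,
    fit_weights,
    flat_target,
    pdd_metrics,
    plateau_flatness,
    stop_pulse_curve,
    synthesize_sobp,
)


class TestCompose:
    def test_single_peak_identity(self, lib14):
        single = PristinePeakSet(
            peaks=[lib14.peaks[0]], pullbacks=[0.0], step_indices=[0]
        )
        out = compose_sobp(single, [1.0])
        np.testing.assert_allclose(out.dose, lib14.peaks[0].dose, atol=1e-12)

    def test_linearity(self, lib14):
        rng = np.random.default_rng(1)
        wa = rng.uniform(0, 2, len(lib14))
        wb = rng.uniform(0, 2, len(lib14))
        lhs = compose_sobp(lib14, wa).dose + compose_sobp(lib14, wb).dose
        rhs = compose_sobp(lib14, wa + wb).dose
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_negative_weights_rejected(self, lib14):
        w = np.ones(len(lib14))
        w[3] = -0.1
        with pytest.raises(SOBPError, match="non-negative"):
            compose_sobp(lib14, w)

    def test_grid_mismatch_rejected(self, lib14):
        from sobpkit import DepthDoseCurve

        other = DepthDoseCurve(
            lib14.depths[:-1] + 0.05, lib14.peaks[0].dose[:-1]
        )
        with pytest.raises(Exception):
            PristinePeakSet(
                peaks=[lib14.peaks[0], other],
                pullbacks=[0.0, 0.7],
                step_indices=[0, 1],
            )


class TestFlatTarget:
    def test_plateau_span(self):
        t = flat_target(25.0, 20.0)
        sel = (t.depths >= 5.0) & (t.depths <= 24.9)
        assert np.all(t.dose[sel] == 100.0)
        assert pdd_metrics(t).d90 == pytest.approx(25.0, abs=1e-6)

    def test_full_modulation_starts_at_surface(self):
        t = flat_target(15.3, 15.3)
        assert t.dose[0] == 100.0

    def test_own_width_metric(self):
        t = flat_target(25.0, 20.0)
        assert pdd_metrics(t).sobp_width == pytest.approx(20.0, abs=0.15)

    def test_modulation_beyond_range_rejected(self):
        with pytest.raises(SOBPError):
            flat_target(10.0, 12.0)


class TestFitWeights:
    def test_recovers_known_weights(self, lib14):
        """A curve composed from known positive weights is recovered: the
        refit reproduces the curve to 0.1% of plateau and, because the
        pullback pitch exceeds 3 sigma, the weights themselves."""
        rng = np.random.default_rng(7)
        w_true = rng.uniform(0.5, 2.0, len(lib14))
        target = compose_sobp(lib14, w_true)
        fit = fit_weights(lib14, target)
        plateau = float(np.max(target.dose))
        recomposed = compose_sobp(lib14, fit.weights)
        assert np.max(np.abs(recomposed.dose - target.dose)) <= 1e-3 * plateau
        assert fit.sse <= 1e-6 * plateau**2
        np.testing.assert_allclose(fit.weights, w_true, rtol=1e-3)

    def test_single_peak_target(self, lib14):
        target = lib14.peaks[5].copy()
        fit = fit_weights(lib14, target)
        assert fit.weights[5] == pytest.approx(1.0, abs=1e-6)
        others = np.delete(fit.weights, 5)
        assert np.max(others) <= 1e-6
        assert fit.sse <= 1e-12

    def test_beats_random_candidates(self, lib14):
        """Convexity check: the NNLS solution's SSE is no worse than a
        thousand random non-negative candidate weight vectors."""
        target = flat_target(25.0, 8.0, grid=np.array(lib14.depths))
        fit = fit_weights(lib14, target, window=(17.0, 25.3))
        lattice = 17.0 + 0.1 * np.arange(fit.n_points)
        A = np.column_stack(
            [np.interp(lattice, lib14.depths, p.dose) for p in lib14.peaks]
        )
        b = np.interp(lattice, target.depths, target.dose)
        rng = np.random.default_rng(11)
        scale = np.max(fit.weights)
        for _ in range(1000):
            w = rng.uniform(0, 2 * scale, len(lib14))
            assert np.sum((A @ w - b) ** 2) >= fit.sse - 1e-9

    def test_deterministic(self, lib14):
        target = flat_target(25.0, 8.0, grid=np.array(lib14.depths))
        f1 = fit_weights(lib14, target)
        f2 = fit_weights(lib14, target)
        np.testing.assert_array_equal(f1.weights, f2.weights)
        assert f1.sse == f2.sse

    def test_scale_invariance(self, lib14):
        target = flat_target(25.0, 8.0, grid=np.array(lib14.depths))
        f1 = fit_weights(lib14, target)
        f3 = fit_weights(lib14, target.with_dose(3.0 * target.dose))
        np.testing.assert_allclose(f3.weights, 3.0 * f1.weights, rtol=1e-9, atol=1e-12)
        assert f3.sse == pytest.approx(9.0 * f1.sse, rel=1e-6, abs=1e-12)

    def test_zero_target_gives_zero_weights(self, lib14):
        target = flat_target(25.0, 8.0, grid=np.array(lib14.depths)).with_dose(
            np.zeros(lib14.depths.size)
        )
        fit = fit_weights(lib14, target)
        assert np.all(fit.weights == 0.0)
        assert fit.sse == 0.0

    def test_underdetermined_window_rejected(self, lib14):
        target = flat_target(25.0, 8.0, grid=np.array(lib14.depths))
        with pytest.raises(SOBPError, match="lattice"):
            fit_weights(lib14, target, window=(24.0, 25.0))

    def test_n_points_lattice_convention(self, lib14):
        target = flat_target(25.0, 8.0, grid=np.array(lib14.depths))
        fit = fit_weights(lib14, target, window=(5.0, 25.0))
        assert fit.n_points == 201


class TestSynthesis:
    @pytest.mark.parametrize(
        "range_d90,modulation", [(25.0, 20.0), (32.0, 10.0), (15.3, 15.3)]
    )
    def test_flat_sobp_quality(self, range_d90, modulation):
        """End-to-end synthesis: plateau flat to 1% and modulation width
        on target for the three reference (range, modulation) cases."""
        res = synthesize_sobp(range_d90, modulation)
        flat = plateau_flatness(
            res.sobp, range_d90 - modulation + 0.5, range_d90 - 0.5
        )
        m = pdd_metrics(res.sobp)
        assert flat <= 1.0
        assert m.sobp_width == pytest.approx(modulation, abs=0.15)
        assert m.d90 == pytest.approx(range_d90, abs=0.1)


class TestStopPulse:
    def test_entry_zero_is_full_modulation(self, sweep_rig):
        curve = sweep_rig["curve"]
        assert curve.entries[0][0] == 0
        assert curve.max_width == pytest.approx(sweep_rig["modulation"], abs=0.15)

    def test_monotone_non_increasing(self, sweep_rig):
        widths = sweep_rig["curve"].widths
        assert np.all(np.diff(widths) <= 1e-12)

    def test_removing_thickest_step_pulses_shrinks_width(self, sweep_rig):
        """Draining the shallowest peaks pulls the proximal edge deeper."""
        curve = sweep_rig["curve"]
        lib = sweep_rig["lib"]
        fmap = sweep_rig["fmap"]
        pb = dict(zip(lib.step_indices, lib.pullbacks))
        sw = dict(zip(lib.step_indices, sweep_rig["step_weights"]))
        # thickest step whose peak actually carries weight in the SOBP
        target_pb = max(
            pb[s] for s in lib.step_indices if sw[s] > 1e-9
        )
        n_removed = sum(
            1
            for k in curve.removal_order
            if pb[fmap.landing_step[k]] >= target_pb
        )
        assert curve.widths[n_removed] < curve.widths[0]

    def test_removal_order_is_shallowest_first(self, sweep_rig):
        curve = sweep_rig["curve"]
        fmap = sweep_rig["fmap"]
        lib = sweep_rig["lib"]
        pb = dict(zip(lib.step_indices, lib.pullbacks))
        order_pb = [pb[fmap.landing_step[k]] for k in curve.removal_order]
        assert np.all(np.diff(order_pb) <= 1e-12)

    def test_final_width_near_single_step(self, sweep_rig):
        """By the end of the curve the plateau has shrunk to the scale of
        one pullback step."""
        pitch = float(np.diff(sweep_rig["lib"].pullbacks).max())
        assert sweep_rig["curve"].min_width <= 2.0 * pitch


class TestAdjustModulation:
    def test_tabulated_width_exact(self, sweep_rig):
        curve = sweep_rig["curve"]
        k, width = curve.entries[10]
        adj = adjust_modulation(
            curve,
            width,
            sweep_rig["lib"],
            sweep_rig["fmap"],
            sweep_rig["pulse_weights"],
            step_weights=sweep_rig["step_weights"],
        )
        assert adj.fractional_stop_pulse == k
        assert adj.achieved_width == pytest.approx(width, abs=1e-9)

    def test_halfway_request_gives_half_fraction(self, sweep_rig):
        curve = sweep_rig["curve"]
        widths = curve.widths
        gaps = -np.diff(widths)
        i = int(np.argmax(gaps))  # a bracket with a clear width change
        desired = 0.5 * (widths[i] + widths[i + 1])
        adj = adjust_modulation(
            curve,
            float(desired),
            sweep_rig["lib"],
            sweep_rig["fmap"],
            sweep_rig["pulse_weights"],
            step_weights=sweep_rig["step_weights"],
        )
        frac = adj.fractional_stop_pulse - curve.entries[i][0]
        assert frac == pytest.approx(0.5, abs=1e-9)

    def test_idempotent_at_tabulated_width(self, sweep_rig):
        curve = sweep_rig["curve"]
        _, width = curve.entries[25]
        kwargs = dict(
            peaks=sweep_rig["lib"],
            fmap=sweep_rig["fmap"],
            pulse_weights=sweep_rig["pulse_weights"],
            step_weights=sweep_rig["step_weights"],
        )
        a = adjust_modulation(curve, width, kwargs["peaks"], kwargs["fmap"],
                              kwargs["pulse_weights"], step_weights=kwargs["step_weights"])
        b = adjust_modulation(curve, a.achieved_width, kwargs["peaks"], kwargs["fmap"],
                              kwargs["pulse_weights"], step_weights=kwargs["step_weights"])
        np.testing.assert_allclose(b.weights, a.weights, atol=1e-9)

    def test_out_of_range_names_interval(self, sweep_rig):
        curve = sweep_rig["curve"]
        with pytest.raises(SOBPError, match="achievable"):
            adjust_modulation(
                curve,
                curve.max_width + 5.0,
                sweep_rig["lib"],
                sweep_rig["fmap"],
                sweep_rig["pulse_weights"],
                step_weights=sweep_rig["step_weights"],
            )

    def test_sweep_accuracy_sample(self, sweep_rig):
        """Requested widths between 5 and 18 cm are achieved within the
        machine's 0.1 cm granularity."""
        for desired in np.arange(5.0, 18.0, 1.3):
            adj = adjust_modulation(
                sweep_rig["curve"],
                float(desired),
                sweep_rig["lib"],
                sweep_rig["fmap"],
                sweep_rig["pulse_weights"],
                step_weights=sweep_rig["step_weights"],
            )
            assert adj.achieved_width == pytest.approx(desired, abs=0.1)
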