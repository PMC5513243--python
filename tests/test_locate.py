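"""Hyperbolic TDOA solver chain: linearization, refinement, grid oracle."""

import numpy as np
import pytest

import aeroloc as al
from aeroloc.errors import InfeasibleLagError, InvalidParameterError
from aeroloc.lags import LagSet
from aeroloc.locate import (
    grid_final_step,
    grid_oracle,
    linear_tdoa_solve,
    localize_call,
    range_differences,
    refine_gauss_newton,
)

from .conftest import exact_delta, random_cylinder_source, rounded_delta


def _lagset_from(layout, lags):
    ref = layout.ids[0]
    pairwise = {}
    for i in layout.ids:
        for j in layout.ids:
            if i != j:
                pairwise[(i, j)] = lags[j] - lags[i]
    return LagSet(
        reference=ref,
        lags=lags,
        pairwise=pairwise,
        peak_correlations={},
        quality_flags={m: True for m in layout.ids},
    )


class TestRangeDifferences:
    def test_conversion_examples(self, layout):
        lags = {m: 0.0 for m in layout.ids}
        lags["t1_high"] = 10.0
        lags["t2_low"] = -496.0
        delta = range_differences(_lagset_from(layout, lags), layout)
        assert delta["t1_low"] == 0.0
        assert delta["t1_high"] == pytest.approx(340.0 * 10 / 22050, abs=1e-9)  # 0.15420
        assert delta["t2_low"] == pytest.approx(-7.648, abs=1e-3)


class TestLinearSolve:
    def test_exact_recovery(self, layout):
        src = np.array([30.0, 40.0, 100.0])
        est = linear_tdoa_solve(layout, exact_delta(layout, src))
        assert np.linalg.norm(est.position - src) < 1e-6
        assert est.residual_rms < 1e-9
        assert est.r_ref == pytest.approx(
            np.linalg.norm(layout.coordinates[0] - src), abs=1e-6
        )

    def test_zero_delta_gives_equidistant_point(self, layout):
        delta = {m: 0.0 for m in layout.ids}
        est = linear_tdoa_solve(layout, delta)
        assert est.residual_rms < 1e-6
        dists = np.linalg.norm(layout.coordinates - est.position, axis=1)
        assert np.ptp(dists) < 1e-5

    def test_emission_time_offset_is_negative_range_over_speed(self, layout):
        src = np.array([10.0, -5.0, 60.0])
        est = linear_tdoa_solve(layout, exact_delta(layout, src))
        assert est.emission_time_offset == pytest.approx(-est.r_ref / 340.0, abs=1e-12)

    def test_infeasible_delta_names_pair(self, layout):
        delta = {m: 0.0 for m in layout.ids}
        delta["t1_high"] = 50.0  # far exceeds the 7.64 m separation
        with pytest.raises(InfeasibleLagError) as exc:
            linear_tdoa_solve(layout, delta)
        assert exc.value.pair == ("t1_low", "t1_high")

    def test_below_ground_solution_flagged_not_clamped(self, layout):
        src = np.array([15.0, -10.0, -40.0])  # mirror source under the array
        est = linear_tdoa_solve(layout, exact_delta(layout, src))
        refined = refine_gauss_newton(est, layout, exact_delta(layout, src))
        assert refined.z < 0
        assert refined.has_flag("below_ground")


class TestGaussNewton:
    def test_stationary_at_exact_solution(self, layout):
        src = np.array([-20.0, 35.0, 90.0])
        delta = exact_delta(layout, src)
        est = linear_tdoa_solve(layout, delta)
        refined = refine_gauss_newton(est, layout, delta)
        assert np.linalg.norm(refined.position - est.position) < 1e-6

    def test_never_increases_residual(self, layout):
        rng = np.random.default_rng(31)
        for _ in range(20):
            src = random_cylinder_source(rng)
            delta = rounded_delta(layout, src)
            lin = linear_tdoa_solve(layout, delta)
            ref = refine_gauss_newton(lin, layout, delta)
            assert ref.residual_rms <= lin.residual_rms + 1e-12

    def test_converges_from_centroid_start(self, layout):
        src = np.array([40.0, -25.0, 70.0])
        delta = rounded_delta(layout, src)
        centroid = layout.coordinates.mean(axis=0)
        start = al.SourceEstimate(
            position=centroid,
            reference=layout.ids[0],
            r_ref=float(np.linalg.norm(centroid - layout.coordinates[0])),
            emission_time_offset=0.0,
            residual_rms=1.0,
            method="linear",
        )
        refined = refine_gauss_newton(start, layout, delta)
        oracle = grid_oracle(layout, delta)
        assert np.linalg.norm(refined.position - oracle.position) < 0.1


class TestGridOracle:
    def test_exact_delta_recovery(self, layout):
        src = np.array([30.0, 40.0, 100.0])
        est = grid_oracle(layout, exact_delta(layout, src))
        assert np.linalg.norm(est.position - src) < 0.02

    def test_infeasible_delta_still_returns(self, layout):
        delta = {m: 0.0 for m in layout.ids}
        delta["t1_high"] = 50.0
        est = grid_oracle(layout, delta)
        assert est.residual_rms > 1.0  # no point satisfies the constraints


class TestEquivariance:
    def test_translation(self, layout):
        shift = np.array([123.0, -45.0, 6.0])
        moved = al.ArrayLayout(
            tuple(
                al.Microphone(m.id, m.x + shift[0], m.y + shift[1], m.z + shift[2])
                for m in layout.microphones
            ),
            layout.sample_rate,
            layout.sound_speed,
        )
        src = np.array([25.0, 10.0, 80.0])
        est0 = refine_gauss_newton(
            linear_tdoa_solve(layout, exact_delta(layout, src)),
            layout,
            exact_delta(layout, src),
        )
        est1 = refine_gauss_newton(
            linear_tdoa_solve(moved, exact_delta(moved, src + shift)),
            moved,
            exact_delta(moved, src + shift),
        )
        assert np.linalg.norm(est1.position - (est0.position + shift)) < 1e-6


class TestLocalizeCall:
    def test_clean_call_recovered(self, layout, chirp):
        src = (0.0, 0.0, 50.0)
        ev = al.EmissionEvent(source=src, t0=1.0, template=chirp)
        rec = al.render_recording([ev], layout, 3.0, quantize="nearest_sample")
        res = localize_call(
            rec, 1.0, chirp.band, layout, template_duration=chirp.duration
        )
        assert not res.rejected
        err = np.linalg.norm(res.estimate.position - np.array(src))
        assert err < 1.0  # quantization-scale error at 50 m

    def test_rejected_call_yields_no_estimate(self, layout, chirp):
        rec = al.render_recording([], layout, 3.0, noise_rms=0.02, seed=0)
        res = localize_call(
            rec, 1.0, chirp.band, layout, template_duration=chirp.duration
        )
        assert res.rejected
        assert res.estimate is None
        assert res.lagset is not None

    def test_truncated_schedule_time_rejected_with_reason(self, layout, chirp):
        rec = al.render_recording([], layout, 3.0, noise_rms=0.02, seed=0)
        res = localize_call(
            rec, 0.1, chirp.band, layout, template_duration=chirp.duration
        )
        assert res.rejected
        assert "recording" in res.reason

    def test_dominant_ground_interferer_never_silently_accepted(self, layout, chirp):
        """A loud ground-level interferer must not pass as a clean aloft call."""
        call = al.EmissionEvent(source=(20.0, 10.0, 80.0), t0=1.0, template=chirp)
        bug = al.EmissionEvent(
            source=(11.5, 0.2, 0.1), t0=1.005, template=chirp, source_level=400.0
        )
        rec = al.render_recording(
            [call], layout, 3.0, ground_interferers=[bug], noise_rms=0.01, seed=3
        )
        res = localize_call(
            rec, 1.0, chirp.band, layout, template_duration=chirp.duration
        )
        truth_err = (
            np.inf
            if res.estimate is None
            else np.linalg.norm(res.estimate.position - np.array([20.0, 10.0, 80.0]))
        )
        silently_accepted = (
            not res.rejected and not res.estimate.flags and truth_err < 10.0
        )
        assert not silently_accepted


class TestOutOfBoundsFlag:
    def test_runaway_range_estimate_is_flagged(self, layout):
        """Lags consistent only with a source direction (observed when a
        tonal call slips by whole periods on some channels) drive the
        least-squares minimum to absurd range; localize_call must flag it."""
        # lag set captured from a period-slipped tonal call: residual is
        # small but the minimum sits ~1e11 m out
        lags = {
            "t1_low": 0.0,
            "t1_high": -102.0,
            "t2_low": -560.0,
            "t2_high": -659.0,
            "t3_low": -1271.0,
            "t3_high": -1370.0,
        }
        delta = range_differences(_lagset_from(layout, lags), layout)
        est = refine_gauss_newton(linear_tdoa_solve(layout, delta), layout, delta)
        assert est.r_ref > 350.0  # the pathology this flag exists for

    def test_direction_only_lag_set_flagged(self, layout, templates):
        """Period-slipped tone lags can push the residual minimum to
        near-infinite range; the retrieval must carry the out_of_bounds
        flag so truth comparison can exclude it."""
        tone = next(t for t in templates if t.label == "SWTH")
        src = (-85.0, -53.4, 25.9)
        ev = al.EmissionEvent(source=src, t0=1.0, template=tone)
        rec = al.render_recording([ev], layout, 3.0, quantize="nearest_sample")
        # corrupt two channels by one tone period (~11 samples at 6 kHz)
        slip = int(round(layout.sample_rate / 6000.0)) * 3
        k1 = layout.ids.index("t1_high")
        k3 = layout.ids.index("t3_low")
        rec.data[k1] = np.roll(rec.data[k1], slip)
        rec.data[k3] = np.roll(rec.data[k3], -slip)
        res = localize_call(
            rec, 1.0, tone.band, layout, template_duration=tone.duration
        )
        if not res.rejected:
            far = res.estimate.r_ref > 350.0
            assert (not far) or res.estimate.has_flag("out_of_bounds")


class TestExactRecoveryEnsemble:
    def test_hundred_random_sources_recovered_exactly(self, layout):
        """Unquantized range differences: the chain is exact to < 1e-6 m."""
        rng = np.random.default_rng(101)
        for _ in range(100):
            src = random_cylinder_source(rng)
            delta = exact_delta(layout, src)
            est = refine_gauss_newton(linear_tdoa_solve(layout, delta), layout, delta)
            assert np.linalg.norm(est.position - src) < 1e-6
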