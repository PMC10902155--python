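import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noseflow.forcing import ForcingMode, ForcingSpec, percent_change
from noseflow.lumped import (
    AirwayNetwork,
    CalibrationSpec,
    SegmentLaw,
    apply_virtual_surgery,
    branch_split,
    calibrate,
    closed_form_single_segment,
    cpi_relaxed_iteration,
    dp_of_Q,
    lateral_resistances,
    solve_steady,
)

REF_Q0 = 2.67e-4
REF_DP0 = 24.45
# frozen oracle: b = dp0 / Q0^2 for the pure quadratic calibration
PURE_QUADRATIC_B = REF_DP0 / REF_Q0**2  # = 3.4297...e8 Pa s^2/m^6


def quadratic_segment_network():
    return AirwayNetwork.single_segment(0.0, PURE_QUADRATIC_B)


class TestSegmentLaw:
    def test_monotone(self):
        seg = SegmentLaw(10.0, 5.0)
        q = np.linspace(0.0, 1.0, 50)
        dp = [seg.dp(x) for x in q]
        assert np.all(np.diff(dp) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            SegmentLaw(-1.0, 0.0)

    def test_zero_branch_rejected_in_network(self):
        z = SegmentLaw(0.0, 0.0)
        with pytest.raises(ValueError):
            AirwayNetwork(left=z, right=SegmentLaw(1.0, 0.0), common=z)


class TestDpOfQ:
    def test_linear_resistors_in_series_parallel(self):
        # identical linear branches a_b in parallel with common a_c: a_c + a_b/2
        a_c, a_b = 3.0, 8.0
        net = AirwayNetwork(
            left=SegmentLaw(a_b, 0.0),
            right=SegmentLaw(a_b, 0.0),
            common=SegmentLaw(a_c, 0.0),
        )
        assert dp_of_Q(net, 1.0) == pytest.approx(a_c + a_b / 2.0, rel=1e-12)

    def test_pure_quadratic_reference(self):
        net = quadratic_segment_network()
        assert PURE_QUADRATIC_B == pytest.approx(3.4297e8, rel=1e-4)
        assert dp_of_Q(net, REF_Q0) == pytest.approx(REF_DP0, rel=1e-12)

    def test_zero_flow_zero_drop(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0))
        assert dp_of_Q(net, 0.0) == 0.0

    def test_asymmetric_split_balances_branch_drops(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0, blend=0.3, split=0.7))
        Q = 4e-4
        q_left = branch_split(net, Q)
        assert 0.0 < q_left < Q
        assert net.left.dp(q_left) == pytest.approx(net.right.dp(Q - q_left), rel=1e-10)


class TestCalibrate:
    def test_reference_point_pure_linear(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0, blend=1.0))
        assert dp_of_Q(net, REF_Q0) == pytest.approx(REF_DP0, rel=1e-10)

    def test_reference_point_pure_quadratic(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0, blend=0.0))
        assert dp_of_Q(net, REF_Q0) == pytest.approx(REF_DP0, rel=1e-10)

    def test_half_blend_single_segment_polynomial(self):
        # degenerate single-segment network: half the drop linear, half quadratic
        lam = 0.5
        net = calibrate(
            CalibrationSpec(REF_Q0, REF_DP0, blend=lam, split=0.5, common_fraction=0.0)
        )
        expected = lam * REF_DP0 / 2.0 + (1.0 - lam) * REF_DP0 / 4.0
        assert dp_of_Q(net, REF_Q0 / 2.0) == pytest.approx(expected, rel=1e-10)

    @settings(max_examples=60, deadline=None)
    @given(
        blend=st.floats(min_value=0.0, max_value=1.0),
        split=st.floats(min_value=0.05, max_value=0.95),
        cf=st.floats(min_value=0.0, max_value=0.9),
    )
    def test_calibration_closure_property(self, blend, split, cf):
        net = calibrate(
            CalibrationSpec(REF_Q0, REF_DP0, blend=blend, split=split, common_fraction=cf)
        )
        assert dp_of_Q(net, REF_Q0) == pytest.approx(REF_DP0, rel=1e-10)


class TestVirtualSurgery:
    def test_identity(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0))
        assert apply_virtual_surgery(net, "right", 1.0) == net

    def test_resistance_decreases(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0, blend=1.0))
        post = apply_virtual_surgery(net, "right", 0.5)
        assert dp_of_Q(post, REF_Q0) < dp_of_Q(net, REF_Q0)

    def test_other_side_untouched(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0))
        post = apply_virtual_surgery(net, "right", 0.3)
        assert post.left == net.left
        assert post.common == net.common

    def test_pure_quadratic_cfr_drop_by_construction(self):
        # factor 0.754 on a quadratic-only law drops the fixed-Q pressure by 24.6%
        net = quadratic_segment_network()
        post = apply_virtual_surgery(net, "both", 0.754)
        change = percent_change(dp_of_Q(net, REF_Q0), dp_of_Q(post, REF_Q0))
        assert change == pytest.approx(-24.6, abs=1e-9)

    def test_bad_factor(self):
        net = quadratic_segment_network()
        with pytest.raises(ValueError):
            apply_virtual_surgery(net, "right", 0.0)
        with pytest.raises(ValueError):
            apply_virtual_surgery(net, "middle", 0.5)


class TestSolveSteady:
    def test_cpi_linear_closed_form(self):
        # linear law: Q = sqrt(P0 / R0)
        R0 = REF_DP0 / REF_Q0  # 9.157e4 Pa s/m3
        net = AirwayNetwork.single_segment(R0, 0.0)
        P0 = REF_Q0 * REF_DP0
        gq = solve_steady(net, ForcingSpec(ForcingMode.CPI, P0))
        assert gq.Q_mean == pytest.approx(np.sqrt(P0 / R0), rel=1e-10)
        assert gq.Q_mean == pytest.approx(REF_Q0, rel=1e-10)

    def test_cpg_quadratic_closed_form(self):
        net = quadratic_segment_network()
        gq = solve_steady(net, ForcingSpec(ForcingMode.CPG, REF_DP0))
        assert gq.Q_mean == pytest.approx(np.sqrt(REF_DP0 / PURE_QUADRATIC_B), rel=1e-10)

    @pytest.mark.parametrize("mode", ["CFR", "CPG", "CPI"])
    @pytest.mark.parametrize("a,b", [(9.157e4, 0.0), (0.0, PURE_QUADRATIC_B), (4.0e4, 1.7e8)])
    def test_single_segment_against_independent_oracle(self, mode, a, b):
        net = AirwayNetwork.single_segment(a, b)
        target = {"CFR": REF_Q0, "CPG": REF_DP0, "CPI": REF_Q0 * REF_DP0}[mode]
        forcing = ForcingSpec(mode, target)
        got = solve_steady(net, forcing)
        oracle = closed_form_single_segment(a, b, forcing)
        assert got.Q_mean == pytest.approx(oracle.Q_mean, rel=1e-10)
        assert got.dp_mean == pytest.approx(oracle.dp_mean, rel=1e-10)

    def test_constraint_residuals(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0, blend=0.3, split=0.65))
        g_cpg = solve_steady(net, ForcingSpec(ForcingMode.CPG, REF_DP0))
        assert g_cpg.dp_mean == pytest.approx(REF_DP0, rel=1e-10)
        g_cpi = solve_steady(net, ForcingSpec(ForcingMode.CPI, 6.5e-3))
        assert g_cpi.P_mean == pytest.approx(6.5e-3, rel=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(
        blend=st.floats(min_value=0.0, max_value=1.0),
        split=st.floats(min_value=0.1, max_value=0.9),
        cf=st.floats(min_value=0.0, max_value=0.8),
    )
    def test_cross_forcing_equivalence_property(self, blend, split, cf):
        # single geometry: the three forcings cross-seeded agree
        net = calibrate(
            CalibrationSpec(REF_Q0, REF_DP0, blend=blend, split=split, common_fraction=cf)
        )
        ref = solve_steady(net, ForcingSpec(ForcingMode.CFR, REF_Q0))
        via_cpg = solve_steady(net, ForcingSpec(ForcingMode.CPG, ref.dp_mean))
        via_cpi = solve_steady(net, ForcingSpec(ForcingMode.CPI, ref.P_mean))
        for other in (via_cpg, via_cpi):
            assert other.Q_mean == pytest.approx(ref.Q_mean, rel=1e-8)
            assert other.dp_mean == pytest.approx(ref.dp_mean, rel=1e-8)
            assert other.P_mean == pytest.approx(ref.P_mean, rel=1e-8)


class TestForcingOrdering:
    def test_pure_quadratic_exponents(self):
        # analytic: post/pre resistance ratios are f, f^(2/3), f^(1/2)
        f = 0.6
        net = quadratic_segment_network()
        post = apply_virtual_surgery(net, "both", f)
        R0 = REF_DP0 / REF_Q0
        triple = {"Q0": REF_Q0, "dp0": REF_DP0, "P0": REF_Q0 * REF_DP0}
        r_cfr = solve_steady(post, ForcingSpec("CFR", triple["Q0"])).R / R0
        r_cpi = solve_steady(post, ForcingSpec("CPI", triple["P0"])).R / R0
        r_cpg = solve_steady(post, ForcingSpec("CPG", triple["dp0"])).R / R0
        assert r_cfr == pytest.approx(f, rel=1e-9)
        assert r_cpi == pytest.approx(f ** (2.0 / 3.0), rel=1e-9)
        assert r_cpg == pytest.approx(f**0.5, rel=1e-9)

    @pytest.mark.parametrize("severity", [0.5, 0.75, 0.9])
    @pytest.mark.parametrize("blend", [0.0, 0.5, 1.0])
    def test_reduction_ordering(self, severity, blend):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0, blend=blend))
        post = apply_virtual_surgery(net, "right", severity)
        ref = solve_steady(net, ForcingSpec(ForcingMode.CFR, REF_Q0))
        red = {}
        for mode, target in (
            ("CFR", ref.Q_mean),
            ("CPG", ref.dp_mean),
            ("CPI", ref.P_mean),
        ):
            gq = solve_steady(post, ForcingSpec(mode, target))
            red[mode] = abs(percent_change(ref.R, gq.R))
        if blend < 1.0:
            assert red["CFR"] > red["CPI"] > red["CPG"]
        else:  # pure linear law: the three forcings coincide
            assert red["CFR"] == pytest.approx(red["CPI"], rel=1e-7)
            assert red["CPI"] == pytest.approx(red["CPG"], rel=1e-7)


class TestLateralResistances:
    def test_symmetric(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0, split=0.5))
        gq = solve_steady(net, ForcingSpec(ForcingMode.CFR, REF_Q0))
        r_left, r_right = lateral_resistances(net, gq)
        assert r_left == pytest.approx(r_right, rel=1e-10)

    def test_operated_side_lower(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0))
        post = apply_virtual_surgery(net, "right", 0.5)
        gq = solve_steady(post, ForcingSpec(ForcingMode.CFR, REF_Q0))
        r_left, r_right = lateral_resistances(post, gq)
        assert r_right < r_left

    def test_linear_branches_exact(self):
        a_left, a_right = 2.0e5, 3.0e5
        net = AirwayNetwork(
            left=SegmentLaw(a_left, 0.0),
            right=SegmentLaw(a_right, 0.0),
            common=SegmentLaw(1.0e4, 0.0),
        )
        gq = solve_steady(net, ForcingSpec(ForcingMode.CFR, REF_Q0))
        r_left, r_right = lateral_resistances(net, gq)
        assert r_left == pytest.approx(a_left, rel=1e-10)
        assert r_right == pytest.approx(a_right, rel=1e-10)

    def test_lateral_change_exceeds_total(self):
        # per-side resistance change is larger than the total-resistance change
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0, blend=0.0))
        post = apply_virtual_surgery(net, "right", 0.6)
        ref = solve_steady(net, ForcingSpec(ForcingMode.CFR, REF_Q0))
        gq = solve_steady(post, ForcingSpec(ForcingMode.CFR, REF_Q0))
        _, r_right_pre = lateral_resistances(net, ref)
        _, r_right_post = lateral_resistances(post, gq)
        total_change = abs(percent_change(ref.R, gq.R))
        lateral_change = abs(percent_change(r_right_pre, r_right_post))
        assert lateral_change > total_change


class TestCpiRelaxedIteration:
    def test_converges_to_direct_fixed_point(self, calibrated_network):
        P0 = 6.5e-3
        direct = solve_steady(calibrated_network, ForcingSpec(ForcingMode.CPI, P0))
        iterated, n_iter = cpi_relaxed_iteration(calibrated_network, P0, relaxation=0.5)
        assert iterated.Q_mean == pytest.approx(direct.Q_mean, rel=1e-8)
        assert iterated.dp_mean == pytest.approx(direct.dp_mean, rel=1e-8)
        assert n_iter < 200

    def test_fixed_point_closes_power(self, calibrated_network):
        gq, _ = cpi_relaxed_iteration(calibrated_network, 6.5e-3)
        assert gq.Q_mean * gq.dp_mean == pytest.approx(6.5e-3, rel=1e-8)


class TestSerialization:
    def test_round_trip(self):
        net = calibrate(CalibrationSpec(REF_Q0, REF_DP0, blend=0.3))
        clone = AirwayNetwork.from_dict(net.to_dict())
        assert clone == net
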