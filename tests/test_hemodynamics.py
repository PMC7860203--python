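"""Friction and minor-loss laws, the network solver and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinusflow import (
    Bend,
    CalibrationError,
    FluidProperties,
    VenousTree,
    VesselSegment,
    bend_loss_coefficient,
    calibrate,
    friction_drop,
    minor_loss_drop,
    poiseuille_resistance,
    reynolds,
    segment_drop,
    solve_tree,
)
from sinusflow.geometry import SEGMENT_NAMES
from sinusflow.hemodynamics import chain_drop, friction_factor
from sinusflow.units import ml_min_to_m3_s, pa_to_mmhg


def _plain_segment(name="seg", L=0.05, D=6e-3, bends=(), extra=()):
    return VesselSegment(name=name, length=L, diameter=D, bends=tuple(bends),
                         extra_loss_coefficients=tuple(extra))


def _uniform_tree(D_left=7e-3, D_right=7e-3, bends=False):
    """Tree with equal lengths; left/right diameters controllable."""
    segs = {}
    for name in SEGMENT_NAMES:
        if name.endswith("-L"):
            d = D_left
        elif name.endswith("-R"):
            d = D_right
        else:
            d = 6e-3
        b = (Bend(90.0, 1.5),) if bends else ()
        segs[name] = VesselSegment(name=name, length=0.05, diameter=d, bends=b)
    return VenousTree(segments=segs, patient_id="uniform")


class TestReynolds:
    def test_zero_flow(self, blood):
        assert reynolds(0.0, 6e-3, blood) == 0.0

    def test_known_value_two_step_oracle(self, blood):
        # independent route: V = Q/A then Re = rho V D / mu
        Q = ml_min_to_m3_s(600.0)
        D = 6e-3
        V = Q / (math.pi * D**2 / 4)
        expected = blood.density * V * D / blood.viscosity
        assert reynolds(Q, D, blood) == pytest.approx(expected, rel=1e-12)
        assert reynolds(Q, D, blood) == pytest.approx(640, rel=0.01)

    def test_linear_in_flow(self, blood):
        assert reynolds(2e-5, 6e-3, blood) == pytest.approx(
            2 * reynolds(1e-5, 6e-3, blood)
        )


class TestPoiseuille:
    def test_closed_form(self):
        L, D, mu = 0.1078, 5.49e-3, 0.0035
        assert poiseuille_resistance(L, D, mu) == pytest.approx(
            128 * mu * L / (math.pi * D**4), rel=1e-14
        )

    def test_d4_scaling(self):
        assert poiseuille_resistance(0.1, 3e-3, 0.0035) == pytest.approx(
            16 * poiseuille_resistance(0.1, 6e-3, 0.0035)
        )

    def test_zero_length(self):
        assert poiseuille_resistance(0.0, 6e-3, 0.0035) == 0.0


class TestFriction:
    @settings(max_examples=100, deadline=None)
    @given(
        L=st.floats(0.01, 0.3),
        D=st.floats(3e-3, 12e-3),
        Q=st.floats(1e-7, 1.5e-5),
    )
    def test_laminar_equals_poiseuille(self, L, D, Q):
        """Algebraic identity: 64/Re * (L/D) * rho V^2/2 = R_pois * Q."""
        blood = FluidProperties()
        if reynolds(Q, D, blood) > 2300:
            return
        seg = _plain_segment(L=L, D=D)
        assert friction_drop(Q, seg, blood) == pytest.approx(
            poiseuille_resistance(L, D, blood.viscosity) * Q, rel=1e-10
        )

    def test_zero_flow(self, blood):
        assert friction_drop(0.0, _plain_segment(), blood) == 0.0

    def test_blasius_regime_direct_evaluation(self, blood):
        D = 6e-3
        Re_target = 5000.0
        Q = Re_target * math.pi * blood.viscosity * D / (4 * blood.density)
        seg = _plain_segment(L=0.05, D=D)
        V = Q / seg.area
        expected = (0.316 * Re_target**-0.25) * (0.05 / D) * blood.density * V**2 / 2
        assert friction_drop(Q, seg, blood) == pytest.approx(expected, rel=1e-9)

    def test_friction_factor_switch_regimes(self):
        assert friction_factor(1000) == pytest.approx(0.064)
        assert friction_factor(5000) == pytest.approx(0.316 * 5000**-0.25)


class TestMinorLosses:
    def test_bend_k_reference_point(self):
        assert bend_loss_coefficient(90.0, 1.0) == pytest.approx(0.290, abs=5e-4)

    def test_bend_k_vanishes_with_angle(self):
        assert bend_loss_coefficient(1e-9, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_bend_k_linear_in_angle(self):
        k45 = bend_loss_coefficient(45.0, 2.0)
        k90 = bend_loss_coefficient(90.0, 2.0)
        assert k90 == pytest.approx(2 * k45)

    def test_minor_loss_definition(self):
        assert minor_loss_drop(1.0, 1.0, 1000.0) == pytest.approx(500.0)
        assert minor_loss_drop(1.0, 0.0, 1000.0) == 0.0

    def test_velocity_squared_scaling(self):
        assert minor_loss_drop(2.0, 2.0, 1055.0) == pytest.approx(
            4 * minor_loss_drop(2.0, 1.0, 1055.0)
        )


class TestSegmentDrop:
    def test_no_bends_is_linear(self, blood):
        seg = _plain_segment()
        d1 = segment_drop(seg, 1e-6, blood)
        d2 = segment_drop(seg, 2e-6, blood)
        assert d2 == pytest.approx(2 * d1, rel=1e-10)

    def test_zero_length_one_bend_is_quadratic(self, blood):
        seg = _plain_segment(L=0.0, bends=[Bend(90.0, 1.5)])
        d1 = segment_drop(seg, 1e-6, blood)
        d2 = segment_drop(seg, 2e-6, blood)
        assert d2 == pytest.approx(4 * d1, rel=1e-10)

    def test_ab_extraction_predicts_third_flow(self, blood):
        """Interpolation oracle: (a, b) from two flows predicts a third."""
        seg = _plain_segment(L=0.08, D=7e-3, bends=[Bend(60.0, 2.0)], extra=[0.4])
        q1, q2, q3 = 2e-6, 6e-6, 4e-6
        d1, d2 = segment_drop(seg, q1, blood), segment_drop(seg, q2, blood)
        A = np.array([[q1, q1**2], [q2, q2**2]])
        a, b = np.linalg.solve(A, [d1, d2])
        assert a >= 0 and b >= 0
        assert segment_drop(seg, q3, blood) == pytest.approx(
            a * q3 + b * q3**2, rel=1e-9
        )


class TestSolveTree:
    def test_symmetric_split(self, blood):
        sol = solve_tree(_uniform_tree(bends=True), ml_min_to_m3_s(800), 0.30, blood)
        assert sol.left_fraction == pytest.approx(0.5, abs=1e-6)

    def test_occluded_branch(self, blood):
        sol = solve_tree(
            _uniform_tree(D_left=5e-4, D_right=8e-3), ml_min_to_m3_s(800), 0.30, blood
        )
        assert sol.left_fraction < 0.01

    def test_linear_network_matches_current_divider(self, blood):
        """Circuit-theory oracle on a friction-only (laminar) network."""
        tree = _uniform_tree(D_left=6e-3, D_right=8e-3)
        Q = ml_min_to_m3_s(400)  # low flow: everything laminar
        sol = solve_tree(tree, Q, 0.30, blood)
        chains = {
            "L": [tree.segments[n] for n in ("TS-L", "PSS-L", "DSS-L", "IJV-L")],
            "R": [tree.segments[n] for n in ("TS-R", "PSS-R", "DSS-R", "IJV-R")],
        }
        R = {
            side: sum(
                poiseuille_resistance(s.length, s.diameter, blood.viscosity)
                for s in chain
            )
            for side, chain in chains.items()
        }
        expected = R["R"] / (R["L"] + R["R"])
        assert sol.left_fraction == pytest.approx(expected, rel=1e-6)
        # series/parallel combination reproduces the system drop
        q_conf = sol.segment_flows["SSS"] + sol.segment_flows["StS"]
        R_sss = poiseuille_resistance(
            tree.segments["SSS"].length, tree.segments["SSS"].diameter,
            blood.viscosity,
        )
        R_par = R["L"] * R["R"] / (R["L"] + R["R"])
        expected_drop = R_sss * sol.segment_flows["SSS"] + R_par * q_conf
        assert sol.system_drop == pytest.approx(expected_drop, rel=1e-9)

    def test_mass_conservation(self, blood, average_tree):
        sol = solve_tree(average_tree, ml_min_to_m3_s(1000), 0.30, blood)
        f = sol.segment_flows
        # torcula: inflows = branch outflows
        assert f["SSS"] + f["StS"] == pytest.approx(
            f["TS-L"] + f["TS-R"], rel=1e-12
        )
        # each chain carries one flow
        for chain in (("TS-L", "PSS-L", "DSS-L", "IJV-L"),
                      ("TS-R", "PSS-R", "DSS-R", "IJV-R")):
            flows = {f[n] for n in chain}
            assert len(flows) == 1

    def test_parallel_paths_equal_drop(self, blood, average_tree):
        tree = _uniform_tree(D_left=6e-3, D_right=9e-3, bends=True)
        sol = solve_tree(tree, ml_min_to_m3_s(1200), 0.30, blood)
        dl = chain_drop(tree, ("TS-L", "PSS-L", "DSS-L", "IJV-L"),
                        sol.segment_flows["TS-L"], blood)
        dr = chain_drop(tree, ("TS-R", "PSS-R", "DSS-R", "IJV-R"),
                        sol.segment_flows["TS-R"], blood)
        assert dl == pytest.approx(dr, rel=1e-8)

    def test_straight_fraction_splits_inflows(self, blood, average_tree):
        Q = ml_min_to_m3_s(650)
        sol = solve_tree(average_tree, Q, 0.30, blood)
        assert sol.segment_flows["SSS"] == pytest.approx(Q / 1.3, rel=1e-12)
        assert sol.segment_flows["StS"] == pytest.approx(0.3 * Q / 1.3, rel=1e-12)
        sol_sss = solve_tree(average_tree, Q, 0.30, blood, total_inflow=False)
        assert sol_sss.segment_flows["SSS"] == pytest.approx(Q, rel=1e-12)

    def test_drop_increasing_and_convex(self, blood, average_tree):
        qs = np.linspace(200, 2000, 19)
        drops = [
            solve_tree(average_tree, ml_min_to_m3_s(q), 0.30, blood).system_drop
            for q in qs
        ]
        assert np.all(np.diff(drops) > 0)
        assert np.all(np.diff(drops, 2) > -1e-9 * max(drops))

    def test_invalid_inputs(self, blood, average_tree):
        with pytest.raises(ValueError):
            solve_tree(average_tree, 0.0, 0.30, blood)
        with pytest.raises(ValueError):
            solve_tree(average_tree, 1e-5, 1.0, blood)


class TestCalibrate:
    def test_round_trip_anchor(self, blood, average_tree):
        Q = ml_min_to_m3_s(620)
        ref = 4.5 * 133.322
        tree = calibrate(average_tree, Q, ref, 0.30, blood)
        drop = solve_tree(tree, Q, 0.30, blood).system_drop
        assert drop == pytest.approx(ref, rel=1e-6)

    def test_fixed_point_scale_one(self, blood, average_tree):
        Q = ml_min_to_m3_s(620)
        drop = solve_tree(average_tree, Q, 0.30, blood).system_drop
        tree = calibrate(average_tree, Q, drop, 0.30, blood)
        assert tree.k_scale == pytest.approx(1.0, rel=1e-6)

    def test_infeasible_when_friction_exceeds_anchor(self, blood, average_tree):
        Q = ml_min_to_m3_s(620)
        friction_only = solve_tree(
            average_tree.with_k_scale(0.0), Q, 0.30, blood
        ).system_drop
        with pytest.raises(CalibrationError):
            calibrate(average_tree, Q, friction_only * 0.5, 0.30, blood)

    def test_calibrated_tree_exceeds_iih_threshold_at_high_flow(
        self, blood, average_tree
    ):
        """Hyperemic scale check: 2000 mL/min drives the calibrated
        average geometry well past the 8.3 mmHg induction level."""
        tree = calibrate(
            average_tree, ml_min_to_m3_s(620), 4.5 * 133.322, 0.30, blood
        )
        drop = solve_tree(tree, ml_min_to_m3_s(2000), 0.30, blood).system_drop
        assert pa_to_mmhg(drop) > 8.3
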