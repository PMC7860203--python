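"""Reduced-order pressure-drop model of the cerebral venous network.

Each sinus segment loses pressure through two mechanisms:

* distributed wall friction, Darcy-Weisbach ``dP = f (L/D) rho V^2 / 2``
  with ``f = 64/Re`` in laminar flow (which reduces exactly to the
  Poiseuille law, linear in flow) and the Blasius correlation
  ``f = 0.316 Re^{-1/4}`` above Re 2300;
* localized "minor" losses at bends and junctions, ``dP = K rho V^2/2``,
  quadratic in flow. These vortical losses are what make the total
  system pressure drop quadratic rather than linear in cerebral blood
  flow.

In the laminar regime a segment's drop is therefore exactly
``a_seg*Q + b_seg*Q^2`` with ``a_seg`` from friction and ``b_seg`` from
the summed loss coefficients.

The network is solved by mass conservation and a scalar root-find on the
left/right flow split so the two parallel torcula-to-outlet paths carry
equal pressure drops; both jugular outlets are held at gauge pressure 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import CalibrationError, SolverError
from .geometry import (
    BLOOD,
    LEFT_CHAIN,
    RIGHT_CHAIN,
    FluidProperties,
    VenousTree,
    VesselSegment,
)
from .units import m3_s_to_ml_min, pa_to_mmhg

__all__ = [
    "reynolds",
    "poiseuille_resistance",
    "friction_factor",
    "friction_drop",
    "bend_loss_coefficient",
    "minor_loss_drop",
    "segment_total_k",
    "segment_drop",
    "chain_drop",
    "solve_tree",
    "calibrate",
    "TreeSolution",
    "RE_TRANSITION",
]

RE_TRANSITION: float = 2300.0
_SPLIT_TOL: float = 1e-9
_MAX_BISECT: int = 200


def reynolds(Q: float, D: float, fluid: FluidProperties = BLOOD) -> float:
    """Reynolds number for volumetric flow ``Q`` (m^3/s) in a circular
    duct of diameter ``D`` (m): ``Re = 4 rho Q / (pi mu D)``."""
    if Q < 0:
        raise ValueError("flow must be >= 0")
    if D <= 0:
        raise ValueError("diameter must be positive")
    return 4.0 * fluid.density * Q / (math.pi * fluid.viscosity * D)


def poiseuille_resistance(L: float, D: float, mu: float) -> float:
    """Constant laminar resistance ``128 mu L / (pi D^4)`` (Pa.s/m^3) of a
    straight circular tube — the classical linear venous-resistance
    element."""
    if D <= 0 or mu <= 0 or L < 0:
        raise ValueError("need L >= 0 and D, mu > 0")
    return 128.0 * mu * L / (math.pi * D**4)


def friction_factor(Re: float) -> float:
    """Darcy friction factor: ``64/Re`` laminar, Blasius ``0.316 Re^-0.25``
    above Re 2300. The switch is discontinuous; continuity at the
    transition is deliberately not enforced."""
    if Re <= 0:
        raise ValueError("friction factor undefined for Re <= 0")
    if Re <= RE_TRANSITION:
        return 64.0 / Re
    return 0.316 * Re**-0.25


def friction_drop(Q: float, seg: VesselSegment, fluid: FluidProperties = BLOOD) -> float:
    """Darcy-Weisbach distributed friction loss over the segment, Pa."""
    if Q < 0:
        raise ValueError("flow must be >= 0")
    if Q == 0.0 or seg.length == 0.0:
        return 0.0
    V = Q / seg.area
    Re = reynolds(Q, seg.diameter, fluid)
    f = friction_factor(Re)
    return f * (seg.length / seg.diameter) * fluid.density * V * V / 2.0


def bend_loss_coefficient(angle_deg: float, radius_ratio: float) -> float:
    """Loss coefficient of a circular-arc bend.

    ``K = [0.131 + 0.159 (r/D)^{-3.5}] * (angle/90)`` — tight bends
    (small radius-to-diameter ratio) and larger turn angles dissipate
    more; K -> 0 as the bend straightens out.
    """
    if not (0.0 < angle_deg <= 180.0):
        raise ValueError("angle must be in (0, 180] degrees")
    if radius_ratio <= 0:
        raise ValueError("radius_ratio must be positive")
    return (0.131 + 0.159 * radius_ratio**-3.5) * (angle_deg / 90.0)


def minor_loss_drop(K: float, V: float, rho: float) -> float:
    """Localized loss ``K rho V^2 / 2`` (Pa)."""
    if K < 0:
        raise ValueError("K must be >= 0")
    return K * rho * V * V / 2.0


def segment_total_k(seg: VesselSegment) -> float:
    """Sum of bend and extra loss coefficients of a segment (unscaled)."""
    return sum(
        bend_loss_coefficient(b.angle_deg, b.radius_ratio) for b in seg.bends
    ) + sum(seg.extra_loss_coefficients)


def segment_drop(
    seg: VesselSegment,
    Q: float,
    fluid: FluidProperties = BLOOD,
    k_scale: float = 1.0,
) -> float:
    """Total segment pressure drop: friction plus scaled minor losses, Pa.

    In laminar flow this equals ``a_seg Q + b_seg Q^2`` with
    ``a_seg = 128 mu L / (pi D^4)`` and
    ``b_seg = k_scale * K_total * 8 rho / (pi^2 D^4)``.
    """
    if Q < 0:
        raise ValueError("flow must be >= 0")
    if Q == 0.0:
        return 0.0
    V = Q / seg.area
    dp = friction_drop(Q, seg, fluid)
    K = segment_total_k(seg) * k_scale
    if K > 0.0:
        dp += minor_loss_drop(K, V, fluid.density)
    return dp


def chain_drop(
    tree: VenousTree,
    names,
    Q: float,
    fluid: FluidProperties = BLOOD,
) -> float:
    """Series pressure drop over a chain of segments all carrying ``Q``."""
    return sum(segment_drop(tree.segments[n], Q, fluid, tree.k_scale) for n in names)


@dataclass(frozen=True)
class TreeSolution:
    """Solved flow state of the venous tree (SI units).

    ``system_drop`` is the SSS-inlet pressure relative to the jugular
    outlets (gauge 0); it is the drop that maps onto the venous-Ohm term
    ``TCBF * R_ven`` of the intracranial-pressure balance.
    """

    segment_flows: dict[str, float]
    node_pressures: dict[str, float]
    system_drop: float
    left_fraction: float

    @property
    def system_drop_mmhg(self) -> float:
        return pa_to_mmhg(self.system_drop)

    def to_records(self, tree: VenousTree, fluid: FluidProperties = BLOOD) -> list[dict]:
        """Per-segment summary rows (clinical units) for CSV export."""
        rows = []
        for name, Q in self.segment_flows.items():
            seg = tree.segments[name]
            rows.append(
                {
                    "segment": name,
                    "flow_ml_min": m3_s_to_ml_min(Q),
                    "drop_mmhg": pa_to_mmhg(
                        segment_drop(seg, Q, fluid, tree.k_scale)
                    ),
                    "reynolds": reynolds(Q, seg.diameter, fluid),
                }
            )
        return rows


def _inlet_flows(Q_total: float, straight_fraction: float, total_inflow: bool):
    """Resolve SSS and straight-sinus inflows.

    With ``total_inflow`` (default) ``Q_total`` is the combined inflow
    and ``Q_StS = straight_fraction * Q_SSS``; otherwise ``Q_total`` is
    the SSS inflow alone.
    """
    if total_inflow:
        q_sss = Q_total / (1.0 + straight_fraction)
    else:
        q_sss = Q_total
    return q_sss, straight_fraction * q_sss


def solve_tree(
    tree: VenousTree,
    Q_total: float,
    straight_fraction: float = 0.30,
    fluid: FluidProperties = BLOOD,
    *,
    total_inflow: bool = True,
) -> TreeSolution:
    """Solve the two-inlet/two-outlet network at a given inflow.

    The left-branch flow fraction ``x`` is found by bisection on (0, 1)
    so the parallel torcula->outlet drops agree to relative tolerance
    1e-9 (each branch drop is strictly increasing in its flow, so the
    mismatch is monotone in ``x`` and bisection cannot stall; a 200-
    iteration guard raises :class:`SolverError` regardless).
    """
    if Q_total <= 0:
        raise ValueError("Q_total must be positive")
    if not (0.0 <= straight_fraction < 1.0):
        raise ValueError("straight_fraction must be in [0, 1)")
    q_sss, q_sts = _inlet_flows(Q_total, straight_fraction, total_inflow)
    q_conf = q_sss + q_sts  # flow through the torcula

    def mismatch(x: float) -> float:
        return chain_drop(tree, LEFT_CHAIN, x * q_conf, fluid) - chain_drop(
            tree, RIGHT_CHAIN, (1.0 - x) * q_conf, fluid
        )

    lo, hi = 1e-12, 1.0 - 1e-12
    x = 0.5
    converged = False
    for _ in range(_MAX_BISECT):
        x = 0.5 * (lo + hi)
        dl = chain_drop(tree, LEFT_CHAIN, x * q_conf, fluid)
        dr = chain_drop(tree, RIGHT_CHAIN, (1.0 - x) * q_conf, fluid)
        if abs(dl - dr) <= _SPLIT_TOL * max(dl, dr, 1e-300):
            converged = True
            break
        if dl < dr:
            lo = x
        else:
            hi = x
    if not converged:
        raise SolverError(
            f"left/right split did not converge in {_MAX_BISECT} bisections"
        )

    q_left = x * q_conf
    q_right = (1.0 - x) * q_conf
    flows = {"SSS": q_sss, "StS": q_sts}
    flows.update({n: q_left for n in LEFT_CHAIN})
    flows.update({n: q_right for n in RIGHT_CHAIN})

    pressures = {"outlet_l": 0.0, "outlet_r": 0.0}
    # walk the left chain upstream from the outlet
    p = 0.0
    for name, node in (("IJV-L", "dss_l_end"), ("DSS-L", "pss_l_end"),
                       ("PSS-L", "ts_l_end"), ("TS-L", "torcula")):
        p += segment_drop(tree.segments[name], q_left, fluid, tree.k_scale)
        pressures[node] = p
    p = 0.0
    for name, node in (("IJV-R", "dss_r_end"), ("DSS-R", "pss_r_end"),
                       ("PSS-R", "ts_r_end"), ("TS-R", "torcula")):
        p += segment_drop(tree.segments[name], q_right, fluid, tree.k_scale)
        if node != "torcula":
            pressures[node] = p
    p_torcula = pressures["torcula"]
    pressures["sss_inlet"] = p_torcula + segment_drop(
        tree.segments["SSS"], q_sss, fluid, tree.k_scale
    )
    pressures["sts_inlet"] = p_torcula + segment_drop(
        tree.segments["StS"], q_sts, fluid, tree.k_scale
    )

    return TreeSolution(
        segment_flows=flows,
        node_pressures=pressures,
        system_drop=pressures["sss_inlet"],
        left_fraction=x,
    )


def calibrate(
    tree: VenousTree,
    reference_Q: float,
    reference_drop: float,
    straight_fraction: float = 0.30,
    fluid: FluidProperties = BLOOD,
    *,
    total_inflow: bool = True,
) -> VenousTree:
    """Scale all minor-loss coefficients so the tree reproduces a known
    flow/pressure-drop anchor.

    ``reference_Q`` (m^3/s) and ``reference_drop`` (Pa) default in the
    pipeline to the published young-adult operating point of 620 mL/min
    and 4.5 mmHg. Friction terms are untouched: the single scalar
    ``k_scale`` multiplying every K is root-found (bisection with bracket
    doubling) so that the solved system drop matches the anchor.

    Raises
    ------
    CalibrationError
        If friction alone already exceeds ``reference_drop`` (no
        non-negative scaling can match).
    """
    if reference_Q <= 0 or reference_drop <= 0:
        raise ValueError("reference values must be positive")

    def drop_at(s: float) -> float:
        return solve_tree(
            tree.with_k_scale(s), reference_Q, straight_fraction, fluid,
            total_inflow=total_inflow,
        ).system_drop

    d0 = drop_at(0.0)
    if d0 >= reference_drop:
        raise CalibrationError(
            f"friction-only drop {d0:.6g} Pa already exceeds the reference "
            f"{reference_drop:.6g} Pa; minor-loss calibration is infeasible"
        )
    # the drop is strictly increasing in the scale; bracket then bisect
    hi = max(tree.k_scale, 1.0)
    for _ in range(200):
        if drop_at(hi) >= reference_drop:
            break
        hi *= 2.0
    else:
        raise CalibrationError("could not bracket the calibration scale")
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        d = drop_at(mid)
        if abs(d - reference_drop) <= 1e-9 * reference_drop:
            lo = hi = mid
            break
        if d < reference_drop:
            lo = mid
        else:
            hi = mid
    return tree.with_k_scale(0.5 * (lo + hi))
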