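"""Coupling venous pressure to intracranial pressure (ICP).

Davson's equation balances cerebrospinal fluid (CSF) dynamics against
the venous outflow pressure:

    ICP = FR_csf * R_out + SSS_p                      [mmHg]

where ``FR_csf`` is the CSF formation rate (mL/min), ``R_out`` the CSF
outflow resistance (mmHg.min/mL) and ``SSS_p`` the superior sagittal
sinus pressure. The sinus pressure itself obeys a venous Ohm analog,

    SSS_p = TCBF * R_ven + CVP                        [mmHg]

with total cerebral blood flow TCBF, venous outflow resistance R_ven
(SSS to jugular bulbs) and central venous pressure CVP. The classical
picture takes R_ven constant; the quadratic pressure-flow law makes it
flow-dependent, ``R_ven(Q) = a + b Q``, which is what lets hyperemia
raise ICP past the idiopathic-intracranial-hypertension threshold.

In children, diagnosis requires ICP to rise 3.8 mmHg above the 14.6 mmHg
baseline, i.e. the 4.5 mmHg baseline venous drop must reach 8.3 mmHg
(the diagnostic CSF-pressure definition itself is quoted as 18.34 mmHg;
the 0.06 mmHg discrepancy with 14.6 + 3.8 is carried as-is, both
constants kept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .sweep import QuadraticFit

__all__ = [
    "DavsonParams",
    "VenousOhmParams",
    "IIHCriteria",
    "davson_icp",
    "sss_pressure",
    "required_venous_drop",
    "proportion_above",
    "icp_from_flow",
    "iih_onset_flow",
]


@dataclass(frozen=True)
class DavsonParams:
    """Davson's-equation parameters.

    ``fr_csf`` and ``r_out`` have no published values in the source
    cohort; the defaults here are user-supplied round numbers chosen so
    that ``fr_csf * r_out + 11.1 = 14.6`` mmHg, and must be overridden
    for any quantitative CSF work.
    """

    fr_csf: float = 0.35   # CSF formation rate, mL/min (user-supplied)
    r_out: float = 10.0    # CSF outflow resistance, mmHg.min/mL (user-supplied)
    sss_p: float = 11.1    # superior sagittal sinus pressure, mmHg

    def __post_init__(self) -> None:
        if self.fr_csf < 0 or self.r_out < 0 or self.sss_p < 0:
            raise ValueError("Davson parameters must be non-negative")


@dataclass(frozen=True)
class VenousOhmParams:
    """Venous Ohm-analog parameters.

    ``r_ven`` is either a constant resistance (mmHg.min/mL, the
    classical linear model) or a :class:`~sinusflow.sweep.QuadraticFit`,
    in which case the flow-dependent resistance ``a + b*TCBF`` is used.
    """

    tcbf: float
    r_ven: float | QuadraticFit
    cvp: float = 0.0

    def __post_init__(self) -> None:
        if self.tcbf < 0 or self.cvp < 0:
            raise ValueError("tcbf and cvp must be non-negative")
        if isinstance(self.r_ven, (int, float)) and self.r_ven < 0:
            raise ValueError("r_ven must be non-negative")


@dataclass(frozen=True)
class IIHCriteria:
    """Paediatric induction thresholds for idiopathic intracranial
    hypertension (all mmHg, overridable)."""

    baseline_icp: float = 14.6
    required_delta: float = 3.8
    baseline_drop: float = 4.5
    diagnostic_icp: float = 18.34

    def __post_init__(self) -> None:
        if min(self.baseline_icp, self.required_delta, self.baseline_drop,
               self.diagnostic_icp) <= 0:
            raise ValueError("all criteria must be positive")


def davson_icp(p: DavsonParams) -> float:
    """ICP (mmHg) from Davson's equation: ``FR_csf * R_out + SSS_p``."""
    return p.fr_csf * p.r_out + p.sss_p


def sss_pressure(p: VenousOhmParams) -> float:
    """Superior sagittal sinus pressure (mmHg): ``TCBF * R_ven + CVP``.

    With a quadratic fit the drop term is ``a*TCBF + b*TCBF^2`` (the
    fit's intercept, if any, is included), i.e. resistance rising
    linearly with flow.
    """
    if isinstance(p.r_ven, QuadraticFit):
        drop = float(p.r_ven.predict(p.tcbf))
    else:
        drop = p.tcbf * float(p.r_ven)
    return drop + p.cvp


def required_venous_drop(c: IIHCriteria) -> float:
    """Venous pressure drop (mmHg) at which hyperemia alone induces
    intracranial hypertension: ``baseline_drop + required_delta``."""
    return c.baseline_drop + c.required_delta


def proportion_above(flows, threshold: float) -> tuple[int, int, int]:
    """Count cohort flows strictly above a threshold.

    Returns ``(count, total, percent)`` with percent rounded to the
    nearest integer — e.g. 13 of 42 flows above 1500 mL/min gives 31%.
    """
    flows = np.asarray(flows, dtype=float)
    if flows.size == 0:
        raise ValueError("cohort must be non-empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    count = int(np.sum(flows > threshold))
    total = int(flows.size)
    return count, total, int(round(100.0 * count / total))


def icp_from_flow(
    tcbf: float,
    fit: QuadraticFit,
    davson: DavsonParams = DavsonParams(),
    cvp: float = 0.0,
) -> float:
    """ICP (mmHg) at a given cerebral blood flow under the quadratic
    venous model, composing the venous Ohm analog into Davson's
    equation (the supplied ``davson.sss_p`` is replaced by the computed
    sinus pressure)."""
    sssp = sss_pressure(VenousOhmParams(tcbf=tcbf, r_ven=fit, cvp=cvp))
    return davson_icp(DavsonParams(davson.fr_csf, davson.r_out, sssp))


def iih_onset_flow(
    fit: QuadraticFit,
    criteria: IIHCriteria = IIHCriteria(),
    davson: DavsonParams = DavsonParams(),
    cvp: float = 0.0,
) -> float:
    """TCBF (mL/min) at which ICP reaches ``baseline_icp +
    required_delta``.

    Solved by root-finding on the composed ICP(TCBF) relation. When the
    CSF and CVP terms are set so the baseline balances (``fr_csf*r_out +
    cvp = baseline_icp - baseline_drop``), this coincides with
    ``threshold_flow(fit, required_venous_drop(criteria))``.
    """
    target = criteria.baseline_icp + criteria.required_delta

    def g(q: float) -> float:
        return icp_from_flow(q, fit, davson, cvp) - target

    lo, hi = 1e-9, 10.0
    for _ in range(200):
        if g(hi) >= 0:
            break
        hi *= 2.0
    else:
        return math.inf
    if g(lo) > 0:
        raise ValueError("ICP already exceeds the target at zero flow")
    return float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-15))
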