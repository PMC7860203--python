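"""Synthetic cohort, velocity-plane and CFD-surrogate generation.

Patient-resolved CFD of the venous sinuses is not redistributable, so
every pipeline stage is exercised against synthetic data with the
statistical structure of the studied five-patient cohort:

* sinus diameters drawn per patient from truncated normals with the
  published per-sinus means/SDs (SSS 5.49 +/- 0.43, TS 6.28 +/- 1.19,
  PSS 7.77 +/- 0.82, DSS 8.21 +/- 2.45 mm), SSS length 107.8 +/- 11.5 mm
  and straight-sinus length 42.9 +/- 2.3 mm;
* cross-sectional planes carrying a solid-body swirl whose section
  -average curl has a closed form, for validating the curl metrics;
* pressure/curl "CFD surrogate" series: noiseless truths
  ``dP = a Q + b Q^2`` and ``curl = c Q^gamma`` with multiplicative
  Gaussian noise, matching the relative-error character of a validated
  CFD campaign.

All draws are reproducible from a seed; replicates derive their streams
from ``(seed, index)`` seed sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import (
    DEFAULT_BENDS,
    DEFAULT_LENGTHS_MM,
    REFERENCE_DIAMETERS_MM,
    SEGMENT_NAMES,
    SSS_LENGTH_MM,
    STS_LENGTH_MM,
    VenousTree,
    VesselSegment,
    cohort_stats,
)
from .sweep import DEFAULT_FLOW_GRID, PressureFlowCurve
from .units import mm_to_m
from .vorticity import VelocityPlane

__all__ = [
    "CohortSpec",
    "SurrogateSpec",
    "SurrogatePatient",
    "generate_tree",
    "generate_cohort",
    "generate_velocity_plane",
    "generate_surrogate",
    "generate_referral_cohort_flows",
]

_MIN_DIAMETER_MM = 1.0  # truncation bound: no unphysical sub-millimetre lumen


def _table_mean_sd() -> dict[str, tuple[float, float]]:
    return {k: cohort_stats(v) for k, v in REFERENCE_DIAMETERS_MM.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a synthetic patient cohort.

    Diameter means/SDs (mm) default to the published cohort rows;
    lengths to the published SSS/StS means/SDs. ``seed`` fixes all
    downstream randomness.
    """

    diameter_stats: dict[str, tuple[float, float]] = field(
        default_factory=_table_mean_sd
    )
    sss_length: tuple[float, float] = SSS_LENGTH_MM
    sts_length: tuple[float, float] = STS_LENGTH_MM
    n_patients: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (m, s) in self.diameter_stats.items():
            if m <= 0 or s < 0:
                raise ValueError(f"{key}: mean must be > 0 and SD >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lower: float) -> float:
    if sd == 0.0:
        return mean
    a = (lower - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def generate_tree(spec: CohortSpec, patient_index: int) -> VenousTree:
    """Draw one synthetic patient tree, deterministic in
    ``(spec.seed, patient_index)``.

    Left and right branch diameters are drawn independently from the
    same per-sinus distribution, giving the anatomically usual
    asymmetric drainage; the straight sinus reuses the SSS distribution
    and the jugular extension the DSS one, since neither is tabulated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, patient_index]))
    st = spec.diameter_stats

    def draw_d(key: str) -> float:
        m, s = st[key]
        return _trunc_normal(rng, m, s, _MIN_DIAMETER_MM)

    diam_mm = {"SSS": draw_d("SSS_Dh"), "StS": draw_d("SSS_Dh")}
    for side in ("L", "R"):
        diam_mm[f"TS-{side}"] = draw_d("TS_De")
        diam_mm[f"PSS-{side}"] = draw_d("PSS_De")
        dss = draw_d("DSS_De")
        diam_mm[f"DSS-{side}"] = dss
        diam_mm[f"IJV-{side}"] = dss
    len_mm = {
        "SSS": _trunc_normal(rng, *spec.sss_length, _MIN_DIAMETER_MM),
        "StS": _trunc_normal(rng, *spec.sts_length, _MIN_DIAMETER_MM),
    }
    segments = {}
    for name in SEGMENT_NAMES:
        base = name.split("-")[0]
        length = len_mm.get(name, len_mm.get(base, DEFAULT_LENGTHS_MM.get(base)))
        segments[name] = VesselSegment(
            name=name,
            length=mm_to_m(length),
            diameter=mm_to_m(diam_mm[name]),
            bends=DEFAULT_BENDS[name],
        )
    return VenousTree(segments=segments, patient_id=f"synthetic-{patient_index}")


def generate_cohort(spec: CohortSpec) -> list[VenousTree]:
    return [generate_tree(spec, i) for i in range(spec.n_patients)]


def generate_velocity_plane(
    Q: float,
    radius: float,
    swirl: float,
    grid_n: int = 65,
    seed: int | None = None,
    noise: float = 0.0,
) -> VelocityPlane:
    """Circular cross-section carrying a solid-body swirl.

    The in-plane velocity is a rigid rotation whose rim tangential speed
    is ``swirl`` times the mean axial velocity ``V = Q / (pi R^2)``, so
    the analytic curl is uniform: ``2 * swirl * V / radius`` (1/s) —
    a closed form for validating the discrete curl. Optional
    multiplicative Gaussian noise (SD ``noise``) perturbs both
    components, seeded for reproducibility.

    Parameters
    ----------
    Q : float
        Through-plane volumetric flow, m^3/s.
    radius : float
        Lumen radius, m.
    swirl : float
        Rim tangential speed as a fraction of the mean axial speed.
    """
    if radius <= 0 or grid_n < 3:
        raise ValueError("radius must be positive and grid_n >= 3")
    if Q < 0 or swirl < 0 or noise < 0:
        raise ValueError("Q, swirl and noise must be >= 0")
    v_mean = Q / (math.pi * radius**2)
    omega = swirl * v_mean / radius  # rigid-body angular rate, 1/s
    half = grid_n // 2
    spacing = radius / max(half - 1, 1)
    coords = (np.arange(grid_n) - half) * spacing
    X, Y = np.meshgrid(coords, coords)
    mask = X**2 + Y**2 <= radius**2
    u = -omega * Y
    v = omega * X
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        u = u * (1.0 + noise * rng.standard_normal(u.shape))
        v = v * (1.0 + noise * rng.standard_normal(v.shape))
    return VelocityPlane(u=u, v=v, spacing=spacing, mask=mask,
                         label=f"synthetic swirl plane, Q={Q:g} m3/s")


@dataclass(frozen=True)
class SurrogateSpec:
    """Ground truth and noise model for CFD-surrogate series.

    ``a``/``b`` are the true pressure-flow coefficients in mmHg/(mL/min)
    and mmHg/(mL/min)^2; defaults cross the 8.3 mmHg hypertension
    threshold near 1500 mL/min. ``curl_scale``/``curl_exponent`` set the
    superlinear curl growth ``c * Q^gamma`` (gamma defaults to 1.4, the
    midpoint of the 1.2-1.6 range implied by the published 400 -> 2000
    mL/min curl growth factors). ``sigma_p``/``sigma_c`` are
    multiplicative noise SDs for drops and curls.
    """

    a: float = 0.003
    b: float = 1.5e-6
    curl_scale: float = 0.006
    curl_exponent: float = 1.4
    sigma_p: float = 0.02
    sigma_c: float = 0.05
    flows: np.ndarray = field(default_factory=lambda: DEFAULT_FLOW_GRID.copy())
    n_patients: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.curl_scale) < 0:
            raise ValueError("a, b and curl_scale must be >= 0")
        if self.curl_exponent <= 0:
            raise ValueError("curl_exponent must be positive")
        if self.sigma_p < 0 or self.sigma_c < 0:
            raise ValueError("noise SDs must be >= 0")
        object.__setattr__(self, "flows", np.asarray(self.flows, dtype=float))


@dataclass(frozen=True)
class SurrogatePatient:
    """One synthetic patient's surrogate sweep outputs."""

    curve: PressureFlowCurve
    curls: np.ndarray
    true_a: float
    true_b: float


def generate_surrogate(spec: SurrogateSpec) -> list[SurrogatePatient]:
    """Generate per-patient noisy pressure-flow curves and curl series.

    ``drops = (a Q + b Q^2)(1 + eps_p)`` and
    ``curls = c Q^gamma (1 + eps_c)`` with independent Gaussian
    ``eps ~ N(0, sigma)`` per point; the multiplicative form preserves
    positivity at the noise levels used, keeps dP(0) = 0 exactly, and
    mirrors the relative-error character of CFD validation. Patient
    ``i`` uses the stream seeded by ``(seed, i)``.
    """
    out = []
    Q = spec.flows
    for i in range(spec.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        truth = spec.a * Q + spec.b * Q**2
        drops = truth * (1.0 + spec.sigma_p * rng.standard_normal(Q.shape))
        curls = (
            spec.curl_scale
            * Q**spec.curl_exponent
            * (1.0 + spec.sigma_c * rng.standard_normal(Q.shape))
        )
        out.append(
            SurrogatePatient(
                curve=PressureFlowCurve(Q, drops, patient_id=f"surrogate-{i}"),
                curls=curls,
                true_a=spec.a,
                true_b=spec.b,
            )
        )
    return out


def generate_referral_cohort_flows(
    n_total: int = 42,
    n_above: int = 13,
    threshold: float = 1500.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic referral-cohort blood-flow list (mL/min).

    The flows of the 42-child cohort investigated for possible
    intracranial hypertension were never published — only the summary
    that 13 exceeded 1500 mL/min. This generator reproduces that
    composition: ``n_above`` flows drawn above the threshold and the
    remainder below, from truncated normals around plausible paediatric
    values, shuffled deterministically.
    """
    if not (0 <= n_above <= n_total) or n_total < 1:
        raise ValueError("need 0 <= n_above <= n_total and n_total >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 42]))
    below = np.array(
        [
            _trunc_upper(rng, 1100.0, 250.0, lower=300.0, upper=threshold)
            for _ in range(n_total - n_above)
        ]
    )
    above = np.array(
        [
            _trunc_upper(rng, 1700.0, 200.0, lower=threshold + 1e-9, upper=2400.0)
            for _ in range(n_above)
        ]
    )
    flows = np.concatenate([below, above])
    rng.shuffle(flows)
    return flows


def _trunc_upper(rng, mean, sd, lower, upper) -> float:
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
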