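"""Vessel cross-sections, segments and the venous-tree network.

The dural venous sinuses drain cerebral blood from the superior sagittal
sinus (SSS) and straight sinus (StS) through the torcula into paired
transverse (TS), proximal/distal sigmoid (PSS/DSS) sinuses and internal
jugular veins (IJV). Sinus lumens are non-circular, so two scalar
diameters are used: the hydraulic diameter ``D_h = 4A/P`` (which governs
viscous friction) and the effective diameter ``D_e = 2*sqrt(A/pi)`` (the
equal-area circle, which governs mean velocity).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import measure

from .exceptions import InvalidGeometryError
from .units import m_to_mm, mm_to_m

__all__ = [
    "FluidProperties",
    "CrossSection",
    "Bend",
    "VesselSegment",
    "VenousTree",
    "hydraulic_diameter",
    "effective_diameter",
    "diameters_from_mask",
    "cohort_stats",
    "default_tree",
    "REFERENCE_DIAMETERS_MM",
    "SSS_LENGTH_MM",
    "STS_LENGTH_MM",
]

# Published per-patient sinus diameters (mm) for five adults with
# radiologically normal cerebral venous systems: SSS hydraulic diameter
# and TS/PSS/DSS effective diameters.
REFERENCE_DIAMETERS_MM: dict[str, tuple[float, ...]] = {
    "SSS_Dh": (5.62, 5.29, 4.99, 5.41, 6.13),
    "TS_De": (6.55, 4.79, 5.43, 7.81, 6.84),
    "PSS_De": (8.30, 7.84, 6.34, 8.11, 8.28),
    "DSS_De": (6.37, 8.64, 7.53, 12.24, 6.28),
}

# Sinus lengths (mm): mean +/- SD over the same cohort.
SSS_LENGTH_MM: tuple[float, float] = (107.8, 11.5)
STS_LENGTH_MM: tuple[float, float] = (42.9, 2.3)

# Default lengths (mm) for the downstream segments; not measured in the
# reference cohort, chosen as anatomically plausible adult values and
# exposed in every constructor.
DEFAULT_LENGTHS_MM: dict[str, float] = {
    "TS": 50.0,
    "PSS": 40.0,
    "DSS": 40.0,
    "IJV": 30.0,
}


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood model.

    Parameters
    ----------
    density : float
        Mass density, kg/m^3. Default 1055 (whole blood).
    viscosity : float
        Dynamic viscosity, Pa.s. Default 0.0035 (high-shear asymptote).
    """

    density: float = 1055.0
    viscosity: float = 0.0035

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be strictly positive")


BLOOD = FluidProperties()


@dataclass(frozen=True)
class CrossSection:
    """A lumen cross-section described by area and perimeter (SI, m)."""

    area: float
    perimeter: float

    def __post_init__(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise InvalidGeometryError(
                f"area and perimeter must be positive, got "
                f"area={self.area!r}, perimeter={self.perimeter!r}"
            )
        # isoperimetric inequality; the slack tolerates the sub-percent
        # perimeter bias of mask-measured circular sections, for which
        # the inequality is tight
        if self.perimeter**2 < 4.0 * math.pi * self.area * (1.0 - 0.05):
            raise InvalidGeometryError(
                "perimeter^2 < 4*pi*area: no planar region has this "
                "area/perimeter pair"
            )

    @classmethod
    def circle(cls, diameter: float) -> "CrossSection":
        r = diameter / 2.0
        return cls(area=math.pi * r * r, perimeter=math.pi * diameter)


def hydraulic_diameter(cs: CrossSection) -> float:
    """Hydraulic diameter ``D_h = 4*area/perimeter`` (m).

    Equals the geometric diameter for a circular lumen and is smaller for
    any convex non-circular one; it is the length scale entering the
    Reynolds number and the friction factor.
    """
    return 4.0 * cs.area / cs.perimeter


def effective_diameter(cs: CrossSection) -> float:
    """Effective diameter ``D_e = 2*sqrt(area/pi)`` (m): the diameter of
    the circle with the same lumen area."""
    if cs.area <= 0:
        raise InvalidGeometryError("area must be positive")
    return 2.0 * math.sqrt(cs.area / math.pi)


def diameters_from_mask(
    mask: np.ndarray, spacing: float, *, smoothing_sigma: float | None = None
) -> tuple[float, float]:
    """Hydraulic and effective diameters of a binary lumen mask.

    Area is the pixel count times ``spacing**2``. Perimeter is the length
    of the marching-squares contour of the mask after a mild Gaussian
    smoothing. By default the smoothing width scales with the square
    root of the equivalent pixel radius (``0.4*sqrt(R_px)``, at least
    one pixel), which suppresses the pixel staircase while keeping the
    curvature bias vanishing, so the contour length converges to the
    true perimeter under grid refinement; pass ``smoothing_sigma`` to
    override.

    Parameters
    ----------
    mask : ndarray of bool/0-1
        Lumen indicator on a regular grid.
    spacing : float
        Pixel spacing, m.

    Returns
    -------
    (D_h, D_e) in m.
    """
    mask = np.asarray(mask).astype(bool)
    if spacing <= 0:
        raise InvalidGeometryError("spacing must be positive")
    npix = int(mask.sum())
    if npix < 4:
        raise InvalidGeometryError("mask is empty or degenerate (<4 pixels)")
    _, ncomp = ndimage.label(mask)
    if ncomp != 1:
        raise InvalidGeometryError(
            f"mask must be a single connected component, found {ncomp}"
        )
    if smoothing_sigma is None:
        smoothing_sigma = max(1.0, 0.4 * (npix / math.pi) ** 0.25)
    smooth = ndimage.gaussian_filter(mask.astype(float), smoothing_sigma, mode="constant")
    contours = measure.find_contours(smooth, 0.5)
    if not contours:
        raise InvalidGeometryError("no lumen contour found")
    perimeter_px = sum(
        float(np.sqrt((np.diff(c, axis=0) ** 2).sum(axis=1)).sum()) for c in contours
    )
    area = npix * spacing**2
    perimeter = perimeter_px * spacing
    cs = CrossSection(area=area, perimeter=perimeter)
    return hydraulic_diameter(cs), effective_diameter(cs)


def cohort_stats(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    The n-1 convention is what reproduces published per-sinus SD rows
    from the per-patient values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cohort_stats needs at least two values")
    return float(v.mean()), float(v.std(ddof=1))


@dataclass(frozen=True)
class Bend:
    """A vessel bend: turn angle in degrees and bend-radius-to-diameter
    ratio (dimensionless)."""

    angle_deg: float
    radius_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 < self.angle_deg <= 180.0):
            raise InvalidGeometryError("bend angle must be in (0, 180] degrees")
        if self.radius_ratio <= 0:
            raise InvalidGeometryError("bend radius ratio must be positive")


@dataclass(frozen=True)
class VesselSegment:
    """One sinus segment: a straight-pipe friction element plus localized
    (minor) losses from its bends and any extra loss coefficients.

    All lengths in m. ``diameter`` is the representative internal
    diameter (effective diameter at mid-segment).
    """

    name: str
    length: float
    diameter: float
    bends: tuple[Bend, ...] = ()
    extra_loss_coefficients: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.length < 0:
            raise InvalidGeometryError(f"{self.name}: length must be >= 0")
        if self.diameter <= 0:
            raise InvalidGeometryError(f"{self.name}: diameter must be positive")
        if any(k < 0 for k in self.extra_loss_coefficients):
            raise InvalidGeometryError(f"{self.name}: loss coefficients must be >= 0")

    @property
    def area(self) -> float:
        return math.pi * self.diameter**2 / 4.0


# node names of the fixed two-inlet/two-outlet topology
_EDGES: tuple[tuple[str, str, str], ...] = (
    ("sss_inlet", "torcula", "SSS"),
    ("sts_inlet", "torcula", "StS"),
    ("torcula", "ts_l_end", "TS-L"),
    ("ts_l_end", "pss_l_end", "PSS-L"),
    ("pss_l_end", "dss_l_end", "DSS-L"),
    ("dss_l_end", "outlet_l", "IJV-L"),
    ("torcula", "ts_r_end", "TS-R"),
    ("ts_r_end", "pss_r_end", "PSS-R"),
    ("pss_r_end", "dss_r_end", "DSS-R"),
    ("dss_r_end", "outlet_r", "IJV-R"),
)

SEGMENT_NAMES: tuple[str, ...] = tuple(name for _, _, name in _EDGES)
LEFT_CHAIN: tuple[str, ...] = ("TS-L", "PSS-L", "DSS-L", "IJV-L")
RIGHT_CHAIN: tuple[str, ...] = ("TS-R", "PSS-R", "DSS-R", "IJV-R")
INLET_NODES: tuple[str, str] = ("sss_inlet", "sts_inlet")
OUTLET_NODES: tuple[str, str] = ("outlet_l", "outlet_r")


@dataclass(frozen=True)
class VenousTree:
    """The two-inlet/two-outlet dural sinus network.

    SSS and StS inflows merge at the torcula; the combined flow splits
    into symmetric-topology left and right chains (TS -> PSS -> DSS ->
    IJV) ending at the jugular outlets. ``k_scale`` uniformly scales all
    minor-loss coefficients; it is the single free parameter set by
    calibration against a published flow/pressure-drop anchor.
    """

    segments: dict[str, VesselSegment] = field(default_factory=dict)
    k_scale: float = 1.0
    patient_id: str = "default"

    def __post_init__(self) -> None:
        missing = [n for n in SEGMENT_NAMES if n not in self.segments]
        if missing:
            raise InvalidGeometryError(f"tree is missing segments: {missing}")
        if self.k_scale < 0:
            raise InvalidGeometryError("k_scale must be >= 0")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidGeometryError("tree topology must be acyclic")
        if not nx.is_weakly_connected(g):
            raise InvalidGeometryError("tree topology must be connected")
        inlets = [n for n in g if g.in_degree(n) == 0]
        outlets = [n for n in g if g.out_degree(n) == 0]
        if sorted(inlets) != sorted(INLET_NODES) or sorted(outlets) != sorted(OUTLET_NODES):
            raise InvalidGeometryError("tree must have exactly the SSS/StS inlets "
                                       "and left/right jugular outlets")

    @staticmethod
    def graph() -> nx.DiGraph:
        g = nx.DiGraph()
        for u, v, name in _EDGES:
            g.add_edge(u, v, segment=name)
        return g

    def with_k_scale(self, k_scale: float) -> "VenousTree":
        return VenousTree(segments=self.segments, k_scale=k_scale,
                          patient_id=self.patient_id)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "k_scale": self.k_scale,
            "segments": [
                {
                    "name": s.name,
                    "length_mm": m_to_mm(s.length),
                    "diameter_mm": m_to_mm(s.diameter),
                    "bends": [
                        {"angle_deg": b.angle_deg, "radius_ratio": b.radius_ratio}
                        for b in s.bends
                    ],
                    "extra_loss_coefficients": list(s.extra_loss_coefficients),
                }
                for s in (self.segments[n] for n in SEGMENT_NAMES)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VenousTree":
        segments = {}
        for sd in d["segments"]:
            seg = VesselSegment(
                name=sd["name"],
                length=mm_to_m(sd["length_mm"]),
                diameter=mm_to_m(sd["diameter_mm"]),
                bends=tuple(
                    Bend(b["angle_deg"], b["radius_ratio"]) for b in sd.get("bends", ())
                ),
                extra_loss_coefficients=tuple(sd.get("extra_loss_coefficients", ())),
            )
            segments[seg.name] = seg
        return cls(segments=segments, k_scale=float(d.get("k_scale", 1.0)),
                   patient_id=str(d.get("patient_id", "default")))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "VenousTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Default bend descriptors: the transverse sinus sweeps ~90 degrees in
# the tentorial margin, the sigmoid sinus describes its S through the
# mastoid (two tight turns), and the jugular bulb adds one sharp turn
# into the IJV where vortical flow concentrates.
DEFAULT_BENDS: dict[str, tuple[Bend, ...]] = {
    "SSS": (Bend(30.0, 4.0),),
    "StS": (Bend(30.0, 4.0),),
    "TS-L": (Bend(90.0, 2.0),),
    "TS-R": (Bend(90.0, 2.0),),
    "PSS-L": (Bend(90.0, 1.2),),
    "PSS-R": (Bend(90.0, 1.2),),
    "DSS-L": (Bend(90.0, 1.2),),
    "DSS-R": (Bend(90.0, 1.2),),
    "IJV-L": (Bend(75.0, 1.0),),
    "IJV-R": (Bend(75.0, 1.0),),
}


def default_tree(patient_id: str = "average") -> VenousTree:
    """Tree with cohort-average diameters and default lengths/bends.

    Diameters are the cohort means (SSS 5.49, TS 6.28, PSS 7.77, DSS
    8.21 mm); the straight sinus reuses the SSS diameter and the jugular
    extension reuses the DSS diameter, since neither is reported
    separately.
    """
    means = {k: float(np.mean(v)) for k, v in REFERENCE_DIAMETERS_MM.items()}
    diam = {
        "SSS": means["SSS_Dh"],
        "StS": means["SSS_Dh"],
        "TS": means["TS_De"],
        "PSS": means["PSS_De"],
        "DSS": means["DSS_De"],
        "IJV": means["DSS_De"],
    }
    lengths = {
        "SSS": SSS_LENGTH_MM[0],
        "StS": STS_LENGTH_MM[0],
        "TS": DEFAULT_LENGTHS_MM["TS"],
        "PSS": DEFAULT_LENGTHS_MM["PSS"],
        "DSS": DEFAULT_LENGTHS_MM["DSS"],
        "IJV": DEFAULT_LENGTHS_MM["IJV"],
    }
    segments = {}
    for name in SEGMENT_NAMES:
        base = name.split("-")[0]
        segments[name] = VesselSegment(
            name=name,
            length=mm_to_m(lengths[base]),
            diameter=mm_to_m(diam[base]),
            bends=DEFAULT_BENDS[name],
        )
    return VenousTree(segments=segments, patient_id=patient_id)
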