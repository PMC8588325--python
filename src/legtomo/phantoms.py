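"""Parametric leg cross-section phantoms with tissue dielectric properties.

A phantom is a nested set of closed tissue contours — skin ⊃ fat ⊃
muscle ⊃ {tibia, fibula} — immersed in a lossy matching medium.  Each
region carries a complex relative permittivity at the operating
frequency (0.8 GHz), written with the engineering time convention
e^{+jωt}, so lossy media are ε = ε′ − jε″ with ε″ ≥ 0.

Bone permittivity is tied to bone volume fraction (BVF): a healthy bone
(BVF 0.50) has ε = 13 − j3.0 and a severely demineralized one
(BVF 0.10) has ε = 23 − j3.4, with a nine-row lookup table in between;
lower mineral content means more fluid, hence higher permittivity.

Contours are smooth parametric curves (ellipses, optionally perturbed by
a low-order cosine series) standing in for traced anatomical boundaries;
dimensions default to a mid-calf cross section (~11 cm outer diameter).
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml
from shapely.geometry import Point, Polygon

__all__ = [
    "BVF_TABLE",
    "GLYCERIN_WATER",
    "ULTRASOUND_GEL",
    "TISSUE_PERMITTIVITY",
    "MATCHING_MEDIA",
    "GeometryParams",
    "InvalidGeometryError",
    "PhantomModel",
    "TissueRegion",
    "bvf_to_permittivity",
    "make_leg_phantom",
    "permittivity_at",
    "save_phantom_config",
    "load_phantom_config",
    "export_contours_csv",
]

TissueLabel = Literal["skin", "fat", "muscle", "tibia", "fibula"]
Scenario = Literal["thin_fat", "medium_fat", "thick_fat"]

#: Bulk complex relative permittivities of leg tissues at 0.8 GHz
#: (ε′ − jε″ convention); bone entry is the healthy (BVF 0.50) value.
TISSUE_PERMITTIVITY: dict[str, complex] = {
    "skin": 42.0 - 18.8j,
    "fat": 11.0 - 2.3j,
    "muscle": 55.0 - 20.5j,
    "bone": 13.0 - 3.0j,
}

#: 80:20 glycerin/water matching medium at 0.8 GHz.
GLYCERIN_WATER: complex = 26.0 - 18.0j
#: AquaSonic-type ultrasound gel matching medium at 0.8 GHz.
ULTRASOUND_GEL: complex = 71.4 - 10.3j

MATCHING_MEDIA: dict[str, complex] = {
    "glycerin_water": GLYCERIN_WATER,
    "gel": ULTRASOUND_GEL,
}

#: Bone complex relative permittivity vs bone volume fraction, sorted by
#: descending BVF: 0.50 is healthy bone, 0.10 severe mineral loss.
BVF_TABLE: tuple[tuple[float, complex], ...] = (
    (0.50, 13.0 - 3.0j),
    (0.45, 14.0 - 3.05j),
    (0.40, 15.0 - 3.075j),
    (0.35, 16.0 - 3.1j),
    (0.30, 17.0 - 3.15j),
    (0.25, 18.0 - 3.2j),
    (0.20, 19.5 - 3.275j),
    (0.15, 21.0 - 3.35j),
    (0.10, 23.0 - 3.4j),
)

DEFAULT_FREQUENCY = 0.8e9  # Hz


class InvalidGeometryError(ValueError):
    """Raised when phantom contours overlap or violate nesting."""


def bvf_to_permittivity(bvf: float) -> complex:
    """Map a bone volume fraction to a complex relative permittivity.

    At the nine tabulated BVF points the table value is returned
    exactly; between rows, real and imaginary parts are interpolated
    linearly.  No extrapolation outside [0.10, 0.50].

    Parameters
    ----------
    bvf : float
        Bone volume fraction, 0.10 ≤ bvf ≤ 0.50.

    Returns
    -------
    complex
        Relative permittivity ε′ − jε″ of bone at that BVF.
    """
    bvf = float(bvf)
    if not (0.10 <= bvf <= 0.50):
        raise ValueError(
            f"BVF {bvf!r} outside the tabulated range [0.10, 0.50]; "
            "no extrapolation is performed"
        )
    fracs = np.array([b for b, _ in BVF_TABLE])[::-1]  # ascending
    vals = np.array([v for _, v in BVF_TABLE])[::-1]
    re = float(np.interp(bvf, fracs, vals.real))
    im = float(np.interp(bvf, fracs, vals.imag))
    return complex(re, im)


@dataclass(frozen=True)
class TissueRegion:
    """A closed tissue contour with its dielectric properties.

    The contour is a counter-clockwise planar polyline in meters with no
    repeated end point; the stored permittivity follows the ε′ − jε″
    convention (Im ≤ 0 as a Python complex).
    """

    label: TissueLabel
    contour: np.ndarray  # (M, 2), CCW, meters
    permittivity: complex

    def polygon(self) -> Polygon:
        return Polygon(np.asarray(self.contour))

    @property
    def area(self) -> float:
        return self.polygon().area


@dataclass(frozen=True)
class GeometryParams:
    """Geometric parameters of the parametric leg cross section.

    Lengths in meters.  The outer (skin) boundary is an ellipse with
    semi-axes ``outer_a``/``outer_b``, optionally perturbed by a cosine
    series ``perturb_amplitude·cos(perturb_order·θ + phase)``; skin and
    fat are inward-offset rings of constant thickness, and the two bones
    are circles inside the muscle.
    """

    outer_a: float = 0.055
    outer_b: float = 0.050
    skin_thickness: float = 0.002
    fat_thickness: float = 0.004
    tibia_center: tuple[float, float] = (0.018, 0.010)
    tibia_radius: float = 0.011
    fibula_center: tuple[float, float] = (-0.026, -0.008)
    fibula_radius: float = 0.006
    n_points: int = 96
    perturb_amplitude: float = 0.0
    perturb_order: int = 3
    perturb_phase: float = 0.0

    def replace(self, **kw) -> "GeometryParams":
        return dataclasses.replace(self, **kw)


#: Per-scenario geometry defaults; only the fat-ring thickness differs,
#: thick fat being ≥ 2× thin fat.
SCENARIO_GEOMETRY: dict[str, GeometryParams] = {
    "thin_fat": GeometryParams(fat_thickness=0.004),
    "medium_fat": GeometryParams(fat_thickness=0.008),
    "thick_fat": GeometryParams(fat_thickness=0.014),
}


@dataclass(frozen=True)
class PhantomModel:
    """Ground-truth scene: tissue regions + matching medium + frequency."""

    scenario: Scenario
    regions: tuple[TissueRegion, ...]
    matching_medium: complex
    frequency: float = DEFAULT_FREQUENCY
    bvf: float = 0.50
    geometry: GeometryParams = field(default_factory=GeometryParams)

    def region(self, label: str) -> TissueRegion:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)

    @property
    def skin_contour(self) -> np.ndarray:
        return self.region("skin").contour

    def contours(self) -> dict[str, np.ndarray]:
        return {r.label: r.contour for r in self.regions}


def _ellipse(
    a: float,
    b: float,
    n: int,
    center: tuple[float, float] = (0.0, 0.0),
    perturb_amplitude: float = 0.0,
    perturb_order: int = 3,
    perturb_phase: float = 0.0,
) -> np.ndarray:
    """CCW polyline of an (optionally cosine-perturbed) ellipse."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    scale = 1.0 + perturb_amplitude * np.cos(perturb_order * theta + perturb_phase)
    x = center[0] + a * scale * np.cos(theta)
    y = center[1] + b * scale * np.sin(theta)
    return np.column_stack([x, y])


def _circle(center: tuple[float, float], r: float, n: int) -> np.ndarray:
    return _ellipse(r, r, n, center=center)


def make_leg_phantom(
    scenario: Scenario = "thin_fat",
    geometry_params: GeometryParams | None = None,
    bvf: float = 0.50,
    matching_medium: complex | str = "glycerin_water",
    frequency: float = DEFAULT_FREQUENCY,
) -> PhantomModel:
    """Build a parametric leg cross-section phantom.

    Parameters
    ----------
    scenario : {"thin_fat", "medium_fat", "thick_fat"}
        Fat-ring thickness class; per-scenario defaults are used unless
        ``geometry_params`` overrides them.
    geometry_params : GeometryParams, optional
        Explicit geometry; defaults depend on ``scenario``.
    bvf : float
        Bone volume fraction applied to both bones (maps to bone
        permittivity through :func:`bvf_to_permittivity`).
    matching_medium : complex or {"glycerin_water", "gel"}
        Background medium permittivity.
    frequency : float
        Operating frequency in Hz (0.8 GHz by default).

    Raises
    ------
    InvalidGeometryError
        If the rings degenerate or a bone leaves the muscle region.
    """
    if scenario not in SCENARIO_GEOMETRY:
        raise ValueError(f"unknown scenario {scenario!r}")
    g = geometry_params if geometry_params is not None else SCENARIO_GEOMETRY[scenario]
    if isinstance(matching_medium, str):
        try:
            medium = MATCHING_MEDIA[matching_medium]
        except KeyError:
            raise ValueError(f"unknown matching medium {matching_medium!r}") from None
    else:
        medium = complex(matching_medium)

    a_fat = g.outer_a - g.skin_thickness
    b_fat = g.outer_b - g.skin_thickness
    a_mus = a_fat - g.fat_thickness
    b_mus = b_fat - g.fat_thickness
    if min(a_fat, b_fat, a_mus, b_mus) <= 0:
        raise InvalidGeometryError("skin/fat thickness exceeds the leg radius")

    pk = dict(
        perturb_amplitude=g.perturb_amplitude,
        perturb_order=g.perturb_order,
        perturb_phase=g.perturb_phase,
    )
    skin = _ellipse(g.outer_a, g.outer_b, g.n_points, **pk)
    fat = _ellipse(a_fat, b_fat, g.n_points, **pk)
    muscle = _ellipse(a_mus, b_mus, g.n_points, **pk)
    n_bone = max(32, g.n_points // 2)
    tibia = _circle(g.tibia_center, g.tibia_radius, n_bone)
    fibula = _circle(g.fibula_center, g.fibula_radius, n_bone)

    poly_muscle = Polygon(muscle)
    poly_tibia = Polygon(tibia)
    poly_fibula = Polygon(fibula)
    if not poly_muscle.contains(poly_tibia):
        raise InvalidGeometryError("tibia is not strictly inside the muscle region")
    if not poly_muscle.contains(poly_fibula):
        raise InvalidGeometryError("fibula is not strictly inside the muscle region")
    if poly_tibia.intersects(poly_fibula):
        raise InvalidGeometryError("tibia and fibula overlap")
    if not Polygon(fat).contains(poly_muscle) or not Polygon(skin).contains(Polygon(fat)):
        raise InvalidGeometryError("ring contours are not properly nested")

    eps_bone = bvf_to_permittivity(bvf)
    regions = (
        TissueRegion("skin", skin, TISSUE_PERMITTIVITY["skin"]),
        TissueRegion("fat", fat, TISSUE_PERMITTIVITY["fat"]),
        TissueRegion("muscle", muscle, TISSUE_PERMITTIVITY["muscle"]),
        TissueRegion("tibia", tibia, eps_bone),
        TissueRegion("fibula", fibula, eps_bone),
    )
    return PhantomModel(
        scenario=scenario,
        regions=regions,
        matching_medium=medium,
        frequency=frequency,
        bvf=bvf,
        geometry=g,
    )


# Innermost-first order for point queries: a point on a shared boundary
# resolves to the inner region.
_QUERY_ORDER = ("tibia", "fibula", "muscle", "fat", "skin")


def permittivity_at(model: PhantomModel, point: Sequence[float]) -> complex:
    """Permittivity of the innermost region containing ``point``.

    Points outside the skin contour get the matching-medium value;
    points exactly on a boundary resolve to the inner region.
    """
    p = Point(float(point[0]), float(point[1]))
    for label in _QUERY_ORDER:
        if model.region(label).polygon().covers(p):
            return model.region(label).permittivity
    return model.matching_medium


def permittivities_at(model: PhantomModel, points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`permittivity_at` for an (M, 2) point array."""
    from shapely import contains_xy  # shapely 2.x vectorized predicate

    pts = np.asarray(points, dtype=float)
    out = np.full(len(pts), model.matching_medium, dtype=complex)
    # outer-to-inner so inner regions overwrite; tiny buffer gives
    # boundary-inclusive (covers) semantics
    for label in reversed(_QUERY_ORDER):
        poly = model.region(label).polygon().buffer(1e-12)
        mask = contains_xy(poly, pts[:, 0], pts[:, 1])
        out[mask] = model.region(label).permittivity
    return out


# ---------------------------------------------------------------------------
# serialization

def save_phantom_config(model: PhantomModel, path: str | Path) -> None:
    """Write phantom parameters (not contours) as a YAML config."""
    g = model.geometry
    cfg = {
        "scenario": model.scenario,
        "bvf": float(model.bvf),
        "matching_medium": {
            "real": float(model.matching_medium.real),
            "imag": float(model.matching_medium.imag),
        },
        "frequency": float(model.frequency),
        "geometry": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in dataclasses.asdict(g).items()},
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_phantom_config(path: str | Path) -> PhantomModel:
    """Rebuild a phantom from a YAML config written by :func:`save_phantom_config`."""
    cfg = yaml.safe_load(Path(path).read_text())
    gd = dict(cfg["geometry"])
    for key in ("tibia_center", "fibula_center"):
        gd[key] = tuple(gd[key])
    mm = cfg["matching_medium"]
    return make_leg_phantom(
        scenario=cfg["scenario"],
        geometry_params=GeometryParams(**gd),
        bvf=cfg["bvf"],
        matching_medium=complex(mm["real"], mm["imag"]),
        frequency=cfg["frequency"],
    )


def export_contours_csv(model: PhantomModel, directory: str | Path) -> list[Path]:
    """Write one ``<label>.csv`` polyline file (x,y in meters) per region."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in model.regions:
        p = directory / f"{r.label}.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x_m", "y_m"])
            for x, y in r.contour:
                w.writerow([f"{x:.9g}", f"{y:.9g}"])
        paths.append(p)
    return paths
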