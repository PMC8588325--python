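"""Shared fixtures: a small dielectric-cylinder scattering scene.

The cylinder scene (ε = 30 − j5, radius λ/3, in a 26 − j18 glycerin/
water background) is the workhorse for forward-solver and inversion
tests: it has an analytic Mie-series solution and is cheap to mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from legtomo.forward import AntennaArray, assemble_operators, collect_scatter_data
from legtomo.meshing import (
    MESH_SIZE_FACTOR,
    TriMesh,
    _boundary_edges,
    characteristic_length,
    delaunay_mesh,
    extract_imaging_domain,
)

EPS_B = 26.0 - 18.0j
EPS_CYL = 30.0 - 5.0j
FREQ = 0.8e9
LAM_B = 3e8 / (FREQ * np.sqrt(EPS_B.real))
CYL_RADIUS = LAM_B / 3.0


def circle(radius: float, n: int = 128) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(th), np.sin(th)])


def disc_mesh(radius: float, h: float, contours=()) -> TriMesh:
    nodes, tris = delaunay_mesh(circle(radius), h, tuple(contours))
    cents = nodes[tris].mean(axis=1)
    tags = np.zeros(len(tris), dtype=int)
    for c in contours:
        r_c = np.linalg.norm(c, axis=1).mean()
        tags[np.linalg.norm(cents, axis=1) < r_c] = 4
    return TriMesh(nodes, tris, tags, _boundary_edges(tris), h)


def ring_antennas(radius: float, count: int, phase: float = 0.0) -> AntennaArray:
    th = np.linspace(0.0, 2.0 * np.pi, count, endpoint=False) + phase
    return AntennaArray(radius * np.column_stack([np.cos(th), np.sin(th)]), 0.0)


@dataclass
class CylinderScene:
    """Everything needed to test forward solves and inversion on the
    analytic cylinder: decoupled fine/coarse meshes, operators, data."""

    mesh_fwd: TriMesh
    mesh_inv: TriMesh
    domain: object
    antennas: AntennaArray
    ops_fwd: object      # homogeneous background on the fine mesh
    ops_inv: object      # homogeneous background + imaging domain, coarse mesh
    eps_scene_fwd: np.ndarray   # per-triangle scene on the fine mesh
    data: object                # scattered data from the fine mesh


@pytest.fixture(scope="session")
def cylinder() -> CylinderScene:
    a = CYL_RADIUS
    r_ant = 2.0 * a
    R = r_ant + LAM_B / 2.0
    h_fwd = MESH_SIZE_FACTOR * characteristic_length(FREQ, EPS_CYL.real)
    h_inv = MESH_SIZE_FACTOR * 10.0 / 9.0 * characteristic_length(FREQ, EPS_CYL.real)

    mesh_fwd = disc_mesh(R, h_fwd, [circle(a)])
    mesh_inv = disc_mesh(R, h_inv)
    domain = extract_imaging_domain(mesh_inv, circle(1.5 * a, 64))
    antennas = ring_antennas(r_ant, 8, phase=0.1)

    ops_fwd = assemble_operators(mesh_fwd, EPS_B, FREQ, antennas)
    ops_inv = assemble_operators(mesh_inv, EPS_B, FREQ, antennas, domain=domain)
    eps_scene = np.where(mesh_fwd.region_tags == 4, EPS_CYL, EPS_B)
    data = collect_scatter_data(ops_fwd, eps_scene)
    return CylinderScene(
        mesh_fwd=mesh_fwd, mesh_inv=mesh_inv, domain=domain, antennas=antennas,
        ops_fwd=ops_fwd, ops_inv=ops_inv, eps_scene_fwd=eps_scene, data=data)


@pytest.fixture(scope="session")
def thin_phantom():
    from legtomo.phantoms import make_leg_phantom

    return make_leg_phantom("thin_fat", bvf=0.50)
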