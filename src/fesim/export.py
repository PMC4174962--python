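"""Exports: fibre voltage profiles (CSV), field snapshots (legacy VTK),
membrane traces (CSV) and boundary surfaces (OBJ via trimesh)."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .fiber import SimulationTrace
from .field import FieldSolution
from .geometry import VolumeModelSpec

__all__ = [
    "profile_frame",
    "write_profile_csv",
    "write_trace_csv",
    "write_field_vtk",
    "write_boundary_surfaces",
]


def profile_frame(points_m: np.ndarray, values_V_per_A: np.ndarray) -> pd.DataFrame:
    """Tidy frame of a sampled voltage profile along a trajectory."""
    p = np.asarray(points_m, dtype=float)
    arclength = np.concatenate(
        ([0.0], np.cumsum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
    )
    return pd.DataFrame({
        "arclength_mm": arclength * 1e3,
        "Ve_V_per_A": np.asarray(values_V_per_A, dtype=float),
    })


def write_profile_csv(path, points_m, values_V_per_A) -> None:
    profile_frame(points_m, values_V_per_A).to_csv(path, index=False)


def write_trace_csv(path, trace: SimulationTrace) -> None:
    """Membrane trace in long form: time_ms, node_index, V_mV."""
    n_t, n_nodes = trace.V_mV.shape
    df = pd.DataFrame({
        "time_ms": np.repeat(trace.times_ms, n_nodes),
        "node_index": np.tile(np.arange(n_nodes), n_t),
        "V_mV": trace.V_mV.ravel(),
    })
    df.to_csv(path, index=False)


def write_field_vtk(path, solution: FieldSolution) -> None:
    """Legacy-ASCII VTK structured grid of the potential (V per A).

    Points are the cell centres in Cartesian coordinates; readable by any
    VTK-based viewer.
    """
    g = solution.domain.grid
    pts = g.cell_centers()  # (N, 3), C order with the z index fastest
    n0, n1, n2 = g.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("fesim lead field (V per A)\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {n2} {n1} {n0}\n")
        fh.write(f"POINTS {len(pts)} float\n")
        np.savetxt(fh, pts, fmt="%.6e")
        fh.write(f"POINT_DATA {len(pts)}\n")
        fh.write("SCALARS potential float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, solution.potential.ravel()[:, None], fmt="%.6e")


def _surface_mesh(radius_fn, length_m: float, n_theta: int = 96, n_z: int = 33):
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    z = np.linspace(-length_m / 2.0, length_m / 2.0, n_z)
    T, Z = np.meshgrid(theta, z, indexing="ij")
    R = radius_fn(T, Z)
    verts = np.column_stack([
        (R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), Z.ravel()
    ])
    faces = []
    for i in range(n_theta):
        i2 = (i + 1) % n_theta
        for k in range(n_z - 1):
            a = i * n_z + k
            b = i2 * n_z + k
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    return verts, np.asarray(faces)


def write_boundary_surfaces(path, model: VolumeModelSpec) -> None:
    """Triangulated tissue-boundary surfaces as a Wavefront OBJ scene."""
    import trimesh

    L = model.axial_length_cm * 1e-2
    scene = trimesh.Scene()
    if model.representation == "PM":
        bounds = model.layer_radii_cm * 1e-2
        W = model.width_cm * 1e-2
        for name, y in zip(("bone_outer", "muscle_outer", "fat_outer", "skin_outer"),
                           bounds[1:]):
            verts = np.array([
                [-W / 2, y, -L / 2], [W / 2, y, -L / 2],
                [W / 2, y, L / 2], [-W / 2, y, L / 2],
            ])
            faces = np.array([[0, 1, 2], [0, 2, 3]])
            scene.add_geometry(trimesh.Trimesh(verts, faces), node_name=name)
    else:
        for name in ("bone_outer", "muscle_outer", "fat_outer", "skin_outer"):
            if name == "bone_outer":
                r0 = model.base_boundary_radius_cm(name) * 1e-2
                bx, by = (v * 1e-3 for v in model.bone_offset_mm)

                def rf(T, Z, r0=r0, bx=bx, by=by):
                    # off-centre circle in polar form about the model axis
                    along = bx * np.cos(T) + by * np.sin(T)
                    perp2 = bx * bx + by * by - along ** 2
                    return along + np.sqrt(np.maximum(r0 * r0 - perp2, 0.0))
            else:
                def rf(T, Z, name=name):
                    return model.boundary_radius_m(name, T, Z)
            verts, faces = _surface_mesh(rf, L)
            scene.add_geometry(trimesh.Trimesh(verts, faces), node_name=name)
        for inc in model.inclusions:
            cx, cy = (v * 1e-3 for v in inc.axis_offset_mm)
            r = inc.radius_mm * 1e-3
            cyl = trimesh.creation.cylinder(radius=r, height=L, sections=48)
            cyl.apply_translation([cx, cy, 0.0])
            scene.add_geometry(cyl, node_name=inc.kind)
    scene.export(str(path))
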