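"""Deterministic synthetic fixtures for the analysis and mesh estimators.

Each fixture emulates one slice of simulator output with known ground
truth, so that every estimator can be validated in closed loop:

* ``toy_mesh`` -- small cylinder and icosphere membranes (curvature and
  remeshing oracles know the closed-form answers);
* ``exp_series`` -- exponentially growing stem-cell counts with optional
  lognormal noise and a configurable doubling time;
* ``scripted_trajectory`` -- a sequence of observation records with a
  prescribed turnover pattern, compression samples and a Paneth-cell
  cluster that splits into two at a chosen observation (one fission
  event by construction);
* ``ode_table`` -- a (time, area, crypt count) table from the
  density-controlled growth model.

All fixtures are pure functions of ``seed``; the same seed yields
byte-identical results.
"""

from __future__ import annotations

import math
from types import SimpleNamespace

import numpy as np

from .analytic import AnalyticParams, density_controlled_trajectory
from .mesh import BMNetwork, build_cylinder_mesh

__all__ = ["make_fixture", "icosphere_mesh"]


def icosphere_mesh(radius: float = 10.0, subdivisions: int = 3,
                   **mesh_kwargs) -> BMNetwork:
    """Subdivided-icosahedron sphere mesh with outward normals.

    The luminal side is the interior, so knot curvature is +1/radius.
    """
    phi = (1 + math.sqrt(5)) / 2
    verts = np.array([
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ], dtype=float)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    verts = list(verts)
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in cache:
            m = verts[i] + verts[j]
            verts.append(m / np.linalg.norm(m))
            cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(subdivisions):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c),
                          (ab, bc, ca)]
        faces = new_faces
    knots = radius * np.asarray(verts)
    tris = np.asarray(faces, dtype=np.int64)
    # orient normals outward
    p = knots[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = np.einsum("ij,ij->i", n, p.mean(axis=1)) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    edge = np.median(np.linalg.norm(knots[tris[:, 0]] - knots[tris[:, 1]], axis=1))
    mesh_kwargs.setdefault("l_min", 0.3 * edge)
    mesh_kwargs.setdefault("l_max", 2.0 * edge)
    return BMNetwork(knots, tris, **mesh_kwargs)


def _exp_series(rng, t_d_days: float = 2.0, n0: float = 8.0,
                sigma: float = 0.0, n_obs: int = 100,
                dt_days: float = 0.05):
    times = np.arange(n_obs) * dt_days
    counts = n0 * 2.0 ** (times / t_d_days)
    if sigma > 0:
        counts = counts * rng.lognormal(0.0, sigma, size=n_obs)
    return times, counts


def _scripted_trajectory(rng, n_obs: int = 60, turnover_per_obs: int = 1,
                         split_at: int = 25, compression: float = 0.08,
                         n_sc: int = 25):
    """Observation records with one PC cluster splitting into two.

    Ten PCs start as one tight cluster; from ``split_at`` on, two halves
    (5 + 5 members) move apart and stay separated, producing exactly one
    fission event for any persistence window that fits in the tail.
    """
    records = []
    ids = np.arange(10)
    for k in range(n_obs):
        if k < split_at:
            centers = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        else:
            gap = 30.0 + 2.0 * (k - split_at)
            centers = np.array([[-gap / 2, 0, 0], [gap / 2, 0, 0]])
        pos = np.concatenate([
            centers[0] + rng.normal(0, 1.0, (5, 3)),
            centers[1] + rng.normal(0, 1.0, (5, 3)),
        ])
        records.append(SimpleNamespace(
            time=1.2 * k,
            turnover_increment=turnover_per_obs,
            sc_compression=np.full(n_sc, compression),
            pc_ids=ids.copy(),
            pc_pos=pos,
            census={"SC": n_sc, "PC": 10, "GC": 0, "pseudoGC": 0,
                    "EC": 0, "FIB": 0},
        ))
    return records


def make_fixture(kind: str, seed: int = 0, **kwargs):
    """Deterministic fixture factory.

    ``kind`` is one of ``toy_mesh``, ``exp_series``,
    ``scripted_trajectory``, ``ode_table``; unknown kinds raise
    ValueError.  Keyword arguments tune the fixture (see the private
    builders for the accepted names).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1D0]))
    if kind == "toy_mesh":
        shape = kwargs.pop("shape", "cylinder")
        if shape == "cylinder":
            return build_cylinder_mesh(
                kwargs.pop("radius", 10.0), kwargs.pop("length", 30.0),
                kwargs.pop("target_edge", 4.0), **kwargs)
        if shape == "sphere":
            return icosphere_mesh(**kwargs)
        raise ValueError(f"unknown toy_mesh shape {shape!r}")
    if kind == "exp_series":
        return _exp_series(rng, **kwargs)
    if kind == "scripted_trajectory":
        return _scripted_trajectory(rng, **kwargs)
    if kind == "ode_table":
        import pandas as pd

        p = kwargs.pop("params", AnalyticParams())
        traj = density_controlled_trajectory(
            p, kwargs.pop("t_end", 20.0), kwargs.pop("dt", 1e-2))
        return pd.DataFrame({
            "time": traj.times, "A": traj.A, "N_C": traj.N_C,
            "n_C": traj.n_C, "c": traj.c, "t_d": traj.t_d_analytic,
        })
    raise ValueError(f"unknown fixture kind {kind!r}")
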