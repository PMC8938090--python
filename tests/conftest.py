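"""Shared fixtures: parametric tube meshes and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from laametrics.io import SurfaceMesh


def sweep_tube(curve_fn, n_s=80, n_ring=48, radius=5.0,
               radius_fn=None) -> SurfaceMesh:
    """Sweep a circular section along ``curve_fn: [0,1] -> R^3``.

    The tube is open at t=0 (the first ring is the ostium rim) and closed
    by a hemispherical cap of the local radius at t=1. ``radius_fn(t)``
    optionally modulates the section radius.
    """
    ts = np.linspace(0.0, 1.0, n_s)
    pts = np.array([curve_fn(t) for t in ts])
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    n0 = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(n0, tang[0])) > 0.9:
        n0 = np.array([0.0, 0.0, 1.0])
    n0 = n0 - tang[0] * np.dot(n0, tang[0])
    n0 /= np.linalg.norm(n0)
    normals = [n0]
    for i in range(1, n_s):
        v = np.cross(tang[i - 1], tang[i])
        if np.linalg.norm(v) < 1e-12:
            normals.append(normals[-1])
            continue
        ang = np.arcsin(np.clip(np.linalg.norm(v), -1.0, 1.0))
        v = v / np.linalg.norm(v)
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        normals.append(R @ normals[-1])
    normals = np.array(normals)
    binorm = np.cross(tang, normals)
    rads = np.array([radius * (radius_fn(t) if radius_fn else 1.0)
                     for t in ts])
    th = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    verts = [pts[i] + rads[i] * (np.outer(np.cos(th), normals[i])
                                 + np.outer(np.sin(th), binorm[i]))
             for i in range(n_s)]
    # hemispherical tip rings
    n_cap = 8
    r_tip = rads[-1]
    for k in range(1, n_cap):
        phi = 0.5 * np.pi * k / n_cap
        centre = pts[-1] + tang[-1] * r_tip * np.sin(phi)
        verts.append(centre + r_tip * np.cos(phi)
                     * (np.outer(np.cos(th), normals[-1])
                        + np.outer(np.sin(th), binorm[-1])))
    verts = np.vstack(verts)
    apex = pts[-1] + tang[-1] * r_tip
    verts = np.vstack([verts, apex])
    ai = len(verts) - 1
    n_rows = n_s + n_cap - 1
    faces = []
    for i in range(n_rows - 1):
        for j in range(n_ring):
            a = i * n_ring + j
            b = i * n_ring + (j + 1) % n_ring
            c = (i + 1) * n_ring + j
            d = (i + 1) * n_ring + (j + 1) % n_ring
            faces += [[a, b, d], [a, d, c]]
    last = (n_rows - 1) * n_ring
    for j in range(n_ring):
        faces.append([last + j, last + (j + 1) % n_ring, ai])
    return SurfaceMesh(np.array(verts), np.array(faces, dtype=int),
                       np.arange(n_ring))


@pytest.fixture(scope="session")
def cylinder_mesh() -> SurfaceMesh:
    """Straight tube along +y, radius 5, total extent 40 mm incl. tip."""
    return sweep_tube(lambda t: np.array([0.0, 35.0 * t, 0.0]), radius=5.0)


@pytest.fixture(scope="session")
def quarter_torus_mesh() -> SurfaceMesh:
    """Quarter-circle tube, ring radius 20 mm, tube radius 4 mm."""

    def curve(t):
        a = t * np.pi / 2.0
        return np.array([20.0 * (1 - np.cos(a)), 20.0 * np.sin(a), 0.0])

    return sweep_tube(curve, radius=4.0)


@pytest.fixture(scope="session")
def laa_subject():
    """One mild, well-resolved synthetic appendage with its ground truth."""
    from laametrics.synthetic import build_laa_mesh

    params = {"D_max": 26.0, "D_min": 17.0, "centreline_length": 36.0,
              "tortuosity": 0.85, "bending_angle": 120.0, "LAA_volume": 7.0,
              "TAWSS": 0.31, "OSI": 0.15, "Vel_over_LAAv": 0.99,
              "stagnation_pct": 12.39}
    mesh, gt = build_laa_mesh(params, edge_length=0.5)
    return params, mesh, gt


@pytest.fixture(scope="session")
def small_cohort_df():
    from laametrics.synthetic import default_spec, sample_cohort_params

    return sample_cohort_params(default_spec(), seed=42)
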