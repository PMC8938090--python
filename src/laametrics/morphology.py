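"""Morphological characterization of the left atrial appendage.

Everything is computed in a common reference frame in which the ostium
plane coincides with the zx-plane, the appendage body extends toward +y,
the rim centroid sits at the origin, and the maximum ostium diameter runs
along x. The indices mirror the standard LAA morphometric set: ostium
diameters/area/perimeter/eccentricity, appendage volume and wall area,
neck height, distal point length, anterior/posterior extents, and the
centreline-derived length, tortuosity (chord/arc, lower = more winding)
and bending angle (180 deg = straight).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, cKDTree

from .config import PipelineConfig, log_stage
from .io import MeshFormatError, SurfaceMesh, _triangle_areas

__all__ = [
    "OstiumMetrics", "Centreline", "MorphoFeatures",
    "align_to_ostium_frame", "ostium_metrics", "extract_centreline",
    "centreline_metrics", "appendage_extents", "mesh_measures",
    "region_partition", "cap_ostium", "compute_morpho_features",
]

REGION_NAMES = ("inferior", "middle", "superior")


@dataclasses.dataclass
class OstiumMetrics:
    D_max: float          # mm, max pairwise rim distance
    D_min: float          # mm, minimal caliper width of the projected rim
    D_mean: float         # mm, (D_max + D_min)/2
    r_min: float          # mm, min centroid-to-rim distance
    area: float           # mm^2, planar polygon area
    perimeter: float      # mm
    eccentricity: float   # 1 - D_min/D_max
    centroid: np.ndarray  # O_LAA, 3D


@dataclasses.dataclass
class Centreline:
    points: np.ndarray    # (n, 3) ordered, ostium centre -> tip, mm
    arc_length: float     # mm
    tortuosity: float     # chord/arc in (0, 1]
    bending_angle: float  # degrees, 180 = straight


@dataclasses.dataclass
class MorphoFeatures:
    """The full per-subject morphological feature vector."""

    D_max: float
    D_min: float
    D_mean: float
    r_min: float
    ostium_area: float
    ostium_perimeter: float
    eccentricity: float
    LAA_volume: float       # ml
    LAA_area: float         # mm^2, ostium cap excluded
    h_LAA: float            # mm, neck height (extent above ostium plane)
    h_theta: float          # mm, distal point length (max distance from O_LAA)
    d_A: float              # mm, anterior extent from centre of mass
    d_P: float              # mm, posterior extent
    d_AP: float             # mm, d_A + d_P
    centreline_length: float
    tortuosity: float
    bending_angle: float
    LA_volume: float = float("nan")       # ml, carried metadata if known
    ratio_LAAv_LAv: float = float("nan")
    shape_label: str | None = None        # chicken-wing / non-chicken-wing

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _rim_plane(rim_points: np.ndarray):
    """Least-squares plane through the rim: (centroid, unit normal)."""
    c = rim_points.mean(axis=0)
    centred = rim_points - c
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise MeshFormatError("ostium rim is degenerate (collinear points)")
    return c, vt[2]


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 deg flip about any axis orthogonal to a
        axis = np.eye(3)[np.argmin(np.abs(a))]
        axis = axis - a * np.dot(axis, a)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def align_to_ostium_frame(mesh: SurfaceMesh):
    """Rigidly move the mesh into the common ostium-aligned frame.

    After alignment the least-squares rim plane has normal +y with the
    appendage body on the +y side, the rim centroid is at the origin, and
    the maximum-diameter direction of the rim lies along x (sign chosen so
    the body's centre of mass has non-negative x). Returns the aligned
    mesh and the 4x4 rigid transform that was applied.
    """
    rim = mesh.rim_points()
    c, normal = _rim_plane(rim)
    body = mesh.vertices.mean(axis=0)
    if np.dot(normal, body - c) < 0:
        normal = -normal
    R1 = _rotation_between(normal, np.array([0.0, 1.0, 0.0]))

    # in-plane rotation: put the rim's major principal axis (the
    # max-diameter direction for elliptical rims, and a numerically stable
    # proxy for irregular ones) along x
    rim1 = (rim - c) @ R1.T
    uv = rim1[:, [0, 2]]                       # (x, z) in-plane coords
    cov = np.cov(uv.T)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    ang = np.arctan2(direction[1], direction[0])   # angle from +x toward +z
    # rotate about y by +ang to bring the axis onto the x axis
    ca, sa = np.cos(ang), np.sin(ang)
    R2 = np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])
    R = R2 @ R1

    body_x = float((R @ (body - c))[0])
    if body_x < -1e-9 or (abs(body_x) <= 1e-9 and abs(ang) > np.pi / 2):
        flip = np.diag([-1.0, 1.0, -1.0])      # 180 deg about y
        R = flip @ R

    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = -R @ c
    aligned = mesh.transformed(T)
    log_stage("align_to_ostium_frame", input_hash=mesh.content_hash())
    return aligned, T


def require_aligned(mesh: SurfaceMesh, tol: float = 1e-6) -> None:
    rim = mesh.rim_points()
    scale = max(np.abs(rim).max(), 1.0)
    if np.abs(rim[:, 1]).max() > tol * scale or \
            np.linalg.norm(rim.mean(axis=0)) > tol * scale:
        raise ValueError("mesh is not in the ostium-aligned frame; "
                         "run align_to_ostium_frame first")


# ---------------------------------------------------------------------------
# ostium metrics
# ---------------------------------------------------------------------------

def ostium_metrics(rim_points: np.ndarray) -> OstiumMetrics:
    """Characterize the ostium from its ordered rim loop (>= 16 points).

    D_max is the maximum pairwise distance between rim points, D_min the
    minimal rotating-caliper width of the rim projected onto its
    least-squares plane (a genuinely different quantity from the minimal
    centroid chord), r_min the minimal centroid-to-rim distance, and the
    area/perimeter come from the projected polygon.
    """
    rim_points = np.asarray(rim_points, dtype=float)
    if len(rim_points) < 16:
        raise ValueError("need >= 16 ordered rim points")
    c, normal = _rim_plane(rim_points)
    centred = rim_points - c
    # orthonormal in-plane basis
    e1 = centred[0] - np.dot(centred[0], normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    uv = np.column_stack([centred @ e1, centred @ e2])

    from shapely.geometry import Polygon

    poly = Polygon(uv)
    if not poly.is_valid:
        raise ValueError("rim polygon is self-intersecting")

    hull_pts = uv[ConvexHull(uv).vertices]
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    D_max = float(np.sqrt((diff ** 2).sum(-1).max()))
    D_min = _min_caliper_width(hull_pts)
    closed = np.vstack([uv, uv[:1]])
    perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    area = float(poly.area)
    r_min = float(np.linalg.norm(uv, axis=1).min())
    return OstiumMetrics(
        D_max=D_max, D_min=D_min, D_mean=0.5 * (D_max + D_min), r_min=r_min,
        area=area, perimeter=perimeter, eccentricity=1.0 - D_min / D_max,
        centroid=c,
    )


def _min_caliper_width(hull_pts: np.ndarray) -> float:
    """Minimal width over rotations; attained orthogonal to a hull edge."""
    edges = np.roll(hull_pts, -1, axis=0) - hull_pts
    lengths = np.linalg.norm(edges, axis=1)
    edges = edges[lengths > 1e-12] / lengths[lengths > 1e-12, None]
    normals = np.column_stack([-edges[:, 1], edges[:, 0]])
    proj = hull_pts @ normals.T                     # (n_pts, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


# ---------------------------------------------------------------------------
# volume / area / cap
# ---------------------------------------------------------------------------

def cap_ostium(mesh: SurfaceMesh) -> SurfaceMesh:
    """Close the ostium with a triangle fan from the rim centroid."""
    if mesh.is_capped:
        return mesh
    centre = mesh.rim_points().mean(axis=0)
    vertices = np.vstack([mesh.vertices, centre[None, :]])
    ci = len(mesh.vertices)
    rim = mesh.ostium_rim
    fan = np.array([[rim[i], ci, rim[(i + 1) % len(rim)]]
                    for i in range(len(rim))])
    faces = np.vstack([mesh.faces, fan])
    capped = SurfaceMesh(vertices, faces, rim, is_capped=True,
                         cap_faces=np.arange(len(mesh.faces), len(faces)))
    tm = capped.to_trimesh()
    if not tm.is_watertight:
        raise MeshFormatError("capping the ostium did not yield a watertight mesh")
    if tm.volume < 0:  # flip cap orientation if winding disagrees with wall
        faces[len(mesh.faces):] = fan[:, ::-1]
        capped = dataclasses.replace(capped, faces=faces)
    return capped


def mesh_measures(capped_mesh: SurfaceMesh):
    """(volume in ml, wall surface area in mm^2) of a capped appendage.

    Volume uses the signed-tetrahedra formula on the watertight surface;
    the area sums wall triangles only, excluding the ostium cap.
    """
    if not capped_mesh.is_capped:
        raise MeshFormatError("mesh_measures requires a capped (watertight) mesh")
    tm = capped_mesh.to_trimesh()
    if not tm.is_watertight:
        raise MeshFormatError("capped mesh is not watertight")
    volume_ml = abs(float(tm.volume)) / 1000.0     # mm^3 -> ml
    wall = capped_mesh.wall_faces()
    area = float(_triangle_areas(capped_mesh.vertices,
                                 capped_mesh.faces[wall]).sum())
    return volume_ml, area


# ---------------------------------------------------------------------------
# extents
# ---------------------------------------------------------------------------

def appendage_extents(aligned_mesh: SurfaceMesh):
    """(h_LAA, h_theta, d_A, d_P, d_AP) in the ostium-aligned frame.

    p_mass is the volume-weighted centroid of the capped appendage; the
    anterior/posterior extents are measured from p_mass to the most distal
    wall points along +x / -x, the neck height h_LAA is the perpendicular
    extent above the ostium plane and h_theta the maximal distance of any
    wall point from the ostium centre O_LAA (the origin).
    """
    require_aligned(aligned_mesh)
    capped = cap_ostium(aligned_mesh)
    p_mass = np.asarray(capped.to_trimesh().center_mass)
    v = aligned_mesh.vertices
    d_A = float(v[:, 0].max() - p_mass[0])
    d_P = float(p_mass[0] - v[:, 0].min())
    h_LAA = float(v[:, 1].max())
    h_theta = float(np.linalg.norm(v, axis=1).max())
    return h_LAA, h_theta, d_A, d_P, d_A + d_P


# ---------------------------------------------------------------------------
# centreline
# ---------------------------------------------------------------------------

_NEIGH = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)])


def extract_centreline(mesh: SurfaceMesh,
                       config: PipelineConfig | None = None) -> Centreline:
    """Extract the interior centreline from the ostium centre to the tip.

    The lumen is voxelized and flood-filled; a Dijkstra path from the
    ostium centre to the tip is traced through the interior with step cost
    inversely weighted by the distance-to-wall field, so the path follows
    the medial ridge. The tip is the wall vertex farthest (geodesically
    along the wall graph) from the rim. The raw voxel path is smoothed and
    resampled at a fixed spacing.
    """
    config = config or PipelineConfig()
    capped = cap_ostium(mesh)
    pitch = config.centreline_voxel_pitch
    o_laa = mesh.rim_points().mean(axis=0)

    # shift the grid by an irrational sub-voxel offset so that meshes whose
    # aligned coordinates sit exactly on rounding boundaries (tiny fp
    # differences between poses) still voxelize identically
    offset = pitch * np.array([0.31459, 0.27183, 0.16180])
    tm = capped.to_trimesh()
    tm.apply_translation(offset)
    vg = tm.voxelized(pitch).fill()
    mask = np.asarray(vg.matrix, dtype=bool)
    if mask.sum() < 8:
        raise MeshFormatError("voxelized interior is empty; mesh may be non-manifold")

    filled = np.argwhere(mask)
    ids = -np.ones(mask.shape, dtype=np.int64)
    ids[tuple(filled.T)] = np.arange(len(filled))
    centres = trimesh.transform_points(filled.astype(float),
                                       vg.transform) - offset

    rows, cols, lengths = [], [], []
    for off in _NEIGH:
        nb = filled + off
        ok = np.all((nb >= 0) & (nb < mask.shape), axis=1)
        nb_ids = np.full(len(filled), -1, dtype=np.int64)
        nb_ids[ok] = ids[tuple(nb[ok].T)]
        ok &= nb_ids >= 0
        a = np.nonzero(ok)[0]
        rows.append(a)
        cols.append(nb_ids[a])
        lengths.append(np.full(len(a), np.linalg.norm(off) * pitch))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    lengths = np.concatenate(lengths)
    graph = sparse.csr_matrix((lengths, (rows, cols)),
                              shape=(len(filled), len(filled)))

    tree = cKDTree(centres)
    # seed just inside the lumen, off the cap plane
    start = int(tree.query(o_laa + 0.5 * pitch * _inward_dir(mesh, o_laa))[1])
    # through-lumen geodesic distance from the ostium orders the lumen
    # from neck to tip; the tip is the wall vertex farthest by this metric
    d = dijkstra(graph, indices=start)
    v_off, v_idx = tree.query(mesh.vertices)
    reach = np.isfinite(d[v_idx])
    if not reach.any():
        raise MeshFormatError("no interior path from ostium to tip "
                              "(non-manifold or disconnected lumen)")
    score = np.where(reach, d[v_idx] + v_off, -np.inf)
    # near-ties (within one voxel) are resolved toward the vertex
    # farthest from the ostium centre, stabilizing blunt-tip cases
    near = score >= score.max() - 1.0 * pitch
    radial = np.linalg.norm(mesh.vertices - o_laa, axis=1)
    tip_vertex = int(np.argmax(np.where(near, radial, -np.inf)))
    tip = mesh.vertices[tip_vertex]
    end = int(v_idx[tip_vertex])

    # initial path: Dijkstra on a medial-ridge cost (step length divided by
    # the squared wall distance), which hugs the lumen axis instead of the
    # geometric shortest route
    edt = ndimage.distance_transform_edt(mask) * pitch
    edt_filled = edt[tuple(filled.T)]
    inv = 1.0 / (edt_filled + 0.25 * pitch)
    pen = (0.5 * (inv[rows] + inv[cols])) ** 2
    medial = sparse.csr_matrix((lengths * pen, (rows, cols)),
                               shape=graph.shape)
    dist, pred = dijkstra(medial, indices=start, return_predecessors=True)
    if not np.isfinite(dist[end]):
        raise MeshFormatError("no interior path from ostium to tip "
                              "(non-manifold or disconnected lumen)")
    path = [end]
    while path[-1] != start:
        path.append(int(pred[path[-1]]))
    pts = np.vstack([o_laa, centres[path[::-1]], tip])

    # the raw voxel path zigzags and cuts bend corners; smooth, recentre
    # on true cross-sections (slab perpendicular to the path at matched
    # geodesic level), smooth again, and resample
    pts = _smooth_polyline(pts, window=5, iterations=1)
    pts = _recentre_on_sections(pts, centres, tree, edt_filled, d, pitch,
                                iterations=2)
    pts = _smooth_polyline(pts, window=3, iterations=2)
    pts = _resample_polyline(pts, config.centreline_spacing)
    length, tort, bend = centreline_metrics(pts)
    log_stage("extract_centreline", input_hash=mesh.content_hash(),
              pitch=pitch, spacing=config.centreline_spacing)
    return Centreline(points=pts, arc_length=length, tortuosity=tort,
                      bending_angle=bend)


def _inward_dir(mesh: SurfaceMesh, origin: np.ndarray) -> np.ndarray:
    _, normal = _rim_plane(mesh.rim_points())
    body = mesh.vertices.mean(axis=0)
    return normal if np.dot(normal, body - origin) > 0 else -normal


def _recentre_on_sections(pts: np.ndarray, centres: np.ndarray, tree,
                          edt_filled: np.ndarray, d_filled: np.ndarray,
                          pitch: float, iterations: int = 3) -> np.ndarray:
    """Move interior path points to local lumen cross-section centroids.

    For each point, lumen voxels within a thin slab perpendicular to the
    local path direction, within a radius bounded by a multiple of the
    local wall distance, and at a similar through-lumen geodesic level
    (which excludes voxels of other limbs of a hooked appendage) are
    averaged. Endpoints stay fixed.
    """
    for _ in range(iterations):
        out = pts.copy()
        tang = np.gradient(pts, axis=0)
        norms = np.linalg.norm(tang, axis=1)
        tang = tang / np.where(norms > 1e-12, norms, 1.0)[:, None]
        for i in range(1, len(pts) - 1):
            nearest = int(tree.query(pts[i])[1])
            local_edt = edt_filled[nearest]
            local_d = d_filled[nearest]
            rmax = 3.0 * local_edt + pitch
            cand = np.asarray(tree.query_ball_point(pts[i], rmax))
            if len(cand) == 0:
                continue
            lvl = np.abs(d_filled[cand] - local_d) <= \
                2.5 * pitch + 0.6 * local_edt
            cand = cand[lvl]
            if len(cand) < 3:
                continue
            rel = centres[cand] - pts[i]
            proj = rel @ tang[i]
            slab = np.abs(proj) <= 0.75 * pitch
            if slab.sum() < 3:
                continue
            lateral = rel[slab] - np.outer(proj[slab], tang[i])
            out[i] = pts[i] + lateral.mean(axis=0) + \
                tang[i] * proj[slab].mean()
        pts = out
    return pts


def _smooth_polyline(pts: np.ndarray, window: int = 5,
                     iterations: int = 1) -> np.ndarray:
    """Endpoint-preserving moving-average smoothing."""
    half = window // 2
    for _ in range(iterations):
        if len(pts) <= 2 * half:
            break
        out = pts.copy()
        cs = np.vstack([np.zeros(3), np.cumsum(pts, axis=0)])
        for i in range(1, len(pts) - 1):
            lo, hi = max(0, i - half), min(len(pts), i + half + 1)
            out[i] = (cs[hi] - cs[lo]) / (hi - lo)
        pts = out
    return pts


def _resample_polyline(pts: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / spacing)), 2)
    si = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])


def centreline_metrics(points: np.ndarray):
    """(arc length, tortuosity, bending angle in degrees) of a polyline.

    Tortuosity is the chord-to-arc ratio (1 = straight). The bending angle
    is 180 deg minus the angle between the chord of the proximal third and
    the chord of the distal third of the polyline, so a straight line
    scores 180 and a right-angle elbow scores 90.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need >= 3 centreline points")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(s[-1])
    chord = float(np.linalg.norm(points[-1] - points[0]))
    tort = chord / length

    def point_at(si):
        return np.array([np.interp(si, s, points[:, k]) for k in range(3)])

    u = point_at(length / 3.0) - points[0]
    v = points[-1] - point_at(2.0 * length / 3.0)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    bend = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return length, tort, bend


# ---------------------------------------------------------------------------
# regional partition
# ---------------------------------------------------------------------------

def region_partition(mesh: SurfaceMesh, centreline: Centreline) -> np.ndarray:
    """Label each wall vertex inferior/middle/superior (0/1/2).

    The centreline is split at one third and two thirds of its arc length;
    every vertex inherits the third containing its nearest centreline
    point. Inferior is the third adjoining the ostium.
    """
    pts = centreline.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    thirds = np.digitize(s, [s[-1] / 3.0, 2.0 * s[-1] / 3.0])
    _, nearest = cKDTree(pts).query(mesh.vertices)
    labels = thirds[nearest]
    counts = np.bincount(labels, minlength=3)
    if np.any(counts == 0):
        raise ValueError(f"empty region in partition (counts {counts.tolist()}); "
                         "mesh/centreline mismatch")
    return labels


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def compute_morpho_features(mesh: SurfaceMesh,
                            config: PipelineConfig | None = None,
                            la_volume_ml: float = float("nan"),
                            shape_label: str | None = None) -> MorphoFeatures:
    """Run the full morphology pipeline on one subject's mesh."""
    config = config or PipelineConfig()
    aligned, _ = align_to_ostium_frame(mesh)
    om = ostium_metrics(aligned.rim_points())
    capped = cap_ostium(aligned)
    volume, area = mesh_measures(capped)
    h_LAA, h_theta, d_A, d_P, d_AP = appendage_extents(aligned)
    cl = extract_centreline(aligned, config)
    ratio = volume / la_volume_ml if la_volume_ml and np.isfinite(la_volume_ml) \
        else float("nan")
    return MorphoFeatures(
        D_max=om.D_max, D_min=om.D_min, D_mean=om.D_mean, r_min=om.r_min,
        ostium_area=om.area, ostium_perimeter=om.perimeter,
        eccentricity=om.eccentricity, LAA_volume=volume, LAA_area=area,
        h_LAA=h_LAA, h_theta=h_theta, d_A=d_A, d_P=d_P, d_AP=d_AP,
        centreline_length=cl.arc_length, tortuosity=cl.tortuosity,
        bending_angle=cl.bending_angle, LA_volume=la_volume_ml,
        ratio_LAAv_LAv=ratio, shape_label=shape_label,
    )
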