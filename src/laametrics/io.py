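"""Readers, writers and in-memory containers for the pipeline's inputs.

Three kinds of data flow through the pipeline: triangulated LA/LAA wall
surfaces with an identified ostium rim, time-resolved wall shear stress
fields exported by a flow solver, and per-subject feature tables. This
module owns loading, validation and serialisation of all three; downstream
modules only ever see validated containers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from ._vtk import read_vtk_polydata, write_vtk_polydata
from .config import UNITS, array_hash, log_stage

__all__ = [
    "SurfaceMesh",
    "WallFieldSeries",
    "FlowSeries",
    "CohortTable",
    "MeshFormatError",
    "read_surface_mesh",
    "write_surface_mesh",
    "read_wall_series",
    "read_flow_series",
    "write_feature_table",
    "read_cohort_table",
]


class MeshFormatError(ValueError):
    """Raised when an input mesh violates a structural invariant."""


@dataclasses.dataclass
class SurfaceMesh:
    """Triangulated LAA (or LA+LAA) wall geometry in mm.

    The ostium rim — the orifice loop separating appendage from atrial
    body — is carried as an ordered, closed loop of vertex indices; it
    defines the reference plane for all morphometrics. When ``is_capped``
    the ostium is closed by a triangle fan so the surface is watertight and
    volumes are well defined; ``cap_faces`` indexes those cap triangles so
    wall-only areas can exclude them.
    """

    vertices: np.ndarray          # (n, 3) float, mm
    faces: np.ndarray             # (m, 3) int
    ostium_rim: np.ndarray        # ordered rim vertex indices, closed loop
    is_capped: bool = False
    cap_faces: np.ndarray | None = None  # face indices forming the ostium cap

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.ostium_rim = np.asarray(self.ostium_rim, dtype=np.int64)
        if self.cap_faces is not None:
            self.cap_faces = np.asarray(self.cap_faces, dtype=np.int64)

    # -- validation -----------------------------------------------------
    def validate(self, check_rim_simple: bool = True) -> "SurfaceMesh":
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshFormatError("face references a missing vertex")
        if self.faces.min(initial=0) < 0:
            raise MeshFormatError("negative vertex index in faces")
        areas = _triangle_areas(self.vertices, self.faces)
        if np.any(areas <= 1e-12):
            raise MeshFormatError(
                f"{int(np.sum(areas <= 1e-12))} degenerate (zero-area) triangles"
            )
        if len(self.ostium_rim) < 16:
            raise MeshFormatError("ostium rim must be a loop of >= 16 vertices")
        if len(np.unique(self.ostium_rim)) != len(self.ostium_rim):
            raise MeshFormatError("ostium rim revisits a vertex (not a simple loop)")
        if check_rim_simple and _rim_self_intersects(self.rim_points()):
            raise MeshFormatError("ostium rim projects to a self-intersecting polygon")
        if self.is_capped and not self.to_trimesh().is_watertight:
            raise MeshFormatError("capped mesh is not watertight")
        return self

    # -- helpers --------------------------------------------------------
    def rim_points(self) -> np.ndarray:
        return self.vertices[self.ostium_rim]

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def wall_faces(self) -> np.ndarray:
        """Face indices excluding the ostium cap."""
        if self.cap_faces is None or not self.is_capped:
            return np.arange(len(self.faces))
        return np.setdiff1d(np.arange(len(self.faces)), self.cap_faces)

    def transformed(self, matrix: np.ndarray) -> "SurfaceMesh":
        """Return a copy with a 4x4 rigid transform applied to the vertices."""
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        return dataclasses.replace(self, vertices=v)

    def content_hash(self) -> str:
        return array_hash(self.vertices, self.faces, self.ostium_rim)


def _triangle_areas(vertices, faces):
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _rim_self_intersects(points: np.ndarray) -> bool:
    """Check the rim loop projected onto its best-fit plane for crossings."""
    from shapely.geometry import Polygon

    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    uv = centred @ vt[:2].T
    return not Polygon(uv).is_valid


@dataclasses.dataclass
class WallFieldSeries:
    """Per-node wall shear stress vectors (Pa) over simulated beats."""

    times: np.ndarray        # (nt,) s, strictly increasing
    beat_period: float       # s
    n_beats: int
    wss: np.ndarray          # (nt, n_nodes, 3) Pa
    node_ids: np.ndarray     # (n_nodes,) indices into the SurfaceMesh

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.wss = np.asarray(self.wss, dtype=float)
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)

    def validate(self) -> "WallFieldSeries":
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.wss.shape != (len(self.times), len(self.node_ids), 3):
            raise ValueError(
                f"wss shape {self.wss.shape} inconsistent with "
                f"{len(self.times)} timesteps x {len(self.node_ids)} nodes"
            )
        span = self.times[-1] - self.times[0]
        dt = np.median(np.diff(self.times))
        if span + dt * 1.5 < self.n_beats * self.beat_period:
            raise ValueError("time axis does not span n_beats x beat_period")
        return self

    def beat_window_mask(self, window: tuple[int, int]) -> np.ndarray:
        """Boolean mask of timesteps inside a 1-based inclusive beat range."""
        lo = (window[0] - 1) * self.beat_period
        hi = window[1] * self.beat_period
        t = self.times - self.times[0]
        eps = 1e-9 * self.beat_period
        return (t >= lo - eps) & (t <= hi + eps)


@dataclasses.dataclass
class FlowSeries:
    """Ostium flow-rate trace plus intra-LAA velocity samples.

    ``q_ostium`` is signed (ml/s, positive = out of the LAA);
    ``vel_samples`` holds speed magnitudes (m/s) at fixed sample points,
    ``sample_weights`` their volume weights (ml), summing to the LAA volume.
    """

    times: np.ndarray          # (nt,) s
    q_ostium: np.ndarray       # (nt,) ml/s
    vel_samples: np.ndarray    # (nt, n_samples) m/s
    sample_weights: np.ndarray  # (n_samples,) ml
    beat_period: float = 1.0
    n_beats: int = 3

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.q_ostium = np.asarray(self.q_ostium, dtype=float)
        self.vel_samples = np.asarray(self.vel_samples, dtype=float)
        self.sample_weights = np.asarray(self.sample_weights, dtype=float)

    def validate(self, laa_volume_ml: float | None = None) -> "FlowSeries":
        nt = len(self.times)
        if len(self.q_ostium) != nt or self.vel_samples.shape[0] != nt:
            raise ValueError("flow series arrays have inconsistent lengths")
        if self.vel_samples.shape[1] != len(self.sample_weights):
            raise ValueError("sample_weights inconsistent with vel_samples")
        if laa_volume_ml is not None:
            total = float(self.sample_weights.sum())
            if abs(total - laa_volume_ml) > 0.02 * laa_volume_ml:
                raise ValueError(
                    f"sample weights sum to {total:.3f} ml, expected LAA "
                    f"volume {laa_volume_ml:.3f} ml within 2%"
                )
        return self

    def beat_window_mask(self, window: tuple[int, int]) -> np.ndarray:
        lo = (window[0] - 1) * self.beat_period
        hi = window[1] * self.beat_period
        t = self.times - self.times[0]
        eps = 1e-9 * self.beat_period
        return (t >= lo - eps) & (t <= hi + eps)


@dataclasses.dataclass
class CohortTable:
    """Subjects x features with a binary group label (control vs case)."""

    data: pd.DataFrame
    group_col: str = "group"

    def validate(self) -> "CohortTable":
        if self.group_col not in self.data.columns:
            raise ValueError(f"missing group column {self.group_col!r}")
        levels = self.data[self.group_col].dropna().unique()
        if len(levels) != 2:
            raise ValueError(f"group must have exactly 2 levels, got {list(levels)}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names in cohort table")
        return self

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns
                if c not in (self.group_col, "subject_id")]

    def groups(self):
        """Yield (level, sub-frame) for the two group levels, sorted."""
        for level in sorted(self.data[self.group_col].unique()):
            yield level, self.data[self.data[self.group_col] == level]


# ---------------------------------------------------------------------------
# mesh IO
# ---------------------------------------------------------------------------

_MESH_EXTS = {".stl": "stl", ".ply": "ply", ".vtk": "vtk", ".vtp": "vtk"}


def read_surface_mesh(path, format_hint: str | None = None,
                      rim_path=None, validate: bool = True) -> SurfaceMesh:
    """Load an STL/PLY/VTK-polydata surface with its ostium rim.

    The rim is taken from a per-vertex ``ostium_rim`` scalar in the file
    (VTK: 0 = not on rim, k >= 1 = position along the loop) or from a
    separate rim file (CSV with a ``vertex_index`` column, or ``x,y,z``
    point rows matched to the nearest mesh vertex). Units are assumed mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or _MESH_EXTS.get(path.suffix.lower()))
    if fmt is None:
        raise MeshFormatError(f"cannot infer mesh format for {path}")
    rim_order = None
    if fmt == "vtk":
        vertices, faces, point_data = read_vtk_polydata(path)
        if "ostium_rim" in point_data:
            rim_order = point_data["ostium_rim"]
    elif fmt in ("stl", "ply"):
        m = trimesh.load(str(path), file_type=fmt, process=(fmt == "stl"))
        if not isinstance(m, trimesh.Trimesh) or len(m.faces) == 0:
            raise MeshFormatError(f"{path}: no triangulated surface found")
        vertices, faces = np.asarray(m.vertices, float), np.asarray(m.faces)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")

    if rim_path is not None:
        rim = _read_rim_file(rim_path, vertices)
    elif rim_order is not None:
        idx = np.nonzero(rim_order > 0)[0]
        rim = idx[np.argsort(rim_order[idx])]
    else:
        rim = np.array([], dtype=int)

    capped = bool(len(faces)) and trimesh.Trimesh(
        vertices, faces, process=False).is_watertight
    mesh = SurfaceMesh(vertices, faces, rim, is_capped=capped)
    if validate:
        mesh.validate(check_rim_simple=len(rim) >= 16)
        if len(rim) < 16:
            raise MeshFormatError("no usable ostium rim (need >= 16 vertices)")
    log_stage("read_surface_mesh", input_hash=mesh.content_hash(),
              path=str(path), fmt=fmt, unit=UNITS["length"])
    return mesh


def _read_rim_file(rim_path, vertices) -> np.ndarray:
    df = pd.read_csv(rim_path)
    if "vertex_index" in df.columns:
        return df["vertex_index"].to_numpy(dtype=np.int64)
    if not {"x", "y", "z"} <= set(df.columns):
        raise MeshFormatError("rim file needs vertex_index or x,y,z columns")
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    from scipy.spatial import cKDTree

    dist, idx = cKDTree(vertices).query(pts)
    if np.any(dist > 1e-3):
        raise MeshFormatError("rim points do not coincide with mesh vertices")
    return idx.astype(np.int64)


def write_surface_mesh(mesh: SurfaceMesh, path, format_hint=None) -> None:
    """Write STL/PLY/VTK; VTK carries the rim as an ``ostium_rim`` scalar."""
    path = Path(path)
    fmt = format_hint or _MESH_EXTS.get(path.suffix.lower())
    if fmt == "vtk":
        rim_scalar = np.zeros(len(mesh.vertices))
        rim_scalar[mesh.ostium_rim] = np.arange(1, len(mesh.ostium_rim) + 1)
        write_vtk_polydata(path, mesh.vertices, mesh.faces,
                           {"ostium_rim": rim_scalar})
    elif fmt in ("stl", "ply"):
        tm = mesh.to_trimesh()
        if fmt == "stl":
            path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))
        else:
            data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
            path.write_bytes(data if isinstance(data, bytes) else data.encode())
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")


def write_rim_csv(mesh: SurfaceMesh, path) -> None:
    pd.DataFrame({"vertex_index": mesh.ostium_rim}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# wall-field and flow series IO
# ---------------------------------------------------------------------------

def read_wall_series(manifest_path) -> WallFieldSeries:
    """Load a wall shear stress series from a JSON manifest.

    Two layouts are accepted: ``{"wss_csv": f}`` with a long-format CSV
    (columns node, t, tau_x, tau_y, tau_z), or ``{"steps": [{"t": ..,
    "file": ..}, ...]}`` with one VTK point-data file per timestep carrying
    wss_x/wss_y/wss_z scalars. Timesteps are returned time-sorted; node
    counts must be constant across steps.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    beat_period = float(manifest["beat_period"])
    n_beats = int(manifest["n_beats"])
    base = manifest_path.parent

    if "wss_csv" in manifest:
        df = pd.read_csv(base / manifest["wss_csv"])
        need = {"node", "t", "tau_x", "tau_y", "tau_z"}
        if not need <= set(df.columns):
            raise ValueError(f"wss csv must have columns {sorted(need)}")
        times = np.sort(df["t"].unique())
        nodes = np.sort(df["node"].unique())
        counts = df.groupby("t")["node"].count()
        if counts.nunique() != 1:
            raise ValueError("inconsistent node counts between timesteps")
        df = df.sort_values(["t", "node"])
        wss = (df[["tau_x", "tau_y", "tau_z"]].to_numpy()
               .reshape(len(times), len(nodes), 3))
    else:
        steps = sorted(manifest["steps"], key=lambda s: float(s["t"]))
        times, frames = [], []
        n_nodes = None
        for step in steps:
            _, _, pd_arrays = read_vtk_polydata(base / step["file"])
            vec = np.column_stack(
                [pd_arrays["wss_x"], pd_arrays["wss_y"], pd_arrays["wss_z"]])
            if n_nodes is None:
                n_nodes = len(vec)
            elif len(vec) != n_nodes:
                raise ValueError("inconsistent node counts between timesteps")
            times.append(float(step["t"]))
            frames.append(vec)
        times = np.array(times)
        wss = np.stack(frames)
        nodes = np.asarray(manifest.get("node_ids", np.arange(n_nodes)))
    return WallFieldSeries(times, beat_period, n_beats, wss,
                           np.asarray(nodes, dtype=np.int64)).validate()


def write_wall_series(series: WallFieldSeries, outdir, stem="wss") -> Path:
    """Write a series as long-format CSV + JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nt, nn, _ = series.wss.shape
    df = pd.DataFrame({
        "node": np.tile(series.node_ids, nt),
        "t": np.repeat(series.times, nn),
        "tau_x": series.wss[:, :, 0].ravel(),
        "tau_y": series.wss[:, :, 1].ravel(),
        "tau_z": series.wss[:, :, 2].ravel(),
    })
    csv_name = f"{stem}.csv"
    df.to_csv(outdir / csv_name, index=False, float_format="%.9g")
    manifest = {"beat_period": series.beat_period, "n_beats": series.n_beats,
                "wss_csv": csv_name}
    mpath = outdir / f"{stem}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def read_flow_series(manifest_path) -> FlowSeries:
    """Load ostium flow rate + intra-LAA velocity samples from a manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    q = pd.read_csv(base / manifest["flow_csv"]).sort_values("t")
    vel = pd.read_csv(base / manifest["vel_csv"])
    piv = vel.pivot(index="t", columns="sample", values="speed").sort_index()
    if not np.allclose(piv.index.to_numpy(), q["t"].to_numpy()):
        raise ValueError("flow and velocity series have different time axes")
    return FlowSeries(
        times=q["t"].to_numpy(), q_ostium=q["q"].to_numpy(),
        vel_samples=piv.to_numpy(),
        sample_weights=np.asarray(manifest["sample_weights"], float),
        beat_period=float(manifest.get("beat_period", 1.0)),
        n_beats=int(manifest.get("n_beats", 3)),
    ).validate()


def write_flow_series(flow: FlowSeries, outdir, stem="flow") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t": flow.times, "q": flow.q_ostium}).to_csv(
        outdir / f"{stem}_q.csv", index=False, float_format="%.9g")
    nt, ns = flow.vel_samples.shape
    pd.DataFrame({
        "t": np.repeat(flow.times, ns),
        "sample": np.tile(np.arange(ns), nt),
        "speed": flow.vel_samples.ravel(),
    }).to_csv(outdir / f"{stem}_vel.csv", index=False, float_format="%.9g")
    manifest = {
        "flow_csv": f"{stem}_q.csv", "vel_csv": f"{stem}_vel.csv",
        "sample_weights": [float(w) for w in flow.sample_weights],
        "beat_period": flow.beat_period, "n_beats": flow.n_beats,
    }
    mpath = outdir / f"{stem}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(records, path) -> pd.DataFrame:
    """Write per-subject feature records to CSV (one row per subject).

    ``records`` is a sequence of dicts sharing a schema; column order
    follows the first record with ``subject_id`` first. Duplicate subject
    ids are an error. Floats are written at full precision so the table
    round-trips losslessly through ``read_cohort_table``.
    """
    records = list(records)
    if records:
        cols = list(records[0].keys())
        if "subject_id" in cols:
            cols.insert(0, cols.pop(cols.index("subject_id")))
        df = pd.DataFrame.from_records(records)[cols]
    else:
        df = pd.DataFrame(columns=["subject_id"])
    if "subject_id" in df.columns and df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id: {dupes}")
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_cohort_table(path, group_col: str = "group") -> CohortTable:
    # round_trip parsing so write_feature_table -> read is bit-lossless
    df = pd.read_csv(path, float_precision="round_trip")
    return CohortTable(df, group_col=group_col).validate()
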