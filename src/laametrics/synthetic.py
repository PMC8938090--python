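"""Synthetic LAA cohort generator with stored ground truth.

Generates everything the downstream pipeline consumes — surface meshes
with ostium rims, wall shear stress series, ostium flow traces, and
cohort feature tables — from per-group statistical calibration targets
(group means/SDs or medians/ranges for each morphological and
haemodynamic feature). Every generated subject carries a ground-truth
record (exact centreline curve, analytic arc length and volume, per-node
index targets) so parameter recovery is testable end to end.

The default calibration reproduces the control / TIA-CVA group
distributions of the clinical cohort the pipeline was designed around:
ostium diameters around 26/30 mm (control/case), centreline lengths
around 34/39 mm, tortuosity medians near 0.79/0.77, wall TAWSS near
0.31/0.35 Pa, OSI near 0.15/0.17, and washout stagnation percentages of
12.39 / 19.77.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import log_stage
from .io import (FlowSeries, SurfaceMesh, WallFieldSeries, write_feature_table,
                 write_flow_series, write_rim_csv, write_surface_mesh,
                 write_wall_series)

__all__ = [
    "SyntheticSpec", "GroundTruth", "default_spec", "sample_cohort_params",
    "build_laa_mesh", "synthesize_flow", "generate_cohort",
    "make_cohort_table", "MU_BLOOD",
]

#: dynamic viscosity of blood (Pa s) used for the Poiseuille-form WSS scale
MU_BLOOD = 0.0035

# ---------------------------------------------------------------------------
# calibration: per-group marginal distributions
# ---------------------------------------------------------------------------
# ("normal", mean, sd)                -> truncated normal (+-3 SD)
# ("lognormal", median, lo, hi)       -> log-normal matched to median & range
# ("logitnormal", median, lo, hi)     -> logit-normal (for ratios in (0,1))

CONTROL_MORPHO = {
    "D_max": ("normal", 25.77, 4.40),
    "D_min": ("normal", 17.46, 3.66),
    "r_min": ("normal", 6.99, 2.37),
    "ostium_area": ("normal", 367.18, 125.16),
    "ostium_perimeter": ("normal", 71.16, 12.27),
    "h_LAA": ("lognormal", 14.80, 9.18, 22.93),
    "centreline_length": ("normal", 34.48, 7.06),
    "tortuosity": ("logitnormal", 0.79, 0.50, 0.96),
    "d_A": ("normal", 13.87, 3.75),
    "d_P": ("normal", 11.38, 3.17),
    "bending_angle": ("normal", 114.0, 17.55),
    "LA_volume": ("lognormal", 163.0, 82.0, 256.0),
    "LAA_area": ("lognormal", 2225.0, 1183.0, 3918.0),
    "LAA_volume": ("lognormal", 6.63, 2.59, 15.50),
}

CASE_MORPHO = {
    "D_max": ("normal", 30.20, 4.90),
    "D_min": ("normal", 19.63, 2.95),
    "r_min": ("normal", 8.20, 1.81),
    "ostium_area": ("normal", 486.35, 148.42),
    "ostium_perimeter": ("normal", 80.99, 12.14),
    "h_LAA": ("lognormal", 15.34, 8.83, 30.63),
    "centreline_length": ("normal", 38.82, 8.74),
    "tortuosity": ("logitnormal", 0.77, 0.45, 0.88),
    "d_A": ("normal", 16.03, 3.18),
    "d_P": ("normal", 12.83, 3.54),
    "bending_angle": ("normal", 103.0, 23.84),
    "LA_volume": ("lognormal", 164.0, 100.0, 269.0),
    "LAA_area": ("lognormal", 2677.0, 1747.0, 6006.0),
    "LAA_volume": ("lognormal", 8.09, 4.12, 15.88),
}

CONTROL_HAEMO = {
    "TAWSS": ("normal", 0.31, 0.12),
    "ECAP": ("normal", 0.87, 0.61),
    "OSI": ("normal", 0.15, 0.05),
    "RRT": ("normal", 10.03, 5.97),
    "Vel_over_LAAv": ("normal", 0.99, 0.80),
}

CASE_HAEMO = {
    "TAWSS": ("normal", 0.35, 0.14),
    "ECAP": ("normal", 1.08, 0.69),
    "OSI": ("normal", 0.17, 0.04),
    "RRT": ("normal", 11.38, 7.04),
    "Vel_over_LAAv": ("normal", 0.84, 0.35),
}

#: lower bounds enforced on physically positive haemodynamic draws
_HAEMO_FLOOR = {"TAWSS": 0.02, "ECAP": 0.02, "OSI": 0.01, "RRT": 0.5,
                "Vel_over_LAAv": 0.05}
_OSI_CEIL = 0.45

#: mean stagnation percentage per group; the SD is a modelling choice
STAGNATION_MEAN = {"control": 12.39, "case": 19.77}
STAGNATION_SD = 5.0

CHICKEN_WING_PROB = {"control": 0.1579, "case": 0.1333}

#: published group sizes behind the calibration tables; the median/range ->
#: sigma conversion always refers to these, independent of the generated n
CALIB_N = {"control": 38, "case": 33}


@dataclasses.dataclass
class SyntheticSpec:
    """Cohort-level generator settings."""

    n_control: int = 38
    n_case: int = 33
    beat_period: float = 1.0   # s
    n_beats: int = 3
    steps_per_beat: int = 80
    mesh_edge_length: float = 0.5   # mm
    max_field_nodes: int = 2000
    #: correlation among ostium size metrics / between ostium size and volume
    rho_ostium: float = 0.7
    rho_ostium_volume: float = 0.4
    morpho: dict = dataclasses.field(
        default_factory=lambda: {"control": CONTROL_MORPHO, "case": CASE_MORPHO})
    haemo: dict = dataclasses.field(
        default_factory=lambda: {"control": CONTROL_HAEMO, "case": CASE_HAEMO})

    def validate(self) -> "SyntheticSpec":
        for grp in ("control", "case"):
            for name, desc in {**self.morpho[grp], **self.haemo[grp]}.items():
                if desc[0] == "normal" and desc[2] <= 0:
                    raise ValueError(f"{grp}/{name}: SD must be > 0")
        if not (0 <= CHICKEN_WING_PROB["control"] <= 1):
            raise ValueError("chicken-wing probability outside [0,1]")
        w = np.linalg.eigvalsh(self._correlation(list(CONTROL_MORPHO)))
        if w.min() < -1e-10:
            raise ValueError("feature correlation matrix not PSD")
        return self

    def _correlation(self, names: list[str]) -> np.ndarray:
        """Gaussian-copula correlation over morphological features."""
        size_block = {"D_max", "D_min", "r_min", "ostium_area",
                      "ostium_perimeter"}
        n = len(names)
        C = np.eye(n)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i == j:
                    continue
                if a in size_block and b in size_block:
                    C[i, j] = self.rho_ostium
                elif {a, b} & size_block and "LAA_volume" in {a, b}:
                    C[i, j] = self.rho_ostium_volume
        return C


def default_spec(**overrides) -> SyntheticSpec:
    return dataclasses.replace(SyntheticSpec(), **overrides).validate()


# ---------------------------------------------------------------------------
# marginal transforms
# ---------------------------------------------------------------------------

def _range_z(n: int) -> float:
    """Expected standard score of the sample extreme for sample size n."""
    return float(stats.norm.ppf(n / (n + 1.0)))


def _marginal_ppf(desc, u, n_group):
    kind = desc[0]
    if kind == "normal":
        mean, sd = desc[1], desc[2]
        return mean + sd * stats.truncnorm.ppf(u, -3.0, 3.0)
    if kind == "lognormal":
        med, lo, hi = desc[1:]
        sigma = np.log(hi / lo) / (2.0 * _range_z(n_group))
        return np.exp(np.log(med) + sigma * stats.norm.ppf(u))
    if kind == "logitnormal":
        med, lo, hi = desc[1:]
        logit = lambda p: np.log(p / (1.0 - p))
        sigma = (logit(hi) - logit(lo)) / (2.0 * _range_z(n_group))
        z = logit(med) + sigma * stats.norm.ppf(u)
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown marginal kind {kind!r}")


def sample_cohort_params(spec: SyntheticSpec, seed: int) -> pd.DataFrame:
    """Draw per-subject generating parameters for both groups.

    Morphological features are drawn through a Gaussian copula with the
    spec's correlation structure and the per-group marginals; normal
    marginals are truncated at +-3 SD. Haemodynamic targets are drawn
    independently (bounded below away from zero, OSI capped at 0.45).
    Rows violating hard constraints (D_min >= D_max, non-positive
    extents) are resampled; the resample count is logged.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    frames = []
    n_resampled = 0
    n_vol_adjusted = 0
    for group, n in (("control", spec.n_control), ("case", spec.n_case)):
        morpho = spec.morpho[group]
        names = list(morpho)
        C = spec._correlation(names)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
        # conditional law of the volume coordinate given the others, used
        # to redraw volumes whose ratio to the swept-tube capacity is
        # geometrically unrealizable (keeps all other marginals exact)
        iv = names.index("LAA_volume")
        others = [k for k in range(len(names)) if k != iv]
        wv = np.linalg.solve(C[np.ix_(others, others)], C[others, iv])
        sv = float(np.sqrt(max(1.0 - wv @ C[others, iv], 1e-9)))
        n_cal = CALIB_N[group]
        rows = []
        while len(rows) < n:
            z = L @ rng.standard_normal(len(names))
            u = stats.norm.cdf(z)
            draw = {nm: float(_marginal_ppf(morpho[nm], u[k], n_cal))
                    for k, nm in enumerate(names)}
            if draw["D_min"] >= draw["D_max"] or draw["d_A"] <= 0 \
                    or draw["d_P"] <= 0 or not 60 < draw["bending_angle"] < 178:
                n_resampled += 1
                continue
            cap = (np.pi * draw["D_max"] * draw["D_min"] / 4.0
                   * draw["centreline_length"]) / 1000.0      # ml
            bc = _bulge_cap(draw["D_max"] / 2.0, draw["centreline_length"])
            hi_ratio = min(RATIO_BAND[1], _volume_ratio(NECK_DEFAULT, bc))
            lo, hi = RATIO_BAND[0] * cap, hi_ratio * cap
            if hi <= lo:            # degenerate band: pin to the floor
                draw["LAA_volume"] = lo
                n_vol_adjusted += 1
            elif not lo <= draw["LAA_volume"] <= hi:
                med, vlo, vhi = morpho["LAA_volume"][1:]
                sigma = np.log(vhi / vlo) / (2.0 * _range_z(n_cal))
                zb = (np.log([lo, hi]) - np.log(med)) / sigma
                m = float(wv @ z[others])
                zv = m + sv * stats.truncnorm.rvs(
                    (zb[0] - m) / sv, (zb[1] - m) / sv, random_state=rng)
                draw["LAA_volume"] = float(np.exp(np.log(med) + sigma * zv))
                n_vol_adjusted += 1
            for nm, desc in spec.haemo[group].items():
                v = desc[1] + desc[2] * float(
                    stats.truncnorm.ppf(rng.uniform(), -3.0, 3.0))
                v = max(v, _HAEMO_FLOOR[nm])
                if nm == "OSI":
                    v = min(v, _OSI_CEIL)
                draw[nm] = v
            draw["stagnation_pct"] = float(np.clip(
                rng.normal(STAGNATION_MEAN[group], STAGNATION_SD), 1.0, 60.0))
            draw["shape_label"] = ("chicken-wing"
                                   if rng.uniform() < CHICKEN_WING_PROB[group]
                                   else "non-chicken-wing")
            draw["group"] = group
            rows.append(draw)
        frames.append(pd.DataFrame(rows))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(len(df))])
    # derived features
    df["D_mean"] = 0.5 * (df["D_max"] + df["D_min"])
    df["eccentricity"] = 1.0 - df["D_min"] / df["D_max"]
    df["d_AP"] = df["d_A"] + df["d_P"]
    df["ratio_LAAv_LAv"] = df["LAA_volume"] / df["LA_volume"]
    log_stage("sample_cohort_params", seed=seed, n=len(df),
              n_resampled=n_resampled, n_volume_adjusted=n_vol_adjusted)
    return df


def make_cohort_table(spec: SyntheticSpec, seed: int):
    """Table-only cohort (no mesh realization) for the statistical stage."""
    from .io import CohortTable

    df = sample_cohort_params(spec, seed)
    return CohortTable(df).validate()


# ---------------------------------------------------------------------------
# centreline curve realization
# ---------------------------------------------------------------------------

_T = np.linspace(0.0, 1.0, 801)

#: default relative width of the distal tube vs the ostium ellipse
NECK_DEFAULT = 0.42
#: fold-margin threshold: curvature times half-width in the tightest bend.
#: 0.72 leaves ~0.8 half-widths of inner-wall clearance, which avoids wall
#: folding and keeps the lumen resolvable by the voxel centreline extractor
FOLD_MARGIN = 0.72
#: feasible swept-volume ratio band V / (pi a b L) of the section profile
#: (below: even the narrowest neck is too wide; above: the body bulge
#: needed would dwarf the ostium)
RATIO_BAND = (0.24, 0.74)


def _section_profile(neck: float, bulge: float):
    """Section scale c(u) along the normalized centreline parameter.

    The ostium ellipse narrows over the neck region to a winding distal
    tube of relative width ``neck``; a proximal body hump of amplitude
    ``bulge`` (the main volume reservoir, as in real appendages) peaks
    around u ~ 0.15, and a superelliptic factor rounds the tip.
    """

    def c(uu):
        base = neck + (1.0 - neck) * (1.0 - _smoothstep(uu, 0.06, 0.34))
        hump = _smoothstep(uu, 0.02, 0.14) * (1.0 - _smoothstep(uu, 0.17, 0.38))
        tip = np.sqrt(np.clip(1.0 - uu ** 3, 0.0, 1.0))
        return (base + bulge * hump) * tip

    return c


def _volume_ratio(neck: float, bulge: float) -> float:
    """integral of c(u)^2 — the swept volume in units of pi a b L."""
    uu = np.linspace(0.0, 1.0, 401)
    c = _section_profile(neck, bulge)(uu)
    return float(np.trapezoid(c * c, uu))


def _bulge_cap(a: float, L: float) -> float:
    """Largest bulge whose wing stays clearly nearer the ostium than the tip.

    Caps the body half-width a*(base+bulge) at 0.6 of the centreline
    length so the tail apex remains the unambiguous farthest point.
    """
    return max(0.0, min(1.1, 0.6 * L / a - 0.62))


def _solve_section(ratio_target: float, bulge_max: float = 1.1):
    """(neck, bulge, clamped) whose swept-volume ratio hits the target."""
    base = _volume_ratio(NECK_DEFAULT, 0.0)
    if ratio_target < base:
        f = lambda n: _volume_ratio(n, 0.0) - ratio_target
        if f(0.26) > 0:
            return 0.26, 0.0, True
        return float(optimize.brentq(f, 0.26, NECK_DEFAULT, xtol=1e-5)), 0.0, False
    f = lambda bb: _volume_ratio(NECK_DEFAULT, bb) - ratio_target
    if f(bulge_max) < 0:
        return NECK_DEFAULT, bulge_max, True
    return NECK_DEFAULT, float(
        optimize.brentq(f, 0.0, bulge_max, xtol=1e-5)), False


def _smoothstep(t, lo, hi):
    x = np.clip((t - lo) / (hi - lo), 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _ramp(t, lo, hi, f=0.2):
    """Smooth trapezoid ramp 0 -> 1 over [lo, hi].

    The derivative is a cosine-tapered plateau with peak only 1/(1-f)
    times the mean, so bend curvature stays spread out along the curve
    instead of concentrating at the window centre.
    """
    x = np.clip((t - lo) / (hi - lo), 0.0, 1.0)

    def head(z):  # integral of 0.5(1 - cos(pi z / f)) over [0, z], z <= f
        return 0.5 * (z - (f / np.pi) * np.sin(np.pi * z / f))

    y = np.empty_like(x)
    lo_m = x < f
    hi_m = x > 1.0 - f
    mid = ~(lo_m | hi_m)
    y[lo_m] = head(x[lo_m])
    y[mid] = 0.5 * f + (x[mid] - f)
    y[hi_m] = (1.0 - f) - head(1.0 - x[hi_m])
    return y / (1.0 - f)


def _heading_profiles(yaw: float, p1: float, p2: float):
    """(phi, psi) heading-angle profiles over the normalized parameter.

    ``yaw`` turns in the ostium (xy) plane over the proximal half;
    ``p1``/``p2`` form an out-of-plane S-hook: a distal pitch sweep that
    may partially swing back (p2 < 0), which is what lets the curve lose
    chord length (low tortuosity) while keeping the proximal and distal
    chord directions — hence the bending angle — nearly independent.
    """
    t = _T
    phi = yaw * _ramp(t, 0.28, 0.65)
    psi = p1 * _ramp(t, 0.34, 0.75) + p2 * _ramp(t, 0.64, 0.98)
    return phi, psi


def _curve_directions(yaw: float, p1: float, p2: float) -> np.ndarray:
    """Unit tangent field of the hooked centreline family (start = +y)."""
    phi, psi = _heading_profiles(yaw, p1, p2)
    return np.column_stack([np.cos(psi) * np.sin(phi),
                            np.cos(psi) * np.cos(phi),
                            np.sin(psi)])


def _curve_points(yaw: float, p1: float, p2: float) -> np.ndarray:
    d = _curve_directions(yaw, p1, p2)
    dt = _T[1] - _T[0]
    return np.vstack([np.zeros(3),
                      np.cumsum((d[1:] + d[:-1]) / 2, axis=0) * dt])


def _curve_metrics(pts: np.ndarray):
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = s[-1]
    tort = np.linalg.norm(pts[-1] - pts[0]) / length

    def at(si):
        return np.array([np.interp(si, s, pts[:, k]) for k in range(3)])

    u = at(length / 3.0) - pts[0]
    v = pts[-1] - at(2.0 * length / 3.0)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    bend = 180.0 - np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return float(tort), float(bend)


def _solve_curve(tortuosity: float, bending_deg: float):
    """Find (yaw, p1, p2) realizing the target chord/arc ratio and bending.

    Solved as a weighted least-squares problem prioritizing tortuosity,
    with a mild preference for simple (non-hooked) shapes; the clamp flag
    is set when the target pair is outside the family's reach (bending
    residual above 2 degrees or tortuosity residual above 0.005).
    """

    def resid(x):
        tort, bend = _curve_metrics(_curve_points(*x))
        return [60.0 * (tort - tortuosity), bend - bending_deg, 0.3 * x[2]]

    # initial guess from the arc-implied total turn, biased toward pitch
    # (out-of-plane bending has more fold clearance against the minor axis)
    f = lambda th: np.sinc(th / (2.0 * np.pi)) - tortuosity  # sin(x/2)/(x/2)
    total = min(optimize.brentq(f, 1e-6, 2.0 * np.pi - 1e-6), 3.0)
    best = None
    for x0 in ([0.3 * total, 0.8 * total, -0.3 * total],
               [0.2 * total, 0.9 * total, -0.8 * total],
               [0.5 * total, 0.6 * total, 0.0]):
        sol = optimize.least_squares(
            resid, x0=x0, bounds=([0.0, 0.0, -2.9], [2.8, 2.9, 0.5]),
            xtol=1e-10, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 0.05:
            best = sol
            break
    x = best.x
    tort_r, bend_r = _curve_metrics(_curve_points(*x))
    clamped = abs(tort_r - tortuosity) > 0.005 or abs(bend_r - bending_deg) > 2.0
    return float(x[0]), float(x[1]), float(x[2]), clamped


# ---------------------------------------------------------------------------
# mesh realization
# ---------------------------------------------------------------------------

def _transport_frames(tangents: np.ndarray):
    """Parallel-transported section frames along a curve.

    Starts from normal (1,0,0) so the first section's major axis lies
    along x; returns (normals, binormals) arrays matching ``tangents``.
    """
    n = np.empty_like(tangents)
    n0 = np.array([1.0, 0.0, 0.0])
    n0 = n0 - tangents[0] * np.dot(n0, tangents[0])
    n[0] = n0 / np.linalg.norm(n0)
    for i in range(1, len(tangents)):
        v = np.cross(tangents[i - 1], tangents[i])
        nv = np.linalg.norm(v)
        if nv < 1e-14:
            n[i] = n[i - 1]
            continue
        ang = np.arcsin(np.clip(nv, -1.0, 1.0))
        if np.dot(tangents[i - 1], tangents[i]) < 0:
            ang = np.pi - ang
        v = v / nv
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        n[i] = R @ n[i - 1]
        n[i] -= tangents[i] * np.dot(n[i], tangents[i])
        n[i] /= np.linalg.norm(n[i])
    return n, np.cross(tangents, n)

@dataclasses.dataclass
class GroundTruth:
    """Generating parameters and exact geometry for one synthetic subject."""

    params: dict
    curve: np.ndarray            # exact centreline polyline (mm)
    arc_length: float            # mm (realized)
    chord: float                 # mm
    tortuosity: float            # realized chord/arc
    bending_angle: float         # realized, degrees
    volume_analytic: float       # ml, swept integral of section area
    rim_points: np.ndarray
    station_s: np.ndarray        # arc position of each ring (mm)
    station_radius: np.ndarray   # hydraulic radius sqrt(a*b)*c(u) per ring (mm)
    n_ring: int
    clamped: bool                # tortuosity/volume target clamped
    node_s: np.ndarray | None = None        # arc position per wall vertex
    wss_targets: dict | None = None          # per-node target TAWSS/OSI etc.

    def to_json(self) -> str:
        d = {
            "params": {k: (v if isinstance(v, str) else float(v))
                       for k, v in self.params.items()},
            "arc_length": self.arc_length, "chord": self.chord,
            "tortuosity": self.tortuosity, "bending_angle": self.bending_angle,
            "volume_analytic": self.volume_analytic, "clamped": self.clamped,
            "curve": np.round(self.curve, 6).tolist(),
        }
        return json.dumps(d, sort_keys=True)


def build_laa_mesh(params, edge_length: float = 0.5):
    """Realize one subject's appendage as a swept elliptical tube.

    The ostium ellipse (semi-axes D_max/2 along x, D_min/2 along z) is
    swept along a planar curve whose arc length, chord/arc ratio and
    mid-curve bend match the drawn centreline length, tortuosity and
    bending angle; sections taper as sqrt(1 - u^q) toward a rounded tip,
    with q solved so the swept volume matches the drawn LAA volume when
    geometrically feasible. The mesh starts in the ostium-aligned frame:
    rim in the zx-plane, body toward +y, D_max along x.
    """
    a = params["D_max"] / 2.0
    b = params["D_min"] / 2.0
    L = params["centreline_length"]
    if not (a > b > 0):
        raise ValueError("require D_max > D_min > 0")
    # section scale profile solved so the swept volume matches the draw
    v_target = params["LAA_volume"] * 1000.0           # ml -> mm^3
    neck, bulge, clamped_v = _solve_section(
        v_target / (np.pi * a * b * L), _bulge_cap(a, L))
    c_of = _section_profile(neck, bulge)

    yaw, p1, p2, clamped = _solve_curve(params["tortuosity"],
                                        params["bending_angle"])
    # fold safety: per-plane curvature times the section half-width in the
    # bending direction must stay below 1 or the inner wall folds; shrink
    # the offending bend component for extreme draws
    c_t = c_of(_T)

    def fold_margins(x):
        phi, psi = _heading_profiles(*x)
        m_yaw = np.max(np.abs(np.gradient(phi, _T)) * a * c_t) / L
        m_pitch = np.max(np.abs(np.gradient(psi, _T)) * b * c_t) / L
        return float(m_yaw), float(m_pitch)

    def arms_clear(x):
        """Genuinely separate tube segments must keep a wall-to-wall gap
        wider than the voxel scale, or the voxelized lumen merges and the
        centreline becomes ambiguous. Pairs within 2.5 radius-sums of arc
        are part of the same bend and exempt."""
        sub = slice(0, len(_T), 8)
        pts = _curve_points(*x)[sub] * L
        rr = (a * c_t)[sub]
        ss = _T[sub] * L
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        gap = ss[:, None] - ss[None, :]
        rsum = rr[:, None] + rr[None, :]
        check = np.abs(gap) > 2.5 * rsum
        return bool(np.all(d[check] >= rsum[check] + 2.0))

    for _ in range(60):
        m_yaw, m_pitch = fold_margins((yaw, p1, p2))
        if m_yaw <= FOLD_MARGIN and m_pitch <= FOLD_MARGIN and arms_clear((yaw, p1, p2)):
            break
        if m_yaw > FOLD_MARGIN:
            yaw *= 0.93
        if m_pitch > FOLD_MARGIN:
            p1 *= 0.93
            p2 *= 0.93
        if m_yaw <= FOLD_MARGIN and m_pitch <= FOLD_MARGIN:
            # bends fold-safe but arms too close: relax the hook overall
            yaw, p1, p2 = 0.95 * yaw, 0.95 * p1, 0.95 * p2
        clamped = True
    if max(fold_margins((yaw, p1, p2))) > FOLD_MARGIN:
        raise ValueError(
            f"self-intersecting sweep: tortuosity {params['tortuosity']:.2f} "
            f"with ostium {2*a:.0f}x{2*b:.0f} mm and length {L:.0f} mm "
            "cannot be realized without the wall folding onto itself")
    clamped = clamped or clamped_v
    curve = _curve_points(yaw, p1, p2) * L
    tort_r, bend_r = _curve_metrics(curve)

    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s_curve = np.concatenate([[0.0], np.cumsum(seg)])
    n_ring = max(int(round(np.pi * (a + b) / edge_length)), 24)
    n_stations = max(int(round(L / edge_length)), 20)
    u_all = np.linspace(0.0, 1.0, n_stations + 1)
    c_all = c_of(u_all)
    keep = c_all * b >= max(2.0 * edge_length, 0.35)
    keep[0] = True
    u = u_all[keep]
    c = c_all[keep]

    def curve_at(si):
        return np.column_stack([np.interp(si, s_curve, curve[:, k])
                                for k in range(3)])

    pts = curve_at(u * s_curve[-1])
    tang = np.gradient(curve, s_curve, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    tu = np.column_stack([np.interp(u * s_curve[-1], s_curve, tang[:, k])
                          for k in range(3)])
    tu /= np.linalg.norm(tu, axis=1)[:, None]
    normal, binorm = _transport_frames(tu)

    psi = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    verts = []
    for i in range(len(u)):
        ring = (pts[i][None, :]
                + a * c[i] * np.outer(np.cos(psi), normal[i])
                + b * c[i] * np.outer(np.sin(psi), binorm[i]))
        verts.append(ring)
    verts = np.vstack(verts)
    apex = curve[-1]
    verts = np.vstack([verts, apex[None, :]])
    ai = len(verts) - 1
    faces = []
    for i in range(len(u) - 1):
        for j in range(n_ring):
            p0 = i * n_ring + j
            p1 = i * n_ring + (j + 1) % n_ring
            p2 = (i + 1) * n_ring + j
            p3 = (i + 1) * n_ring + (j + 1) % n_ring
            faces += [[p0, p1, p3], [p0, p3, p2]]
    last = (len(u) - 1) * n_ring
    for j in range(n_ring):
        faces.append([last + j, last + (j + 1) % n_ring, ai])
    faces = np.asarray(faces)

    mesh = SurfaceMesh(verts, faces, np.arange(n_ring))
    # analytic swept volume of the realized taper (tip fan adds the sliver
    # between the last kept ring and the apex; account for it analytically)
    vol = np.pi * a * b * s_curve[-1] * float(np.trapezoid(c_all ** 2, u_all))
    station_s = u * s_curve[-1]
    node_s = np.repeat(station_s, n_ring)
    node_s = np.append(node_s, s_curve[-1])
    gt = GroundTruth(
        params=dict(params), curve=curve, arc_length=float(s_curve[-1]),
        chord=float(np.linalg.norm(curve[-1] - curve[0])),
        tortuosity=tort_r, bending_angle=bend_r,
        volume_analytic=vol / 1000.0, rim_points=verts[:n_ring].copy(),
        station_s=station_s, station_radius=np.sqrt(a * b) * c,
        n_ring=n_ring, clamped=bool(clamped), node_s=node_s,
    )
    try:
        mesh.validate(check_rim_simple=True)
    except Exception as exc:
        raise ValueError(
            f"swept surface is degenerate (tortuosity {tort_r:.2f}, bend "
            f"{bend_r:.0f} deg, D_max {2*a:.1f} mm): {exc}") from exc
    return mesh, gt


# ---------------------------------------------------------------------------
# field synthesis
# ---------------------------------------------------------------------------

def _beat_waveform(tau: np.ndarray) -> np.ndarray:
    """Non-negative pulsatile modulation over one beat (tau = t/P mod 1)."""
    return 0.2 + np.sin(np.pi * tau) ** 2


def synthesize_flow(params, mesh: SurfaceMesh, gt: GroundTruth,
                    spec: SyntheticSpec | None = None,
                    rng: np.random.Generator | None = None):
    """Synthesize wall shear stress and flow series hitting the draws.

    Axial speed decays from ostium to tip as exp(-s/lambda) with
    lambda = L/2 (velocities progressively decrease toward the tip); wall
    shear magnitude follows the Poiseuille form 4 mu v / r. Shear
    direction reverses over a sub-interval of each beat sized so the
    oscillatory shear index matches the subject's OSI target; the overall
    scale is set so the trimmed-mean TAWSS matches the TAWSS target. The
    ostium flow rate is a half-sine pulse whose per-beat outflow volume
    inverts the mixing washout model at the subject's stagnation target.
    Beat 1 ramps up from zero amplitude (a deliberately non-periodic
    stabilisation transient), so windows that include it are biased.
    """
    spec = spec or SyntheticSpec()
    P, n_beats, spb = spec.beat_period, spec.n_beats, spec.steps_per_beat
    osi_t = float(params["OSI"])
    if not 0.0 <= osi_t <= 0.5:
        raise ValueError(f"OSI target {osi_t} unreachable (must be <= 0.5)")
    times = np.arange(n_beats * spb + 1) * (P / spb)
    tau_beat = (times / P) % 1.0
    w = _beat_waveform(tau_beat)
    ramp = np.clip(times / P, 0.0, 1.0)
    ramp[times < P] = times[times < P] / P

    # sign pattern: reversal over a grid-aligned sub-interval of each beat,
    # sized on the beat-2 trapezoid weights; the reversed-lobe amplitude is
    # then scaled so the oscillatory index is exact under the same
    # trapezoid rule the index computation uses
    i0 = spb  # first index of beat 2
    wt = w[i0:i0 + spb + 1].copy()
    trap = np.empty(spb + 1)
    trap[0] = trap[-1] = 0.5
    trap[1:-1] = 1.0
    contrib = wt * trap
    total = contrib.sum()
    cum = np.cumsum(contrib) / total
    sign_beat = np.ones(spb)
    if osi_t > 0:
        j1 = int(np.searchsorted(cum, 0.30))
        j2 = min(max(int(np.searchsorted(cum, 0.30 + osi_t)), j1 + 1), spb)
        sign_beat[j1:j2] = -1.0
    sign = np.concatenate([np.tile(sign_beat, n_beats), [sign_beat[-1]]])
    if osi_t > 0:
        w_mask0 = times >= P - 1e-9          # beats 2..n window
        tw0 = times[w_mask0]
        m_trial = (w * sign)[w_mask0]
        int_abs = np.trapezoid(np.abs(m_trial), tw0)
        int_signed = np.trapezoid(m_trial, tw0)
        B_rev = 0.5 * (int_abs - int_signed)
        A_fwd = 0.5 * (int_abs + int_signed)
        gamma = A_fwd * osi_t / (B_rev * (1.0 - osi_t)) if B_rev > 0 else 0.0
        sign = np.where(sign < 0, -gamma, 1.0)

    # node selection and axial profile
    n_wall = len(mesh.vertices) - 1          # exclude apex from field nodes
    stride = max(1, int(np.ceil(n_wall / spec.max_field_nodes)))
    node_ids = np.arange(0, n_wall, stride)
    s = gt.node_s[node_ids]
    lam = gt.arc_length / 2.0
    r_node = np.interp(s, gt.station_s, gt.station_radius)
    base = np.exp(-s / lam) / np.maximum(r_node, 0.3)
    # in a blind pouch the wall shear cannot exceed its upstream neck
    # value: clip the Poiseuille profile to a running minimum along the
    # tube so the inferior > middle > superior ordering always holds
    order = np.argsort(s, kind="stable")
    base[order] = np.minimum.accumulate(base[order])

    # scale so the trimmed-mean TAWSS equals the draw
    from .haemodynamics import trimmed_aggregate

    w_mask = (times >= P - 1e-9)
    tw = times[w_mask]
    mean_w = np.trapezoid(np.abs(w * sign)[w_mask], tw) / (tw[-1] - tw[0])
    mean_w_vel = np.trapezoid(w[w_mask], tw) / (tw[-1] - tw[0])
    tawss_unscaled = base * mean_w
    alpha = params["TAWSS"] / trimmed_aggregate(tawss_unscaled)["whole"]
    tawss_target = alpha * base * mean_w

    tang = np.gradient(gt.curve, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    seg = np.linalg.norm(np.diff(gt.curve, axis=0), axis=1)
    s_curve = np.concatenate([[0.0], np.cumsum(seg)])
    e_node = np.column_stack([np.interp(s, s_curve, tang[:, k])
                              for k in range(3)])
    mod = w * ramp * sign                            # (nt,)
    wss = (alpha * base)[None, :, None] * mod[:, None, None] * e_node[None, :, :]
    series = WallFieldSeries(times=times, beat_period=P, n_beats=n_beats,
                             wss=wss, node_ids=node_ids).validate()

    # flow: half-sine outflow pulse inverting the mixing washout model
    v_laa = gt.volume_analytic                        # ml
    v_out = -v_laa * np.log(params["stagnation_pct"] / 100.0)
    q0 = np.pi * v_out / P
    q = q0 * np.sin(2.0 * np.pi * tau_beat) * ramp    # ml/s, signed

    # intra-LAA speed samples at ring stations, volume-weighted
    a_half, b_half = params["D_max"] / 2.0, params["D_min"] / 2.0
    c_station = gt.station_radius / np.sqrt(a_half * b_half)
    ds = np.gradient(gt.station_s)
    seg_vol = np.pi * a_half * b_half * c_station ** 2 * ds / 1000.0  # ml
    seg_vol *= v_laa / seg_vol.sum()
    prof = np.exp(-gt.station_s / lam)
    wmean_prof = float(np.average(prof, weights=seg_vol))
    v0 = params["Vel_over_LAAv"] * v_laa / (wmean_prof * mean_w_vel)
    vel = v0 * prof[None, :] * (w * ramp)[:, None]    # m/s
    flow = FlowSeries(times=times, q_ostium=q, vel_samples=vel,
                      sample_weights=seg_vol, beat_period=P,
                      n_beats=n_beats).validate(v_laa)

    gt.wss_targets = {
        "node_ids": node_ids, "TAWSS": tawss_target,
        "OSI": np.full(len(node_ids), osi_t),
        "Vel_over_LAAv": float(params["Vel_over_LAAv"]),
        "stagnation_pct": float(params["stagnation_pct"]),
    }
    return series, flow


# ---------------------------------------------------------------------------
# cohort bundles
# ---------------------------------------------------------------------------

def generate_cohort(spec: SyntheticSpec, seed: int, outdir,
                    write_fields: bool = True) -> Path:
    """Generate a full cohort bundle on disk; returns the manifest path.

    Each subject gets a PLY mesh, a rim CSV, optionally a WSS series and
    flow series, and a ground-truth JSON; a top-level manifest records
    SHA-256 hashes of every file so reruns are verifiably identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = sample_cohort_params(spec, seed)
    records = []
    files: dict[str, str] = {}
    try:
        for _, row in df.iterrows():
            sid = row["subject_id"]
            sdir = outdir / sid
            sdir.mkdir(exist_ok=True)
            mesh, gt = build_laa_mesh(row, spec.mesh_edge_length)
            write_surface_mesh(mesh, sdir / "laa.ply")
            write_rim_csv(mesh, sdir / "rim.csv")
            (sdir / "truth.json").write_text(gt.to_json())
            if write_fields:
                series, flow = synthesize_flow(row, mesh, gt, spec)
                write_wall_series(series, sdir)
                write_flow_series(flow, sdir)
            for f in sorted(sdir.iterdir()):
                files[str(f.relative_to(outdir))] = _sha256(f)
            records.append({k: row[k] for k in df.columns})
    except Exception:
        # partial bundles are worse than none: clean up before re-raising
        import shutil

        shutil.rmtree(outdir, ignore_errors=True)
        raise
    write_feature_table(records, outdir / "cohort_params.csv")
    files["cohort_params.csv"] = _sha256(outdir / "cohort_params.csv")
    manifest = {"seed": int(seed), "n_subjects": len(df),
                "mesh_edge_length": spec.mesh_edge_length, "files": files}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log_stage("generate_cohort", seed=seed, n=len(df), outdir=str(outdir))
    return mpath


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
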