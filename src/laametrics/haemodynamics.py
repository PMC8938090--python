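"""In silico haemodynamic indices from wall shear stress and flow series.

The four endothelial indices are computed per wall node from the WSS
vector history tau(t) over an averaging window (by default the second and
third simulated beats; the first beat is a solver stabilisation transient):

    TAWSS = (1/T) int ||tau|| dt
    OSI   = 1/2 (1 - ||int tau dt|| / int ||tau|| dt)
    ECAP  = OSI / TAWSS
    RRT   = [(1 - 2 OSI) * TAWSS]^-1

OSI is 0 for unidirectional shear and 0.5 for fully reversing shear; RRT
diverges as OSI -> 0.5 and is capped at a configurable ceiling. Cohort
summaries use a percentile-trimmed mean (10th-90th band) to be robust to
outlier nodes. Flow stagnation is estimated from the ostium flow-rate
trace by a washout argument: the volume leaving the appendage per beat is
compared with the appendage volume, either assuming perfect mixing
(exponential washout) or plug flow (piston model).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import PipelineConfig, log_stage
from .io import FlowSeries, WallFieldSeries

__all__ = [
    "NodeIndexMaps", "HaemoFeatures", "compute_wss_indices",
    "trimmed_aggregate", "velocity_index", "stagnation_fraction",
    "minmax_normalize", "compute_haemo_features",
]


@dataclasses.dataclass
class NodeIndexMaps:
    """Per-node shear-derived index maps; NaN marks undefined entries."""

    tawss: np.ndarray   # Pa, >= 0
    osi: np.ndarray     # in [0, 0.5]
    ecap: np.ndarray    # 1/Pa
    rrt: np.ndarray     # s, capped
    rrt_capped: np.ndarray  # bool, True where the RRT cap was applied
    node_ids: np.ndarray

    def validate(self) -> "NodeIndexMaps":
        if np.any(self.tawss < -1e-12):
            raise ValueError("negative TAWSS")
        if np.any((self.osi < -1e-9) | (self.osi > 0.5 + 1e-9)):
            raise ValueError("OSI outside [0, 0.5]")
        return self


@dataclasses.dataclass
class HaemoFeatures:
    """Whole-LAA and per-region haemodynamic summary for one subject."""

    tawss: dict
    osi: dict
    ecap: dict
    rrt: dict
    vel_over_laav: float  # (m/s)/ml
    stagnation_pct: float

    def to_dict(self) -> dict:
        out = {}
        for name in ("tawss", "osi", "ecap", "rrt"):
            for region, value in getattr(self, name).items():
                key = name.upper() if name != "tawss" else "TAWSS"
                out[f"{key}_{region}" if region != "whole" else key] = value
        out["Vel_over_LAAv"] = self.vel_over_laav
        out["stagnation_pct"] = self.stagnation_pct
        return out


def compute_wss_indices(series: WallFieldSeries,
                        window: tuple[int, int] | None = None,
                        rrt_max: float = 1e3) -> NodeIndexMaps:
    """Per-node TAWSS/OSI/ECAP/RRT over a beat window (default beats 2-3).

    Time integrals use the trapezoid rule on the series' own time axis.
    Nodes with identically zero WSS get TAWSS = 0, OSI = 0 and missing
    (NaN) ECAP/RRT; RRT is capped at ``rrt_max`` where the denominator
    (1 - 2 OSI) * TAWSS underflows 1/rrt_max.
    """
    window = window or (2, 3)
    series.validate()
    mask = series.beat_window_mask(window)
    t = series.times[mask]
    if len(t) < 2 or t[-1] - t[0] <= 0:
        raise ValueError(f"beat window {window} selects a zero-duration interval")
    n_sel_beats = window[1] - window[0] + 1
    if (len(t) - 1) / n_sel_beats < 20:
        raise ValueError("need >= 20 timesteps per beat in the averaging window")
    tau = series.wss[mask]                       # (nt, nn, 3)
    T = t[-1] - t[0]
    mag = np.linalg.norm(tau, axis=2)
    int_mag = np.trapezoid(mag, t, axis=0)       # (nn,)
    int_vec = np.trapezoid(tau, t, axis=0)       # (nn, 3)
    tawss = int_mag / T
    with np.errstate(invalid="ignore", divide="ignore"):
        osi = 0.5 * (1.0 - np.linalg.norm(int_vec, axis=1) / int_mag)
        osi = np.where(int_mag > 0, osi, 0.0)
        osi = np.clip(osi, 0.0, 0.5)
        ecap = np.where(tawss > 0, osi / tawss, np.nan)
        denom = (1.0 - 2.0 * osi) * tawss
        rrt = np.where(denom > 1.0 / rrt_max, 1.0 / denom, rrt_max)
        rrt = np.where(tawss > 0, rrt, np.nan)
    capped = (denom <= 1.0 / rrt_max) & (tawss > 0)
    if capped.any():
        log_stage("compute_wss_indices", rrt_capped_nodes=int(capped.sum()),
                  rrt_max=rrt_max)
    return NodeIndexMaps(tawss=tawss, osi=osi, ecap=ecap, rrt=rrt,
                         rrt_capped=capped, node_ids=series.node_ids).validate()


def trimmed_aggregate(values: np.ndarray,
                      labels: np.ndarray | None = None,
                      percentiles: tuple[float, float] = (10.0, 90.0),
                      weights: np.ndarray | None = None) -> dict:
    """Percentile-trimmed mean of per-node values, whole and per region.

    Values outside the [P10, P90] band (linear-interpolation percentiles)
    are discarded before averaging; NaNs are ignored. ``labels`` holds the
    0/1/2 inferior/middle/superior region labels; without labels only the
    whole-surface mean is returned under key "whole". Aggregation is
    unweighted over nodes unless per-node ``weights`` (e.g. areas) are given.
    """
    values = np.asarray(values, dtype=float)

    def one(sel, wsel):
        v = sel[np.isfinite(sel)]
        if len(v) < 10:
            raise ValueError(f"need >= 10 values per region, got {len(v)}")
        lo, hi = np.percentile(v, percentiles)
        keep = (sel >= lo) & (sel <= hi) & np.isfinite(sel)
        if wsel is None:
            return float(sel[keep].mean())
        return float(np.average(sel[keep], weights=wsel[keep]))

    out = {"whole": one(values, weights)}
    if labels is not None:
        from .morphology import REGION_NAMES

        labels = np.asarray(labels)
        for k, name in enumerate(REGION_NAMES):
            m = labels == k
            out[name] = one(values[m], weights[m] if weights is not None else None)
    return out


def velocity_index(flow: FlowSeries, laa_volume_ml: float,
                   window: tuple[int, int] | None = None) -> float:
    """Volume-normalized mean intra-LAA speed, (m/s)/ml.

    The speed samples are volume-weight averaged over space and
    trapezoid-averaged over the beat window, then divided by the appendage
    volume — the size normalization applied before group comparisons.
    """
    window = window or (2, 3)
    if laa_volume_ml <= 0:
        raise ValueError("LAA volume must be positive")
    flow.validate()
    mask = flow.beat_window_mask(window)
    t = flow.times[mask]
    w = flow.sample_weights / flow.sample_weights.sum()
    mean_space = flow.vel_samples[mask] @ w           # (nt,)
    mean_speed = np.trapezoid(mean_space, t) / (t[-1] - t[0])
    return float(mean_speed / laa_volume_ml)


def stagnation_fraction(flow: FlowSeries, laa_volume_ml: float,
                        window: tuple[int, int] | None = None,
                        model: str = "mixing") -> float:
    """Percentage of LAA blood not renewed per beat, from the ostium flow.

    The outflow volume per beat V_out = int max(q, 0) dt (averaged over the
    beats of the window) is compared with the appendage volume V. Under
    perfect mixing the retained fraction after one beat is exp(-V_out/V);
    under piston (plug-flow) washout it is max(0, 1 - V_out/V).
    """
    window = window or (2, 3)
    if laa_volume_ml <= 0:
        raise ValueError("LAA volume must be positive")
    flow.validate()
    mask = flow.beat_window_mask(window)
    t = flow.times[mask]
    n_sel_beats = window[1] - window[0] + 1
    v_out = np.trapezoid(np.maximum(flow.q_ostium[mask], 0.0), t) / n_sel_beats
    ratio = v_out / laa_volume_ml
    if model == "mixing":
        return float(100.0 * np.exp(-ratio))
    if model == "piston":
        return float(100.0 * max(0.0, 1.0 - ratio))
    raise ValueError(f"unknown stagnation model {model!r}")


def minmax_normalize(frame: pd.DataFrame, columns: list[str],
                     suffix: str = "_norm"):
    """Min-max scale selected columns over the cohort, keeping raw values.

    Returns (frame with added ``<col><suffix>`` columns, scaling record
    {col: (min, max)}). Constant columns are an error because the scaling
    is undefined for them.
    """
    frame = frame.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = frame[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi - lo <= 0:
            raise ValueError(f"column {col!r} is constant; min-max scaling undefined")
        frame[col + suffix] = (x - lo) / (hi - lo)
        scaling[col] = (float(lo), float(hi))
    return frame, scaling


def minmax_restore(frame: pd.DataFrame, scaling: dict,
                   suffix: str = "_norm") -> pd.DataFrame:
    """Invert :func:`minmax_normalize` (exact up to float rounding)."""
    frame = frame.copy()
    for col, (lo, hi) in scaling.items():
        frame[col] = frame[col + suffix] * (hi - lo) + lo
    return frame


def compute_haemo_features(series: WallFieldSeries, flow: FlowSeries,
                           laa_volume_ml: float,
                           region_labels: np.ndarray | None = None,
                           config: PipelineConfig | None = None) -> HaemoFeatures:
    """Full haemodynamic summary for one subject."""
    config = config or PipelineConfig()
    maps = compute_wss_indices(series, config.beat_window, config.rrt_max)
    labels = None
    if region_labels is not None:
        labels = np.asarray(region_labels)[series.node_ids]
    trim = config.trim_percentiles
    return HaemoFeatures(
        tawss=trimmed_aggregate(maps.tawss, labels, trim),
        osi=trimmed_aggregate(maps.osi, labels, trim),
        ecap=trimmed_aggregate(maps.ecap, labels, trim),
        rrt=trimmed_aggregate(maps.rrt, labels, trim),
        vel_over_laav=velocity_index(flow, laa_volume_ml, config.beat_window),
        stagnation_pct=stagnation_fraction(flow, laa_volume_ml,
                                           config.beat_window,
                                           config.stagnation_model),
    )
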