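"""Utilization distributions and foraging-space overlap.

Individual foraging UDs are estimated with biased random bridges (BRB):
probability mass is spread along the interpolated path between serial
fixes, with a time-dependent bridge variance floored at a minimum
smoothing parameter, so that serial autocorrelation in the fixes informs
the estimate.  Segments longer than ``tmax_min`` in time are not bridged;
segments shorter than ``lmin_m`` are treated as resting and contribute
point kernels.  The diffusion coefficient D (m^2/min) is estimated by the
plug-in method: maximizing the leave-one-out likelihood of each interior
fix under the Brownian-bridge interpolation of its neighbours.

Colony-level roosting/foraging UDs use weighted bivariate-normal fixed
kernels with a reference (href) bandwidth computed from weighted standard
deviations and the effective sample size (sum w)^2 / sum w^2.

Overlap between two UDs on a common grid is quantified by the utilization
distribution overlap index (UDOI; 1 for uniform independent complete
overlap, >1 for concentrated joint use) and the Bhattacharyya affinity
(BA; 0 disjoint, 1 identical).
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GridSpec",
    "UDGrid",
    "BRBParams",
    "Track",
    "segment_track",
    "estimate_diffusion_plugin",
    "plugin_loglik",
    "brb_ud",
    "weighted_kernel_ud",
    "isopleth",
    "udoi",
    "bhattacharyya_affinity",
    "ud_centroid",
    "centroid_shift",
    "foraging_overlap_network",
    "write_asc",
    "isopleth_geojson",
]

M2_PER_HA = 1e4


@dataclass(frozen=True)
class GridSpec:
    """Regular raster: origin = lower-left corner, row 0 = southernmost."""

    x0: float
    y0: float
    cell_size: float
    n_x: int
    n_y: int

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_x) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_y) + 0.5) * self.cell_size

    @classmethod
    def from_points(
        cls, xy: np.ndarray, cell_size: float = 30.0, buffer_m: float = 500.0
    ) -> "GridSpec":
        xy = np.asarray(xy, dtype=float)
        x0 = xy[:, 0].min() - buffer_m
        y0 = xy[:, 1].min() - buffer_m
        n_x = int(math.ceil((xy[:, 0].max() + buffer_m - x0) / cell_size))
        n_y = int(math.ceil((xy[:, 1].max() + buffer_m - y0) / cell_size))
        return cls(x0, y0, cell_size, max(n_x, 1), max(n_y, 1))


@dataclass
class UDGrid:
    """Discrete utilization distribution: probability mass per cell, sum 1."""

    spec: GridSpec
    mass: np.ndarray  # shape (n_y, n_x)
    meta: dict = field(default_factory=dict)

    def density(self) -> np.ndarray:
        """Probability density per cell (mass / cell area), 1/m^2."""
        return self.mass / self.spec.cell_area

    def validate(self) -> None:
        if self.mass.shape != (self.spec.n_y, self.spec.n_x):
            raise ValueError("mass shape does not match grid spec")
        if np.any(self.mass < 0) or abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("UD mass must be non-negative and sum to 1")


@dataclass(frozen=True)
class BRBParams:
    """BRB estimation constants (minutes / meters)."""

    tmax_min: float = 60.0   # max bridgeable gap between successive fixes
    lmin_m: float = 50.0     # below this a segment is resting
    hmin_m: float = 88.0     # minimum smoothing parameter
    diffusion: float | None = None  # m^2/min; None -> plug-in estimate

    def validate(self) -> None:
        if min(self.tmax_min, self.lmin_m, self.hmin_m) <= 0:
            raise ValueError("BRB parameters must be strictly positive")
        if self.diffusion is not None and not (
            np.isfinite(self.diffusion) and self.diffusion > 0
        ):
            raise ValueError("diffusion must be positive and finite")


@dataclass
class Track:
    """One bat's ordered fixes plus labelled inter-fix segments."""

    bat_id: str
    fixes: pd.DataFrame     # timestamp, x_m, y_m (strictly increasing time)
    segments: pd.DataFrame  # x0,y0,x1,y1,t0,t1,duration_min,length_m,status


def segment_track(fixes: pd.DataFrame, params: BRBParams) -> Track:
    """Label inter-fix segments as bridge / resting / unusable.

    A segment spanning more than ``tmax_min`` minutes is unusable for
    bridging; a shorter segment covering less than ``lmin_m`` meters is a
    resting segment (point-kernel contribution only); the rest are
    bridges.
    """
    params.validate()
    if len(fixes) < 2:
        raise ValueError("need >= 2 fixes to segment a track")
    f = fixes.sort_values("timestamp", kind="stable").reset_index(drop=True)
    t = pd.to_datetime(f["timestamp"])
    if (t.diff().dropna() <= pd.Timedelta(0)).any():
        raise ValueError("fix timestamps must be strictly increasing")
    dur = t.diff().dt.total_seconds().to_numpy()[1:] / 60.0
    dx = f["x_m"].diff().to_numpy()[1:]
    dy = f["y_m"].diff().to_numpy()[1:]
    length = np.hypot(dx, dy)
    status = np.where(
        dur > params.tmax_min, "unusable", np.where(length < params.lmin_m, "resting", "bridge")
    )
    seg = pd.DataFrame(
        {
            "x0": f["x_m"].to_numpy()[:-1],
            "y0": f["y_m"].to_numpy()[:-1],
            "x1": f["x_m"].to_numpy()[1:],
            "y1": f["y_m"].to_numpy()[1:],
            "t0": t.to_numpy()[:-1],
            "t1": t.to_numpy()[1:],
            "duration_min": dur,
            "length_m": length,
            "status": status,
        }
    )
    bat_id = str(f["bat_id"].iloc[0]) if "bat_id" in f else ""
    return Track(bat_id, f, seg)


def _plugin_triplets(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """(squared deviation, T*p*(1-p)) for interior fixes flanked by
    non-unusable segments."""
    seg = track.segments
    f = track.fixes
    d2, w = [], []
    for i in range(1, len(f) - 1):
        s_prev, s_next = seg.iloc[i - 1], seg.iloc[i]
        if s_prev["status"] == "unusable" or s_next["status"] == "unusable":
            continue
        T = s_prev["duration_min"] + s_next["duration_min"]
        p = s_prev["duration_min"] / T
        mx = s_prev["x0"] + p * (s_next["x1"] - s_prev["x0"])
        my = s_prev["y0"] + p * (s_next["y1"] - s_prev["y0"])
        d2.append((f["x_m"].iloc[i] - mx) ** 2 + (f["y_m"].iloc[i] - my) ** 2)
        w.append(T * p * (1.0 - p))
    return np.asarray(d2), np.asarray(w)


def plugin_loglik(track: Track, diffusion: float) -> float:
    """Leave-one-out log-likelihood of interior fixes at a given D.

    Each interior fix is modelled as bivariate normal around the linear
    interpolation of its neighbours with per-coordinate variance
    2 D T p (1-p).
    """
    d2, w = _plugin_triplets(track)
    if len(d2) == 0:
        raise ValueError("cannot estimate D: no usable interior fix")
    var = 2.0 * diffusion * w
    return float(np.sum(-np.log(2.0 * np.pi * var) - d2 / (2.0 * var)))


def estimate_diffusion_plugin(track: Track, params: BRBParams | None = None) -> float:
    """Plug-in diffusion estimate D (m^2/min).

    Closed-form maximizer of :func:`plugin_loglik`:
    D = sum(d_i^2 / w_i) / (4 n) with w_i = T_i p_i (1 - p_i).
    """
    d2, w = _plugin_triplets(track)
    if len(d2) == 0:
        raise ValueError("cannot estimate D: no usable interior fix")
    d_hat = float(np.sum(d2 / w) / (4.0 * len(d2)))
    if not (np.isfinite(d_hat) and d_hat > 0):
        raise ValueError("plug-in diffusion estimate degenerate (coincident fixes?)")
    return d_hat


def _deposit_gaussian(
    mass: np.ndarray, spec: GridSpec, mu: tuple[float, float], sd: float, weight: float
) -> None:
    """Add an isotropic Gaussian kernel's cell-integrated mass in place."""
    if weight == 0.0:
        return
    half = 6.0 * sd
    x_edges = spec.x0 + np.arange(spec.n_x + 1) * spec.cell_size
    y_edges = spec.y0 + np.arange(spec.n_y + 1) * spec.cell_size
    # symmetric cell window around mu so reflective configurations stay exact
    i0 = max(int(math.floor((mu[0] - half - spec.x0) / spec.cell_size)), 0)
    i1 = min(int(math.ceil((mu[0] + half - spec.x0) / spec.cell_size)), spec.n_x)
    j0 = max(int(math.floor((mu[1] - half - spec.y0) / spec.cell_size)), 0)
    j1 = min(int(math.ceil((mu[1] + half - spec.y0) / spec.cell_size)), spec.n_y)
    if i1 <= i0 or j1 <= j0:
        return
    px = np.diff(norm.cdf(x_edges[i0 : i1 + 1], loc=mu[0], scale=sd))
    py = np.diff(norm.cdf(y_edges[j0 : j1 + 1], loc=mu[1], scale=sd))
    mass[j0:j1, i0:i1] += weight * np.outer(py, px)


def brb_ud(
    track: Track,
    params: BRBParams,
    spec: GridSpec,
    n_substeps: int = 12,
    min_coverage: float = 0.999,
) -> UDGrid:
    """Biased-random-bridge utilization distribution on a grid.

    Bridge segments deposit Gaussian mass at ``n_substeps`` interpolated
    positions with per-coordinate variance hmin^2 + 2 D T p (1-p); resting
    segments deposit hmin kernels at their endpoint fixes.  Segment
    contributions are weighted by duration.  Raises when the grid holds
    less than ``min_coverage`` of the total mass.
    """
    params.validate()
    diffusion = params.diffusion
    if diffusion is None:
        diffusion = estimate_diffusion_plugin(track, params)
    seg = track.segments
    usable = seg[seg["status"] != "unusable"]
    mass = np.zeros((spec.n_y, spec.n_x))
    total_weight = 0.0
    if len(usable) > 0:
        for s in usable.itertuples():
            T = s.duration_min
            total_weight += T
            if s.status == "resting":
                _deposit_gaussian(mass, spec, (s.x0, s.y0), params.hmin_m, T / 2.0)
                _deposit_gaussian(mass, spec, (s.x1, s.y1), params.hmin_m, T / 2.0)
                continue
            ps = (np.arange(n_substeps) + 0.5) / n_substeps
            for p in ps:
                mu = (s.x0 + p * (s.x1 - s.x0), s.y0 + p * (s.y1 - s.y0))
                var = params.hmin_m**2 + 2.0 * diffusion * T * p * (1.0 - p)
                _deposit_gaussian(mass, spec, mu, math.sqrt(var), T / n_substeps)
    else:
        # all gaps exceed tmax: fall back to point kernels on the fixes
        for row in track.fixes.itertuples():
            _deposit_gaussian(mass, spec, (row.x_m, row.y_m), params.hmin_m, 1.0)
            total_weight += 1.0
    if total_weight == 0.0:
        raise ValueError("no usable segment or resting fix")
    coverage = mass.sum() / total_weight
    if coverage < min_coverage:
        raise ValueError(
            f"extend grid: only {coverage:.4f} of UD mass falls inside the grid"
        )
    mass /= mass.sum()
    return UDGrid(
        spec,
        mass,
        meta={
            "method": "brb",
            "diffusion_m2_per_min": diffusion,
            "hmin_m": params.hmin_m,
            "tmax_min": params.tmax_min,
            "lmin_m": params.lmin_m,
            "n_substeps": n_substeps,
        },
    )


def href_weighted(xy: np.ndarray, weights: np.ndarray) -> float:
    """Reference bandwidth for weighted points.

    h = sigma * n_eff^(-1/6) with sigma = sqrt((var_x + var_y)/2) from
    weighted variances and n_eff = (sum w)^2 / sum(w^2).
    """
    w = weights / weights.sum()
    mu = (w[:, None] * xy).sum(axis=0)
    var = (w[:, None] * (xy - mu) ** 2).sum(axis=0)
    n_eff = 1.0 / np.sum(w**2)
    sigma = math.sqrt((var[0] + var[1]) / 2.0)
    return sigma * n_eff ** (-1.0 / 6.0)


def weighted_kernel_ud(
    points: np.ndarray,
    weights: np.ndarray | None,
    spec: GridSpec,
    bandwidth: float | None = None,
) -> UDGrid:
    """Weight-normalized mixture of bivariate normal kernels.

    *bandwidth* defaults to the weighted reference rule
    (:func:`href_weighted`); for degenerate configurations (all points
    coincident) it falls back to 3 cell sizes with a warning.
    """
    xy = np.atleast_2d(np.asarray(points, dtype=float))
    if xy.shape[0] == 0:
        raise ValueError("no points")
    if weights is None:
        weights = np.ones(xy.shape[0])
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    if bandwidth is None:
        bandwidth = href_weighted(xy, w)
        if bandwidth <= 0:
            warnings.warn(
                "degenerate point spread; falling back to 3-cell bandwidth",
                stacklevel=2,
            )
            bandwidth = 3.0 * spec.cell_size
    w = w / w.sum()
    mass = np.zeros((spec.n_y, spec.n_x))
    for (x, y), wi in zip(xy, w):
        _deposit_gaussian(mass, spec, (x, y), bandwidth, wi)
    if mass.sum() < 0.999:
        raise ValueError("extend grid: kernel mass escapes the grid")
    mass /= mass.sum()
    n_eff = float((np.asarray(weights, dtype=float).sum() ** 2) / np.sum(np.asarray(weights, dtype=float) ** 2))
    return UDGrid(
        spec,
        mass,
        meta={
            "method": "weighted_kernel",
            "bandwidth_m": float(bandwidth),
            "n_eff": n_eff,
            "href_convention": "sigma*n_eff^(-1/6), sigma^2=(var_x+var_y)/2 weighted",
        },
    )


def isopleth(ud: UDGrid, level: float = 0.95) -> tuple[np.ndarray, float]:
    """Highest-density cell set holding >= *level* of the mass.

    Returns (boolean mask, area in hectares).
    """
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    flat = ud.mass.ravel()
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, level * flat.sum() - 1e-12)) + 1
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.mass.shape)
    area_ha = k * ud.spec.cell_area / M2_PER_HA
    return mask, area_ha


def _check_common_grid(ud_a: UDGrid, ud_b: UDGrid) -> None:
    if ud_a.spec != ud_b.spec:
        raise ValueError("UDs must share a common grid")


def udoi(
    ud_a: UDGrid, ud_b: UDGrid, level: float = 0.95, truncate: bool = True
) -> float:
    """Utilization distribution overlap index.

    UDOI = A_overlap * sum(f_a f_b dA), with A_overlap the intersection
    area of the two level-isopleths.  With ``truncate=True`` (default) the
    integral uses the level-truncated, renormalized UDs; identical uniform
    UDs give exactly 1, concentrated joint use gives values > 1.
    Symmetric and >= 0.
    """
    _check_common_grid(ud_a, ud_b)
    mask_a, _ = isopleth(ud_a, level)
    mask_b, _ = isopleth(ud_b, level)
    a_overlap = float(np.sum(mask_a & mask_b)) * ud_a.spec.cell_area
    if truncate:
        ma = np.where(mask_a, ud_a.mass, 0.0)
        mb = np.where(mask_b, ud_b.mass, 0.0)
        ma = ma / ma.sum()
        mb = mb / mb.sum()
    else:
        ma, mb = ud_a.mass, ud_b.mass
    integral = float(np.sum(ma * mb)) / ud_a.spec.cell_area
    return a_overlap * integral


def bhattacharyya_affinity(ud_a: UDGrid, ud_b: UDGrid) -> float:
    """BA = sum(sqrt(f_a f_b) dA) in [0, 1]; 1 iff the UDs coincide."""
    _check_common_grid(ud_a, ud_b)
    return float(min(1.0, np.sum(np.sqrt(ud_a.mass * ud_b.mass))))


def ud_centroid(points: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted mean location of points (equals a symmetric-kernel UD mean)."""
    xy = np.atleast_2d(np.asarray(points, dtype=float))
    if xy.shape[0] == 0:
        raise ValueError("no points")
    w = np.ones(xy.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    w = w / w.sum()
    c = (w[:, None] * xy).sum(axis=0)
    return float(c[0]), float(c[1])


def centroid_shift(c1: tuple[float, float], c2: tuple[float, float]) -> float:
    """Euclidean distance between two centroids, meters."""
    return float(math.hypot(c2[0] - c1[0], c2[1] - c1[1]))


def foraging_overlap_network(
    uds: dict[str, UDGrid], threshold: float = 1.0, level: float = 0.95
) -> tuple[nx.Graph, pd.DataFrame, float]:
    """UDOI-thresholded foraging association network.

    One node per UD-eligible bat; an edge joins a dyad whose UDOI is
    strictly greater than *threshold*.  Returns (graph, dyad table,
    fraction of dyads above threshold).
    """
    if len(uds) < 2:
        raise ValueError("need >= 2 UD-eligible bats")
    ids = sorted(uds)
    g = nx.Graph()
    g.add_nodes_from(ids)
    rows = []
    for a, b in itertools.combinations(ids, 2):
        val = udoi(uds[a], uds[b], level=level)
        ba = bhattacharyya_affinity(uds[a], uds[b])
        edge = val > threshold
        if edge:
            g.add_edge(a, b)
        rows.append({"bat_a": a, "bat_b": b, "udoi": val, "ba": ba, "edge": edge})
    table = pd.DataFrame(rows)
    fraction = float(table["edge"].mean())
    return g, table, fraction


# ---------------------------------------------------------------------------
# output formats


def write_asc(ud: UDGrid, path) -> None:
    """ESRI ASCII grid of the UD mass (row 1 = northernmost)."""
    s = ud.spec
    header = (
        f"ncols {s.n_x}\nnrows {s.n_y}\nxllcorner {s.x0}\nyllcorner {s.y0}\n"
        f"cellsize {s.cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, ud.mass[::-1], fmt="%.6e")
    sidecar = dict(ud.meta)
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def isopleth_geojson(ud: UDGrid, level: float = 0.95) -> dict:
    """GeoJSON (planar CRS) polygon union of the level-isopleth cells."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    mask, area_ha = isopleth(ud, level)
    s = ud.spec
    boxes = [
        box(
            s.x0 + i * s.cell_size,
            s.y0 + j * s.cell_size,
            s.x0 + (i + 1) * s.cell_size,
            s.y0 + (j + 1) * s.cell_size,
        )
        for j, i in zip(*np.nonzero(mask))
    ]
    geom = unary_union(boxes)
    return {
        "type": "Feature",
        "properties": {"level": level, "area_ha": area_ha},
        "geometry": mapping(geom),
    }
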