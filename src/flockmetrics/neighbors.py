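"""Neighbor assignment and neighbor-exchange statistics.

Neighbors are defined metrically: the radial distribution function g(r)
of cell positions is computed, the r of its first valley (the minimum
after the first coordination peak) becomes the neighbor distance
threshold, and cells strictly closer than the threshold are neighbors.

Cell rearrangement is quantified by tracking pairs that are neighbors at
a reference time t and following their separation:

    d(δt) = ⟨ (1/N(t)) Σ_i (1/n_i(t)) Σ_{j ∈ nbrs_i(t)} |r_i(t+δt) − r_j(t+δt)| ⟩_t

with N(t) cells in view and n_i(t) neighbors of cell i at t. Δd(δt) =
d(δt) − d(0) starts at zero; its linear growth rate (µm/h) is the
neighbor-exchange readout: ≈ 0 for solids (jammed or flocking), positive
and large for fluids. The companion probability map P(r, δt) histograms
the change of the relative position vector of such pairs with the same
1/(N·n_i) weighting, normalized to unit integral.

Pairs whose tracks end before t+δt are dropped (and counted); short
track gaps (≤ 3 frames, the usual gap-closing setting) can be
interpolated first with :func:`interpolate_gaps`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree


@dataclass
class RDFCurve:
    r_um: np.ndarray
    g: np.ndarray
    bin_width_um: float
    n_points: int
    first_valley_um: float | None = None


@dataclass
class ExchangeCurve:
    delta_t_h: np.ndarray
    d_um: np.ndarray            # mean separation of initially-neighboring pairs
    delta_d_um: np.ndarray      # d(δt) − d(0)
    n_pairs: np.ndarray
    slope_um_per_h: float = np.nan
    slope_ci95_um_per_h: float = np.nan


@dataclass
class DisplacementMap:
    x_edges_um: np.ndarray
    y_edges_um: np.ndarray
    P: np.ndarray               # density, integrates to 1 over the map
    delta_t_h: float
    bin_width_um: float


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def radial_distribution(
    positions: np.ndarray,
    box_size_um: float | tuple[float, float],
    bin_width_um: float,
    r_max_um: float | None = None,
    periodic: bool = True,
) -> RDFCurve:
    """Pair-correlation function g(r) of a 2D point set.

    Normalized by the ideal-gas expectation at the sample density, so
    g → 1 at large r for homogeneous points. Periodic boxes use the
    minimum-image convention; bounded fields of view use a guard-region
    edge correction (only reference points farther than r_max from every
    border contribute, all points count as partners)."""
    if bin_width_um <= 0:
        raise ValueError("bin_width must be positive")
    pos = np.asarray(positions, float)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 points for an RDF")
    if np.isscalar(box_size_um):
        lx = ly = float(box_size_um)
    else:
        lx, ly = map(float, box_size_um)
    if r_max_um is None:
        r_max_um = min(lx, ly) / (2.0 if periodic else 4.0)
    area = lx * ly
    rho = n / area
    n_bins = int(np.ceil(r_max_um / bin_width_um))
    edges = np.arange(n_bins + 1) * bin_width_um

    if periodic:
        tree = cKDTree(np.mod(pos, (lx, ly)), boxsize=(lx, ly))
        pairs = tree.query_pairs(min(r_max_um, min(lx, ly) / 2 * 0.999), output_type="ndarray")
        d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
        d -= np.array([lx, ly]) * np.round(d / np.array([lx, ly]))
        dist = np.hypot(d[:, 0], d[:, 1])
        counts = np.histogram(dist, bins=edges)[0] * 2.0  # ordered pairs
        n_ref = n
    else:
        interior = (
            (pos[:, 0] >= r_max_um)
            & (pos[:, 0] <= lx - r_max_um)
            & (pos[:, 1] >= r_max_um)
            & (pos[:, 1] <= ly - r_max_um)
        )
        refs = pos[interior]
        n_ref = len(refs)
        if n_ref == 0:
            raise ValueError("no interior reference points for guard-region RDF")
        tree = cKDTree(pos)
        counts = np.zeros(n_bins)
        for p in refs:
            idx = tree.query_ball_point(p, r_max_um)
            d = np.hypot(*(pos[idx] - p).T)
            d = d[d > 0]
            counts += np.histogram(d, bins=edges)[0]

    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = counts / (n_ref * rho * annulus)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFCurve(centers, g, bin_width_um, n)


def first_valley_threshold(rdf: RDFCurve, smoothing_bins: int = 3) -> float:
    """r of the first local minimum of the smoothed g(r) after its first
    peak — the neighbor distance threshold.

    The valley must dip below 1.0 (rejects shoulder artifacts); a
    monotone or valley-free g(r) raises with advice to set the threshold
    manually. Ties break to the smallest r.
    """
    g = rdf.g.astype(float)
    if smoothing_bins > 1:
        kernel = np.ones(smoothing_bins) / smoothing_bins
        g = np.convolve(g, kernel, mode="same")
    r = rdf.r_um
    # first peak: first local max that clears 1.2 — a real coordination
    # shell, not density noise around g = 1 (ideal gas fluctuates ±few %)
    peak = None
    for i in range(1, len(g) - 1):
        if g[i] >= g[i - 1] and g[i] > g[i + 1] and g[i] > 1.2:
            peak = i
            break
    if peak is None:
        raise ValueError(
            "no coordination peak in g(r); set the neighbor threshold manually"
        )
    for i in range(peak + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] < g[i + 1] and g[i] < 1.0:
            return float(r[i])
    raise ValueError(
        "no valley after the first peak of g(r); set the neighbor threshold manually"
    )


# ---------------------------------------------------------------------------
# neighbor graph
# ---------------------------------------------------------------------------

def assign_neighbors(
    positions: np.ndarray,
    r_thresh_um: float,
    box_size_um: float | None = None,
) -> list[set[int]]:
    """Adjacency sets: j is a neighbor of i iff |r_i − r_j| < r_thresh
    (strict). Periodic minimum-image when ``box_size_um`` is given."""
    if r_thresh_um <= 0:
        raise ValueError("r_thresh must be positive")
    pos = np.asarray(positions, float)
    if box_size_um is not None:
        tree = cKDTree(np.mod(pos, box_size_um), boxsize=box_size_um)
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(r_thresh_um, output_type="ndarray")
    if len(pairs):
        if box_size_um is not None:
            d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
            d -= box_size_um * np.round(d / box_size_um)
            dist = np.hypot(d[:, 0], d[:, 1])
        else:
            dist = np.hypot(*(pos[pairs[:, 1]] - pos[pairs[:, 0]]).T)
        pairs = pairs[dist < r_thresh_um]  # strict inequality
    adj: list[set[int]] = [set() for _ in range(len(pos))]
    for i, j in pairs:
        adj[i].add(int(j))
        adj[j].add(int(i))
    return adj


# ---------------------------------------------------------------------------
# track plumbing
# ---------------------------------------------------------------------------

def interpolate_gaps(tracks: pd.DataFrame, max_gap_frames: int = 3) -> pd.DataFrame:
    """Linearly interpolate missing frames inside tracks, up to
    ``max_gap_frames`` consecutive missing frames; longer gaps remain and
    break pairs downstream."""
    out = []
    num_cols = [c for c in tracks.columns if tracks[c].dtype.kind in "fc" or c == "frame"]
    for _tid, grp in tracks.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        segments = np.split(np.arange(len(frames)), np.nonzero(np.diff(frames) > max_gap_frames + 1)[0] + 1)
        for seg in segments:
            sub = grp.iloc[seg]
            full = pd.DataFrame({"frame": np.arange(sub["frame"].min(), sub["frame"].max() + 1)})
            merged = full.merge(sub, on="frame", how="left")
            merged["track_id"] = sub["track_id"].iloc[0]
            for c in num_cols:
                if c != "frame":
                    merged[c] = merged[c].interpolate(method="linear")
            out.append(merged)
    return (
        pd.concat(out, ignore_index=True)
        .sort_values(["track_id", "frame"], kind="stable")
        .reset_index(drop=True)
    )


def _track_arrays(
    tracks: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Dense (frame × track) position arrays (NaN = absent) plus frame
    numbers. Unwrapped coordinates are used when present."""
    xcol = "x_unwrap_um" if "x_unwrap_um" in tracks.columns else "x_um"
    ycol = "y_unwrap_um" if "y_unwrap_um" in tracks.columns else "y_um"
    px = tracks.pivot(index="frame", columns="track_id", values=xcol)
    py = tracks.pivot(index="frame", columns="track_id", values=ycol)
    frames = px.index.to_numpy()
    if not np.array_equal(frames, np.arange(frames.min(), frames.max() + 1)):
        px = px.reindex(np.arange(frames.min(), frames.max() + 1))
        py = py.reindex(px.index)
        frames = px.index.to_numpy()
    return px.to_numpy(float), py.to_numpy(float), frames, px.columns.to_numpy()


def _reference_pairs(
    X: np.ndarray,
    Y: np.ndarray,
    ti: int,
    r_thresh_um: float,
    box_size_um: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ordered (i, j) neighbor pairs at frame-index ti with weights
    1/(N(t)·n_i(t)) and, for periodic data, the image offset that makes
    the pair separation continuous across the boundary."""
    present = np.nonzero(np.isfinite(X[ti]))[0]
    pos = np.stack([X[ti, present], Y[ti, present]], axis=1)
    adj = assign_neighbors(pos, r_thresh_um, box_size_um)
    n_t = len(present)
    ii, jj, ww = [], [], []
    for a, nbrs in enumerate(adj):
        if not nbrs:
            continue
        w = 1.0 / (n_t * len(nbrs))
        for b in nbrs:
            ii.append(present[a])
            jj.append(present[b])
            ww.append(w)
    ii = np.array(ii, int)
    jj = np.array(jj, int)
    ww = np.array(ww, float)
    if box_size_um is not None and len(ii):
        raw = np.stack([X[ti, jj] - X[ti, ii], Y[ti, jj] - Y[ti, ii]], axis=1)
        offset = -box_size_um * np.round(raw / box_size_um)
    else:
        offset = np.zeros((len(ii), 2))
    return ii, jj, ww, offset


def neighbor_distance_curve(
    tracks: pd.DataFrame,
    r_thresh_um: float,
    delta_t_frames: np.ndarray | None = None,
    box_size_um: float | None = None,
    stride: int = 1,
) -> ExchangeCurve:
    """The d(δt) / Δd(δt) neighbor-exchange statistic with a linear fit.

    For every reference frame t (stride-subsampled), pairs neighboring at
    t are followed to t+δt; separations are averaged with weights
    1/(N(t)·n_i(t)) over surviving pairs (pairs whose tracks end are
    dropped and reflected in ``n_pairs``). The slope of Δd(δt) in µm/h
    (least squares, with a 95% CI) quantifies neighbor exchange.
    """
    X, Y, frames, _ids = _track_arrays(tracks)
    T = len(frames)
    interval = _frame_interval(tracks)
    if delta_t_frames is None:
        max_dt = max(T // 3, 1)
        delta_t_frames = np.unique(np.linspace(0, max_dt, min(max_dt + 1, 13)).astype(int))
    delta_t_frames = np.asarray(delta_t_frames, int)
    max_dt = int(delta_t_frames.max())
    if max_dt >= T:
        raise ValueError("δt grid exceeds track duration")

    pair_cache: dict[int, tuple] = {}

    def pairs_at(ti: int):
        if ti not in pair_cache:
            pair_cache[ti] = _reference_pairs(X, Y, ti, r_thresh_um, box_size_um)
        return pair_cache[ti]

    sum_wd = np.zeros(len(delta_t_frames))
    sum_w = np.zeros(len(delta_t_frames))
    pair_counts = np.zeros(len(delta_t_frames), dtype=int)
    for k, dtf in enumerate(delta_t_frames):
        # all valid reference times for this delay
        for ti in range(0, T - dtf, stride):
            ii, jj, ww, off = pairs_at(ti)
            if len(ii) == 0:
                continue
            tj = ti + dtf
            dx = X[tj, jj] - X[tj, ii] + off[:, 0]
            dy = Y[tj, jj] - Y[tj, ii] + off[:, 1]
            alive = np.isfinite(dx) & np.isfinite(dy)
            if not alive.any():
                continue
            dist = np.hypot(dx[alive], dy[alive])
            sum_wd[k] += float(np.dot(ww[alive], dist))
            sum_w[k] += float(ww[alive].sum())
            pair_counts[k] += int(alive.sum())

    with np.errstate(invalid="ignore"):
        d = np.where(sum_w > 0, sum_wd / np.maximum(sum_w, 1e-300), np.nan)
    delta_d = d - d[delta_t_frames == 0][0] if (delta_t_frames == 0).any() else d - d[0]
    dt_h = delta_t_frames * interval
    curve = ExchangeCurve(dt_h, d, delta_d, pair_counts)
    ok = np.isfinite(delta_d)
    if ok.sum() >= 2 and np.ptp(dt_h[ok]) > 0:
        res = stats.linregress(dt_h[ok], delta_d[ok])
        curve.slope_um_per_h = float(res.slope)
        curve.slope_ci95_um_per_h = float(1.96 * res.stderr) if np.isfinite(res.stderr) else np.nan
    return curve


def _frame_interval(tracks: pd.DataFrame) -> float:
    t = tracks.drop_duplicates("frame").sort_values("frame")
    if len(t) < 2:
        return 1.0 / 12.0
    return float(np.median(np.diff(t["t_h"]) / np.diff(t["frame"])))


def neighbor_displacement_map(
    tracks: pd.DataFrame,
    r_thresh_um: float,
    delta_t_frames: int,
    bin_width_um: float = 5.0,
    extent_um: float | None = None,
    box_size_um: float | None = None,
    stride: int = 1,
) -> DisplacementMap:
    """P(r, δt): probability density of the relative-position change
    r_ij(t+δt) − r_ij(t) of pairs neighboring at t, weighted
    1/(N(t)·n_i(t)), time-averaged, normalized to unit integral."""
    X, Y, frames, _ids = _track_arrays(tracks)
    T = len(frames)
    if delta_t_frames >= T:
        raise ValueError("δt exceeds track duration")
    if extent_um is None:
        extent_um = max(4.0 * r_thresh_um, 10.0 * bin_width_um)
    n_bins = 2 * int(np.ceil(extent_um / bin_width_um)) + 1
    half = n_bins * bin_width_um / 2.0
    edges = np.linspace(-half, half, n_bins + 1)
    H = np.zeros((n_bins, n_bins))
    total_w = 0.0
    any_pairs = False
    for ti in range(0, T - delta_t_frames, stride):
        ii, jj, ww, off = _reference_pairs(X, Y, ti, r_thresh_um, box_size_um)
        if len(ii) == 0:
            continue
        tj = ti + delta_t_frames
        dx0 = X[ti, jj] - X[ti, ii] + off[:, 0]
        dy0 = Y[ti, jj] - Y[ti, ii] + off[:, 1]
        dx1 = X[tj, jj] - X[tj, ii] + off[:, 0]
        dy1 = Y[tj, jj] - Y[tj, ii] + off[:, 1]
        ux, uy = dx1 - dx0, dy1 - dy0
        alive = np.isfinite(ux) & np.isfinite(uy)
        if not alive.any():
            continue
        any_pairs = True
        H += np.histogram2d(
            uy[alive], ux[alive], bins=(edges, edges), weights=ww[alive]
        )[0]
        total_w += float(ww[alive].sum())
    if not any_pairs:
        raise ValueError("no surviving neighbor pairs at this δt")
    P = H / (total_w * bin_width_um**2)
    interval = _frame_interval(tracks)
    return DisplacementMap(edges, edges, P, delta_t_frames * interval, bin_width_um)


__all__ = [
    "DisplacementMap",
    "ExchangeCurve",
    "RDFCurve",
    "assign_neighbors",
    "first_valley_threshold",
    "interpolate_gaps",
    "neighbor_displacement_map",
    "neighbor_distance_curve",
    "radial_distribution",
]
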