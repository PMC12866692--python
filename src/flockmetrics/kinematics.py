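"""Kinematic observables of collective motility.

From a PIV velocity field: the center-of-mass velocity V_cm(t) (spatial
average over interrogation windows), the root-mean-square velocity
V_RMS(t) = sqrt(⟨|v_i|²⟩), and the alignment order parameter

    ψ = |⟨v_i⟩_i| / sqrt(⟨|v_i|²⟩_i)

which equals 1 only for perfectly uniform motion (same speed, same
direction) and ≈ 0 for randomly oriented velocities. A second common
variant ψ = |⟨v⟩|/⟨|v|⟩ is available (``variant="magnitude_ratio"``);
both lie in [0, 1] and the default never exceeds the variant
(Cauchy–Schwarz vs triangle inequality).

From tracks: V_RMS-CM, the RMS of per-cell centroid velocities, a
tracking-based readout of local velocity fluctuations.

Undefined values (no valid windows, no spanning tracks) propagate as NaN,
never as zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import VelocityField


def _valid_vectors(field: VelocityField, t_index: int) -> tuple[np.ndarray, np.ndarray]:
    vx, vy, valid = field.frame(t_index)
    return vx[valid], vy[valid]


def center_of_mass_velocity(field: VelocityField, t_index: int) -> np.ndarray:
    """Component-wise mean velocity over valid windows, (vx, vy) µm/h."""
    vx, vy = _valid_vectors(field, t_index)
    if vx.size == 0:
        return np.array([np.nan, np.nan])
    return np.array([vx.mean(), vy.mean()])


def root_mean_square_velocity(
    field: VelocityField, t_index: int, drift_corrected: bool = False
) -> float:
    """sqrt(⟨|v_i|²⟩) over valid windows; optionally about V_cm.

    The default (no drift correction) matches headline V_RMS curves; the
    drift-corrected variant removes coherent motion first.
    """
    vx, vy = _valid_vectors(field, t_index)
    if vx.size == 0:
        return float("nan")
    if drift_corrected:
        vx = vx - vx.mean()
        vy = vy - vy.mean()
    return float(np.sqrt(np.mean(vx**2 + vy**2)))


def order_parameter_vectors(
    vx: np.ndarray, vy: np.ndarray, variant: str = "eq_ratio"
) -> float:
    """ψ of a flat set of velocity vectors.

    variant="eq_ratio" (default): |⟨v⟩| / sqrt(⟨|v|²⟩);
    variant="magnitude_ratio": |⟨v⟩| / ⟨|v|⟩.
    Returns NaN if all speeds are zero.
    """
    vx = np.asarray(vx, float).ravel()
    vy = np.asarray(vy, float).ravel()
    if vx.size == 0:
        return float("nan")
    speed_sq = vx**2 + vy**2
    if not np.any(speed_sq > 0):
        return float("nan")
    mean_mag = float(np.hypot(vx.mean(), vy.mean()))
    if variant == "eq_ratio":
        denom = float(np.sqrt(np.mean(speed_sq)))
    elif variant == "magnitude_ratio":
        denom = float(np.mean(np.sqrt(speed_sq)))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return mean_mag / denom


def order_parameter(
    field: VelocityField, t_index: int, variant: str = "eq_ratio"
) -> float:
    """Alignment order parameter ψ ∈ [0, 1] of one field frame."""
    vx, vy = _valid_vectors(field, t_index)
    return order_parameter_vectors(vx, vy, variant)


def track_rms_cm_velocity(
    tracks: pd.DataFrame, frame: int, frame_interval_h: float | None = None
) -> float:
    """V_RMS-CM at one frame: RMS of per-cell centroid velocities.

    Per-cell velocity is the displacement between ``frame`` and
    ``frame + 1`` divided by the frame interval, over cells present in
    both frames. Uses unwrapped coordinates when available (periodic
    synthetic data), else raw positions. NaN if no track spans the pair.
    """
    xcol, ycol = _position_columns(tracks)
    a = tracks[tracks["frame"] == frame].set_index("track_id")
    b = tracks[tracks["frame"] == frame + 1].set_index("track_id")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        return float("nan")
    if frame_interval_h is None:
        dt = float(b.loc[common[0], "t_h"] - a.loc[common[0], "t_h"])
    else:
        dt = frame_interval_h
    dx = (b.loc[common, xcol] - a.loc[common, xcol]).to_numpy(float)
    dy = (b.loc[common, ycol] - a.loc[common, ycol]).to_numpy(float)
    return float(np.sqrt(np.mean((dx / dt) ** 2 + (dy / dt) ** 2)))


def _position_columns(tracks: pd.DataFrame) -> tuple[str, str]:
    if "x_unwrap_um" in tracks.columns:
        return "x_unwrap_um", "y_unwrap_um"
    return "x_um", "y_um"


def motility_timeseries(
    field: VelocityField, tracks: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-frame kinematics table: V_cm, V_rms, ψ (both variants), and —
    when tracks are supplied — V_rms_cm; plus the valid-window count."""
    rows = []
    for t in range(field.n_frames):
        vx, vy = _valid_vectors(field, t)
        vcm = center_of_mass_velocity(field, t)
        rows.append(
            {
                "t_h": field.times[t],
                "v_cm_x": vcm[0],
                "v_cm_y": vcm[1],
                "v_cm": float(np.hypot(*vcm)) if np.isfinite(vcm).all() else np.nan,
                "v_rms": root_mean_square_velocity(field, t),
                "v_rms_drift_corrected": root_mean_square_velocity(
                    field, t, drift_corrected=True
                ),
                "psi": order_parameter(field, t),
                "psi_magnitude_ratio": order_parameter(
                    field, t, variant="magnitude_ratio"
                ),
                "n_valid_windows": int(vx.size),
            }
        )
    out = pd.DataFrame(rows)
    if tracks is not None:
        frames = np.sort(tracks["frame"].unique())
        frame_of_t = dict(zip(np.round(field.times, 9), range(field.n_frames)))
        vcm_track = np.full(field.n_frames, np.nan)
        t_track = tracks.drop_duplicates("frame").sort_values("frame")
        lookup = dict(zip(np.round(t_track["t_h"], 9), t_track["frame"]))
        for i, t in enumerate(np.round(field.times, 9)):
            if t in lookup:
                vcm_track[i] = track_rms_cm_velocity(tracks, int(lookup[t]))
        out["v_rms_cm"] = vcm_track
    return out


def framecut_mean(times: np.ndarray, values: np.ndarray, t0: float, t1: float) -> float:
    """Mean of a per-frame series over t0 ≤ t < t1, skipping NaN entries.

    The framecut convention used for summary statistics (e.g. mean V_RMS
    in the 15–40 h window). Raises if the window does not overlap the
    series support or contains only undefined values.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    sel = (times >= t0) & (times < t1)
    if not sel.any():
        raise ValueError(
            f"framecut [{t0}, {t1}) h does not overlap series support "
            f"[{times.min():.3g}, {times.max():.3g}] h"
        )
    vals = values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("framecut window contains no defined values")
    return float(vals.mean())


def find_motility_peak(
    times: np.ndarray,
    values: np.ndarray,
    smoothing_frames: int = 5,
    window_h: float = 10.0,
) -> tuple[float, tuple[float, float]]:
    """Locate the motility peak and a centered analysis window.

    The series is smoothed with a centered moving average of
    ``smoothing_frames`` (NaN-aware); the peak time is the argmax, ties
    broken to the earliest frame. Returns (t_peak, (t_lo, t_hi)) with the
    window of length ``window_h`` clipped to the series support.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(values) < smoothing_frames:
        raise ValueError("series shorter than the smoothing window")
    if not np.isfinite(values).any():
        raise ValueError("series has no defined values")
    kernel = np.ones(smoothing_frames)
    finite = np.isfinite(values)
    num = np.convolve(np.where(finite, values, 0.0), kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    smoothed = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    smoothed = np.where(np.isfinite(smoothed), smoothed, -np.inf)
    i_peak = int(np.argmax(smoothed))  # argmax takes the first maximum
    t_peak = float(times[i_peak])
    lo = max(t_peak - window_h / 2.0, float(times.min()))
    hi = min(t_peak + window_h / 2.0, float(times.max()))
    return t_peak, (lo, hi)


def velocity_field_from_tracks(
    tracks: pd.DataFrame,
    box_size_um: float,
    spacing_um: float = 25.0,
    frame_interval_h: float | None = None,
) -> VelocityField:
    """Grid per-cell frame-to-frame velocities into a pseudo-PIV field.

    Cell velocities (from consecutive positions) are averaged in square
    windows of side 2·``spacing_um`` centered on a grid of pitch
    ``spacing_um`` — the 50%-overlap window geometry of PIV, so each
    window holds a handful of cells like a real interrogation window
    (single-cell bins would be dominated by shot noise). Windows wrap
    periodically (synthetic boxes). Empty windows are flagged invalid.
    This puts tracking data on the same footing as PIV so the
    correlation and kinematics stages can consume either.
    """
    xcol, ycol = _position_columns(tracks)
    tracks = tracks.sort_values(["track_id", "frame"], kind="stable")
    if tracks["frame"].nunique() < 2:
        raise ValueError("need at least two frames to derive velocities")
    n_bins = max(int(round(box_size_um / spacing_um)), 2)
    pitch = box_size_um / n_bins
    centers = (np.arange(n_bins) + 0.5) * pitch

    gid = tracks["track_id"].to_numpy()
    frm = tracks["frame"].to_numpy()
    t_h = tracks["t_h"].to_numpy(float)
    x = tracks[xcol].to_numpy(float)
    y = tracks[ycol].to_numpy(float)
    # consecutive rows of the same track one frame apart
    same = (gid[1:] == gid[:-1]) & (frm[1:] == frm[:-1] + 1)
    dt = t_h[1:] - t_h[:-1]
    if frame_interval_h is not None:
        dt = np.full_like(dt, frame_interval_h)
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = (x[1:] - x[:-1]) / dt
        vy = (y[1:] - y[:-1]) / dt
    # position at the start frame, wrapped into the box for binning
    bx = np.mod(tracks["x_um"].to_numpy(float)[:-1], box_size_um)
    by = np.mod(tracks["y_um"].to_numpy(float)[:-1], box_size_um)

    frames = np.sort(tracks["frame"].unique())[:-1]
    frame_index = {f: i for i, f in enumerate(frames)}
    T = len(frames)
    sum_vx = np.zeros((T, n_bins, n_bins))
    sum_vy = np.zeros((T, n_bins, n_bins))
    count = np.zeros((T, n_bins, n_bins))
    fi = np.array([frame_index.get(f, -1) for f in frm[:-1]])
    ok = same & (fi >= 0)
    ixb = np.clip((bx[ok] / pitch).astype(int), 0, n_bins - 1)
    iyb = np.clip((by[ok] / pitch).astype(int), 0, n_bins - 1)
    np.add.at(sum_vx, (fi[ok], iyb, ixb), vx[ok])
    np.add.at(sum_vy, (fi[ok], iyb, ixb), vy[ok])
    np.add.at(count, (fi[ok], iyb, ixb), 1.0)

    # 2×2 periodic window sum: windows of side 2·pitch at 50% overlap
    def window_sum(a: np.ndarray) -> np.ndarray:
        return (
            a
            + np.roll(a, -1, axis=1)
            + np.roll(a, -1, axis=2)
            + np.roll(np.roll(a, -1, axis=1), -1, axis=2)
        )

    sum_vx, sum_vy, count = window_sum(sum_vx), window_sum(sum_vy), window_sum(count)
    valid = count > 0
    with np.errstate(invalid="ignore"):
        mean_vx = np.where(valid, sum_vx / np.maximum(count, 1), np.nan)
        mean_vy = np.where(valid, sum_vy / np.maximum(count, 1), np.nan)
    times = frames * (
        frame_interval_h
        if frame_interval_h is not None
        else float(np.median(dt[same])) if same.any() else 1.0 / 12.0
    )
    return VelocityField(
        times=times,
        grid_x=centers,
        grid_y=centers,
        vx=mean_vx,
        vy=mean_vy,
        window_size_um=2 * pitch,
        overlap_fraction=0.5,
        pixel_size_um=pitch,
        valid_mask=valid,
    )


__all__ = [
    "center_of_mass_velocity",
    "find_motility_peak",
    "framecut_mean",
    "motility_timeseries",
    "order_parameter",
    "order_parameter_vectors",
    "root_mean_square_velocity",
    "track_rms_cm_velocity",
    "velocity_field_from_tracks",
]
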