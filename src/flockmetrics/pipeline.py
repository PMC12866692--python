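"""End-to-end orchestration: inputs → metric bundle → state call.

`run_pipeline` chains the stages (PIV if images, kinematics, motility
peak, velocity correlation, neighbor exchange, density, shape if masks,
classification) with per-stage error isolation: a failed stage marks its
section failed, downstream dependents are skipped, and the report keeps
explicit gaps instead of silent holes. `summarize_tracks` is the
tracks-only closure used heavily with simulator output. Multi-replicate
series are combined with `aggregate_replicates` (per-time mean ± SD over
fields of view, nearest-frame matched), the same aggregation used for
experimental time courses.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation, density, kinematics, neighbors, piv as piv_mod, shape as shape_mod
from .classify import StateThresholds, classify_state
from .io import AnalysisConfig, ImageStack, LabelMaskStack, VelocityField


def _framecut_bounds(config: AnalysisConfig, times: np.ndarray) -> tuple[float, float]:
    """Configured framecut, or the last half of the run when the series
    is too short to overlap it (short synthetic runs)."""
    t0, t1 = config.framecut_h
    tmax = float(np.max(times))
    if t0 >= tmax:
        t0, t1 = tmax / 2.0, tmax + 1e-9
    return t0, min(t1, tmax + 1e-9)


def estimate_neighbor_threshold(
    positions: np.ndarray,
    box_size_um: float,
    bin_width_um: float = 2.0,
    periodic: bool = True,
) -> tuple[float, str]:
    """Neighbor distance threshold from the RDF first valley, with a
    nearest-neighbor-spacing fallback when g(r) shows no valley (dilute
    or disordered configurations). Returns (threshold, method)."""
    rdf = neighbors.radial_distribution(
        positions, box_size_um, bin_width_um, periodic=periodic
    )
    try:
        return neighbors.first_valley_threshold(rdf), "rdf_first_valley"
    except ValueError:
        from scipy.spatial import cKDTree

        pos = np.mod(positions, box_size_um) if periodic else positions
        tree = (
            cKDTree(pos, boxsize=box_size_um) if periodic else cKDTree(pos)
        )
        dist, _ = tree.query(pos, k=2)
        return 1.8 * float(np.median(dist[:, 1])), "nn_spacing_fallback"


def summarize_tracks(
    tracks: pd.DataFrame,
    box_size_um: float,
    config: AnalysisConfig | None = None,
    periodic: bool = True,
    exchange_stride: int = 4,
) -> dict:
    """Full metric bundle from a track table alone.

    Velocities are gridded into a pseudo-PIV field (pitch = half the PIV
    window) for V_RMS, ψ and the drift-corrected correlation length;
    neighbor exchange comes from the RDF-thresholded pair statistic.
    Framecut means use the configured window, or the last half of short
    runs. Returns a flat dict consumable by :func:`classify_state`.
    """
    config = config or AnalysisConfig()
    field = kinematics.velocity_field_from_tracks(
        tracks, box_size_um, spacing_um=config.piv_window_um / 2.0
    )
    series = kinematics.motility_timeseries(field, tracks)
    t0, t1 = _framecut_bounds(config, series["t_h"].to_numpy())
    v_rms = kinematics.framecut_mean(series["t_h"], series["v_rms"], t0, t1)
    psi = kinematics.framecut_mean(series["t_h"], series["psi"], t0, t1)
    v_rms_cm = kinematics.framecut_mean(series["t_h"], series["v_rms_cm"], t0, t1)

    frame_sel = np.nonzero((field.times >= t0) & (field.times < t1))[0]
    curve = correlation.correlation_over_window(field, frame_sel, drift_correct=True)

    mid_frame = int(np.median(tracks["frame"].unique()))
    pos = tracks[tracks["frame"] == mid_frame][["x_um", "y_um"]].to_numpy(float)
    r_thresh, thresh_method = estimate_neighbor_threshold(
        pos, box_size_um, config.rdf_bin_width_um, periodic=periodic
    )

    n_frames = tracks["frame"].nunique()
    interval = float(np.median(np.diff(np.sort(tracks["t_h"].unique()))))
    max_dt_frames = min(int(round(3.0 / interval)), max(n_frames // 3, 1))
    dt_grid = np.unique(np.linspace(0, max_dt_frames, 13).astype(int))
    exchange = neighbors.neighbor_distance_curve(
        tracks,
        r_thresh,
        dt_grid,
        box_size_um=box_size_um if periodic else None,
        stride=exchange_stride,
    )
    return {
        "v_rms": v_rms,
        "v_rms_cm": v_rms_cm,
        "psi": psi,
        "l_corr": curve.fit["l_corr_um"],
        "gamma": curve.fit["gamma"],
        "l_corr_converged": curve.fit["converged"],
        "exchange_slope": exchange.slope_um_per_h,
        "neighbor_threshold_um": r_thresh,
        "neighbor_threshold_method": thresh_method,
        "framecut_h": (t0, t1),
    }


def aggregate_replicates(
    series_list: list[pd.DataFrame],
    value_column: str,
    time_column: str = "t_h",
) -> pd.DataFrame:
    """Per-time mean ± SD (ddof=1) across replicate series.

    Series are matched to the first series' time base by nearest frame
    (within half the base's median interval); disjoint time bases raise.
    Returns columns (t, mean, sd, n)."""
    if not series_list:
        raise ValueError("no series to aggregate")
    base = np.asarray(series_list[0][time_column], float)
    tol = (
        np.median(np.diff(np.sort(base))) / 2.0 if len(base) > 1 else np.inf
    )
    stacked = np.full((len(series_list), len(base)), np.nan)
    for i, s in enumerate(series_list):
        t = np.asarray(s[time_column], float)
        v = np.asarray(s[value_column], float)
        idx = np.searchsorted(base, t)
        for j, (tj, vj) in enumerate(zip(t, v)):
            k = np.clip(idx[j], 0, len(base) - 1)
            if k > 0 and abs(base[k - 1] - tj) < abs(base[k] - tj):
                k -= 1
            if abs(base[k] - tj) <= tol:
                stacked[i, k] = vj
        if not np.isfinite(stacked[i]).any():
            raise ValueError(f"replicate {i} shares no time points with the base series")
    n = np.isfinite(stacked).sum(axis=0)
    with np.errstate(all="ignore"):
        mean = np.nanmean(stacked, axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=1)
    return pd.DataFrame({time_column: base, "mean": mean, "sd": sd, "n": n})


def run_pipeline(
    tracks: pd.DataFrame | None = None,
    stack: ImageStack | None = None,
    masks: LabelMaskStack | None = None,
    config: AnalysisConfig | None = None,
    box_size_um: float | None = None,
    periodic: bool = False,
    thresholds: StateThresholds | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage the inputs allow and return the report bundle.

    Partial inputs produce partial reports: absent stages are marked
    ``"not computed"`` with the missing prerequisite; failing stages are
    marked failed with the error, and their dependents are skipped.
    """
    config = config or AnalysisConfig()
    report: dict = {"stages": {}, "metrics": {}, "timings_s": {}}

    def stage(name: str, fn, *deps_ok: bool):
        if not all(deps_ok):
            report["stages"][name] = {"status": "skipped (missing prerequisite)"}
            return None
        t_start = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 — stage isolation is the contract
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            return None
        report["stages"][name] = {"status": "ok"}
        report["timings_s"][name] = round(time.perf_counter() - t_start, 3)
        return result

    field: VelocityField | None = None
    if stack is not None:
        field = stage(
            "piv",
            lambda: piv_mod.compute_piv(
                stack,
                piv_mod.PivParams(
                    window_size_um=config.piv_window_um,
                    overlap_fraction=config.piv_overlap,
                ),
            ),
        )
    else:
        report["stages"]["piv"] = {"status": "not computed (no images)"}

    if field is None and tracks is not None and box_size_um is not None:
        field = stage(
            "velocity_field_from_tracks",
            lambda: kinematics.velocity_field_from_tracks(
                tracks, box_size_um, spacing_um=config.piv_window_um / 2.0
            ),
        )

    series = None
    if field is not None:
        series = stage("kinematics", lambda: kinematics.motility_timeseries(field, tracks))
    if series is not None:
        t0, t1 = _framecut_bounds(config, series["t_h"].to_numpy())
        report["metrics"]["framecut_h"] = (t0, t1)
        for key in ("v_rms", "psi", "v_rms_cm"):
            if key in series:
                try:
                    report["metrics"][key] = kinematics.framecut_mean(
                        series["t_h"], series[key], t0, t1
                    )
                except ValueError:
                    report["metrics"][key] = None
        peak = stage(
            "motility_peak",
            lambda: kinematics.find_motility_peak(
                series["t_h"].to_numpy(),
                series["v_rms"].to_numpy(),
                window_h=config.peak_window_h,
            ),
        )
        if peak is not None:
            report["metrics"]["t_peak_h"] = peak[0]
            lo, hi = peak[1]
            frame_sel = np.nonzero((field.times >= lo) & (field.times <= hi))[0]
            curve = stage(
                "velocity_correlation",
                lambda: correlation.correlation_over_window(field, frame_sel),
            )
            if curve is not None:
                report["metrics"]["l_corr_um"] = curve.fit["l_corr_um"]
                report["metrics"]["gamma"] = curve.fit["gamma"]
                report["metrics"]["l_corr_converged"] = curve.fit["converged"]
                report["_correlation_curve"] = curve
    else:
        report["stages"].setdefault("kinematics", {"status": "not computed (no velocity field)"})

    exchange = None
    if tracks is not None:
        def _exchange():
            mid = int(np.median(tracks["frame"].unique()))
            pos = tracks[tracks["frame"] == mid][["x_um", "y_um"]].to_numpy(float)
            box = box_size_um or float(
                max(tracks["x_um"].max(), tracks["y_um"].max())
            )
            r_thresh, method = estimate_neighbor_threshold(
                pos, box, config.rdf_bin_width_um, periodic=periodic
            )
            report["metrics"]["neighbor_threshold_um"] = r_thresh
            report["metrics"]["neighbor_threshold_method"] = method
            return neighbors.neighbor_distance_curve(
                tracks, r_thresh, box_size_um=box if periodic else None
            )

        exchange = stage("neighbor_exchange", _exchange)
        if exchange is not None:
            report["metrics"]["exchange_slope_um_per_h"] = exchange.slope_um_per_h
            report["_exchange_curve"] = exchange

        def _density():
            box = box_size_um or float(
                max(tracks["x_um"].max(), tracks["y_um"].max())
            )
            return density.local_density(
                tracks, box, config.density_radius_um, periodic=periodic
            )

        dens = stage("density", _density)
        if dens is not None:
            report["metrics"]["density_fluctuation_mean"] = float(
                density.density_fluctuation_map(dens).mean()
            ) if dens.values.shape[0] >= 2 else None
    else:
        for name in ("neighbor_exchange", "density"):
            report["stages"][name] = {"status": "not computed (no tracks)"}

    if masks is not None:
        def _shape():
            shapes = shape_mod.shapes_from_mask(masks.frames[0], masks.pixel_size_um)
            return shape_mod.shape_distribution_stats(shapes)

        stats = stage("shape", _shape)
        if stats is not None:
            report["metrics"].update(
                {"mean_ar": stats["mean_ar"], "sd_ar": stats["sd_ar"],
                 "mean_si": stats["mean_si"], "sd_si": stats["sd_si"]}
            )
    else:
        report["stages"]["shape"] = {"status": "not computed (no masks)"}

    m = report["metrics"]
    if all(k in m for k in ("v_rms", "l_corr_um")) and exchange is not None:
        call = classify_state(
            {
                "v_rms": m["v_rms"],
                "l_corr": m["l_corr_um"],
                "exchange_slope": m["exchange_slope_um_per_h"],
                "psi": m.get("psi"),
                "si_sd": m.get("sd_si"),
            },
            thresholds,
        )
        report["stages"]["classification"] = {"status": "ok"}
        report["state_call"] = {
            "state": call.state,
            "rationale": call.rationale,
            "thresholds": call.thresholds,
            "reasons_unclassifiable": call.reasons_unclassifiable,
        }
    else:
        report["stages"]["classification"] = {
            "status": "skipped (metrics incomplete)"
        }

    if out_dir is not None:
        _write_report(report, series, Path(out_dir), config)
    return report


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items() if not k.startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    return obj


def _write_report(report: dict, series, out_dir: Path, config: AnalysisConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if series is not None:
        series.to_csv(out_dir / "motility.csv", index=False)
    curve = report.get("_correlation_curve")
    if curve is not None:
        pd.DataFrame(
            {
                "r_um": curve.r_um,
                "C": curve.C,
                "C_corrected": curve.C_corrected,
                "C_normalized": curve.C_normalized,
                "n_pairs": curve.n_pairs,
            }
        ).to_csv(out_dir / "corr.csv", index=False)
    exchange = report.get("_exchange_curve")
    if exchange is not None:
        pd.DataFrame(
            {
                "delta_t_h": exchange.delta_t_h,
                "d_um": exchange.d_um,
                "delta_d_um": exchange.delta_d_um,
                "n_pairs": exchange.n_pairs,
            }
        ).to_csv(out_dir / "exchange.csv", index=False)
    if "state_call" in report:
        (out_dir / "state.json").write_text(
            json.dumps(_json_safe(report["state_call"]), indent=2)
        )
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "stages": _json_safe(report["stages"]),
        "metrics": _json_safe(report["metrics"]),
        "timings_s": report["timings_s"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


__all__ = [
    "aggregate_replicates",
    "estimate_neighbor_threshold",
    "run_pipeline",
    "summarize_tracks",
]
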