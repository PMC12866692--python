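"""Readers, writers and the shared data model.

Conventions used across the package:

* image origin is the top-left corner, x increases rightward, y downward;
  positions refer to pixel centers and are converted to µm on ingest;
* frames are 0-based and time is ``t = frame * frame_interval`` (hours);
* all histogram/bin edges are half-open ``[lo, hi)``;
* invalid velocity vectors are flagged in ``valid_mask``, never silently
  zeroed.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml


class FormatError(ValueError):
    """A file violates its declared dialect (missing column, bad value...)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

#: canonical TrackTable columns (a TrackTable is a pandas DataFrame)
TRACK_COLUMNS = ("track_id", "frame", "t_h", "x_um", "y_um")


def validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Check TrackTable invariants and return the table sorted by
    (track_id, frame).

    Raises :class:`FormatError` on missing columns, duplicate
    (track_id, frame) pairs or non-finite coordinates.
    """
    for col in TRACK_COLUMNS:
        if col not in tracks.columns:
            raise FormatError(f"track table missing required column {col!r}")
    dup = tracks.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = tracks[dup].iloc[0]
        raise FormatError(
            "duplicate (track_id, frame) pair: "
            f"({row['track_id']}, {row['frame']})"
        )
    if not np.isfinite(tracks[["x_um", "y_um"]].to_numpy(float)).all():
        raise FormatError("non-finite coordinates in track table")
    return tracks.sort_values(["track_id", "frame"], kind="stable").reset_index(
        drop=True
    )


@dataclass
class VelocityField:
    """Regular grid of PIV velocity vectors over time.

    ``vx``/``vy`` have shape (T, Ny, Nx) in µm/h; ``grid_x``/``grid_y`` are
    window-center coordinates in µm; ``valid_mask`` flags vectors that
    passed validation (replaced outliers are stored but flagged False).
    """

    times: np.ndarray          # (T,) hours
    grid_x: np.ndarray         # (Nx,) µm
    grid_y: np.ndarray         # (Ny,) µm
    vx: np.ndarray             # (T, Ny, Nx) µm/h
    vy: np.ndarray             # (T, Ny, Nx) µm/h
    window_size_um: float
    overlap_fraction: float
    pixel_size_um: float
    valid_mask: np.ndarray = field(default=None)  # (T, Ny, Nx) bool

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.grid_x = np.asarray(self.grid_x, float)
        self.grid_y = np.asarray(self.grid_y, float)
        self.vx = np.asarray(self.vx, float)
        self.vy = np.asarray(self.vy, float)
        T, ny, nx = self.vx.shape
        if self.vy.shape != (T, ny, nx):
            raise FormatError("velocity field arrays have inconsistent shapes")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.vx) & np.isfinite(self.vy)
        self.valid_mask = np.asarray(self.valid_mask, bool)
        if self.valid_mask.shape != (T, ny, nx):
            raise FormatError("valid_mask shape inconsistent with arrays")
        if len(self.times) != T or len(self.grid_x) != nx or len(self.grid_y) != ny:
            raise FormatError("velocity field axes inconsistent with arrays")
        if nx > 1 and not np.all(np.diff(self.grid_x) > 0):
            raise FormatError("grid_x must be strictly increasing")
        if ny > 1 and not np.all(np.diff(self.grid_y) > 0):
            raise FormatError("grid_y must be strictly increasing")
        if not 0 <= self.overlap_fraction < 1:
            raise FormatError("overlap_fraction must be in [0, 1)")

    @property
    def n_frames(self) -> int:
        return self.vx.shape[0]

    def frame(self, t_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(vx, vy, valid) arrays for one time index."""
        return self.vx[t_index], self.vy[t_index], self.valid_mask[t_index]


@dataclass
class ImageStack:
    """T×H×W intensity stack with physical calibration."""

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_h: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError("image stack must be T×H×W with T ≥ 1")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size must be positive")
        if self.frame_interval_h <= 0:
            raise FormatError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class LabelMaskStack:
    """T×H×W integer label masks (0 = background) from external segmentation."""

    frames: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.min() < 0:
            raise FormatError("labels must be non-negative")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size must be positive")


_CONFIG_DEFAULTS: dict[str, object] = {
    "pixel_size_um": 0.65,
    "frame_interval_h": 1.0 / 12.0,     # 5 min
    "piv_window_um": 50.0,              # ≈5 cells per window
    "piv_overlap": 0.5,
    "framecut_h": (15.0, 40.0),
    "density_radius_um": 50.0,
    "rdf_bin_width_um": 2.0,
    "peak_window_h": 10.0,
    "v_rms_low": 5.0,                   # µm/h, classifier
    "l_corr_low_factor": 1.0,           # × piv window
    "exchange_slope_high": 0.08,        # µm/h, classifier
    "seed": 0,
}


@dataclass
class AnalysisConfig:
    """Run configuration with documented defaults.

    Defaults: PIV window 50 µm with 50% overlap, 5-min frame interval,
    50-µm density kernel, 15–40 h framecut for summary means.
    """

    pixel_size_um: float = 0.65
    frame_interval_h: float = 1.0 / 12.0
    piv_window_um: float = 50.0
    piv_overlap: float = 0.5
    framecut_h: tuple[float, float] = (15.0, 40.0)
    density_radius_um: float = 50.0
    rdf_bin_width_um: float = 2.0
    peak_window_h: float = 10.0
    v_rms_low: float = 5.0
    l_corr_low_factor: float = 1.0
    exchange_slope_high: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "frame_interval_h",
            "piv_window_um",
            "density_radius_um",
            "rdf_bin_width_um",
            "peak_window_h",
        ):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be positive")
        if not 0 <= self.piv_overlap < 1:
            raise FormatError("piv_overlap must be in [0, 1)")
        t0, t1 = self.framecut_h
        if not t0 < t1:
            raise FormatError("framecut requires t0 < t1")


# ---------------------------------------------------------------------------
# track CSV
# ---------------------------------------------------------------------------

_TRACKMATE_MAP = {
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_X": "x_um",
    "POSITION_Y": "y_um",
    "POSITION_T": "t_h",
    "AREA": "area_um2",
    "PERIMETER": "perimeter_um",
    "ELLIPSE_MAJOR": "major_um",
    "ELLIPSE_MINOR": "minor_um",
}


def read_tracks_csv(
    path: str | Path,
    dialect: str = "native",
    pixel_size_um: float | None = None,
    frame_interval_h: float | None = None,
) -> pd.DataFrame:
    """Read a track table from CSV.

    dialect="native" expects columns (track_id, frame, x, y | x_um, y_um,
    ...); pixel coordinates (columns x, y or x_px, y_px) require
    ``pixel_size_um``. dialect="trackmate" reads TrackMate spot-table
    exports (POSITION_X/Y/T, TRACK_ID, FRAME), skipping the extra header
    rows TrackMate emits (detected, not counted). TrackMate positions are
    assumed already calibrated (µm / h), matching its export convention.
    """
    path = Path(path)
    if dialect == "trackmate":
        df = _read_trackmate(path)
    elif dialect == "native":
        df = pd.read_csv(path)
        rename = {}
        if "x" in df.columns and "x_um" not in df.columns:
            rename.update({"x": "x_px", "y": "y_px"})
        df = df.rename(columns=rename)
        if "x_px" in df.columns:
            if pixel_size_um is None:
                raise FormatError(
                    "pixel coordinates present; pixel_size_um is required"
                )
            df["x_um"] = df["x_px"] * pixel_size_um
            df["y_um"] = df["y_px"] * pixel_size_um
    else:
        raise FormatError(f"unknown dialect {dialect!r}; use native|trackmate")

    if "t_h" not in df.columns:
        if frame_interval_h is None:
            raise FormatError("no t_h column; frame_interval_h is required")
        if "frame" not in df.columns:
            raise FormatError("track table missing required column 'frame'")
        df["t_h"] = df["frame"] * frame_interval_h
    if "frame" not in df.columns:
        raise FormatError("track table missing required column 'frame'")
    df["track_id"] = df["track_id"].astype(int)
    df["frame"] = df["frame"].astype(int)
    return validate_tracks(df)


def _read_trackmate(path: Path) -> pd.DataFrame:
    """TrackMate CSV exports carry up to three extra header rows (human
    label, units, and an empty row) after the column names; detect and skip
    any row whose FRAME/TRACK_ID fields are not numeric."""
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y") if c not in raw.columns]
    if missing:
        raise FormatError(f"TrackMate export missing column {missing[0]!r}")
    numeric = pd.to_numeric(raw["FRAME"], errors="coerce").notna() & pd.to_numeric(
        raw["TRACK_ID"], errors="coerce"
    ).notna()
    raw = raw[numeric]
    keep = {c: n for c, n in _TRACKMATE_MAP.items() if c in raw.columns}
    df = raw[list(keep)].rename(columns=keep)
    for col in df.columns:
        if col != "channel":
            df[col] = pd.to_numeric(df[col])
    return df


def write_tracks_csv(tracks: pd.DataFrame, path: str | Path) -> None:
    validate_tracks(tracks).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# velocity field archive (.pivz)
# ---------------------------------------------------------------------------

def write_velocity_field(field: VelocityField, path: str | Path) -> None:
    """Write a VelocityField as an NPZ archive with an embedded JSON header.

    No community standard exists for PIV grids; the archive is
    self-describing and round-trips bit-identically.
    """
    if field.n_frames == 0:
        raise FormatError("refusing to write an empty (T=0) velocity field")
    header = json.dumps(
        {
            "format": "flockmetrics.velocity_field",
            "version": 1,
            "window_size_um": field.window_size_um,
            "overlap_fraction": field.overlap_fraction,
            "pixel_size_um": field.pixel_size_um,
        }
    )
    np.savez_compressed(
        path,
        header=np.frombuffer(header.encode(), dtype=np.uint8),
        times=field.times,
        grid_x=field.grid_x,
        grid_y=field.grid_y,
        vx=field.vx,
        vy=field.vy,
        valid_mask=field.valid_mask,
    )


def read_velocity_field(path: str | Path) -> VelocityField:
    with np.load(path) as z:
        try:
            header = json.loads(bytes(z["header"]).decode())
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"not a velocity-field archive: {exc}") from exc
        if header.get("format") != "flockmetrics.velocity_field":
            raise FormatError("not a flockmetrics velocity-field archive")
        return VelocityField(
            times=z["times"],
            grid_x=z["grid_x"],
            grid_y=z["grid_y"],
            vx=z["vx"],
            vy=z["vy"],
            window_size_um=float(header["window_size_um"]),
            overlap_fraction=float(header["overlap_fraction"]),
            pixel_size_um=float(header["pixel_size_um"]),
            valid_mask=z["valid_mask"],
        )


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Multi-page TIFF with ImageJ-compatible calibration metadata."""
    frames = np.asarray(stack.frames)
    if frames.dtype != np.uint16:
        frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        frames,
        imagej=True,
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata={
            "unit": "um",
            "finterval": stack.frame_interval_h * 3600.0,
            "axes": "TYX",
        },
    )


def read_image_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_h: float | None = None,
) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        if pixel_size_um is None:
            try:
                xres = tif.pages[0].tags["XResolution"].value
                pixel_size_um = xres[1] / xres[0]
            except (KeyError, ZeroDivisionError):
                raise FormatError(
                    "TIFF has no resolution tag; pass pixel_size_um"
                ) from None
        if frame_interval_h is None:
            meta = tif.imagej_metadata or {}
            if "finterval" in meta:
                frame_interval_h = float(meta["finterval"]) / 3600.0
            else:
                raise FormatError(
                    "TIFF has no frame interval; pass frame_interval_h"
                )
    return ImageStack(frames, pixel_size_um, frame_interval_h)


def read_label_masks(path: str | Path, pixel_size_um: float) -> LabelMaskStack:
    frames = tifffile.imread(path)
    return LabelMaskStack(frames, pixel_size_um)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None = None, text: str | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key-value file.

    Absent keys take the documented defaults; unknown keys produce a
    warning (not an error) so configs stay forward-compatible; invalid
    values raise :class:`FormatError`.
    """
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    data = yaml.safe_load(_io.StringIO(text)) or {}
    if not isinstance(data, dict):
        raise FormatError("config must be a key-value mapping")
    known = set(_CONFIG_DEFAULTS)
    kwargs: dict[str, object] = {}
    for key, value in data.items():
        if key not in known:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
            continue
        if key == "framecut_h":
            value = tuple(float(v) for v in value)
        kwargs[key] = value
    try:
        return AnalysisConfig(**kwargs)
    except TypeError as exc:
        raise FormatError(str(exc)) from exc


__all__ = [
    "AnalysisConfig",
    "FormatError",
    "ImageStack",
    "LabelMaskStack",
    "TRACK_COLUMNS",
    "VelocityField",
    "load_config",
    "read_image_stack",
    "read_label_masks",
    "read_tracks_csv",
    "read_velocity_field",
    "validate_tracks",
    "write_image_stack",
    "write_tracks_csv",
    "write_velocity_field",
]
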