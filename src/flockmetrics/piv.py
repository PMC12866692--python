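"""Cross-correlation particle image velocimetry.

Single-pass PIV: each frame pair is tiled into interrogation windows
(default 50 × 50 µm with 50% overlap — about five cells per window at
confluent density), each window pair is zero-normalized and circularly
cross-correlated via FFT, and the displacement is the correlation peak
with optional three-point Gaussian subpixel refinement. Velocities are
displacement · pixel_size / frame_interval in µm/h.

Validation: windows with no texture or a low peak signal-to-noise ratio,
and vectors failing the normalized-median neighborhood test (ε = 0.1 px,
threshold 2.0 — the common community default), are flagged invalid and
replaced by the median of their valid neighbors; replacements stay
flagged so downstream statistics can exclude them. Border windows that
do not fully fit are dropped, not padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FormatError, ImageStack, VelocityField


@dataclass
class PivParams:
    window_size_um: float = 50.0
    overlap_fraction: float = 0.5
    subpixel: str = "gaussian3"          # gaussian3 | parabolic | none
    outlier_epsilon_px: float = 0.1
    outlier_threshold: float = 2.0
    min_signal_to_noise: float = 1.05    # peak1/peak2 ratio; ≤ 1 disables

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.subpixel not in ("gaussian3", "parabolic", "none"):
            raise ValueError(f"unknown subpixel mode {self.subpixel!r}")


def piv_window_geometry(
    frame_shape: tuple[int, int], window_px: int, overlap_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Window-center pixel coordinates (x_centers, y_centers).

    Centers are spaced window·(1−overlap) apart starting at window/2;
    windows that would overrun the frame are dropped."""
    h, w = frame_shape
    step = max(int(round(window_px * (1.0 - overlap_fraction))), 1)
    half = window_px / 2.0

    def centers(dim: int) -> np.ndarray:
        c = np.arange(half, dim - half + 1e-9, step)
        return c[c + half <= dim + 1e-9]

    return centers(w), centers(h)


def _subpixel_offset(c_minus: float, c_zero: float, c_plus: float, mode: str) -> float:
    if mode == "none":
        return 0.0
    if mode == "gaussian3" and min(c_minus, c_zero, c_plus) > 0:
        denom = 2.0 * np.log(c_minus) - 4.0 * np.log(c_zero) + 2.0 * np.log(c_plus)
        if denom != 0:
            return float(np.clip((np.log(c_minus) - np.log(c_plus)) / denom, -1.0, 1.0))
    denom = 2.0 * (c_minus - 2.0 * c_zero + c_plus)
    if denom != 0:
        return float(np.clip((c_minus - c_plus) / denom, -1.0, 1.0))
    return 0.0


def _normalized_median_outliers(
    u: np.ndarray, valid: np.ndarray, eps: float, threshold: float
) -> np.ndarray:
    """Westerweel–Scarano normalized median test on one component.
    Returns a boolean map of detected outliers."""
    ny, nx = u.shape
    out = np.zeros_like(valid)
    for iy in range(ny):
        for ix in range(nx):
            if not valid[iy, ix]:
                continue
            ys = slice(max(iy - 1, 0), min(iy + 2, ny))
            xs = slice(max(ix - 1, 0), min(ix + 2, nx))
            nb = u[ys, xs].copy()
            vb = valid[ys, xs].copy()
            vb[iy - max(iy - 1, 0), ix - max(ix - 1, 0)] = False
            vals = nb[vb]
            if vals.size < 3:
                continue
            med = np.median(vals)
            fluct = np.median(np.abs(vals - med))
            if np.abs(u[iy, ix] - med) / (fluct + eps) > threshold:
                out[iy, ix] = True
    return out


def _fill_invalid(u: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid vectors by the median of valid 8-neighbors,
    iterating outward; isolated holes fall back to the global median."""
    out = u.copy()
    todo = ~valid
    guard = 0
    while todo.any() and guard < 100:
        guard += 1
        progressed = False
        ny, nx = u.shape
        for iy, ix in zip(*np.nonzero(todo)):
            ys = slice(max(iy - 1, 0), min(iy + 2, ny))
            xs = slice(max(ix - 1, 0), min(ix + 2, nx))
            vals = out[ys, xs][valid[ys, xs]]
            if vals.size:
                out[iy, ix] = np.median(vals)
                todo[iy, ix] = False
                progressed = True
        if not progressed:
            out[todo] = np.median(out[valid]) if valid.any() else 0.0
            break
    return out


def compute_piv(stack: ImageStack, params: PivParams | None = None) -> VelocityField:
    """PIV velocity field from consecutive frame pairs of a stack."""
    params = params or PivParams()
    if stack.n_frames < 2:
        raise FormatError("PIV needs at least two frames")
    window_px = int(round(params.window_size_um / stack.pixel_size_um))
    if window_px < 8:
        raise FormatError(
            f"interrogation window {window_px} px below the 8-px minimum"
        )
    h, w = stack.frames.shape[1:]
    if window_px > min(h, w):
        raise FormatError("interrogation window larger than the frame")
    cx, cy = piv_window_geometry((h, w), window_px, params.overlap_fraction)
    nx, ny = len(cx), len(cy)
    x0 = (cx - window_px / 2.0).astype(int)
    y0 = (cy - window_px / 2.0).astype(int)

    T = stack.n_frames - 1
    vx = np.zeros((T, ny, nx))
    vy = np.zeros((T, ny, nx))
    valid = np.zeros((T, ny, nx), bool)
    half = window_px // 2
    frames = stack.frames.astype(float)

    for t in range(T):
        a_frame, b_frame = frames[t], frames[t + 1]
        wins_a = np.empty((ny * nx, window_px, window_px))
        wins_b = np.empty_like(wins_a)
        k = 0
        for iy in range(ny):
            for ix in range(nx):
                ys = slice(y0[iy], y0[iy] + window_px)
                xs = slice(x0[ix], x0[ix] + window_px)
                wins_a[k] = a_frame[ys, xs]
                wins_b[k] = b_frame[ys, xs]
                k += 1
        wins_a -= wins_a.mean(axis=(1, 2), keepdims=True)
        wins_b -= wins_b.mean(axis=(1, 2), keepdims=True)
        fa = np.fft.rfft2(wins_a)
        fb = np.fft.rfft2(wins_b)
        cc = np.fft.irfft2(np.conj(fa) * fb, s=(window_px, window_px))
        # Non-periodic window content makes circular correlation carry an
        # implicit triangular overlap taper (1 − |k|/w per axis) that
        # biases broad peaks toward zero displacement; divide it out and
        # keep the search inside |k| ≤ w/3 where the correction is mild.
        lag = np.minimum(np.arange(window_px), window_px - np.arange(window_px))
        taper = np.outer(1.0 - lag / window_px, 1.0 - lag / window_px)
        cc = cc / taper
        search = np.outer(lag <= window_px // 3, lag <= window_px // 3)

        std_a = wins_a.std(axis=(1, 2))
        std_b = wins_b.std(axis=(1, 2))
        for k in range(ny * nx):
            iy, ix = divmod(k, nx)
            if std_a[k] == 0 or std_b[k] == 0:
                continue  # texture-free window: invalid
            c = cc[k]
            c_search = np.where(search, c, -np.inf)
            pk = np.unravel_index(np.argmax(c_search), c.shape)
            peak1 = c[pk]
            if params.min_signal_to_noise > 1.0:
                masked = c_search.copy()
                ys = (np.arange(pk[0] - 1, pk[0] + 2)) % window_px
                xs = (np.arange(pk[1] - 1, pk[1] + 2)) % window_px
                masked[np.ix_(ys, xs)] = -np.inf
                peak2 = masked.max()
                baseline = c[search].min()
                if peak2 > baseline and (peak1 - baseline) / (peak2 - baseline) < params.min_signal_to_noise:
                    continue
            dy_i, dx_i = pk
            sub_y = _subpixel_offset(
                c[(dy_i - 1) % window_px, dx_i], peak1, c[(dy_i + 1) % window_px, dx_i],
                params.subpixel,
            )
            sub_x = _subpixel_offset(
                c[dy_i, (dx_i - 1) % window_px], peak1, c[dy_i, (dx_i + 1) % window_px],
                params.subpixel,
            )
            dx = dx_i if dx_i <= half else dx_i - window_px
            dy = dy_i if dy_i <= half else dy_i - window_px
            vx[t, iy, ix] = dx + sub_x
            vy[t, iy, ix] = dy + sub_y
            valid[t, iy, ix] = True

        # iterate the median test: clustered outliers (e.g. periodic-
        # texture ambiguities) are peeled from the edges inward
        for _ in range(5):
            out_x = _normalized_median_outliers(
                vx[t], valid[t], params.outlier_epsilon_px, params.outlier_threshold
            )
            out_y = _normalized_median_outliers(
                vy[t], valid[t], params.outlier_epsilon_px, params.outlier_threshold
            )
            bad = out_x | out_y
            if not bad.any():
                break
            valid[t] &= ~bad
        if not valid[t].all():
            vx[t] = _fill_invalid(vx[t], valid[t])
            vy[t] = _fill_invalid(vy[t], valid[t])

    scale = stack.pixel_size_um / stack.frame_interval_h
    return VelocityField(
        times=np.arange(T) * stack.frame_interval_h,
        grid_x=cx * stack.pixel_size_um,
        grid_y=cy * stack.pixel_size_um,
        vx=vx * scale,
        vy=vy * scale,
        window_size_um=window_px * stack.pixel_size_um,
        overlap_fraction=params.overlap_fraction,
        pixel_size_um=stack.pixel_size_um,
        valid_mask=valid,
    )


__all__ = ["PivParams", "compute_piv", "piv_window_geometry"]
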