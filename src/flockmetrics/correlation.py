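"""Spatial velocity correlation and the correlation length L_CORR.

The two-point equal-time correlation of a gridded velocity field
v = (v_x, v_y) is computed with the Fourier method,

    C_vv(r) = F⁻¹( |F(v_x)|² + |F(v_y)|² ) / N,

using the periodic (circular) convention, which matches a direct average
over all circular shifts exactly. Because coherent motion gives the field
a nonzero mean, the curve is corrected by subtracting the mean velocity
variance, C'(r) = C(r) − |⟨v⟩|², then normalized to C'(0) = 1. The
correlation length and stretching exponent come from a bounded
least-squares fit of

    C_norm(r) = exp(−(r / L_CORR)^γ),        γ ∈ (0, 2]

over r from the first nonzero bin to half the box (beyond which periodic
aliasing corrupts the curve). γ = 1 reproduces a plain exponential decay.

By default the field is drift-corrected (per-frame mean removed) before
correlation, so the statistic measures velocity *fluctuations*; the
uncorrected route plus the explicit variance subtraction is available
with ``drift_correct=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import curve_fit

from .io import VelocityField


@dataclass
class CorrelationCurve:
    """Radially averaged velocity correlation with its fit record."""

    r_um: np.ndarray
    C: np.ndarray               # raw radial average
    C_corrected: np.ndarray     # after mean-variance subtraction
    C_normalized: np.ndarray    # C_corrected / C_corrected(0)
    n_pairs: np.ndarray
    fit: dict = dc_field(default_factory=dict)


def inpaint_invalid(
    component: np.ndarray, valid: np.ndarray, max_invalid_fraction: float = 0.3
) -> np.ndarray:
    """Fill invalid grid entries with the median of valid 8-neighbors,
    iterating until full; refuses when more than ``max_invalid_fraction``
    of the grid is invalid (inpainting would dominate the statistic)."""
    valid = np.asarray(valid, bool)
    frac = 1.0 - valid.mean()
    if frac > max_invalid_fraction:
        raise ValueError(
            f"{frac:.0%} of vectors invalid exceeds the "
            f"{max_invalid_fraction:.0%} inpainting cap"
        )
    out = np.array(component, float)
    mask = ~valid
    out[mask] = np.nan
    while np.isnan(out).any():
        nanmask = np.isnan(out)
        padded = np.pad(out, 1, constant_values=np.nan)
        stacks = [
            padded[1 + dy : padded.shape[0] - 1 + dy, 1 + dx : padded.shape[1] - 1 + dx]
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dy, dx) != (0, 0)
        ]
        neigh = np.stack(stacks)
        with np.errstate(all="ignore"):
            med = np.nanmedian(neigh, axis=0)
        fill = nanmask & np.isfinite(med)
        if not fill.any():
            raise ValueError("inpainting stalled: isolated invalid region")
        out[fill] = med[fill]
    return out


def spatial_correlation_2d(
    vx: np.ndarray,
    vy: np.ndarray,
    valid: np.ndarray | None = None,
    drift_correct: bool = True,
) -> np.ndarray:
    """Periodic 2D velocity autocorrelation map of one frame.

    Returns C(r) with zero lag at index [0, 0] (FFT convention);
    C[dy, dx] = (1/N) Σ_x v(x)·v(x + (dx, dy)) with circular wrapping.
    """
    vx = np.asarray(vx, float)
    vy = np.asarray(vy, float)
    if valid is not None and not np.all(valid):
        vx = inpaint_invalid(vx, valid)
        vy = inpaint_invalid(vy, valid)
    if drift_correct:
        vx = vx - vx.mean()
        vy = vy - vy.mean()
    n = vx.size
    fx = np.fft.fft2(vx)
    fy = np.fft.fft2(vy)
    return np.fft.ifft2(np.abs(fx) ** 2 + np.abs(fy) ** 2).real / n


def lag_grid_um(shape: tuple[int, int], spacing_um: float) -> np.ndarray:
    """Modulus of the (signed, wrapped) lag vector for each map entry."""
    ny, nx = shape
    ly = np.fft.fftfreq(ny, d=1.0 / ny) * spacing_um
    lx = np.fft.fftfreq(nx, d=1.0 / nx) * spacing_um
    return np.hypot(ly[:, None], lx[None, :])


def radial_average(
    map2d: np.ndarray, spacing_um: float, bin_width_um: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Azimuthal average of a correlation map (zero lag at [0, 0]).

    Bins are half-open annuli of width ``bin_width_um`` (default: one
    grid spacing); empty bins are dropped. Returns (r_centers, C(r),
    n_pairs)."""
    if bin_width_um is None:
        bin_width_um = spacing_um
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    lags = lag_grid_um(map2d.shape, spacing_um).ravel()
    vals = np.asarray(map2d, float).ravel()
    idx = np.floor(lags / bin_width_um).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    keep = counts > 0
    centers = (np.arange(n_bins) + 0.5) * bin_width_um
    centers[0] = 0.0  # the zero-lag bin reports r = 0 exactly
    return centers[keep], sums[keep] / counts[keep], counts[keep]


def correct_and_normalize(
    r_um: np.ndarray, C: np.ndarray, mean_velocity_sq: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Apply the mean-variance correction and normalize to C'(0) = 1.

    C'(r) = C(r) − |⟨v⟩|². Returns (C_corrected, C_normalized,
    converged); a non-positive C'(0) (degenerate field, e.g. uniform
    motion after drift removal) flags not-converged instead of dividing.
    """
    C_corr = np.asarray(C, float) - mean_velocity_sq
    c0 = C_corr[np.argmin(np.asarray(r_um, float))]
    if not np.isfinite(c0) or c0 <= 0:
        return C_corr, np.full_like(C_corr, np.nan), False
    return C_corr, C_corr / c0, True


def _stretched_exp(r: np.ndarray, L: float, gamma: float) -> np.ndarray:
    return np.exp(-((r / L) ** gamma))


def fit_correlation_length(
    r_um: np.ndarray,
    c_normalized: np.ndarray,
    r_min_um: float | None = None,
    r_max_um: float | None = None,
) -> dict:
    """Fit C_norm(r) = exp(−(r/L)^γ) and return the fit record.

    The r = 0 bin (self-correlation) is always excluded; the default
    range runs from the first nonzero bin to the largest available lag.
    Initialisation: L₀ from the linear-interpolated 1/e crossing (or
    r_max/2 when the curve never crosses), γ₀ = 1; bounds L > 0,
    γ ∈ (0, 2]. Failure returns a not-converged record with diagnostics,
    never a silent fallback.
    """
    r = np.asarray(r_um, float)
    c = np.asarray(c_normalized, float)
    if r_max_um is None:
        r_max_um = float(r.max())
    if r_min_um is None:
        r_min_um = float(r[r > 0].min()) if np.any(r > 0) else 0.0
    sel = (r >= r_min_um) & (r <= r_max_um) & (r > 0) & np.isfinite(c)
    record = {
        "l_corr_um": np.nan,
        "gamma": np.nan,
        "rmse": np.nan,
        "r_range_used": (r_min_um, r_max_um),
        "converged": False,
        "message": "",
    }
    if sel.sum() < 5:
        record["message"] = f"only {int(sel.sum())} bins in fit range (need ≥ 5)"
        return record
    rr, cc = r[sel], c[sel]

    below = np.nonzero(cc < np.exp(-1.0))[0]
    if below.size and below[0] > 0:
        i = below[0]
        f = (np.exp(-1.0) - cc[i - 1]) / (cc[i] - cc[i - 1])
        L0 = float(rr[i - 1] + f * (rr[i] - rr[i - 1]))
    elif below.size:
        L0 = float(rr[0])
    else:
        L0 = r_max_um / 2.0
    L0 = max(L0, 1e-6)
    try:
        popt, _ = curve_fit(
            _stretched_exp,
            rr,
            cc,
            p0=[L0, 1.0],
            bounds=([1e-9, 1e-3], [np.inf, 2.0]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        record["message"] = f"least-squares failure: {exc}"
        return record
    resid = cc - _stretched_exp(rr, *popt)
    record.update(
        l_corr_um=float(popt[0]),
        gamma=float(popt[1]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        converged=True,
    )
    return record


def correlation_over_window(
    velocity_field: VelocityField,
    frames: np.ndarray | None = None,
    drift_correct: bool = True,
    bin_width_um: float | None = None,
    r_max_um: float | None = None,
) -> CorrelationCurve:
    """Frame-averaged correlation curve with L_CORR fit.

    Per-frame 2D maps are averaged *before* radial averaging and fitting,
    as is the correlation-map normalisation. With ``drift_correct`` off,
    the mean-velocity variance (frame-averaged |⟨v⟩|²) is subtracted from
    the radial curve instead. The fit range is capped at half the grid
    extent unless ``r_max_um`` narrows it further.
    """
    if frames is None:
        frames = np.arange(velocity_field.n_frames)
    frames = np.atleast_1d(frames).astype(int)
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    spacing = velocity_field.window_size_um * (1.0 - velocity_field.overlap_fraction)
    acc = None
    mean_v_sq = 0.0
    for t in frames:
        vx, vy, valid = velocity_field.frame(t)
        m = spatial_correlation_2d(vx, vy, valid, drift_correct=drift_correct)
        acc = m if acc is None else acc + m
        if not drift_correct:
            vxi = vx[valid] if not np.all(valid) else vx
            vyi = vy[valid] if not np.all(valid) else vy
            mean_v_sq += np.hypot(vxi.mean(), vyi.mean()) ** 2
    acc /= len(frames)
    mean_v_sq /= len(frames)
    if drift_correct:
        mean_v_sq = 0.0  # per-frame mean already removed

    r, C, n_pairs = radial_average(acc, spacing, bin_width_um)
    C_corr, C_norm, converged = correct_and_normalize(r, C, mean_v_sq)
    box_half = min(acc.shape[0], acc.shape[1]) * spacing / 2.0
    r_cap = box_half if r_max_um is None else min(r_max_um, box_half)
    if converged:
        fit = fit_correlation_length(r, C_norm, r_max_um=r_cap)
    else:
        fit = {
            "l_corr_um": np.nan,
            "gamma": np.nan,
            "rmse": np.nan,
            "r_range_used": (np.nan, r_cap),
            "converged": False,
            "message": "degenerate correlation: C'(0) ≤ 0",
        }
    return CorrelationCurve(r, C, C_corr, C_norm, n_pairs, fit)


__all__ = [
    "CorrelationCurve",
    "correct_and_normalize",
    "correlation_over_window",
    "fit_correlation_length",
    "inpaint_invalid",
    "lag_grid_um",
    "radial_average",
    "spatial_correlation_2d",
]
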