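"""Self-propelled-particle monolayer simulator.

Generates labeled ground truth for every analysis stage: cell tracks in
each of the four dynamic tissue regimes (jammed solid, disordered fluid,
flocking fluid, flocking solid), rendered nuclei movies, synthetic FRAP
stacks and wetting-area series.

Model
-----
Overdamped soft disks with continuous-time Vicsek alignment in a periodic
square box. Each cell i carries a position r_i (µm) and a heading θ_i:

    dr_i/dt = v0 · n(θ_i) + μ [ Σ_j F_rep(r_ij) + Σ_b F_bond(r_ib) ]
    dθ_i/dt = J · sin(Θ_i − θ_i) + sqrt(2 D_r) ξ(t)

where n(θ) = (cosθ, sinθ), Θ_i is the circular mean heading of cells
within the alignment radius (self included), F_rep is a linear soft-disk
repulsion active below 2a, and F_bond are optional harmonic springs to the
initial Delaunay neighbors (k_bond > 0 suppresses neighbor exchange while
allowing aligned drift — the flocking-solid regime). With k_rep = k_bond
= 0 the update reduces to a continuous-time Vicsek model.

Units are µm and hours throughout, matching typical monolayer speeds of
3–30 µm/h at 5-min frame intervals. Alignment as torque relaxation (not
velocity averaging) keeps the dynamics well-defined at contact.

Determinism: a single master seed is split into independent sub-streams
(initialisation, rotational noise, rendering) so that adding rendering
never perturbs the trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .io import ImageStack

REGIMES = ("jammed_solid", "disordered_fluid", "flocking_fluid", "flocking_solid")

Regime = Literal["jammed_solid", "disordered_fluid", "flocking_fluid", "flocking_solid"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one monolayer run (units: µm, hours, radians)."""

    n_cells: int
    box_size_um: float
    cell_radius_um: float
    v0: float                 # self-propulsion speed, µm/h
    align_rate: float         # J, heading relaxation toward local mean, 1/h
    rot_diffusion: float      # D_r, rad²/h
    k_rep: float              # soft-disk repulsion stiffness, 1/h
    k_bond: float             # harmonic bond stiffness, 1/h (0 disables)
    align_radius_um: float
    dt_h: float
    duration_h: float
    frame_interval_h: float = 1.0 / 12.0   # 5 min
    seed: int = 0
    regime_label: str | None = None
    #: von Mises concentration of the initial heading distribution; 0 means
    #: uniform. Flocking presets use a weak bias (κ ≈ 1.5, initial ψ ≈ 0.6)
    #: to break the rotational symmetry the way a real monolayer picks a
    #: direction, instead of waiting out slow domain coarsening.
    init_heading_kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be ≥ 2")
        if self.box_size_um <= 4 * self.cell_radius_um:
            raise ValueError("box_size must exceed 4 cell radii")
        if not self.dt_h < self.frame_interval_h:
            raise ValueError("dt must be smaller than frame_interval")
        phi = self.packing_fraction
        if not 0.5 < phi < 1.2:
            raise ValueError(
                f"packing fraction {phi:.3f} outside the confluent range (0.5, 1.2)"
            )
        if self.regime_label is not None and self.regime_label not in REGIMES:
            raise ValueError(
                f"unknown regime {self.regime_label!r}; valid: {', '.join(REGIMES)}"
            )

    @property
    def packing_fraction(self) -> float:
        return self.n_cells * np.pi * self.cell_radius_um**2 / self.box_size_um**2


def make_regime_config(regime: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Documented preset for one of the four dynamic regimes.

    Presets share geometry (400 cells of radius 10 µm at packing fraction
    0.85, 12 h at 5-min frames) and differ only in propulsion, alignment,
    noise and bonding:

    ==================  ====  ===  =====  ======
    regime              v0    J    D_r    k_bond
    ==================  ====  ===  =====  ======
    jammed_solid         0.5  1.0  0.5     0
    disordered_fluid    30.0  0.0  3.0     0
    flocking_fluid      25.0  8.0  0.6     0
    flocking_solid      25.0  8.0  0.6    20
    ==================  ====  ===  =====  ======

    The flocking presets start from a weakly biased heading distribution
    (von Mises κ = 1.5 around a seed-dependent direction) so the flock's
    direction is set early, as in monolayers that break symmetry during
    activation; the flocking-solid preset bonds each cell to its initial
    Delaunay neighbors (and integrates with a smaller step for bond
    stability), suppressing rearrangement while allowing aligned drift.
    """
    if regime not in REGIMES:
        raise ValueError(
            f"unknown regime {regime!r}; valid regimes: {', '.join(REGIMES)}"
        )
    n_cells = int(overrides.pop("n_cells", 400))
    a = float(overrides.pop("cell_radius_um", 10.0))
    phi = 0.85
    box = float(np.sqrt(n_cells * np.pi * a**2 / phi))
    base = dict(
        n_cells=n_cells,
        box_size_um=box,
        cell_radius_um=a,
        k_rep=25.0,
        align_radius_um=3.0 * a,
        dt_h=0.02,
        duration_h=12.0,
        frame_interval_h=1.0 / 12.0,
        seed=seed,
        regime_label=regime,
    )
    presets = {
        "jammed_solid": dict(v0=0.5, align_rate=1.0, rot_diffusion=0.5, k_bond=0.0),
        "disordered_fluid": dict(v0=30.0, align_rate=0.0, rot_diffusion=3.0, k_bond=0.0),
        "flocking_fluid": dict(
            v0=25.0, align_rate=8.0, rot_diffusion=0.6, k_bond=0.0,
            init_heading_kappa=1.5,
        ),
        "flocking_solid": dict(
            v0=25.0, align_rate=8.0, rot_diffusion=0.6, k_bond=20.0,
            init_heading_kappa=1.5, dt_h=0.005,
        ),
    }
    base.update(presets[regime])
    base.update(overrides)
    return SimulationConfig(**base)


def _initial_positions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered square lattice — near-uniform density without overlap blow-up."""
    n_side = int(np.ceil(np.sqrt(cfg.n_cells)))
    spacing = cfg.box_size_um / n_side
    ix = np.arange(n_side)
    gx, gy = np.meshgrid(ix, ix, indexing="xy")
    pts = (np.stack([gx.ravel(), gy.ravel()], axis=1) + 0.5) * spacing
    pts = pts[rng.permutation(len(pts))[: cfg.n_cells]]
    pts += rng.uniform(-0.2, 0.2, pts.shape) * cfg.cell_radius_um
    return np.mod(pts, cfg.box_size_um)


def _delaunay_bonds(pos: np.ndarray, box: float) -> np.ndarray:
    """Edges of the periodic Delaunay triangulation, as (i, j) index pairs.

    Built by 3×3 tiling; only edges with at least one endpoint in the
    central copy are kept, mapped back to original indices.
    """
    n = len(pos)
    shifts = np.array([(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)], float)
    tiled = (pos[None, :, :] + shifts[:, None, :] * box).reshape(-1, 2)
    tri = Delaunay(tiled)
    center = 4 * n  # index offset of the (0,0) copy in `shifts` order
    edges = set()
    for simplex in tri.simplices:
        for u in range(3):
            p, q = simplex[u], simplex[(u + 1) % 3]
            if center <= p < center + n or center <= q < center + n:
                i, j = int(p % n), int(q % n)
                if i != j:
                    edges.add((min(i, j), max(i, j)))
    return np.array(sorted(edges), dtype=int)


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def simulate_monolayer(config: SimulationConfig) -> pd.DataFrame:
    """Integrate the monolayer model and return a TrackTable.

    Columns: track_id, frame, t_h, x_um, y_um (wrapped into the box),
    theta_rad, x_unwrap_um, y_unwrap_um (periodic images unwound, so that
    per-track displacement statistics are correct).

    Sampling: positions are recorded every ``frame_interval_h``; the
    integrator step is adjusted to the nearest integer divisor of the
    frame interval so frame times are exact.

    Raises RuntimeError with a displacement diagnostic if the state blows
    up (non-finite positions or a per-step displacement beyond a quarter
    box).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_noise, _rng_render = (np.random.default_rng(s) for s in ss.spawn(3))

    steps_per_frame = max(1, round(cfg.frame_interval_h / cfg.dt_h))
    dt = cfg.frame_interval_h / steps_per_frame
    n_frames = int(np.floor(cfg.duration_h / cfg.frame_interval_h)) + 1

    pos = _initial_positions(cfg, rng_init)
    unwrap = pos.copy()
    if cfg.init_heading_kappa > 0:
        mu = rng_init.uniform(0.0, 2.0 * np.pi)
        theta = rng_init.vonmises(mu, cfg.init_heading_kappa, cfg.n_cells)
    else:
        theta = rng_init.uniform(0.0, 2.0 * np.pi, cfg.n_cells)

    bonds = None
    rest = None
    if cfg.k_bond > 0:
        bonds = _delaunay_bonds(pos, cfg.box_size_um)
        dvec = _min_image(pos[bonds[:, 1]] - pos[bonds[:, 0]], cfg.box_size_um)
        rest = np.hypot(dvec[:, 0], dvec[:, 1])
        # drop spurious long tiling edges (> 2 alignment radii)
        keep = rest < 2.0 * cfg.align_radius_um
        bonds, rest = bonds[keep], rest[keep]

    cutoff = max(2.0 * cfg.cell_radius_um, cfg.align_radius_um)
    noise_amp = np.sqrt(2.0 * cfg.rot_diffusion * dt)

    records_x = np.empty((n_frames, cfg.n_cells))
    records_y = np.empty((n_frames, cfg.n_cells))
    records_ux = np.empty((n_frames, cfg.n_cells))
    records_uy = np.empty((n_frames, cfg.n_cells))
    records_th = np.empty((n_frames, cfg.n_cells))

    def record(f: int) -> None:
        records_x[f] = pos[:, 0]
        records_y[f] = pos[:, 1]
        records_ux[f] = unwrap[:, 0]
        records_uy[f] = unwrap[:, 1]
        records_th[f] = np.mod(theta, 2.0 * np.pi)

    record(0)
    for f in range(1, n_frames):
        for _ in range(steps_per_frame):
            tree = cKDTree(pos, boxsize=cfg.box_size_um)
            pairs = tree.query_pairs(cutoff, output_type="ndarray")
            force = np.zeros_like(pos)
            # local mean heading as mean unit vector (self included)
            hx = np.cos(theta).copy()
            hy = np.sin(theta).copy()
            if len(pairs):
                i, j = pairs[:, 0], pairs[:, 1]
                dvec = _min_image(pos[j] - pos[i], cfg.box_size_um)
                dist = np.hypot(dvec[:, 0], dvec[:, 1])
                dist = np.maximum(dist, 1e-9)
                # soft-disk repulsion below contact distance 2a
                overlap = 2.0 * cfg.cell_radius_um - dist
                rep = overlap > 0
                if rep.any():
                    f_mag = cfg.k_rep * overlap[rep] / dist[rep]
                    fvec = -f_mag[:, None] * dvec[rep]
                    np.add.at(force, i[rep], fvec)
                    np.add.at(force, j[rep], -fvec)
                if cfg.align_rate > 0:
                    aligned = dist < cfg.align_radius_um
                    ia, ja = i[aligned], j[aligned]
                    np.add.at(hx, ia, np.cos(theta[ja]))
                    np.add.at(hy, ia, np.sin(theta[ja]))
                    np.add.at(hx, ja, np.cos(theta[ia]))
                    np.add.at(hy, ja, np.sin(theta[ia]))
            if bonds is not None and len(bonds):
                bvec = _min_image(pos[bonds[:, 1]] - pos[bonds[:, 0]], cfg.box_size_um)
                bdist = np.maximum(np.hypot(bvec[:, 0], bvec[:, 1]), 1e-9)
                f_mag = cfg.k_bond * (bdist - rest) / bdist
                fvec = f_mag[:, None] * bvec
                np.add.at(force, bonds[:, 0], fvec)
                np.add.at(force, bonds[:, 1], -fvec)

            disp = dt * (
                cfg.v0 * np.stack([np.cos(theta), np.sin(theta)], axis=1) + force
            )
            max_disp = float(np.max(np.hypot(disp[:, 0], disp[:, 1]), initial=0.0))
            if not np.isfinite(max_disp) or max_disp > cfg.box_size_um / 4:
                raise RuntimeError(
                    f"simulation blow-up at frame {f}: max displacement per "
                    f"step {max_disp:.3g} µm (box {cfg.box_size_um:.3g} µm); "
                    "reduce dt or stiffnesses"
                )
            pos = pos + disp
            unwrap = unwrap + disp
            pos = np.mod(pos, cfg.box_size_um)

            if cfg.align_rate > 0:
                target = np.arctan2(hy, hx)
                dtheta = cfg.align_rate * np.sin(target - theta) * dt
            else:
                dtheta = 0.0
            theta = theta + dtheta + noise_amp * rng_noise.standard_normal(cfg.n_cells)
        record(f)

    frames = np.repeat(np.arange(n_frames), cfg.n_cells)
    ids = np.tile(np.arange(cfg.n_cells), n_frames)
    table = pd.DataFrame(
        {
            "track_id": ids,
            "frame": frames,
            "t_h": frames * cfg.frame_interval_h,
            "x_um": records_x.ravel(),
            "y_um": records_y.ravel(),
            "theta_rad": records_th.ravel(),
            "x_unwrap_um": records_ux.ravel(),
            "y_unwrap_um": records_uy.ravel(),
        }
    )
    return table.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_frames(
    tracks: pd.DataFrame,
    pixel_size_um: float,
    image_shape: tuple[int, int] | None = None,
    psf_sigma_px: float = 3.0,
    amplitude: float = 3000.0,
    background: float = 300.0,
    noise_level: float = 1.0,
    read_noise: float = 10.0,
    seed: int = 0,
) -> ImageStack:
    """Render tracks as a 16-bit nuclei movie (Gaussian blobs + noise).

    Each cell becomes an isotropic Gaussian of width ``psf_sigma_px``;
    ``noise_level`` scales Poisson shot noise (0 disables all noise) and
    ``read_noise`` adds Gaussian camera noise. Wrapped coordinates are
    used, so blobs wrap around the box like the periodic dynamics.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size must be positive")
    if len(tracks) == 0:
        raise ValueError("empty track table")
    rng = np.random.default_rng(seed)
    frames_idx = np.sort(tracks["frame"].unique())
    if image_shape is None:
        extent = float(max(tracks["x_um"].max(), tracks["y_um"].max()))
        npx = int(np.ceil(extent / pixel_size_um)) + 1
        image_shape = (npx, npx)
    h, w = image_shape
    t_by_frame = tracks.groupby("frame")
    halo = int(np.ceil(4 * psf_sigma_px))
    stamp_ax = np.arange(-halo, halo + 1)
    frame_interval = _infer_frame_interval(tracks)

    out = np.empty((len(frames_idx), h, w), np.uint16)
    for k, f in enumerate(frames_idx):
        sub = t_by_frame.get_group(f)
        img = np.full((h, w), float(background))
        cx = sub["x_um"].to_numpy() / pixel_size_um
        cy = sub["y_um"].to_numpy() / pixel_size_um
        for x0, y0 in zip(cx, cy):
            ix, iy = int(np.round(x0)), int(np.round(y0))
            gx = np.exp(-((stamp_ax + ix - x0) ** 2) / (2 * psf_sigma_px**2))
            gy = np.exp(-((stamp_ax + iy - y0) ** 2) / (2 * psf_sigma_px**2))
            stamp = amplitude * gy[:, None] * gx[None, :]
            ys = (stamp_ax + iy) % h
            xs = (stamp_ax + ix) % w
            img[np.ix_(ys, xs)] += stamp
        if noise_level > 0:
            img = rng.poisson(np.maximum(img, 0) / noise_level) * noise_level
            img = img + read_noise * rng.standard_normal(img.shape)
        out[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return ImageStack(out, pixel_size_um, frame_interval)


def _infer_frame_interval(tracks: pd.DataFrame) -> float:
    t = tracks.drop_duplicates("frame").sort_values("frame")
    if len(t) < 2:
        return 1.0 / 12.0
    return float(np.median(np.diff(t["t_h"]) / np.diff(t["frame"])))


# ---------------------------------------------------------------------------
# FRAP ground truth
# ---------------------------------------------------------------------------

def simulate_frap_stack(
    radius_px: float = 30.0,
    bleach_depth: float = 1.0,
    mobile_fraction: float = 0.6,
    recovery_rate: float = 0.5,          # 1/min
    bleach_frame: int = 5,
    n_frames: int = 80,
    frame_interval_min: float = 0.25,
    acquisition_bleach_rate: float = 0.0,  # λ, 1/min
    background: float = 100.0,
    pre_intensity: float = 20000.0,
    pixel_size_um: float = 1.0,
    image_shape: tuple[int, int] = (200, 200),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, dict]:
    """Synthetic FRAP movie with known recovery parameters.

    The mean intensity inside the bleach disc follows

        I(t) = bg + (pre − bg) · [(1 − d) + d·f·(1 − e^{−k t_post})] · e^{−λ t}

    with bleach depth ``d``, mobile fraction ``f``, recovery rate ``k``
    (applied from the bleach frame) and acquisition photobleaching λ
    (applied from frame 0, inside and outside the disc alike). Outside
    the disc the intensity is ``(pre − bg)·e^{−λt} + bg``.

    Returns the stack and a ground-truth record (center, radius, the
    generating parameters and the ideal normalized recovery curve).
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if recovery_rate <= 0:
        raise ValueError("recovery_rate must be positive")
    if not 0 <= bleach_frame < n_frames:
        raise ValueError("bleach_frame outside stack")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    cy, cx = h / 2.0, w / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2

    t_min = np.arange(n_frames) * frame_interval_min
    t_post = np.maximum(t_min - t_min[bleach_frame], 0.0)
    decay = np.exp(-acquisition_bleach_rate * t_min)
    d, f, k = bleach_depth, mobile_fraction, recovery_rate
    inside_rel = np.where(
        np.arange(n_frames) < bleach_frame,
        1.0,
        (1.0 - d) + d * f * (1.0 - np.exp(-k * t_post)),
    )
    inside = background + (pre_intensity - background) * inside_rel * decay
    outside = background + (pre_intensity - background) * decay

    frames = np.empty((n_frames, h, w), np.uint16)
    for i in range(n_frames):
        img = np.where(disc, inside[i], outside[i]).astype(float)
        if noise_sd > 0:
            img = img + noise_sd * rng.standard_normal(img.shape)
        frames[i] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth = {
        "center_px": (cx, cy),
        "radius_px": float(radius_px),
        "bleach_depth": d,
        "mobile_fraction": f,
        "recovery_rate_per_min": k,
        "bleach_frame": bleach_frame,
        "acquisition_bleach_rate_per_min": acquisition_bleach_rate,
        "normalized_curve": inside_rel,   # curve after ideal bg/decay correction
        "times_min": t_min,
    }
    stack = ImageStack(frames, pixel_size_um, frame_interval_min / 60.0)
    return stack, truth


# ---------------------------------------------------------------------------
# wetting ground truth
# ---------------------------------------------------------------------------

def simulate_wetting_areas(
    area0_um2: float = 2.0e5,
    growth_model: str = "linear",
    rate: float = 0.1,                  # 1/h
    n_frames: int = 49,
    frame_interval_h: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Spheroid spreading-area series, monotone in expectation.

    growth_model 'linear': A(t) = A0 (1 + g t); 'exponential':
    A(t) = A0 e^{g t}. Multiplicative lognormal noise with the median
    preserved (mean-log 0)."""
    if area0_um2 <= 0:
        raise ValueError("initial area must be positive")
    t = np.arange(n_frames) * frame_interval_h
    if growth_model == "linear":
        area = area0_um2 * (1.0 + rate * t)
    elif growth_model == "exponential":
        area = area0_um2 * np.exp(rate * t)
    else:
        raise ValueError(f"unknown growth_model {growth_model!r}")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        area = area * rng.lognormal(0.0, noise_sigma, n_frames)
    return pd.DataFrame({"t_h": t, "area_um2": area})


__all__ = [
    "REGIMES",
    "SimulationConfig",
    "make_regime_config",
    "render_frames",
    "simulate_frap_stack",
    "simulate_monolayer",
    "simulate_wetting_areas",
]
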