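import numpy as np
import pandas as pd
import pytest

from flockmetrics.io import VelocityField
from flockmetrics.simulate import make_regime_config, simulate_monolayer


def make_field(vx, vy, valid=None, spacing=25.0, window=50.0, times=None):
    """VelocityField from raw (T,Ny,Nx) arrays with a regular µm grid."""
    vx = np.asarray(vx, float)
    vy = np.asarray(vy, float)
    if vx.ndim == 2:
        vx, vy = vx[None], vy[None]
        if valid is not None:
            valid = np.asarray(valid, bool)[None]
    T, ny, nx = vx.shape
    return VelocityField(
        times=np.arange(T) / 12.0 if times is None else times,
        grid_x=(np.arange(nx) + 0.5) * spacing,
        grid_y=(np.arange(ny) + 0.5) * spacing,
        vx=vx,
        vy=vy,
        window_size_um=window,
        overlap_fraction=1.0 - spacing / window,
        pixel_size_um=1.0,
        valid_mask=valid,
    )


def static_tracks(positions, n_frames=3, frame_interval=1.0 / 12.0):
    """TrackTable of motionless cells at the given (N,2) positions."""
    pos = np.asarray(positions, float)
    rows = []
    for f in range(n_frames):
        for i, (x, y) in enumerate(pos):
            rows.append((i, f, f * frame_interval, x, y))
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_h", "x_um", "y_um"])


def hexagonal_lattice(a=20.0, n=12):
    """n×n hexagonal lattice with spacing a; returns (positions, extent)."""
    pts = []
    for row in range(n):
        for col in range(n):
            x = col * a + (row % 2) * a / 2.0
            y = row * a * np.sqrt(3) / 2.0
            pts.append((x, y))
    pts = np.asarray(pts)
    return pts, (n * a, n * a * np.sqrt(3) / 2.0)


@pytest.fixture(scope="session")
def small_flocking_run():
    """One reduced flocking-fluid run shared by closure tests."""
    cfg = make_regime_config("flocking_fluid", seed=11, n_cells=200, duration_h=4.0)
    return cfg, simulate_monolayer(cfg)


@pytest.fixture(scope="session")
def small_disordered_run():
    cfg = make_regime_config("disordered_fluid", seed=11, n_cells=200, duration_h=4.0)
    return cfg, simulate_monolayer(cfg)
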