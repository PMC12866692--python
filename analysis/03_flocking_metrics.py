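"""Kinematics and velocity correlation across the four regimes.

For each simulated regime: the motility time series (V_cm, V_RMS, ψ),
the motility-peak window, and the drift-corrected spatial velocity
correlation with its stretched-exponential fit (L_CORR, γ). Writes a
per-regime metric table and correlation curves.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flockmetrics.correlation import correlation_over_window
from flockmetrics.kinematics import (
    find_motility_peak,
    framecut_mean,
    motility_timeseries,
    velocity_field_from_tracks,
)
from flockmetrics.simulate import REGIMES, make_regime_config, simulate_monolayer

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for regime in REGIMES:
        cfg = make_regime_config(regime, seed=1)
        tracks = simulate_monolayer(cfg)
        field = velocity_field_from_tracks(tracks, cfg.box_size_um)
        series = motility_timeseries(field, tracks)
        t_peak, (lo, hi) = find_motility_peak(
            series["t_h"].to_numpy(), series["v_rms"].to_numpy()
        )
        frames = np.nonzero((field.times >= lo) & (field.times <= hi))[0]
        curve = correlation_over_window(field, frames)
        half = series["t_h"].max() / 2
        rows.append(
            {
                "regime": regime,
                "v_rms_um_per_h": framecut_mean(
                    series["t_h"], series["v_rms"], half, series["t_h"].max() + 1e-9
                ),
                "psi": framecut_mean(
                    series["t_h"], series["psi"], half, series["t_h"].max() + 1e-9
                ),
                "t_peak_h": t_peak,
                "l_corr_um": curve.fit["l_corr_um"],
                "gamma": curve.fit["gamma"],
                "fit_converged": curve.fit["converged"],
            }
        )
        pd.DataFrame(
            {
                "r_um": curve.r_um,
                "C_normalized": curve.C_normalized,
                "n_pairs": curve.n_pairs,
            }
        ).to_csv(OUT / f"corr_{regime}.csv", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "flocking_metrics.csv", index=False)
    print(table.round(2).to_string(index=False))
    print("\nflocking states combine high V_RMS with extended L_CORR;")
    print("the disordered fluid is fast but short-ranged; the jammed solid is static.")
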