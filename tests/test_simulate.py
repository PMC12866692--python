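import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flockmetrics import kinematics
from flockmetrics.simulate import (
    REGIMES,
    SimulationConfig,
    make_regime_config,
    render_frames,
    simulate_frap_stack,
    simulate_monolayer,
    simulate_wetting_areas,
)


def small_config(**overrides):
    return make_regime_config(
        overrides.pop("regime", "disordered_fluid"),
        seed=overrides.pop("seed", 0),
        n_cells=overrides.pop("n_cells", 60),
        duration_h=overrides.pop("duration_h", 1.0),
        **overrides,
    )


class TestMonolayerDynamics:
    def test_same_seed_bit_identical(self):
        cfg = small_config(seed=5)
        a = simulate_monolayer(cfg)
        b = simulate_monolayer(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate_monolayer(small_config(seed=1))
        b = simulate_monolayer(small_config(seed=2))
        assert not np.allclose(a["x_um"], b["x_um"])

    @staticmethod
    def _relaxation_config(**overrides):
        """Sub-jamming packing (φ ≈ 0.7) so repulsion can fully relax."""
        base = dict(
            n_cells=60,
            box_size_um=165.0,
            cell_radius_um=10.0,
            v0=0.0,
            align_rate=0.0,
            rot_diffusion=0.0,
            k_rep=25.0,
            k_bond=0.0,
            align_radius_um=30.0,
            dt_h=0.02,
            duration_h=2.0,
            seed=0,
        )
        base.update(overrides)
        return SimulationConfig(**base)

    def test_zero_propulsion_gives_negligible_rms(self):
        tracks = simulate_monolayer(self._relaxation_config())
        last = tracks["frame"].max() - 1
        v = kinematics.track_rms_cm_velocity(tracks, int(last))
        assert v < 0.05  # residual soft-disk relaxation only

    def test_pure_relaxation_displacement_decreases(self):
        """With v0 = 0 and D_r = 0 the dynamics are gradient descent on
        the repulsive energy: per-frame displacement decays to ≈ 0."""
        tracks = simulate_monolayer(self._relaxation_config())
        disp = []
        for f in range(12):
            a = tracks[tracks["frame"] == f].sort_values("track_id")
            b = tracks[tracks["frame"] == f + 1].sort_values("track_id")
            disp.append(
                np.hypot(
                    b["x_unwrap_um"].to_numpy() - a["x_unwrap_um"].to_numpy(),
                    b["y_unwrap_um"].to_numpy() - a["y_unwrap_um"].to_numpy(),
                ).sum()
            )
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(disp, disp[1:]))
        assert disp[-1] < 0.01 * disp[0] + 1e-9

    def test_positions_inside_box_and_frames_complete(self):
        cfg = small_config()
        tracks = simulate_monolayer(cfg)
        assert tracks["x_um"].between(0, cfg.box_size_um).all()
        assert tracks["y_um"].between(0, cfg.box_size_um).all()
        assert tracks.groupby("track_id")["frame"].count().nunique() == 1
        per_track_t = tracks.groupby("track_id")["t_h"].apply(
            lambda s: bool(np.all(np.diff(s) > 0))
        )
        assert per_track_t.all()

    def test_blow_up_aborts_with_diagnostic(self):
        cfg = small_config(k_rep=5000.0)  # stiffness far beyond stable dt
        with pytest.raises(RuntimeError, match="displacement"):
            simulate_monolayer(cfg)

    def test_vicsek_limit_order_decreases_with_noise(self):
        """With repulsion and bonds off, the model is continuous-time
        Vicsek: mean ψ over seeds decreases with rotational noise."""
        noise_levels = [0.1, 1.0, 6.0]
        psis = []
        for d_r in noise_levels:
            vals = []
            for seed in range(10):
                cfg = SimulationConfig(
                    n_cells=80,
                    box_size_um=170.0,
                    cell_radius_um=10.0,
                    v0=25.0,
                    align_rate=8.0,
                    rot_diffusion=d_r,
                    k_rep=0.0,
                    k_bond=0.0,
                    align_radius_um=30.0,
                    dt_h=0.02,
                    duration_h=3.0,
                    seed=seed,
                )
                tracks = simulate_monolayer(cfg)
                last = int(tracks["frame"].max()) - 1
                sub_a = tracks[tracks["frame"] == last].sort_values("track_id")
                theta = sub_a["theta_rad"].to_numpy()
                vals.append(np.hypot(np.cos(theta).mean(), np.sin(theta).mean()))
            psis.append(vals)
        means = [np.mean(v) for v in psis]
        assert means[0] > means[1] > means[2]
        assert stats.wilcoxon(psis[0], psis[2], alternative="greater").pvalue < 0.01

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="packing"):
            small_config(box_size_um=2000.0)
        with pytest.raises(ValueError, match="dt"):
            small_config(dt_h=0.5)
        with pytest.raises(ValueError, match="regime"):
            make_regime_config("liquid_crystal")


class TestRegimePresets:
    @pytest.mark.parametrize("regime", REGIMES)
    def test_presets_valid_and_labeled(self, regime):
        cfg = make_regime_config(regime, seed=3)
        assert cfg.regime_label == regime
        assert 0.5 < cfg.packing_fraction < 1.2

    def test_jammed_preset_is_nearly_static(self):
        assert make_regime_config("jammed_solid").v0 < 1.0

    def test_flocking_solid_preset_is_bonded_and_aligned(self):
        cfg = make_regime_config("flocking_solid")
        assert cfg.k_bond > 0
        assert cfg.align_rate > 0


class TestRenderFrames:
    def test_static_cell_argmax_fixed(self):
        tracks = pd.DataFrame(
            {
                "track_id": [0, 0, 0],
                "frame": [0, 1, 2],
                "t_h": [0, 1 / 12, 2 / 12],
                "x_um": [20.0] * 3,
                "y_um": [30.0] * 3,
            }
        )
        stack = render_frames(
            tracks, pixel_size_um=1.0, image_shape=(64, 64), noise_level=0.0,
            read_noise=0.0,
        )
        for frame in stack.frames:
            iy, ix = np.unravel_index(np.argmax(frame), frame.shape)
            assert (ix, iy) == (20, 30)

    def test_rigid_integer_shift_is_circular_shift(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(5, 60, (12, 2))
        rows = []
        for f in range(2):
            for i, (x, y) in enumerate(pos):
                rows.append((i, f, f / 12, (x + 3 * f) % 64, y % 64))
        tracks = pd.DataFrame(rows, columns=["track_id", "frame", "t_h", "x_um", "y_um"])
        stack = render_frames(
            tracks, pixel_size_um=1.0, image_shape=(64, 64), noise_level=0.0,
            read_noise=0.0,
        )
        shifted = np.roll(stack.frames[0], 3, axis=1)
        assert np.array_equal(stack.frames[1], shifted)

    def test_invalid_pixel_size_rejected(self):
        tracks = pd.DataFrame(
            {"track_id": [0], "frame": [0], "t_h": [0.0], "x_um": [1.0], "y_um": [1.0]}
        )
        with pytest.raises(ValueError):
            render_frames(tracks, pixel_size_um=0.0)


class TestFrapGenerator:
    def test_immobile_pool_never_recovers(self):
        _, truth = simulate_frap_stack(mobile_fraction=0.0, bleach_depth=0.8)
        post = truth["normalized_curve"][truth["bleach_frame"] :]
        assert np.allclose(post, 0.2)

    def test_fully_mobile_recovers_to_one(self):
        _, truth = simulate_frap_stack(
            mobile_fraction=1.0, recovery_rate=2.0, n_frames=400,
            acquisition_bleach_rate=0.0, background=0.0,
        )
        assert truth["normalized_curve"][-1] == pytest.approx(1.0, abs=1e-3)

    def test_bleach_frame_bounds_checked(self):
        with pytest.raises(ValueError):
            simulate_frap_stack(bleach_frame=100, n_frames=50)


class TestWettingGenerator:
    def test_linear_growth_exact_when_noiseless(self):
        df = simulate_wetting_areas(growth_model="linear", rate=0.5, noise_sigma=0.0)
        norm = df["area_um2"] / df["area_um2"].iloc[0]
        assert np.allclose(norm, 1 + 0.5 * df["t_h"])

    def test_zero_rate_constant(self):
        df = simulate_wetting_areas(rate=0.0, noise_sigma=0.0)
        assert np.allclose(df["area_um2"], df["area_um2"].iloc[0])

    def test_lognormal_noise_mean_tracks_truth(self):
        clean = simulate_wetting_areas(rate=0.1, noise_sigma=0.0, n_frames=10)
        reps = np.stack(
            [
                simulate_wetting_areas(
                    rate=0.1, noise_sigma=0.05, n_frames=10, seed=s
                )["area_um2"].to_numpy()
                for s in range(1000)
            ]
        )
        assert np.allclose(reps.mean(axis=0), clean["area_um2"], rtol=0.02)
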