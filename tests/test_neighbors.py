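import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flockmetrics.neighbors import (
    assign_neighbors,
    first_valley_threshold,
    interpolate_gaps,
    neighbor_displacement_map,
    neighbor_distance_curve,
    radial_distribution,
)

from conftest import hexagonal_lattice


def random_walk_tracks(n_cells, n_frames, step_sd, seed, box=400.0):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, (n_cells, 2))
    rows = []
    for f in range(n_frames):
        for i, (x, y) in enumerate(pos):
            rows.append((i, f, f / 12.0, x, y))
        pos = pos + rng.normal(0, step_sd, pos.shape)
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_h", "x_um", "y_um"])


def brute_force_d(tracks, r_thresh, dt_frames):
    """Literal O(N²) evaluation of d(δt): for every reference frame t,
    (1/N)Σ_i (1/n_i)Σ_j |r_i(t+δt) − r_j(t+δt)|, averaged over t."""
    frames = sorted(tracks["frame"].unique())
    by_frame = {
        f: g.set_index("track_id")[["x_um", "y_um"]] for f, g in tracks.groupby("frame")
    }
    totals = []
    for t in frames:
        if t + dt_frames > frames[-1]:
            break
        now = by_frame[t]
        later = by_frame[t + dt_frames]
        ids = now.index.to_numpy()
        n_t = len(ids)
        acc = 0.0
        wsum = 0.0
        for i in ids:
            pi = now.loc[i].to_numpy()
            nbrs = [
                j
                for j in ids
                if j != i and np.hypot(*(now.loc[j].to_numpy() - pi)) < r_thresh
            ]
            if not nbrs:
                continue
            w = 1.0 / (n_t * len(nbrs))
            for j in nbrs:
                if i in later.index and j in later.index:
                    d = np.hypot(*(later.loc[j].to_numpy() - later.loc[i].to_numpy()))
                    acc += w * d
                    wsum += w
        totals.append((acc, wsum))
    num = sum(a for a, _ in totals)
    den = sum(w for _, w in totals)
    return num / den


class TestRdf:
    def test_poisson_points_flat_at_large_r(self):
        rng = np.random.default_rng(0)
        box = 1000.0
        pts = rng.uniform(0, box, (2000, 2))
        rdf = radial_distribution(pts, box, bin_width_um=5.0, periodic=True)
        spacing = box / np.sqrt(2000)
        sel = rdf.r_um > 2 * spacing
        assert np.abs(rdf.g[sel] - 1.0).max() < 0.1

    def test_hexagonal_lattice_peak_and_gap(self):
        a = 20.0
        pts, (lx, ly) = hexagonal_lattice(a, n=16)
        rdf = radial_distribution(
            pts, (lx, ly), bin_width_um=1.0, r_max_um=80.0, periodic=False
        )
        first_peak_bin = rdf.r_um[np.argmax(rdf.g > 0)]
        assert abs(first_peak_bin - a) <= 1.0
        gap = (rdf.r_um > a + 1.0) & (rdf.r_um < a * np.sqrt(3) - 1.0)
        assert np.all(rdf.g[gap] == 0)

    def test_two_points_single_bin(self):
        pts = np.array([[100.0, 100.0], [160.0, 100.0]])
        rdf = radial_distribution(
            pts, 1000.0, bin_width_um=5.0, r_max_um=200.0, periodic=True
        )
        nz = np.nonzero(rdf.g)[0]
        assert len(nz) == 1
        assert rdf.r_um[nz[0]] == pytest.approx(62.5)  # bin [60, 65)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            radial_distribution(np.zeros((20, 2)), 100.0, bin_width_um=0.0)


class TestFirstValley:
    def test_hexagonal_valley_between_shells(self):
        a = 20.0
        pts, (lx, ly) = hexagonal_lattice(a, n=16)
        # jitter slightly so shells have width but stay separated
        rng = np.random.default_rng(1)
        pts = pts + rng.normal(0, 0.5, pts.shape)
        rdf = radial_distribution(
            pts, (lx, ly), bin_width_um=2.0, r_max_um=80.0, periodic=False
        )
        r_thresh = first_valley_threshold(rdf)
        assert a < r_thresh < a * np.sqrt(3)
        interior = (
            (pts[:, 0] > 3 * a)
            & (pts[:, 0] < lx - 3 * a)
            & (pts[:, 1] > 3 * a)
            & (pts[:, 1] < ly - 3 * a)
        )
        adj = assign_neighbors(pts, r_thresh)
        counts = [len(adj[i]) for i in np.nonzero(interior)[0]]
        assert set(counts) == {6}

    def test_ideal_gas_has_no_valley(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1000, (3000, 2))
        rdf = radial_distribution(pts, 1000.0, bin_width_um=5.0, periodic=True)
        with pytest.raises(ValueError, match="manual"):
            first_valley_threshold(rdf)

    def test_simulated_monolayer_threshold_and_coordination(self, small_disordered_run):
        cfg, tracks = small_disordered_run
        mid = int(tracks["frame"].max()) // 2
        pos = tracks[tracks["frame"] == mid][["x_um", "y_um"]].to_numpy()
        rdf = radial_distribution(pos, cfg.box_size_um, bin_width_um=2.0, periodic=True)
        r_thresh = first_valley_threshold(rdf)
        a = cfg.cell_radius_um
        assert 2 * a < r_thresh < 4 * a
        adj = assign_neighbors(pos, r_thresh, box_size_um=cfg.box_size_um)
        counts = np.array([len(s) for s in adj])
        mode = np.bincount(counts).argmax()
        assert mode == 6


class TestAssignNeighbors:
    def test_exactly_at_threshold_excluded(self):
        adj = assign_neighbors(np.array([[0.0, 0.0], [10.0, 0.0]]), 10.0)
        assert adj[0] == set() and adj[1] == set()

    def test_just_below_threshold_included(self):
        adj = assign_neighbors(np.array([[0.0, 0.0], [9.99, 0.0]]), 10.0)
        assert adj[0] == {1}

    def test_isolated_cell_has_no_neighbors(self):
        adj = assign_neighbors(np.array([[0.0, 0.0], [500.0, 500.0]]), 10.0)
        assert all(len(s) == 0 for s in adj)

    def test_symmetry_and_irreflexivity(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 100, (50, 2))
        adj = assign_neighbors(pts, 20.0)
        for i, nbrs in enumerate(adj):
            assert i not in nbrs
            for j in nbrs:
                assert i in adj[j]


class TestExchangeCurve:
    def test_rigid_translation_exact_zero(self):
        tracks = random_walk_tracks(50, 10, 0.0, seed=4)
        tracks["x_um"] += tracks["frame"] * 7.0
        tracks["y_um"] -= tracks["frame"] * 3.0
        curve = neighbor_distance_curve(tracks, 60.0, np.arange(6))
        assert np.all(np.abs(curve.delta_d_um) < 1e-12)

    def test_rigid_rotation_exact_zero(self):
        base = random_walk_tracks(50, 1, 0.0, seed=5)
        rows = []
        cx = cy = 200.0
        for f in range(8):
            ang = 0.05 * f
            c, s = np.cos(ang), np.sin(ang)
            for _, r in base.iterrows():
                dx, dy = r["x_um"] - cx, r["y_um"] - cy
                rows.append(
                    (r["track_id"], f, f / 12.0, cx + c * dx - s * dy, cy + s * dx + c * dy)
                )
        tracks = pd.DataFrame(rows, columns=["track_id", "frame", "t_h", "x_um", "y_um"])
        curve = neighbor_distance_curve(tracks, 60.0, np.arange(4))
        assert np.all(np.abs(curve.delta_d_um) < 1e-12)

    def test_matches_brute_force_oracle(self):
        tracks = random_walk_tracks(40, 8, 2.0, seed=6)
        r_thresh = 80.0
        curve = neighbor_distance_curve(tracks, r_thresh, np.array([0, 2, 5]))
        for k, dtf in enumerate([0, 2, 5]):
            assert curve.d_um[k] == pytest.approx(
                brute_force_d(tracks, r_thresh, dtf), abs=1e-10
            )

    def test_random_walkers_grow_monotonically(self):
        tracks = random_walk_tracks(150, 30, 3.0, seed=7)
        curve = neighbor_distance_curve(tracks, 80.0, np.arange(0, 30, 4))
        assert np.all(np.diff(curve.delta_d_um) > 0)
        assert curve.slope_um_per_h > 0

    def test_n_pairs_non_increasing_with_dt(self):
        tracks = random_walk_tracks(30, 12, 1.0, seed=8)
        # truncate some tracks to create attrition
        tracks = tracks[~((tracks["track_id"] < 8) & (tracks["frame"] > 5))]
        curve = neighbor_distance_curve(tracks, 100.0, np.arange(0, 10, 2))
        assert np.all(np.diff(curve.n_pairs) <= 0)

    def test_gap_interpolation_fills_short_gaps_only(self):
        tracks = random_walk_tracks(5, 10, 1.0, seed=9)
        dropped = tracks[~((tracks["track_id"] == 0) & (tracks["frame"].isin([3, 4])))]
        filled = interpolate_gaps(dropped, max_gap_frames=3)
        sub = filled[filled["track_id"] == 0]
        assert set(sub["frame"]) == set(range(10))
        dropped_long = tracks[
            ~((tracks["track_id"] == 0) & (tracks["frame"].isin([2, 3, 4, 5, 6])))
        ]
        filled_long = interpolate_gaps(dropped_long, max_gap_frames=3)
        sub = filled_long[filled_long["track_id"] == 0]
        assert set(sub["frame"]) == {0, 1, 7, 8, 9}


class TestDisplacementMap:
    def test_zero_delay_concentrates_at_origin(self):
        tracks = random_walk_tracks(40, 4, 2.0, seed=10)
        dm = neighbor_displacement_map(tracks, 80.0, delta_t_frames=0, bin_width_um=5.0)
        iy, ix = np.unravel_index(np.argmax(dm.P), dm.P.shape)
        assert dm.P.sum() * dm.bin_width_um**2 == pytest.approx(1.0)
        assert dm.P[iy, ix] * dm.bin_width_um**2 == pytest.approx(1.0)

    def test_rigid_translation_stays_central(self):
        tracks = random_walk_tracks(40, 6, 0.0, seed=11)
        tracks["x_um"] += tracks["frame"] * 9.0
        dm = neighbor_displacement_map(tracks, 80.0, delta_t_frames=4, bin_width_um=5.0)
        center = np.unravel_index(np.argmax(dm.P), dm.P.shape)
        mass_center = dm.P[center] * dm.bin_width_um**2
        assert mass_center == pytest.approx(1.0)

    def test_isotropy_of_random_walkers(self):
        """Relative displacements of independent walkers are isotropic:
        quadrant masses are uniform under a χ² test at α = 0.01."""
        tracks = random_walk_tracks(120, 16, 4.0, seed=12)
        dm = neighbor_displacement_map(tracks, 80.0, delta_t_frames=10, bin_width_um=4.0)
        n = dm.P.shape[0]
        h = n // 2
        q = [
            dm.P[:h, :h].sum(),
            dm.P[:h, h + 1 :].sum(),
            dm.P[h + 1 :, :h].sum(),
            dm.P[h + 1 :, h + 1 :].sum(),
        ]
        q = np.array(q) / np.sum(q)
        assert stats.chisquare(q * 1000, [250] * 4).pvalue > 0.01
        assert np.all(np.abs(q - 0.25) < 0.05)

    def test_empty_pair_set_rejected(self):
        tracks = random_walk_tracks(5, 4, 1.0, seed=13, box=10000.0)
        with pytest.raises(ValueError):
            neighbor_displacement_map(tracks, 1.0, delta_t_frames=1)
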