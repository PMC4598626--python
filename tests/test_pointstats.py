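"""Ripley statistics, CSR envelopes, k-NN colocalization, rendering, profiles."""

import math

import numpy as np
import pytest
from scipy import stats

import svspread as sv
from svspread.pointstats import render_sigma, widefield_sigma

WIN = (0.0, 0.0, 1000.0, 1000.0)


# --- independent brute-force oracle (scalar loops, interval-union arcs) ------

def _arc_fraction_inside(cx, cy, r, window):
    """Fraction of the circle of radius r centred at (cx, cy) inside a rectangle,
    by explicit union of the blocked arcs of all four edges."""
    x0, y0, x1, y1 = window
    blocked = []
    for dist, centre in (
        (x1 - cx, 0.0),
        (y1 - cy, math.pi / 2),
        (cx - x0, math.pi),
        (cy - y0, 3 * math.pi / 2),
    ):
        if dist < r:
            half = math.acos(max(-1.0, min(1.0, dist / r)))
            blocked.append((centre - half, centre + half))
    if not blocked:
        return 1.0
    # normalise intervals into [0, 2pi), splitting wrap-around ones
    ivs = []
    for a, b in blocked:
        length = b - a
        a %= 2 * math.pi
        b = a + length
        if b <= 2 * math.pi:
            ivs.append((a, b))
        else:
            ivs.append((a, 2 * math.pi))
            ivs.append((0.0, b - 2 * math.pi))
    ivs.sort()
    total, cur_a, cur_b = 0.0, *ivs[0]
    for a, b in ivs[1:]:
        if a > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    total += cur_b - cur_a
    return 1.0 - total / (2 * math.pi)


def ripley_K_bruteforce(points, window, radii):
    x0, y0, x1, y1 = window
    area = (x1 - x0) * (y1 - y0)
    n = len(points)
    out = []
    for r in radii:
        acc = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(points[i][0] - points[j][0], points[i][1] - points[j][1])
                if d < r:
                    w = _arc_fraction_inside(points[i][0], points[i][1], d, window)
                    acc += 1.0 / w
        out.append(acc * area / n**2)
    return np.asarray(out)


class TestRipley:
    def test_single_pair_far_from_edges(self):
        """Two interior points distance d apart: K jumps from 0 to A·2/N² at d."""
        pts = np.array([[500.0, 500.0], [560.0, 500.0]])
        res = sv.ripley_K(pts, WIN, np.array([50.0, 80.0, 100.0]))
        area = 1e6
        np.testing.assert_allclose(res.K, [0.0, area * 2 / 4, area * 2 / 4], rtol=1e-9)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            sv.ripley_K(np.array([[1.0, 1.0]]), WIN, np.array([10.0]))

    def test_radii_beyond_half_window_truncated(self):
        pts = np.array([[100.0, 100.0], [200.0, 200.0], [300.0, 100.0]])
        with pytest.warns(UserWarning):
            res = sv.ripley_K(pts, WIN, np.array([100.0, 600.0]))
        assert res.radii.tolist() == [100.0]

    def test_matches_bruteforce_oracle(self, rng):
        """Vectorised K equals the explicit double-sum oracle to 1e-9 on 50
        random patterns with up to 50 points each."""
        radii = np.array([30.0, 100.0, 250.0, 450.0])
        for _ in range(50):
            n = int(rng.integers(2, 51))
            pts = np.column_stack([rng.uniform(0, 1000, n), rng.uniform(0, 1000, n)])
            fast = sv.ripley_K(pts, WIN, radii).K
            slow = ripley_K_bruteforce(pts, WIN, radii)
            np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-9)

    def test_edge_correction_only_increases_K(self, rng):
        """Dropping the weights (w=1) can only lower K near boundaries."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            pts = np.column_stack([r.uniform(0, 1000, 100), r.uniform(0, 1000, 100)])
            radii = np.array([50.0, 150.0, 300.0])
            corrected = sv.ripley_K(pts, WIN, radii).K
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            uncorrected = np.array([(d < rr).sum() for rr in radii]) * 1e6 / 100**2
            assert np.all(corrected >= uncorrected - 1e-9)

    def test_L_identities(self):
        res = sv.RipleyResult(
            radii=np.array([10.0, 50.0]), K=math.pi * np.array([10.0, 50.0]) ** 2,
            L_minus_r=None, envelope_upper=None, N=10, window_area=1e6,
        )
        out = sv.L_minus_r(res)
        np.testing.assert_allclose(out.L_minus_r, 0.0, atol=1e-9)
        res.K = 4 * math.pi * res.radii**2
        out = sv.L_minus_r(res)
        np.testing.assert_allclose(out.L_minus_r, res.radii, rtol=1e-12)

    def test_clustered_pattern_exceeds_csr_envelope_near_cluster_scale(self):
        table = sv.simulate_point_pattern(
            "clustered", WIN, n_parents=10, mean_offspring=20, cluster_sigma=50.0, seed=5
        )
        pts = table.channel("A")
        radii = np.arange(20.0, 320.0, 20.0)
        res = sv.L_minus_r(sv.ripley_K(pts, WIN, radii))
        env = sv.csr_envelope(WIN, res.N, radii, n_sim=10, seed=1)
        assert np.any(res.L_minus_r > env)
        r_peak = radii[int(np.argmax(res.L_minus_r))]
        assert 40.0 <= r_peak <= 300.0  # maximum near the cluster scale


class TestCsrEnvelope:
    def test_single_simulation_equals_its_own_statistic(self):
        radii = np.array([50.0, 100.0])
        env = sv.csr_envelope(WIN, 50, radii, n_sim=1, seed=7)
        rng = np.random.default_rng(7)
        pts = np.column_stack([rng.uniform(0, 1000, 50), rng.uniform(0, 1000, 50)])
        res = sv.L_minus_r(sv.ripley_K(pts, WIN, radii))
        np.testing.assert_allclose(env, res.L_minus_r, rtol=1e-12)

    def test_envelope_finite_and_grows_with_nsim(self):
        radii = np.array([100.0])
        vals = {n: np.mean([sv.csr_envelope(WIN, 100, radii, n_sim=n, seed=s)[0]
                            for s in range(15)]) for n in (2, 10)}
        assert np.isfinite(list(vals.values())).all()
        assert vals[10] > vals[2]

    def test_csr_within_envelope_at_nominal_rate(self):
        """Fresh CSR patterns fall below the 10-simulation envelope ~10/11 of
        the time pointwise."""
        radii = np.array([100.0])
        hits = 0
        n_rep = 60
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            pts = np.column_stack([rng.uniform(0, 1000, 100), rng.uniform(0, 1000, 100)])
            stat = sv.L_minus_r(sv.ripley_K(pts, WIN, radii)).L_minus_r[0]
            env = sv.csr_envelope(WIN, 100, radii, n_sim=10, seed=s)[0]
            hits += stat <= env
        p = 10 / 11
        se = math.sqrt(p * (1 - p) / n_rep)
        assert abs(hits / n_rep - p) < 3 * se


class TestKnn:
    def test_identical_channels_first_neighbour_zero(self):
        pts = np.random.default_rng(0).uniform(0, 1000, (40, 2))
        res = sv.knn_cross(pts, pts, k=1)
        np.testing.assert_array_equal(res.distances, 0.0)

    def test_grid_tenth_neighbour_matches_exhaustive_sort(self):
        """Query at centre of a 3x4 unit grid: k-th NN distance by brute force."""
        gx, gy = np.meshgrid(np.arange(4.0), np.arange(3.0))
        ref = np.column_stack([gx.ravel(), gy.ravel()])
        q = np.array([[1.5, 1.0]])
        res = sv.knn_cross(q, ref, k=10, bin_width=0.5)
        d_all = np.sort(np.hypot(*(ref - q[0]).T))
        assert res.distances[0] == pytest.approx(d_all[9], rel=1e-12)

    def test_reference_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            sv.knn_cross(np.zeros((5, 2)), np.zeros((3, 2)), k=10)

    def test_distances_invariant_under_joint_translation(self, rng):
        q = rng.uniform(100, 900, (30, 2))
        ref = rng.uniform(100, 900, (50, 2))
        a = sv.knn_cross(q, ref, k=5).distances
        b = sv.knn_cross(q + 37.2, ref + 37.2, k=5).distances
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_colocalized_channels_beat_toroidal_null(self):
        """Shared-parent patterns put more k=10 NN mass below 50 nm than the
        toroidal-shift null; independent channels do not (alpha=0.01, 20 seeds)."""
        def mass_diff(seed, shared):
            t = sv.simulate_point_pattern(
                "clustered", WIN, n_parents=10, mean_offspring=20, cluster_sigma=50.0,
                channels=("NEP", "AP180"), shared_parent_fraction=shared, seed=seed,
            )
            q, ref = t.channel("NEP"), t.channel("AP180")
            obs = sv.knn_cross(q, ref, k=10)
            null = sv.knn_cross(q, sv.toroidal_shift(ref, WIN), k=10)
            return np.mean(obs.distances < 50.0) - np.mean(null.distances < 50.0)

        coloc = np.array([mass_diff(s, 1.0) for s in range(20)])
        indep = np.array([mass_diff(s, 0.0) for s in range(20)])
        assert stats.ttest_1samp(coloc, 0.0, alternative="greater").pvalue < 0.01
        assert stats.ttest_1samp(indep, 0.0, alternative="greater").pvalue > 0.01


class TestToroidalShift:
    def test_involution(self, rng):
        pts = rng.uniform(0, 1000, (100, 2))
        back = sv.toroidal_shift(sv.toroidal_shift(pts, WIN), WIN)
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_left_edge_maps_to_centre(self):
        out = sv.toroidal_shift(np.array([[0.0, 123.0]]), WIN)
        assert out[0, 0] == pytest.approx(500.0)
        assert out[0, 1] == 123.0

    def test_csr_knn_distribution_unchanged_by_shift(self):
        """For independent CSR channels the shift is distribution-preserving
        (two-sample KS not rejected at alpha=0.01, pooled over seeds)."""
        pvals = []
        for s in range(10):
            t = sv.simulate_point_pattern("CSR", WIN, n_points=150, channels=("A", "B"), seed=s)
            q, ref = t.channel("A"), t.channel("B")
            d0 = sv.knn_cross(q, ref, k=10).distances
            d1 = sv.knn_cross(q, sv.toroidal_shift(ref, WIN), k=10).distances
            pvals.append(stats.ks_2samp(d0, d1).pvalue)
        # Fisher's combination across seeds
        chi2 = -2 * np.sum(np.log(pvals))
        assert chi2 < stats.chi2.ppf(0.99, df=2 * len(pvals))


class TestRendering:
    def test_pythagorean_sigma(self):
        assert render_sigma(5.0, 3.0) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            render_sigma(3.0, 5.0)

    def test_widefield_sigma_from_abbe(self):
        sig = widefield_sigma(680.0, 1.49)
        assert sig * 2 * math.sqrt(2 * math.log(2)) == pytest.approx(680.0 / (2 * 1.49))

    def test_total_intensity_equals_point_count(self):
        table = sv.simulate_point_pattern("CSR", WIN, n_points=137, seed=3)
        img = sv.render_diffraction_limited(table, "A")
        assert img.sum() == pytest.approx(137.0, rel=1e-6)


class TestRadialProfile:
    def test_single_peak_profile_monotone_from_origin(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, 3.0)
        prof = sv.radial_profile({"A": img}, "A", pixel_size=105.0, bin_width=105.0)
        vals = prof[prof.channel == "A"].sort_values("r_nm").mean_intensity.to_numpy()
        assert vals[0] == prof.mean_intensity.max()
        assert np.all(np.diff(vals[:5]) <= 0)

    def test_coincident_channels_both_peak_at_origin(self):
        rng = np.random.default_rng(2)
        base = np.zeros((41, 41))
        for _ in range(3):
            i, j = rng.integers(8, 33, 2)
            base[i, j] = 1.0
        from scipy.ndimage import gaussian_filter
        imgA = gaussian_filter(base, 2.0)
        imgB = gaussian_filter(base, 2.5)
        prof = sv.radial_profile({"A": imgA, "B": imgB}, "A", pixel_size=105.0)
        for ch in ("A", "B"):
            v = prof[prof.channel == ch].sort_values("r_nm")
            assert v.mean_intensity.iloc[0] == v.mean_intensity.max()

    def test_uniform_image_flat_profile(self):
        img = np.ones((31, 31))
        prof = sv.radial_profile({"A": img}, "A", maxima=np.array([[15.0, 15.0]]))
        np.testing.assert_allclose(prof.mean_intensity, 1.0, atol=1e-12)

    def test_no_maxima_rejected(self):
        with pytest.raises(ValueError):
            sv.radial_profile({"A": np.zeros((31, 31))}, "A", maxima=np.empty((0, 2)))
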