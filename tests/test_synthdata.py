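"""Simulator tests: docking growth, fibrils, rendering, kinetics, TEM."""

import numpy as np
import pytest
from scipy import ndimage

from aggremorph import synthdata as sd
from conftest import render_single


def brute_force_adjacency(centers, diameter):
    """Independent O(n^2) tangency check returning per-punctum degree."""
    centers = np.asarray(centers)
    n = len(centers)
    deg = np.zeros(n, dtype=int)
    cutoff = diameter * 1.01
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(centers[i] - centers[j])) <= cutoff:
                deg[i] += 1
                deg[j] += 1
    return deg


class TestFractalAggregate:
    def test_single_punctum_degenerate(self):
        p = sd.SimParams(n_puncta=1, rng_seed=0)
        t = sd.simulate_fractal_aggregate(p, stage=1)
        assert len(t.punctum_centers) == 1
        assert t.true_longest_chain == pytest.approx(p.punctum_diameter)
        assert t.true_branch_points == 0

    def test_two_puncta_tangent(self):
        p = sd.SimParams(n_puncta=2, rng_seed=1)
        t = sd.simulate_fractal_aggregate(p, stage=1)
        sep = np.hypot(*(t.punctum_centers[0] - t.punctum_centers[1]))
        assert sep == pytest.approx(p.punctum_diameter, rel=1e-9)
        assert t.true_branch_points == 0

    def test_branch_points_match_brute_force_adjacency(self):
        p = sd.SimParams(n_puncta=7, rng_seed=1)
        t = sd.simulate_fractal_aggregate(p, stage=2)
        deg = brute_force_adjacency(t.punctum_centers, p.punctum_diameter)
        assert t.true_branch_points == int(np.sum(deg >= 3))

    @pytest.mark.parametrize("stage,seed", [(1, 3), (2, 5), (3, 9)])
    def test_count_conserved_and_connected(self, stage, seed):
        p = sd.SimParams(n_puncta=9, rng_seed=seed)
        t = sd.simulate_fractal_aggregate(p, stage=stage)
        assert len(t.punctum_centers) == p.n_puncta
        import networkx as nx
        g = sd.adjacency_graph(t.punctum_centers, p.punctum_diameter)
        assert nx.is_connected(g)

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_stage1_chain_length(self, n):
        p = sd.SimParams(n_puncta=n, rng_seed=n)
        t = sd.simulate_fractal_aggregate(p, stage=1)
        expected = n * p.punctum_diameter  # (n-1) bonds + two end caps
        assert t.true_longest_chain == pytest.approx(expected, rel=0.011)

    def test_zero_puncta_rejected(self):
        with pytest.raises(ValueError):
            sd.SimParams(n_puncta=0)

    def test_branched_cluster_has_branches(self):
        p = sd.SimParams(rng_seed=11)
        t = sd.grow_branched_cluster(p, p.rng(), main_puncta=6, n_arms=5)
        assert t.true_branch_points >= 1
        assert t.class_label == "branched_fractal"


class TestFibril:
    def test_infinite_stiffness_is_straight(self):
        p = sd.SimParams(fibril_length=27.0, rng_seed=0, embedded_puncta=0)
        t = sd.simulate_fibril(p, straight=True)
        assert sd.polyline_arc_length(t.backbone_polyline) == pytest.approx(27.0)
        # all points collinear: cross products vanish
        v = np.diff(t.backbone_polyline, axis=0)
        cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
        assert np.allclose(cross, 0.0, atol=1e-9)

    def test_arc_length_matches_request(self):
        p = sd.SimParams(fibril_length=27.0, rng_seed=3, embedded_puncta=0)
        t = sd.simulate_fibril(p)
        assert sd.polyline_arc_length(t.backbone_polyline) == pytest.approx(27.0, rel=0.005)

    def test_embedded_puncta_lie_on_backbone(self):
        p = sd.SimParams(fibril_length=20.0, rng_seed=4, embedded_puncta=2)
        t = sd.simulate_fibril(p)
        assert len(t.punctum_centers) == 2
        for c in t.punctum_centers:
            # independent point-to-polyline distance
            d = np.min(np.hypot(*(t.backbone_polyline - c).T))
            assert d <= p.punctum_diameter / 2

    def test_nonpositive_persistence_raises(self):
        with pytest.raises(ValueError):
            sd.SimParams(persistence_length=-1.0)


class TestRenderScene:
    def test_empty_truth_background_only(self, sim_params):
        a, b, mask = sd.render_scene(sd.GroundTruth([]), sim_params, noise=False)
        assert np.all(a.pixels == sim_params.background_level)
        assert mask.sum() == 0

    def test_no_shift_no_noise_channels_identical(self):
        p = sd.SimParams(n_puncta=3, rng_seed=2, chromatic_shift=(0.0, 0.0))
        t = sd.simulate_fractal_aggregate(p, stage=1)
        a, b, _ = sd.render_scene(sd.GroundTruth([t]), p, noise=False)
        assert np.array_equal(a.pixels, b.pixels)

    def test_single_punctum_centroid(self):
        p = sd.SimParams(n_puncta=1, rng_seed=0)
        t = sd.simulate_fractal_aggregate(p, stage=1)
        truth = sd.GroundTruth([sd._shifted(t, np.array([2.03, 2.81]))])
        img, _b, _m = sd.render_scene(truth, p, noise=False, origin=(0.0, 0.0),
                                      shape=(40, 40))
        sig = img.pixels - p.background_level
        cy, cx = ndimage.center_of_mass(sig)
        assert abs(cy - 2.03 / p.pixel_size) < 0.05
        assert abs(cx - 2.81 / p.pixel_size) < 0.05

    def test_injected_shift_is_exact_translation(self):
        p = sd.SimParams(n_puncta=4, rng_seed=6, chromatic_shift=(2.0, -3.0))
        t = sd.simulate_fractal_aggregate(p, stage=1)
        a, b, _ = sd.render_scene(sd.GroundTruth([t]), p, noise=False)
        manual = ndimage.shift(a.pixels - p.background_level, (2.0, -3.0),
                               order=1, mode="constant")
        assert np.allclose(b.pixels - p.background_level, manual, atol=1e-9)

    def test_overexposure_raises(self):
        p = sd.SimParams(n_puncta=1, rng_seed=0, punctum_photons=1e9)
        t = sd.simulate_fractal_aggregate(p, stage=1)
        with pytest.raises(ValueError, match="65535"):
            sd.render_scene(sd.GroundTruth([t]), p, noise=False)

    def test_seed_determinism(self):
        p = sd.SimParams(n_puncta=5, rng_seed=77)
        out = []
        for _ in range(2):
            rng = p.rng()
            t = sd.simulate_fractal_aggregate(p, stage=2, rng=rng)
            a, b, mask = sd.render_scene(sd.GroundTruth([t]), p, rng=rng)
            out.append((t.punctum_centers, a.pixels, b.pixels, mask))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])
        assert np.array_equal(out[0][2], out[1][2])
        assert np.array_equal(out[0][3], out[1][3])


class TestKinetics:
    def test_zero_amplitude_flat(self):
        kp = sd.KineticsParams(amplitude=0.0, baseline=50.0)
        tr = sd.simulate_kinetics(kp)[0]
        assert np.allclose(tr.intensity, 50.0)

    def test_half_amplitude_at_t_mid(self):
        kp = sd.KineticsParams(amplitude=800.0, baseline=100.0, lag_time=300.0,
                               growth_rate=0.02)
        y = sd.logistic(np.array([kp.t_mid]), kp.baseline, kp.amplitude,
                        kp.growth_rate, kp.t_mid)
        assert y[0] == pytest.approx(kp.baseline + kp.amplitude / 2)

    def test_seeded_crosses_half_amplitude_earlier(self):
        un = sd.simulate_kinetics(sd.KineticsParams(lag_time=300.0))[0]
        se = sd.simulate_kinetics(sd.KineticsParams(lag_time=80.0, seeded=True))[0]
        half = 100.0 + 1000.0 / 2

        def crossing(tr):
            return tr.times[np.argmax(tr.intensity >= half)]

        assert crossing(se) < crossing(un)
        assert se.condition == "seeded" and un.condition == "unseeded"

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            sd.KineticsParams(amplitude=-1.0)

    def test_monomer_peak_decays(self):
        kp = sd.KineticsParams(initial_monomer_peak=500.0, lag_time=600.0,
                               amplitude=200.0)
        tr = sd.simulate_kinetics(kp)[0]
        assert tr.intensity[0] > tr.intensity[10] > tr.intensity[30]


class TestTemRender:
    @pytest.mark.parametrize("width_nm", [150.0, 1200.0])
    def test_peak_to_peak_equals_width(self, width_nm):
        # 1 nm/px: pixel_size in µm/px, widths in µm
        p = sd.SimParams(pixel_size=0.001, background_level=100.0, rng_seed=0)
        img, poly = sd.render_tem_fibril(width_nm / 1000, length=width_nm / 500, params=p)
        row_c = int(round(poly[0, 0]))
        mid_col = img.pixels.shape[1] // 2
        profile = img.pixels[:, mid_col]
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(profile, prominence=np.ptp(profile) * 0.2)
        assert len(peaks) == 2
        assert abs(peaks[1] - peaks[0]) == pytest.approx(width_nm, abs=1.0)
        assert abs((peaks[0] + peaks[1]) / 2 - row_c) <= 1.0

    def test_zero_twist_constant_width(self):
        p = sd.SimParams(pixel_size=0.001, rng_seed=0)
        img, poly = sd.render_tem_fibril(0.15, length=0.4, params=p, twist_amplitude=0.0)
        from scipy.signal import find_peaks
        seps = []
        # columns over the ribbon body (the padded caps are rounded)
        for j in range(int(poly[0, 1]) + 5, int(poly[-1, 1]) - 5):
            peaks, _ = find_peaks(img.pixels[:, j], prominence=np.ptp(img.pixels[:, j]) * 0.2)
            if len(peaks) == 2:
                seps.append(peaks[1] - peaks[0])
        assert np.ptp(seps) <= 1  # constant up to pixel quantisation

    def test_unresolvable_width_raises(self):
        p = sd.SimParams(pixel_size=0.1, rng_seed=0)
        with pytest.raises(ValueError, match="unresolvable"):
            sd.render_tem_fibril(0.15, length=5.0, params=p)
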