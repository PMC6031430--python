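"""Trial statistics: windows, chi, Sidak-Wilcoxon, entropy, time courses."""

import itertools

import numpy as np
import pytest

from optomap import map_geometry as mg
from optomap import opto_phenotyping as op
from optomap import synthetic_arena as sa
from optomap import workflows as wf


@pytest.fixture()
def schedule():
    return sa.make_led_schedule(100, 3, 15, 45)


def _uniform_tensor(grid, n_flies=3, n_cycles=4, roles=None, seed=0):
    rng = np.random.default_rng(seed)
    C = grid.n_cells
    rho = rng.random((n_flies, n_cycles, C)).astype(np.float32)
    rho /= rho.sum(axis=2, keepdims=True)
    rho2 = rng.random((n_flies, n_cycles, C)).astype(np.float32)
    rho2 /= rho2.sum(axis=2, keepdims=True)
    return op.TrialTensor(rho_on=rho, rho_off=rho2,
                          missing=np.zeros((n_flies, n_cycles), bool),
                          roles=roles or ["experimental"] * n_flies,
                          grid=grid, sigma=1.5, on_window=(0, 3),
                          off_window=(30, 45))


class TestWindows:
    def test_printed_window_frame_counts(self, schedule):
        on, off = op.trial_windows(schedule)
        assert on[1] - on[0] == 300     # first 3 s of stimulation
        assert off[1] - off[0] == 1500  # the 15 s window furthest from it
        assert on == (0, 300) and off == (3000, 4500)

    def test_windows_disjoint_and_onset_relative(self, schedule):
        on, off = op.trial_windows(schedule)
        onset = schedule.onset_frames[1]
        assert onset + on[0] == 6000
        assert on[1] <= off[0]

    def test_cycle_too_short_rejected(self):
        short = sa.make_led_schedule(100, 2, 5, 10)
        with pytest.raises(ValueError, match="cycle"):
            op.trial_windows(short)


class TestChi:
    def test_printed_arithmetic(self, schedule):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=2)
        tensor = _uniform_tensor(grid, n_flies=1, n_cycles=2)
        tensor.rho_on[0, 1] = [0.5, 0.3, 0.1, 0.1]
        tensor.rho_off[0, 0] = [0.2, 0.4, 0.2, 0.2]
        tensor.rho_off[0, 1] = [0.4, 0.2, 0.2, 0.2]
        chi = op.chi_map(tensor, 0, 1)
        assert chi[0] == pytest.approx(0.5 - 0.5 * (0.2 + 0.4), abs=1e-7)

    def test_identical_densities_zero_map(self):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=4)
        tensor = _uniform_tensor(grid, n_flies=1, n_cycles=2)
        tensor.rho_off[0, 0] = tensor.rho_on[0, 1]
        tensor.rho_off[0, 1] = tensor.rho_on[0, 1]
        assert np.allclose(op.chi_map(tensor, 0, 1), 0.0, atol=1e-7)

    def test_chi_sums_to_zero(self):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=8)
        tensor = _uniform_tensor(grid, n_flies=2, n_cycles=3, seed=5)
        chi, fi, ci = op.chi_all(tensor)
        assert np.allclose(chi.sum(axis=1), 0.0, atol=1e-5)
        assert np.all(ci >= 1)

    def test_first_cycle_excluded(self):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=4)
        tensor = _uniform_tensor(grid)
        with pytest.raises(ValueError):
            op.chi_map(tensor, 0, 0)


class TestSidak:
    def test_m_one_is_alpha(self):
        assert op.sidak_threshold(0.05, 1) == pytest.approx(0.05)

    def test_closed_form_m20(self):
        assert op.sidak_threshold(0.05, 20) == pytest.approx(0.0025614, abs=1e-7)

    def test_large_m(self):
        a = op.sidak_threshold(0.05, 2 ** 10)
        assert a == pytest.approx(1 - 0.95 ** (1 / 1024), rel=1e-12)

    def test_strictly_decreasing_in_m(self):
        ms = [1, 2, 5, 20, 100, 1000]
        vals = [op.sidak_threshold(0.05, m) for m in ms]
        assert np.all(np.diff(vals) < 0)


class TestEntropy:
    def test_uniform_1024_cells_is_10_bits(self):
        assert op.entropy(np.full(1024, 1 / 1024)) == pytest.approx(10.0)

    def test_point_mass_zero_bits(self):
        p = np.zeros(64)
        p[7] = 1.0
        assert op.entropy(p) == 0.0

    def test_product_density_additivity(self, rng):
        px = rng.random(16)
        px /= px.sum()
        py = rng.random(16)
        py /= py.sum()
        joint = np.outer(px, py)
        assert op.entropy(joint) == pytest.approx(
            op.entropy(px) + op.entropy(py), abs=1e-9)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            op.entropy(np.ones(10))


class TestWilcoxon:
    def test_exact_textbook_case(self):
        p = op.rank_sum_pvalues(np.array([[1.], [2.], [3.]]),
                                np.array([[4.], [5.], [6.]]))
        assert p[0] == pytest.approx(0.1, abs=1e-12)

    def test_matches_exact_enumeration_on_random_instances(self, rng):
        """Brute force: enumerate all rank assignments of the pooled sample."""
        for _ in range(100):
            n1, n2 = rng.integers(3, 8, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            p = op.rank_sum_pvalues(a[:, None], b[:, None])[0]
            pooled = np.concatenate([a, b])
            ranks = np.argsort(np.argsort(pooled)) + 1
            w_obs = ranks[:n1].sum()
            mean_w = n1 * (n1 + n2 + 1) / 2
            count = total = 0
            for comb in itertools.combinations(range(n1 + n2), int(n1)):
                w = ranks[list(comb)].sum()
                total += 1
                if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
                    count += 1
            assert p == pytest.approx(count / total, abs=1e-9)

    def test_identical_samples_p_one(self):
        a = np.ones((6, 3))
        p = op.rank_sum_pvalues(a, a)
        assert np.all(p == 1.0)


class TestSignificance:
    def test_null_tensors_produce_no_significant_cells(self):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=10)
        rng = np.random.default_rng(11)
        def draw(seed):
            r = np.random.default_rng(seed)
            x = r.random((6, 8, grid.n_cells)).astype(np.float32)
            return x / x.sum(axis=2, keepdims=True)
        te = op.TrialTensor(rho_on=draw(1), rho_off=draw(2),
                            missing=np.zeros((6, 8), bool),
                            roles=["experimental"] * 6, grid=grid, sigma=1.5,
                            on_window=(0, 3), off_window=(30, 45))
        tc = op.TrialTensor(rho_on=draw(3), rho_off=draw(4),
                            missing=np.zeros((6, 8), bool),
                            roles=["control"] * 6, grid=grid, sigma=1.5,
                            on_window=(0, 3), off_window=(30, 45))
        sig = op.significance_maps(te, tc)
        assert sig.mask.sum() == 0
        assert sig.alpha_corrected == pytest.approx(
            1 - 0.95 ** (1 / sig.m), rel=1e-12)
        assert sig.m == int(np.ceil(2.0 ** sig.H))

    def test_strong_shift_detected_in_correct_cells(self):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=4)
        rng = np.random.default_rng(2)
        C = grid.n_cells
        base = rng.dirichlet(np.ones(C), size=(6, 10)).astype(np.float32)
        off = rng.dirichlet(np.ones(C), size=(6, 10)).astype(np.float32)
        on = off.copy()
        on[:, :, 0] += 0.5  # strong activation of cell 0
        on /= on.sum(axis=2, keepdims=True)
        te = op.TrialTensor(rho_on=on, rho_off=off,
                            missing=np.zeros((6, 10), bool),
                            roles=["experimental"] * 6, grid=grid, sigma=1.5,
                            on_window=(0, 3), off_window=(30, 45))
        tc = op.TrialTensor(rho_on=base, rho_off=base.copy(),
                            missing=np.zeros((6, 10), bool),
                            roles=["control"] * 6, grid=grid, sigma=1.5,
                            on_window=(0, 3), off_window=(30, 45))
        sig = op.significance_maps(te, tc)
        assert sig.mask[0]
        # cell 0 is the only *activated* cell; others only lose mass
        assert sig.mask.sum() == 1


class TestSignificantRegions:
    def test_empty_mask_zero_regions(self):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=16)
        sig = op.SignificanceMap(
            p_on_off=np.ones(256), p_chi=np.ones(256),
            mask=np.zeros(256, bool), alpha=0.05, alpha_corrected=0.01,
            m=5, H=2.0, mean_density=np.full(256, 1 / 256),
            mean_chi=np.zeros(256), grid=grid)
        regions = mg.RegionSet(labels=np.ones((16, 16), int), grid=grid)
        out = op.significant_regions(sig, regions)
        assert out.n_components == 0

    def test_two_disjoint_blobs_counted(self):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=16)
        mask = np.zeros((16, 16), bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        labels = np.zeros((16, 16), int)
        labels[:8] = 1
        labels[8:] = 2
        sig = op.SignificanceMap(
            p_on_off=np.ones(256), p_chi=np.ones(256), mask=mask.ravel(),
            alpha=0.05, alpha_corrected=0.01, m=5, H=2.0,
            mean_density=np.full(256, 1 / 256), mean_chi=np.zeros(256),
            grid=grid)
        regions = mg.RegionSet(labels=labels, grid=grid)
        out = op.significant_regions(sig, regions)
        assert out.n_components == 2
        assert out.overlaps[1] == [1] and out.overlaps[2] == [2]


class TestEntropyCurve:
    def test_pooling_window_is_41_frames(self, schedule):
        # +-200 ms at 100 fps pools 41 frames per cycle
        hw = int(round(0.2 * schedule.fps))
        assert 2 * hw + 1 == 41

    def test_stationary_uniform_track_flat_curve(self):
        # 30 pooled cycles: enough phase-window points for a stable estimate
        sched30 = sa.make_led_schedule(100, 30, 15, 45)
        rng = np.random.default_rng(4)
        grid = mg.MapGrid(0, 1, 0, 1, resolution=16)
        tracks = [op.FlyTrack(frames=np.arange(0, sched30.n_frames, 5),
                              coords=rng.random((sched30.n_frames // 5, 2)))
                  for _ in range(4)]
        curve = op.entropy_curve(tracks, sched30, grid, step=0.5)
        assert np.nanmax(curve.H) - np.nanmin(curve.H) < 0.1
        assert np.nanmax(np.abs(curve.baseline_subtracted)) < 0.1

    def test_led_pinning_drops_entropy_in_on_window(self, schedule):
        rng = np.random.default_rng(5)
        grid = mg.MapGrid(0, 1, 0, 1, resolution=16)
        cycle = schedule.cycle_frames
        frames = np.arange(0, schedule.n_frames, 5)
        phase = frames % cycle
        tracks = []
        for _ in range(4):
            coords = rng.random((len(frames), 2))
            pinned = phase < schedule.on_frames
            coords[pinned] = 0.3 + 0.01 * rng.standard_normal((pinned.sum(), 2))
            tracks.append(op.FlyTrack(frames=frames, coords=coords))
        curve = op.entropy_curve(tracks, schedule, grid, step=0.5)
        tmin = curve.phases_s[np.nanargmin(curve.H)]
        assert 0.0 <= tmin < 15.0
        off_sel = curve.phases_s >= 20.0
        assert np.nanmin(curve.H[~off_sel]) < np.nanmin(curve.H[off_sel]) - 0.5


class TestRegionTimecourse:
    def test_whole_grid_occupancy_is_one(self, schedule, rng):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=8)
        tracks = [op.FlyTrack(frames=np.arange(0, schedule.n_frames, 10),
                              coords=rng.random((schedule.n_frames // 10, 2)))]
        tc = op.region_timecourse(tracks, np.ones((8, 8), bool), schedule, grid)
        assert np.allclose(tc.mean[np.isfinite(tc.mean)], 1.0)

    def test_empty_region_occupancy_zero(self, schedule, rng):
        grid = mg.MapGrid(0, 1, 0, 1, resolution=8)
        tracks = [op.FlyTrack(frames=np.arange(0, schedule.n_frames, 10),
                              coords=rng.random((schedule.n_frames // 10, 2)))]
        tc = op.region_timecourse(tracks, np.zeros((8, 8), bool), schedule, grid)
        assert np.allclose(tc.mean[np.isfinite(tc.mean)], 0.0)


class TestNeuronAverage:
    def test_single_line_positive_significant_chi(self, rng):
        chi = rng.standard_normal(100)
        mask = rng.random(100) < 0.3
        out = op.neuron_average([(chi, mask)])
        expected = np.where(mask & (chi > 0), chi, 0.0)
        assert np.allclose(out, expected)

    def test_two_identical_lines_average_to_same(self, rng):
        chi = np.abs(rng.standard_normal(50))
        mask = np.ones(50, bool)
        out = op.neuron_average([(chi, mask), (chi, mask)])
        assert np.allclose(out, chi)

    def test_disjoint_lines_half_weight(self):
        chi1 = np.zeros(10)
        chi1[2] = 0.4
        chi2 = np.zeros(10)
        chi2[7] = 0.8
        out = op.neuron_average([(chi1, chi1 > 0), (chi2, chi2 > 0)])
        assert out[2] == pytest.approx(0.2)
        assert out[7] == pytest.approx(0.4)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            op.neuron_average([(np.zeros(10), np.zeros(10, bool)),
                               (np.zeros(12), np.zeros(12, bool))])
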