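"""Trial region assignment, plug-in MI, finite-size correction, partial maps."""

import numpy as np
import pytest

from optomap import context_information as ci
from optomap import map_geometry as mg
from optomap import synthetic_arena as sa
from optomap import workflows as wf


@pytest.fixture()
def two_region_set():
    grid = mg.MapGrid(0.0, 1.0, 0.0, 1.0, resolution=64)
    labels = np.zeros((64, 64), int)
    labels[:, :20] = 1          # region 1: columns 0-19
    labels[:, 40:] = 2          # region 2: columns 40-63
    return mg.RegionSet(labels=labels, grid=grid)


def _points_at(cell, n=60, jitter=0.2):
    rng = np.random.default_rng(0)
    base = (np.array(cell) + 0.5) / 64.0
    return base + jitter / 64.0 * rng.standard_normal((n, 2))


class TestAssign:
    def test_mode_inside_region(self, two_region_set):
        label = ci.assign_post_region(_points_at((30, 10)), two_region_set)
        assert label == 1

    def test_within_five_pixels_assigned_to_nearest(self, two_region_set):
        # mode at column 23: 4 px from region 1's edge, 17 px from region 2
        label = ci.assign_post_region(_points_at((30, 23), jitter=0.01),
                                      two_region_set)
        assert label == 1

    def test_beyond_five_pixels_gets_zero_label(self, two_region_set):
        # mode at column 29: 10 px from region 1, 11 px from region 2
        label = ci.assign_post_region(_points_at((30, 29), jitter=0.01),
                                      two_region_set, sigma=0.5)
        assert label == 0

    def test_no_valid_frames_raises(self, two_region_set):
        with pytest.raises(ValueError):
            ci.assign_post_region(np.full((5, 2), np.nan), two_region_set)


def _make_assignments(pre, labels, n_regions, res):
    grid = mg.MapGrid(0, 1, 0, 1, resolution=res)
    return ci.TrialAssignments(pre_densities=np.asarray(pre, np.float32),
                               labels=np.asarray(labels, int),
                               n_regions=n_regions, grid=grid)


class TestPluginMI:
    def test_identical_conditionals_zero_mi(self, rng):
        base = rng.random(16)
        base /= base.sum()
        pre = np.tile(base, (40, 1))
        a = _make_assignments(pre, rng.integers(0, 3, size=40), 2, 4)
        assert ci.mutual_information(a).mi == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_equiprobable_supports_hit_the_bound(self):
        """N=3 regions + zero label, disjoint conditionals -> exactly 2 bits."""
        pre = np.zeros((40, 16))
        labels = np.repeat([0, 1, 2, 3], 10)
        for k in range(4):
            pre[labels == k, 4 * k: 4 * k + 4] = 0.25
        a = _make_assignments(pre, labels, 3, 4)
        est = ci.mutual_information(a)
        assert est.mi == pytest.approx(2.0, abs=1e-6)
        assert a.mi_bound == pytest.approx(np.log2(3 + 1))

    def test_matches_brute_force_double_loop(self, rng):
        """Independent oracle: plug-in MI from raw (cell, label) counts."""
        for _ in range(100):
            n_cells, n_labels, n_trials = rng.integers(3, 8), rng.integers(2, 5), 30
            counts = rng.integers(0, 6, size=(n_trials, n_cells)).astype(float)
            counts[counts.sum(axis=1) == 0, 0] = 1
            pre = counts / counts.sum(axis=1, keepdims=True)
            labels = rng.integers(0, n_labels, size=n_trials)

            # brute force: joint over (cell, label) from averaged conditionals
            uniq = np.unique(labels)
            mi_bf = 0.0
            p_k = {k: (labels == k).mean() for k in uniq}
            cond = {k: pre[labels == k].mean(axis=0) for k in uniq}
            for k in uniq:
                c = cond[k] / cond[k].sum()
                marg = sum(p_k[l] * cond[l] / cond[l].sum() for l in uniq)
                for x in range(n_cells):
                    if c[x] > 0 and marg[x] > 0:
                        mi_bf += p_k[k] * c[x] * np.log2(c[x] / marg[x])
            est = ci._plugin_mi(pre.astype(float), labels)
            assert est == pytest.approx(max(mi_bf, 0.0), abs=1e-12)

    def test_invariances(self, rng):
        pre = rng.dirichlet(np.ones(9), size=60)
        labels = rng.integers(0, 3, size=60)
        base = ci._plugin_mi(pre, labels)
        relabeled = np.array([{0: 7, 1: 2, 2: 5}[l] for l in labels])
        assert ci._plugin_mi(pre, relabeled) == pytest.approx(base, abs=1e-12)
        assert 0.0 <= base <= np.log2(3)


class TestPartialMI:
    def test_decomposition_sums_to_mi(self, rng):
        pre = rng.dirichlet(np.ones(16), size=50).astype(np.float32)
        labels = rng.integers(0, 4, size=50)
        a = _make_assignments(pre, labels, 3, 4)
        total = sum(ci.partial_mi_map(a, k).sum() for k in np.unique(labels))
        assert total == pytest.approx(ci.mutual_information(a).mi, abs=1e-9)

    def test_marginal_equal_conditional_map_is_zero(self, rng):
        base = rng.dirichlet(np.ones(16))
        pre = np.tile(base, (30, 1)).astype(np.float32)
        labels = np.repeat([1, 2, 3], 10)
        a = _make_assignments(pre, labels, 3, 4)
        assert np.allclose(ci.partial_mi_map(a, 2), 0.0, atol=1e-7)


class TestBiasCorrection:
    def _clustered_assignments(self, n_trials, seed, informative=True):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, size=n_trials)
        pre = np.zeros((n_trials, 64))
        for i, l in enumerate(labels):
            center = 16 * (l if informative else rng.integers(0, 4))
            weights = rng.dirichlet(np.ones(16) * 2)
            pre[i, center:center + 16] = weights
        return _make_assignments(pre, labels, 4, 8)

    def test_shuffled_labels_center_on_zero(self):
        rng = np.random.default_rng(1)
        a = self._clustered_assignments(120, 3)
        shuffled = ci.TrialAssignments(pre_densities=a.pre_densities,
                                       labels=rng.permutation(a.labels),
                                       n_regions=4, grid=a.grid)
        est = ci.bias_correct(shuffled, n_boot=60, seed=5)
        assert est.mi > 0.01           # raw plug-in is biased upward
        assert abs(est.corrected) <= max(2 * est.sd, 0.05)

    def test_doubling_trials_shrinks_raw_corrected_gap(self):
        gaps = []
        for n in (60, 120, 240):
            a = self._clustered_assignments(n, 7)
            est = ci.bias_correct(a, n_boot=40, seed=2)
            gaps.append(abs(est.mi - est.corrected))
        assert gaps[2] < gaps[0]

    def test_exact_recovery_on_deterministic_map(self, context_cluster_run):
        """Corrected MI within 5% of the exact chain-level value at 180 trials
        (mean over seeded replicate sessions)."""
        fx = context_cluster_run
        cfg, sched = fx["config"], fx["schedule"]
        vals, analytic = [], None
        for seed in (3, 9, 17, 25, 33, 41):
            cmap = wf.state_cluster_session(cfg, sched, seed=seed, resolution=24,
                                            spread=0.01, stride=2, sigma=1.0)
            analytic = sa.analytic_context_mi(cfg, sched,
                                              label_of_state=cmap.label_of_state)
            est, _ = wf.cluster_context_mi(cmap, sched, n_boot=60, seed=5,
                                           sigma=1.0)
            vals.append(est.corrected)
        assert abs(np.mean(vals) - analytic) / analytic < 0.05

    def test_too_few_trials_rejected(self):
        a = self._clustered_assignments(12, 1)
        with pytest.raises(ValueError):
            ci.bias_correct(a)


class TestInvariants:
    def test_mi_at_most_log2_n_plus_1(self, context_cluster_run):
        fx = context_cluster_run
        est, assign = wf.cluster_context_mi(fx["cmap"], fx["schedule"],
                                            n_boot=30, seed=1, sigma=1.0)
        assert 0 <= est.mi <= assign.mi_bound + 1e-9
        assert est.corrected <= est.mi + 3 * est.sd + 0.05

    def test_adding_empty_region_does_not_change_mi(self, rng):
        pre = rng.dirichlet(np.ones(16), size=40).astype(np.float32)
        labels = rng.integers(0, 3, size=40)
        a1 = _make_assignments(pre, labels, 2, 4)
        a2 = _make_assignments(pre, labels, 5, 4)
        assert ci.mutual_information(a1).mi == pytest.approx(
            ci.mutual_information(a2).mi, abs=1e-12)
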