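"""Context dependence of evoked behavior: pre-stimulus density vs post region.

Each trial is assigned the map region containing (or within 5 pixels of)
the mode of its density during the first second after LED onset; trials
farther than the tolerance from every region receive the 'zero' label.
Mutual information between the pre-stimulus density (t = -1.5 to -0.5 s)
and that label,

    MI = sum_k p(R_k) int dx p_pre(x | R_k) log2[ p_pre(x | R_k)
                                                  / sum_l p_pre(x | R_l) p(R_l) ],

is discretized on the map grid. The plug-in estimate is biased upward at
finite trial counts, so the estimator resamples subsets of trials with
replacement and extrapolates linearly in 1/n_trials to an infinite number
of trials; with N regions plus the zero label, MI is bounded by log2(N+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .map_geometry import MapGrid, RegionSet, region_distance_transform, smooth_and_normalize

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# trial assignment
# ---------------------------------------------------------------------------

def assign_post_region(trial_points: np.ndarray, regions: RegionSet,
                       sigma: float = 1.5, tol: float = 5.0,
                       dt_cache: dict | None = None) -> int:
    """Region label for one trial from the mode of its post-onset density.

    The mode is the argmax cell of the smoothed density of the trial's
    embedded points in the first post-onset second (row-major tie-break).
    The trial gets the nearest region's label if the mode lies within or
    closer than ``tol`` pixels to the region's edge (ties broken by smaller
    distance, then smaller label id), and the zero label otherwise.
    """
    pts = np.atleast_2d(trial_points)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) == 0:
        raise ValueError("trial has no valid embedded frames in the post window")
    grid = regions.grid
    dens = smooth_and_normalize(grid.histogram(pts), sigma)
    mode = np.unravel_index(np.argmax(dens), dens.shape)
    if dt_cache is None:
        dt_cache = {}
    best_label, best_dist = 0, np.inf
    for rid in regions.region_ids:
        if rid not in dt_cache:
            dt_cache[rid] = region_distance_transform(regions, rid)
        d = dt_cache[rid][mode]
        if d < best_dist:  # strict: ties keep the smaller label id
            best_label, best_dist = int(rid), d
    return best_label if best_dist <= tol else 0


@dataclass
class TrialAssignments:
    """Pre-window densities and post-window region labels, one row per trial."""

    pre_densities: np.ndarray   # (n_trials, cells), each row sums to 1
    labels: np.ndarray          # (n_trials,) int, 0 = zero label
    n_regions: int              # N: number of (significant) regions available
    grid: MapGrid

    def __post_init__(self) -> None:
        if len(self.pre_densities) != len(self.labels):
            raise ValueError("one pre-density per label required")
        if len(self.pre_densities):
            sums = self.pre_densities.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-5):
                raise ValueError("pre-window conditional densities must be normalized")

    @property
    def n_trials(self) -> int:
        return len(self.labels)

    @property
    def mi_bound(self) -> float:
        """Maximal possible MI, log2(N + 1), for N regions plus the zero label."""
        return float(np.log2(self.n_regions + 1))


def assign_trials(tracks, regions: RegionSet, schedule, sigma: float = 1.5,
                  tol: float = 5.0, post_window: tuple[float, float] = (0.0, 1.0),
                  pre_window: tuple[float, float] = (-1.5, -0.5),
                  n_regions: int | None = None) -> TrialAssignments:
    """Label every (fly, cycle) trial and collect its pre-window density.

    Trials without valid frames in either window are dropped (logged).
    """
    fps = schedule.fps
    grid = regions.grid
    post = (int(round(post_window[0] * fps)), int(round(post_window[1] * fps)))
    pre = (int(round(pre_window[0] * fps)), int(round(pre_window[1] * fps)))
    dt_cache: dict = {}
    pre_rows, labels = [], []
    dropped = 0
    for track in tracks:
        finite = np.all(np.isfinite(track.coords), axis=1)
        frames = track.frames[finite]
        coords = track.coords[finite]
        for onset in schedule.onset_frames:
            post_sel = (frames >= onset + post[0]) & (frames < onset + post[1])
            pre_sel = (frames >= onset + pre[0]) & (frames < onset + pre[1])
            if not post_sel.any() or not pre_sel.any():
                dropped += 1
                continue
            label = assign_post_region(coords[post_sel], regions, sigma=sigma,
                                       tol=tol, dt_cache=dt_cache)
            pre_rows.append(smooth_and_normalize(
                grid.histogram(coords[pre_sel]), sigma).ravel())
            labels.append(label)
    if dropped:
        log.info("dropped %d trials with empty pre/post windows", dropped)
    return TrialAssignments(
        pre_densities=np.array(pre_rows, dtype=np.float32),
        labels=np.array(labels, dtype=int),
        n_regions=int(regions.n_regions) if n_regions is None else n_regions,
        grid=grid)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

@dataclass
class MIEstimate:
    mi: float                     # raw plug-in MI (bits)
    corrected: float | None = None
    sd: float | None = None
    fractions: tuple = ()
    n_boot: int = 0
    n_trials: int = 0
    n_regions: int = 0
    trials_per_label: dict = field(default_factory=dict)

    @property
    def mi_bound(self) -> float:
        return float(np.log2(self.n_regions + 1))


def _plugin_mi(pre: np.ndarray, labels: np.ndarray,
               weights: np.ndarray | None = None,
               onehot: np.ndarray | None = None) -> float:
    """Plug-in MI between the pre-window density and the label, in bits.

    ``weights`` are per-trial multiplicities (bootstrap resample counts);
    ``onehot`` is an optional precomputed (n_trials, n_labels) label
    indicator reused across bootstrap draws.
    """
    if weights is None:
        weights = np.ones(len(labels))
    if onehot is None:
        uniq = np.unique(labels)
        onehot = (labels[:, None] == uniq[None, :]).astype(float)
    w_k = weights @ onehot                       # weighted trials per label
    live = w_k > 0
    if live.sum() < 2:
        return 0.0
    sums = (weights[:, None] * onehot).T @ pre   # (n_labels, cells)
    p_k = w_k[live] / weights.sum()
    cond = sums[live]
    cond = cond / cond.sum(axis=1, keepdims=True)
    marginal = p_k @ cond
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = cond * np.log2(cond / marginal[None, :])
    terms[~np.isfinite(terms)] = 0.0
    return float(max(p_k @ terms.sum(axis=1), 0.0))


def mutual_information(assignments: TrialAssignments) -> MIEstimate:
    """Raw plug-in MI between pre-stimulus density and post-stimulus region."""
    pre = np.asarray(assignments.pre_densities, dtype=float)
    mi = _plugin_mi(pre, assignments.labels)
    uniq, counts = np.unique(assignments.labels, return_counts=True)
    return MIEstimate(mi=mi, n_trials=assignments.n_trials,
                      n_regions=assignments.n_regions,
                      trials_per_label={int(k): int(c) for k, c in zip(uniq, counts)})


def bias_correct(assignments: TrialAssignments,
                 fractions: tuple = (0.5, 0.625, 0.75, 0.875, 1.0),
                 n_boot: int = 100, seed: int = 0) -> MIEstimate:
    """Finite-size corrected MI by extrapolation to infinite trial count.

    The plug-in estimate is biased upward roughly in proportion to
    1/n_trials. For each fraction below one, random trial subsets are drawn
    (without replacement, so each subset is a genuine smaller experiment
    whose mean traces the finite-size bias path) and the plug-in MI is
    recomputed; the full sample contributes the point at fraction one. The
    subset means are fit linearly against 1/n_trials and the intercept
    (1/n -> 0) is the corrected MI. The subset variance is extrapolated the
    same way to produce the error bar, falling back to the variance at the
    largest subsampled fraction when the intercept is not positive.
    """
    n = assignments.n_trials
    if n < 20:
        raise ValueError("bias correction needs at least 20 trials")
    pre = np.asarray(assignments.pre_densities, dtype=float)
    labels = assignments.labels
    rng = np.random.default_rng(seed)
    uniq = np.unique(labels)
    onehot = (labels[:, None] == uniq[None, :]).astype(float)
    base = mutual_information(assignments)
    inv_n, means = [], []
    inv_n_var, variances = [], []
    for f in fractions:
        n_sub = max(2, min(n, int(round(f * n))))
        if n_sub >= n:
            inv_n.append(1.0 / n)
            means.append(base.mi)
            continue
        vals = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.permutation(n)[:n_sub]
            w = np.zeros(n)
            w[idx] = 1.0
            vals[b] = _plugin_mi(pre, labels, weights=w, onehot=onehot)
        inv_n.append(1.0 / n_sub)
        means.append(vals.mean())
        inv_n_var.append(1.0 / n_sub)
        variances.append(vals.var(ddof=1))
    try:
        coef_m = np.polyfit(inv_n, means, 1)
    except np.linalg.LinAlgError:
        log.warning("bias-correction fit ill-conditioned; returning raw MI")
        return base
    corrected = float(coef_m[1])
    sd = None
    if len(variances) >= 2:
        coef_v = np.polyfit(inv_n_var, variances, 1)
        var_corr = coef_v[1] if coef_v[1] > 0 else variances[-1]
        sd = float(np.sqrt(var_corr))
    return MIEstimate(mi=base.mi, corrected=corrected, sd=sd,
                      fractions=tuple(fractions), n_boot=n_boot,
                      n_trials=n, n_regions=assignments.n_regions,
                      trials_per_label=base.trials_per_label)


def partial_mi_map(assignments: TrialAssignments, region_k: int) -> np.ndarray:
    """Cellwise MI contribution of one label: p(R_k) p(x|R_k) log2[p(x|R_k)/marginal].

    Summing these maps over cells and labels reproduces the raw MI.
    """
    pre = np.asarray(assignments.pre_densities, dtype=float)
    labels = assignments.labels
    uniq = np.unique(labels)
    if region_k not in uniq:
        raise ValueError(f"label {region_k} has no trials")
    p_k = np.array([(labels == k).mean() for k in uniq])
    cond = np.stack([pre[labels == k].mean(axis=0) for k in uniq])
    cond = cond / cond.sum(axis=1, keepdims=True)
    marginal = p_k @ cond
    j = int(np.flatnonzero(uniq == region_k)[0])
    c = cond[j]
    out = np.zeros_like(c)
    pos = (c > 0) & (marginal > 0)
    out[pos] = p_k[j] * c[pos] * np.log2(c[pos] / marginal[pos])
    res = assignments.grid.resolution
    return out.reshape(res, res)


def experimental_vs_control_mi(assignments_exp: TrialAssignments,
                               assignments_ctrl: TrialAssignments,
                               fractions: tuple = (0.5, 0.625, 0.75, 0.875, 1.0),
                               n_boot: int = 100, seed: int = 0):
    """Bias-corrected MI for both arms (regions fixed by the experimental arm)."""
    mi_exp = bias_correct(assignments_exp, fractions, n_boot, seed)
    mi_ctrl = bias_correct(assignments_ctrl, fractions, n_boot, seed + 1)
    return mi_exp, mi_ctrl
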