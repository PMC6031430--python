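"""Trial-aligned statistics over the behavior map.

For each fly i and stimulation cycle n the map density during the first
3 s of LED-on (rho_on) is compared against the 15 s window furthest from
stimulation (rho_off, t = 30-45 s after onset). Two cellwise Wilcoxon
rank-sum tests — rho_on vs rho_off within experimental flies, and the
LED-contrast statistic chi = rho_on - (rho_off_{n-1} + rho_off_n)/2
between experimental and control flies — are Sidak-corrected with an
effective comparison count m = ceil(2^H), H the entropy (bits) of the mean
experimental density. A cell is significantly activated only when both
tests pass. Entropy time courses and region occupancy time courses track
the timing of evoked behaviors across the 60 s cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import mannwhitneyu

from .map_geometry import DensityMap, MapGrid, RegionSet, smooth_and_normalize
from .synthetic_arena import StimulusSchedule

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# embedded session container
# ---------------------------------------------------------------------------

@dataclass
class FlyTrack:
    """One fly's embedded frames: map coordinates indexed by original frame."""

    frames: np.ndarray   # (n,) original frame indices (may be strided)
    coords: np.ndarray   # (n, 2)
    role: str = "experimental"
    fly_id: int = 0


# ---------------------------------------------------------------------------
# windows and trial densities
# ---------------------------------------------------------------------------

def trial_windows(schedule: StimulusSchedule,
                  on_window: tuple[float, float] = (0.0, 3.0),
                  off_window: tuple[float, float] = (30.0, 45.0)):
    """Frame windows (relative to each onset) for the on/off densities.

    Defaults: on = the first three seconds of stimulation, off = the 15 s
    window furthest from stimulation. Windows are half-open in frames.
    """
    cycle_s = schedule.on_duration + schedule.off_duration
    if off_window[1] > cycle_s + 1e-9:
        raise ValueError(
            f"off window ends at {off_window[1]} s but the cycle lasts {cycle_s} s"
        )
    fps = schedule.fps
    on = (int(round(on_window[0] * fps)), int(round(on_window[1] * fps)))
    off = (int(round(off_window[0] * fps)), int(round(off_window[1] * fps)))
    if on[1] > off[0] and off[1] > on[0]:
        raise ValueError("on and off windows must be disjoint")
    return on, off


@dataclass
class TrialTensor:
    """Per-fly, per-cycle on/off densities aligned to the stimulus schedule."""

    rho_on: np.ndarray    # (F, N, cells) float32, rows sum to 1 where present
    rho_off: np.ndarray   # (F, N, cells)
    missing: np.ndarray   # (F, N) bool: True where a window had no valid frames
    roles: list
    grid: MapGrid
    sigma: float
    on_window: tuple
    off_window: tuple

    @property
    def n_flies(self) -> int:
        return self.rho_on.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.rho_on.shape[1]

    def select(self, role: str) -> "TrialTensor":
        keep = np.array([r == role for r in self.roles])
        return TrialTensor(rho_on=self.rho_on[keep], rho_off=self.rho_off[keep],
                           missing=self.missing[keep],
                           roles=[r for r in self.roles if r == role],
                           grid=self.grid, sigma=self.sigma,
                           on_window=self.on_window, off_window=self.off_window)


def _window_density(track: FlyTrack, lo: int, hi: int, grid: MapGrid,
                    sigma: float):
    sel = (track.frames >= lo) & (track.frames < hi)
    pts = track.coords[sel]
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) == 0:
        return None
    return smooth_and_normalize(grid.histogram(pts), sigma).ravel()


def trial_densities(tracks: list[FlyTrack], schedule: StimulusSchedule,
                    grid: MapGrid, sigma: float = 1.5,
                    on_window: tuple[float, float] = (0.0, 3.0),
                    off_window: tuple[float, float] = (30.0, 45.0)) -> TrialTensor:
    """One on- and one off-density per fly per cycle (invalid gaps excluded)."""
    on, off = trial_windows(schedule, on_window, off_window)
    F, N, C = len(tracks), schedule.n_cycles, grid.n_cells
    rho_on = np.zeros((F, N, C), dtype=np.float32)
    rho_off = np.zeros((F, N, C), dtype=np.float32)
    missing = np.zeros((F, N), dtype=bool)
    for i, track in enumerate(tracks):
        for n, onset in enumerate(schedule.onset_frames):
            d_on = _window_density(track, onset + on[0], onset + on[1], grid, sigma)
            d_off = _window_density(track, onset + off[0], onset + off[1], grid, sigma)
            if d_on is None or d_off is None:
                missing[i, n] = True
                continue
            rho_on[i, n] = d_on
            rho_off[i, n] = d_off
    return TrialTensor(rho_on=rho_on, rho_off=rho_off, missing=missing,
                       roles=[t.role for t in tracks], grid=grid, sigma=sigma,
                       on_window=on_window, off_window=off_window)


def chi_map(tensor: TrialTensor, i: int, n: int) -> np.ndarray:
    """chi_{i,n} = rho_on_{i,n} - (rho_off_{i,n-1} + rho_off_{i,n}) / 2.

    Undefined for the first cycle (no preceding off window).
    """
    if n < 1:
        raise ValueError("chi is undefined for the first cycle (needs cycle n-1)")
    if tensor.missing[i, n] or tensor.missing[i, n - 1]:
        raise ValueError(f"fly {i}, cycle {n}: a required window is missing")
    return (tensor.rho_on[i, n]
            - 0.5 * (tensor.rho_off[i, n - 1] + tensor.rho_off[i, n]))


def chi_all(tensor: TrialTensor):
    """All defined chi maps, flattened over (fly, cycle >= 2).

    Returns ``(chi, fly_idx, cycle_idx)``.
    """
    rows, fi, ci = [], [], []
    for i in range(tensor.n_flies):
        for n in range(1, tensor.n_cycles):
            if tensor.missing[i, n] or tensor.missing[i, n - 1]:
                continue
            rows.append(chi_map(tensor, i, n))
            fi.append(i)
            ci.append(n)
    if not rows:
        return np.zeros((0, tensor.grid.n_cells), dtype=np.float32), np.array(fi), np.array(ci)
    return np.stack(rows), np.array(fi), np.array(ci)


# ---------------------------------------------------------------------------
# entropy and the Sidak-corrected significance map
# ---------------------------------------------------------------------------

def entropy(density: np.ndarray) -> float:
    """Shannon entropy of a normalized density, in bits."""
    p = np.asarray(density, dtype=float).ravel()
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("entropy expects a normalized density")
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def sidak_threshold(alpha: float, m: float) -> float:
    """Per-comparison level alpha' = 1 - (1 - alpha)^(1/m)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be at least 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def rank_sum_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values per column.

    Exact null for small tie-free samples, normal approximation with tie
    correction otherwise; columns where every observation is identical get
    p = 1 (no evidence of a shift).

    For heavily tied columns (a cell of the map visited in only a handful
    of trials) the normal approximation is anti-conservative in the far
    tail, so every p-value is floored at the exact probability of the most
    extreme group assignment: with k observations differing from the modal
    value, no exact p can fall below (C(n1,k) + C(n2,k)) / C(n1+n2,k).
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    n1, n2 = a.shape[0], b.shape[0]
    small = max(n1, n2) <= 25
    if small and a.shape[1] == 1:
        has_ties = len(np.unique(np.concatenate([a.ravel(), b.ravel()]))) < n1 + n2
        method = "asymptotic" if has_ties else "exact"
    else:
        method = "asymptotic"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = mannwhitneyu(a, b, axis=0, method=method, alternative="two-sided")
        p = np.atleast_1d(res.pvalue).astype(float)
    pooled = np.vstack([a, b])
    flat = np.ptp(pooled, axis=0) == 0
    p[flat | ~np.isfinite(p)] = 1.0
    if method == "asymptotic":
        # count of observations away from each column's modal value
        srt = np.sort(pooled, axis=0)
        runs = np.diff(srt, axis=0) != 0
        # longest run of equal values per column
        n = pooled.shape[0]
        modal = np.empty(pooled.shape[1], dtype=int)
        for j in range(pooled.shape[1]):
            edges = np.flatnonzero(runs[:, j])
            bounds = np.concatenate(([0], edges + 1, [n]))
            modal[j] = np.max(np.diff(bounds))
        k = n - modal
        floor = np.exp(_log_comb(n1, k)) + np.exp(_log_comb(n2, k))
        floor = floor / np.exp(_log_comb(n, k))
        np.maximum(p, np.minimum(floor, 1.0), out=p)
    return p


def _log_comb(n: int, k: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


@dataclass
class SignificanceMap:
    p_on_off: np.ndarray        # per-cell p, test 1 (on vs off, experimental)
    p_chi: np.ndarray           # per-cell p, test 2 (chi exp vs control)
    mask: np.ndarray            # per-cell bool: significant under both tests
                                # and shifted upward (activation, mean chi > 0)
    alpha: float
    alpha_corrected: float
    m: int                      # effective comparison count, ceil(2^H)
    H: float                    # entropy (bits) of the mean experimental density
    mean_density: np.ndarray    # mean experimental density (cells,)
    mean_chi: np.ndarray        # mean experimental chi (cells,)
    grid: MapGrid

    def mask_image(self) -> np.ndarray:
        return self.mask.reshape(self.grid.resolution, self.grid.resolution)


def significance_maps(tensor_exp: TrialTensor, tensor_ctrl: TrialTensor,
                      alpha: float = 0.05) -> SignificanceMap:
    """Cellwise double Wilcoxon test for significantly activated map cells.

    Both rank-sum tests are two-sided as printed, but the activation mask
    keeps only cells whose density increased (mean chi > 0): cells emptied
    by the stimulus are significant shifts too, yet they are the shadow of
    the activation, not the evoked behavior.
    """
    if tensor_exp.n_flies < 2 or tensor_ctrl.n_flies < 2:
        raise ValueError("need at least two flies per arm")
    if tensor_exp.n_cycles < 2:
        raise ValueError("need at least two stimulation cycles")
    present = ~tensor_exp.missing
    on = tensor_exp.rho_on[present]
    off = tensor_exp.rho_off[present]
    chi_exp, _, _ = chi_all(tensor_exp)
    chi_ctrl, _, _ = chi_all(tensor_ctrl)

    mean_density = np.concatenate([on, off]).mean(axis=0)
    mean_density = mean_density / mean_density.sum()
    H = entropy(mean_density)
    m = int(np.ceil(2.0 ** H))
    a_corr = sidak_threshold(alpha, m)

    p1 = rank_sum_pvalues(on, off)
    p2 = rank_sum_pvalues(chi_exp, chi_ctrl)
    mean_chi = (chi_exp.mean(axis=0) if len(chi_exp)
                else np.zeros(tensor_exp.grid.n_cells))
    mask = (p1 < a_corr) & (p2 < a_corr) & (mean_chi > 0)
    return SignificanceMap(p_on_off=p1, p_chi=p2, mask=mask, alpha=alpha,
                           alpha_corrected=a_corr, m=m, H=H,
                           mean_density=mean_density, mean_chi=mean_chi,
                           grid=tensor_exp.grid)


@dataclass
class SignificantRegions:
    """Connected components of the significant mask and watershed overlaps."""

    component_labels: np.ndarray    # (res, res) int, 0 background
    n_components: int               # N, the number of significant regions
    overlaps: dict                  # component id -> list of watershed region ids
    union_mask: np.ndarray          # (res, res) bool


def significant_regions(signif: SignificanceMap, regions: RegionSet) -> SignificantRegions:
    """Connected significant components and their watershed associations."""
    mask_img = signif.mask_image()
    comp, n = ndimage.label(mask_img)
    overlaps = {}
    for cid in range(1, n + 1):
        ws = np.unique(regions.labels[comp == cid])
        overlaps[cid] = [int(w) for w in ws if w > 0]
    return SignificantRegions(component_labels=comp, n_components=int(n),
                              overlaps=overlaps, union_mask=mask_img)


# ---------------------------------------------------------------------------
# entropy curves and region time courses
# ---------------------------------------------------------------------------

def _phase_pool(tracks, schedule, halfwidth_frames, phase_frames):
    """For each phase, indices pooling points across cycles/flies within
    +/- halfwidth (periodic at the cycle boundary)."""
    cycle = schedule.cycle_frames
    pts = np.vstack([t.coords for t in tracks])
    phases = np.concatenate([t.frames % cycle for t in tracks])
    order = np.argsort(phases, kind="stable")
    phases = phases[order]
    pts = pts[order]
    pools = []
    for pf in phase_frames:
        lo, hi = pf - halfwidth_frames, pf + halfwidth_frames
        sel = slice(np.searchsorted(phases, lo), np.searchsorted(phases, hi + 1))
        idx = [np.arange(sel.start, sel.stop)]
        if lo < 0:  # wrap from the end of the cycle
            idx.append(np.arange(np.searchsorted(phases, lo + cycle), len(phases)))
        if hi >= cycle:
            idx.append(np.arange(0, np.searchsorted(phases, hi - cycle + 1)))
        pools.append(pts[np.concatenate(idx)])
    return pools


@dataclass
class EntropyCurve:
    phases_s: np.ndarray
    H: np.ndarray                   # bits; NaN where the phase window was empty
    baseline_subtracted: np.ndarray
    sigma: float
    halfwidth_s: float


def entropy_curve(tracks: list[FlyTrack], schedule: StimulusSchedule,
                  grid: MapGrid, sigma: float = 2.0, halfwidth: float = 0.2,
                  step: float = 0.1,
                  baseline_window: tuple[float, float] = (30.0, 45.0)) -> EntropyCurve:
    """Entropy of the phase-conditioned density across the stimulus cycle.

    For each phase t of the cycle, points from all trials within +/-
    ``halfwidth`` seconds (periodic boundary) are pooled into a smoothed
    density p_t(x, y) whose Shannon entropy gives H(t). The baseline-
    subtracted variant removes the mean over the off-window phases.
    """
    if schedule.n_cycles < 1:
        raise ValueError("need at least one cycle")
    fps = schedule.fps
    cycle_s = schedule.on_duration + schedule.off_duration
    phases_s = np.arange(0.0, cycle_s, step)
    hw = int(round(halfwidth * fps))
    pools = _phase_pool(tracks, schedule, hw, np.round(phases_s * fps).astype(int))
    H = np.full(len(phases_s), np.nan)
    for k, pts in enumerate(pools):
        if len(pts) == 0:
            continue
        d = smooth_and_normalize(grid.histogram(pts), sigma)
        H[k] = entropy(d)
    base_sel = (phases_s >= baseline_window[0]) & (phases_s < baseline_window[1])
    baseline = np.nanmean(H[base_sel]) if base_sel.any() else np.nanmean(H)
    return EntropyCurve(phases_s=phases_s, H=H, baseline_subtracted=H - baseline,
                        sigma=sigma, halfwidth_s=halfwidth)


@dataclass
class RegionTimecourse:
    phases_s: np.ndarray
    mean: np.ndarray   # mean region occupancy across flies x cycles
    sd: np.ndarray
    window_s: float


def region_timecourse(tracks: list[FlyTrack], region_mask: np.ndarray,
                      schedule: StimulusSchedule, grid: MapGrid,
                      window: float = 3.0, step: float = 0.5) -> RegionTimecourse:
    """Sliding-window occupancy of a map region across the stimulus cycle.

    ``region_mask`` is a boolean image over the grid. For each window
    position each (fly, cycle) contributes the fraction of its embedded
    points inside the region; curves report mean +/- sd over those samples.
    """
    mask_img = np.asarray(region_mask, dtype=bool)
    fps = schedule.fps
    cycle = schedule.cycle_frames
    cycle_s = schedule.on_duration + schedule.off_duration
    starts_s = np.arange(0.0, cycle_s - window + 1e-9, step)
    wf = int(round(window * fps))

    samples = []  # per (fly, cycle): occupancy per window
    for t in tracks:
        finite = np.all(np.isfinite(t.coords), axis=1)
        frames = t.frames[finite]
        idx = grid.cell_indices(t.coords[finite])
        inside = mask_img[idx[:, 0], idx[:, 1]]
        phase = frames % cycle
        cyc = frames // cycle
        for n in range(schedule.n_cycles):
            sel = cyc == n
            ph = phase[sel]
            ins = inside[sel]
            order = np.argsort(ph, kind="stable")
            ph, ins = ph[order], ins[order]
            csum = np.concatenate([[0], np.cumsum(ins)])
            occ = np.full(len(starts_s), np.nan)
            for k, s0 in enumerate(np.round(starts_s * fps).astype(int)):
                a, b = np.searchsorted(ph, [s0, s0 + wf])
                if b > a:
                    occ[k] = (csum[b] - csum[a]) / (b - a)
            samples.append(occ)
    arr = np.array(samples)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(arr, axis=0) if len(arr) else np.full(len(starts_s), np.nan)
        sd = np.nanstd(arr, axis=0) if len(arr) else np.full(len(starts_s), np.nan)
    return RegionTimecourse(phases_s=starts_s, mean=mean, sd=sd, window_s=window)


# ---------------------------------------------------------------------------
# per-neuron averaging across lines
# ---------------------------------------------------------------------------

def neuron_average(line_results: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Average positive significant mean-chi maps across lines targeting a neuron.

    Each entry is ``(mean_chi, significant_mask)`` on the shared grid; per
    line, non-significant cells and negative means are zeroed before the
    across-line average.
    """
    if not line_results:
        raise ValueError("need at least one line result")
    shape = np.asarray(line_results[0][0]).shape
    maps = []
    for mean_chi, mask in line_results:
        mean_chi = np.asarray(mean_chi, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if mean_chi.shape != shape or mask.shape != shape:
            raise ValueError("all line results must share one grid shape")
        maps.append(np.where(mask & (mean_chi > 0), mean_chi, 0.0))
    return np.mean(maps, axis=0)
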