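"""End-to-end drivers: synthetic session -> behavior map -> phenotype -> MI.

These functions chain the stage modules into the line-level analyses the
screen performs per split-GAL4 line: simulate (or load) a 12-fly session,
extract normalized wavelet spectra, train and apply the KL t-SNE embedding,
build the density map and watershed regions, run the double-Wilcoxon
significance analysis with entropy/region time courses, and estimate
context mutual information. The analysis scripts, the tests and the
acceptance script all run through this module so problem sizes stay in one
place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import behavior_embedding as be
from . import context_information as ci
from . import map_geometry as mg
from . import opto_phenotyping as op
from . import spectral_features as sf
from . import synthetic_arena as sa

log = logging.getLogger(__name__)


@dataclass
class FlySession:
    """One fly's strided feature rows plus ground truth."""

    fly_id: int
    role: str
    frames: np.ndarray       # strided original frame indices
    features: np.ndarray     # (n, n_modes * n_channels) float32 rows
    states: np.ndarray       # full-resolution latent state sequence
    low_power: np.ndarray


def simulate_line_features(config: sa.SyntheticConfig, schedule: sa.StimulusSchedule,
                           seed: int, n_experimental: int = 6, n_control: int = 6,
                           stride: int = 5, grid: sf.ChannelGrid | None = None,
                           eps: float = 1e-12) -> list[FlySession]:
    """Simulate a session and extract per-fly normalized wavelet spectra.

    Control flies share the line's genotype but the LED has no effect on
    them. Feature rows are kept every ``stride`` frames (statistics
    downstream select frames by original index, so striding only thins the
    sampling of each analysis window).
    """
    if grid is None:
        grid = sf.channel_grid()
    truths = sa.simulate_session(config, schedule, seed,
                                 n_experimental=n_experimental, n_control=n_control)
    rng = np.random.default_rng(seed + 101)
    sessions = []
    for i, gt in enumerate(truths):
        cfg = config if gt.role == "experimental" else sa.control_of(config)
        modes = sa.synthesize_posture(gt, cfg, seed=int(rng.integers(2 ** 31)),
                                      fps=schedule.fps)
        spec = sf.morlet_cwt(modes.astype(np.float32), grid, schedule.fps)
        frames = np.arange(0, schedule.n_frames, stride)
        feats, low = sf.normalize_spectra(spec[frames], eps=eps)
        sessions.append(FlySession(
            fly_id=i, role=gt.role, frames=frames,
            features=feats.astype(np.float32, copy=False),
            states=gt.state_sequence, low_power=low))
    return sessions


@dataclass
class BehaviorMap:
    """Trained embedding plus the shared analysis geometry."""

    training: be.TrainingSet
    embedding: be.TrainingEmbedding
    grid: mg.MapGrid
    density: mg.DensityMap
    regions: mg.RegionSet
    tracks: list                      # op.FlyTrack per fly
    embedded_fraction: float


def embed_sessions(sessions: list[FlySession], seed: int, quota: int = 600,
                   train_size: int = 1200, perplexity: float = 32.0,
                   max_iter: int = 500):
    """Train the 2D embedding and re-embed every strided frame.

    Returns ``(training, embedding, tracks, embedded_fraction)``.
    """
    feats = [s.features.astype(np.float64) for s in sessions]
    training = be.hierarchical_training_set(feats, quota=quota,
                                            group_size=max(train_size, quota),
                                            final=train_size, seed=seed)
    embedding = be.tsne_embed(training.features, perplexity=perplexity,
                              max_iter=max_iter, seed=seed)
    # re-embed all flies in one batched call
    all_feats = np.vstack([s.features for s in sessions]).astype(np.float64)
    pts = be.reembed(all_feats, training.features, embedding)
    tracks = []
    n_valid = n_embedded = 0
    offset = 0
    for s in sessions:
        coords = pts.coords[offset:offset + len(s.frames)]
        offset += len(s.frames)
        finite = np.all(np.isfinite(coords), axis=1)
        n_valid += len(s.frames)
        n_embedded += int(finite.sum())
        tracks.append(op.FlyTrack(frames=s.frames[finite], coords=coords[finite],
                                  role=s.role, fly_id=s.fly_id))
    return training, embedding, tracks, n_embedded / max(n_valid, 1)


def make_map_geometry(embedding_coords: np.ndarray, tracks: list,
                      resolution: int = 210, sigma: float = 1.5,
                      min_density_quantile: float = 0.35):
    """Analysis grid, overall density and watershed regions for a trained map."""
    grid = mg.MapGrid.from_points(embedding_coords, resolution=resolution)
    all_pts = np.vstack([t.coords for t in tracks])
    density = mg.density_map(all_pts, grid, sigma=sigma)
    regions = mg.watershed_regions(density, min_density_quantile=min_density_quantile)
    return grid, density, regions


def build_behavior_map(sessions: list[FlySession], seed: int,
                       quota: int = 600, train_size: int = 1200,
                       perplexity: float = 32.0, max_iter: int = 500,
                       resolution: int = 210, sigma: float = 1.5,
                       min_density_quantile: float = 0.35) -> BehaviorMap:
    """Train the 2D behavior space on a session set and embed every frame."""
    training, embedding, tracks, frac = embed_sessions(
        sessions, seed, quota=quota, train_size=train_size,
        perplexity=perplexity, max_iter=max_iter)
    grid, density, regions = make_map_geometry(
        embedding.coords, tracks, resolution=resolution, sigma=sigma,
        min_density_quantile=min_density_quantile)
    return BehaviorMap(training=training, embedding=embedding, grid=grid,
                       density=density, regions=regions, tracks=tracks,
                       embedded_fraction=frac)


@dataclass
class PhenotypeResult:
    tensor_exp: op.TrialTensor
    tensor_ctrl: op.TrialTensor
    significance: op.SignificanceMap
    regions: op.SignificantRegions
    entropy_exp: op.EntropyCurve
    entropy_ctrl: op.EntropyCurve


def phenotype_line(bmap: BehaviorMap, schedule: sa.StimulusSchedule,
                   alpha: float = 0.05, sigma: float = 1.5,
                   sigma_entropy: float = 2.0, entropy_step: float = 0.25,
                   entropy_resolution: int | None = None,
                   on_window=(0.0, 3.0), off_window=(30.0, 45.0)) -> PhenotypeResult:
    """Significance maps, significant regions and entropy curves for one line.

    ``entropy_resolution`` optionally coarsens the grid used for the
    entropy time courses: the plug-in entropy of a phase-conditioned
    density is noisy when few trials are pooled, and a coarser grid keeps
    the estimator's fluctuations well below the effects of interest.
    """
    exp_tracks = [t for t in bmap.tracks if t.role == "experimental"]
    ctrl_tracks = [t for t in bmap.tracks if t.role == "control"]
    tensor = op.trial_densities(bmap.tracks, schedule, bmap.grid, sigma=sigma,
                                on_window=on_window, off_window=off_window)
    tensor_exp = tensor.select("experimental")
    tensor_ctrl = tensor.select("control")
    signif = op.significance_maps(tensor_exp, tensor_ctrl, alpha=alpha)
    sig_regions = op.significant_regions(signif, bmap.regions)
    e_grid = bmap.grid
    if entropy_resolution is not None and entropy_resolution != bmap.grid.resolution:
        e_grid = mg.MapGrid(bmap.grid.x_min, bmap.grid.x_max, bmap.grid.y_min,
                            bmap.grid.y_max, resolution=entropy_resolution)
    H_exp = op.entropy_curve(exp_tracks, schedule, e_grid, sigma=sigma_entropy,
                             step=entropy_step, baseline_window=off_window)
    H_ctrl = op.entropy_curve(ctrl_tracks, schedule, e_grid, sigma=sigma_entropy,
                              step=entropy_step, baseline_window=off_window)
    return PhenotypeResult(tensor_exp=tensor_exp, tensor_ctrl=tensor_ctrl,
                           significance=signif, regions=sig_regions,
                           entropy_exp=H_exp, entropy_ctrl=H_ctrl)


def context_mi(bmap: BehaviorMap, schedule: sa.StimulusSchedule,
               regions: mg.RegionSet | None = None, sigma: float = 1.5,
               tol: float = 5.0, pre_window=(-1.5, -0.5), post_window=(0.0, 1.0),
               fractions=(0.5, 0.625, 0.75, 0.875, 1.0), n_boot: int = 100,
               seed: int = 0):
    """Bias-corrected MI for both arms, using one shared region set.

    Returns ``(mi_exp, mi_ctrl, assignments_exp, assignments_ctrl)``.
    """
    regions = bmap.regions if regions is None else regions
    exp_tracks = [t for t in bmap.tracks if t.role == "experimental"]
    ctrl_tracks = [t for t in bmap.tracks if t.role == "control"]
    a_exp = ci.assign_trials(exp_tracks, regions, schedule, sigma=sigma, tol=tol,
                             post_window=post_window, pre_window=pre_window)
    a_ctrl = ci.assign_trials(ctrl_tracks, regions, schedule, sigma=sigma, tol=tol,
                              post_window=post_window, pre_window=pre_window)
    mi_exp, mi_ctrl = ci.experimental_vs_control_mi(a_exp, a_ctrl,
                                                    fractions=fractions,
                                                    n_boot=n_boot, seed=seed)
    return mi_exp, mi_ctrl, a_exp, a_ctrl


# ---------------------------------------------------------------------------
# ground-truth map helpers (oracles for recovery tests)
# ---------------------------------------------------------------------------

def region_state_ownership(bmap: BehaviorMap, sessions: list[FlySession],
                           n_states: int) -> dict:
    """Majority latent state of each watershed region (ground-truth vote).

    Counts, per watershed region, how many embedded points of each latent
    state fall inside it; the region is 'owned' by the plurality state.
    """
    counts = {int(r): np.zeros(n_states) for r in bmap.regions.region_ids}
    labels = bmap.regions.labels
    for sess, track in zip(sessions, bmap.tracks):
        idx = bmap.grid.cell_indices(track.coords)
        rid = labels[idx[:, 0], idx[:, 1]]
        st = sess.states[track.frames]
        for r in counts:
            sel = rid == r
            if sel.any():
                counts[r] += np.bincount(st[sel], minlength=n_states)
    return {r: int(np.argmax(c)) if c.sum() else -1 for r, c in counts.items()}


def state_territory_mask(bmap: BehaviorMap, sessions: list[FlySession],
                         state: int) -> np.ndarray:
    """Grid mask of the watershed regions owned by a latent state.

    A state's postural signature can split into several adjacent watershed
    basins of the map, so the territory is the union of every region whose
    plurality occupant (by ground-truth state labels) is ``state``.
    """
    n_states = int(max(s.states.max() for s in sessions)) + 1
    owner = region_state_ownership(bmap, sessions, n_states)
    mask = np.zeros_like(bmap.regions.labels, dtype=bool)
    for r, s in owner.items():
        if s == state:
            mask |= bmap.regions.labels == r
    return mask


def pure_frame_mask(states: np.ndarray, frames: np.ndarray, fps: float,
                    margin_s: float = 1.5) -> np.ndarray:
    """True for frames whose neighborhood holds a single latent state.

    The wavelet transform smears each frame's spectrum over roughly a
    second, so a frame within ``margin_s`` of a bout boundary carries a
    mixture of two states and has no well-defined single-state label; the
    mask restricts label-based oracles to frames where the label is valid.
    """
    margin = int(round(margin_s * fps))
    changes = np.flatnonzero(np.diff(states)) + 1
    ok = np.ones(len(frames), dtype=bool)
    for i, f in enumerate(frames):
        j = np.searchsorted(changes, f)
        if j > 0 and f - changes[j - 1] < margin:
            ok[i] = False
        if j < len(changes) and changes[j] - f < margin:
            ok[i] = False
    return ok


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


# ---------------------------------------------------------------------------
# state-cluster map emulation (MI estimator studies)
# ---------------------------------------------------------------------------

@dataclass
class ClusterMap:
    """Direct state-to-map emulation: each latent state owns one Gaussian cluster."""

    truths: list
    tracks: list                 # op.FlyTrack per fly
    grid: mg.MapGrid
    regions: mg.RegionSet
    centers: np.ndarray          # (n_states, 2) cluster centers (map units)
    label_of_state: np.ndarray   # watershed region id owning each state


def state_cluster_session(config: sa.SyntheticConfig, schedule: sa.StimulusSchedule,
                          seed: int, n_experimental: int = 6, n_control: int = 6,
                          stride: int = 5, spread: float = 0.02,
                          resolution: int = 64, sigma: float = 1.5) -> ClusterMap:
    """Simulate a session and place frames directly into a synthetic map.

    Bypasses the posture/wavelet/embedding stages by assigning every frame
    a position drawn from its latent state's Gaussian cluster on a unit
    square, the asymptotic geometry a well-separated embedding converges
    to. Used to study the trial-assignment and MI estimators at scale,
    with the analytic chain oracles as ground truth.
    """
    truths = sa.simulate_session(config, schedule, seed,
                                 n_experimental=n_experimental,
                                 n_control=n_control)
    S = config.n_states
    ang = 2 * np.pi * np.arange(S) / S
    centers = 0.5 + 0.32 * np.column_stack([np.cos(ang), np.sin(ang)])
    rng = np.random.default_rng(seed + 7)
    frames = np.arange(0, schedule.n_frames, stride)
    tracks = []
    for i, gt in enumerate(truths):
        st = gt.state_sequence[frames]
        coords = centers[st] + rng.normal(0, spread, size=(len(frames), 2))
        tracks.append(op.FlyTrack(frames=frames, coords=coords,
                                  role=gt.role, fly_id=i))
    grid = mg.MapGrid(0.0, 1.0, 0.0, 1.0, resolution=resolution)
    all_pts = np.vstack([t.coords for t in tracks])
    density = mg.density_map(all_pts, grid, sigma=sigma)
    regions = mg.watershed_regions(density, min_density_quantile=0.35)
    idx = grid.cell_indices(centers)
    label_of_state = regions.labels[idx[:, 0], idx[:, 1]]
    return ClusterMap(truths=truths, tracks=tracks, grid=grid, regions=regions,
                      centers=centers, label_of_state=label_of_state)


def cluster_context_mi(cmap: ClusterMap, schedule: sa.StimulusSchedule,
                       role: str = "experimental", tol: float = 5.0,
                       sigma: float = 1.5, n_boot: int = 50, seed: int = 0,
                       corrected: bool = True):
    """Bias-corrected MI of one arm of a state-cluster session.

    Returns ``(MIEstimate, TrialAssignments)``.
    """
    tracks = [t for t in cmap.tracks if t.role == role]
    assign = ci.assign_trials(tracks, cmap.regions, schedule, sigma=sigma,
                              tol=tol)
    if not corrected:
        return ci.mutual_information(assign), assign
    return ci.bias_correct(assign, n_boot=n_boot, seed=seed), assign


# ---------------------------------------------------------------------------
# one-call line analysis (the unit the screen repeats per line)
# ---------------------------------------------------------------------------

@dataclass
class LineResult:
    sessions: list
    bmap: BehaviorMap
    phenotype: PhenotypeResult
    schedule: sa.StimulusSchedule


def run_line_analysis(config: sa.SyntheticConfig, seed: int,
                      n_cycles: int = 10, fps: float = 100.0,
                      stride: int = 5, train_size: int = 1000,
                      resolution: int = 24, max_iter: int = 350,
                      quota: int = 150, entropy_step: float = 0.25,
                      entropy_resolution: int | None = 16,
                      alpha: float = 0.05) -> LineResult:
    """Simulate one line and run the full phenotyping analysis.

    Defaults are the reduced test-scale problem sizes; the acceptance runs
    pass the full 30-cycle protocol and a finer entropy grid.
    """
    schedule = sa.make_led_schedule(fps, n_cycles, 15, 45)
    sessions = simulate_line_features(config, schedule, seed, stride=stride)
    bmap = build_behavior_map(sessions, seed + 1, quota=quota,
                              train_size=train_size, max_iter=max_iter,
                              resolution=resolution)
    phen = phenotype_line(bmap, schedule, alpha=alpha, entropy_step=entropy_step,
                          entropy_resolution=entropy_resolution)
    return LineResult(sessions=sessions, bmap=bmap, phenotype=phen,
                      schedule=schedule)
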