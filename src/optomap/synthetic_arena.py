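"""Ground-truthed synthetic arena sessions.

Emulates the structure of the optogenetic screen: 12-fly sessions (6
retinal-fed experimental, 6 non-retinal controls), repeated cycles of
15 s LED-on / 45 s LED-off at 100 fps, a hidden behavior-state Markov
process whose state-specific postural oscillations produce separable
wavelet signatures, LED-triggered shifts toward designated states, and
optional dependence of the evoked state on the pre-stimulus state (to
inject a known amount of mutual information).

Every stochastic quantity the downstream analysis estimates (state
occupancies, evoked-state maps, context mutual information) is also
computable here by exact enumeration over the known chain, so the
generator doubles as the oracle for the statistical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSchedule:
    """Periodic LED stimulation protocol.

    Default protocol: 30 cycles of a 15 s red-light pulse followed by a
    45 s recovery interval, recorded at 100 frames per second.
    """

    fps: float
    n_cycles: int
    on_duration: float  # seconds
    off_duration: float  # seconds
    onset_frames: np.ndarray  # strictly increasing LED-on frame indices

    @property
    def cycle_frames(self) -> int:
        return int(round((self.on_duration + self.off_duration) * self.fps))

    @property
    def on_frames(self) -> int:
        return int(round(self.on_duration * self.fps))

    @property
    def n_frames(self) -> int:
        return self.n_cycles * self.cycle_frames

    def led_mask(self) -> np.ndarray:
        """Boolean per-frame mask, True while the LED is on."""
        mask = np.zeros(self.n_frames, dtype=bool)
        for onset in self.onset_frames:
            mask[onset:onset + self.on_frames] = True
        return mask


def _check_integer_frames(seconds: float, fps: float, what: str) -> int:
    frames = seconds * fps
    if abs(frames - round(frames)) > 1e-9:
        raise ValueError(
            f"{what} of {seconds} s at {fps} fps gives a non-integer frame "
            f"count ({frames}); choose durations commensurate with the frame rate"
        )
    return int(round(frames))


def make_led_schedule(fps: float = 100.0, n_cycles: int = 30,
                      on_s: float = 15.0, off_s: float = 45.0) -> StimulusSchedule:
    """Build the periodic LED schedule (default 30 x (15 s on + 45 s off))."""
    if fps <= 0 or n_cycles <= 0 or on_s <= 0 or off_s <= 0:
        raise ValueError("fps, n_cycles, on_s and off_s must all be positive")
    on_frames = _check_integer_frames(on_s, fps, "on duration")
    off_frames = _check_integer_frames(off_s, fps, "off duration")
    cycle = on_frames + off_frames
    onsets = np.arange(n_cycles, dtype=int) * cycle
    return StimulusSchedule(fps=fps, n_cycles=n_cycles, on_duration=on_s,
                            off_duration=off_s, onset_frames=onsets)


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

def _check_stochastic(T: np.ndarray, name: str) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError(f"{name} must be row-stochastic (non-negative rows summing to 1)")
    return T


@dataclass
class SyntheticConfig:
    """Latent-state process and per-state postural oscillation spectra.

    ``state_spectra[s]`` is a list of ``(mode, frequency_hz, amplitude)``
    triples: while the chain occupies state ``s``, posture mode ``mode``
    oscillates at ``frequency_hz``. For context lines, ``delta`` in [0, 1]
    sets the probability that each trial's evoked target follows
    ``context_map`` applied to the pre-stimulus state (read
    ``context_anchor_s`` before onset) instead of an independent draw from
    ``evoked_base``; ``delta = 0`` makes the evoked state independent of
    the pre-stimulus state.
    """

    n_states: int
    n_modes: int
    state_spectra: list  # per state: list of (mode, freq_hz, amplitude)
    T_off: np.ndarray
    T_on: np.ndarray
    context_map: np.ndarray | None = None  # pre-state -> intended evoked state
    delta: float = 0.0
    evoked_base: np.ndarray | None = None  # unconditioned evoked distribution
    context_anchor_s: float = 1.5          # pre-state read this long before onset
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        self.T_off = _check_stochastic(self.T_off, "T_off")
        self.T_on = _check_stochastic(self.T_on, "T_on")
        if self.T_off.shape[0] != self.n_states or self.T_on.shape[0] != self.n_states:
            raise ValueError("transition matrices must be n_states x n_states")
        if len(self.state_spectra) != self.n_states:
            raise ValueError("state_spectra must have one entry per state")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.delta > 0 and self.context_map is None:
            raise ValueError("delta > 0 requires a context_map")
        if self.context_map is not None:
            cm = np.asarray(self.context_map, dtype=int)
            if cm.shape != (self.n_states,) or cm.min() < 0 or cm.max() >= self.n_states:
                raise ValueError("context_map must map each state to a valid state")
            self.context_map = cm
            if self.evoked_base is None:
                self.evoked_base = np.full(self.n_states, 1.0 / self.n_states)
            else:
                eb = np.asarray(self.evoked_base, dtype=float)
                if eb.shape != (self.n_states,) or np.any(eb < 0) or \
                        abs(eb.sum() - 1.0) > 1e-9:
                    raise ValueError("evoked_base must be a distribution over states")
                self.evoked_base = eb

    def validate_frequencies(self, fps: float) -> None:
        for s, triples in enumerate(self.state_spectra):
            for (_, freq, _) in triples:
                if freq >= fps / 2:
                    raise ValueError(
                        f"state {s} drives {freq} Hz, at or above the Nyquist "
                        f"frequency of our system ({fps / 2} Hz)"
                    )


@dataclass
class GroundTruth:
    """Per-fly latent truth emitted by the simulator."""

    state_sequence: np.ndarray  # (n_frames,) int
    evoked_state_by_context: np.ndarray | None  # pre-state -> evoked state
    role: str = "experimental"  # experimental | control
    pre_onset_states: np.ndarray | None = None  # state at the frame before each onset
    evoked_targets: np.ndarray | None = None    # per-cycle drawn target (-1 if none)


# ---------------------------------------------------------------------------
# default study configurations
# ---------------------------------------------------------------------------

#: Per-state drive frequencies (Hz), chosen well separated on the dyadic
#: 1-50 Hz channel grid and below Nyquist at 100 fps.
_STATE_FREQS = (2.0, 4.8, 10.0, 21.0, 40.0)


def _default_spectra(n_states: int, n_modes: int) -> list:
    spectra = []
    for s in range(n_states):
        f = _STATE_FREQS[s % len(_STATE_FREQS)]
        m0 = (2 * s) % n_modes
        m1 = (2 * s + 1) % n_modes
        spectra.append([(m0, f, 1.0), (m1, f / 1.7, 0.6)])
    return spectra


def _sticky_matrix(n_states: int, p_stay: float) -> np.ndarray:
    T = np.full((n_states, n_states), (1 - p_stay) / (n_states - 1))
    np.fill_diagonal(T, p_stay)
    return T


def _activated_matrix(n_states: int, target: int, p_jump: float = 0.08,
                      p_stay_target: float = 0.997) -> np.ndarray:
    """LED-on matrix: quick transition into ``target``, then dwell there."""
    T = np.zeros((n_states, n_states))
    for s in range(n_states):
        if s == target:
            T[s, s] = p_stay_target
            others = [j for j in range(n_states) if j != s]
            T[s, others] = (1 - p_stay_target) / len(others)
        else:
            T[s, target] = p_jump
            T[s, s] = 1 - p_jump
    return T


def null_config(n_states: int = 5, n_modes: int = 10,
                noise_sd: float = 0.05, p_stay: float = 0.99) -> SyntheticConfig:
    """LED has no effect: T_on equals T_off (control-like line)."""
    T = _sticky_matrix(n_states, p_stay)
    return SyntheticConfig(n_states, n_modes, _default_spectra(n_states, n_modes),
                           T_off=T, T_on=T.copy(), noise_sd=noise_sd)


def activated_config(target_state: int = 3, n_states: int = 5, n_modes: int = 10,
                     noise_sd: float = 0.05, p_stay: float = 0.99) -> SyntheticConfig:
    """Strong-effect line: the LED drives the chain into ``target_state``."""
    T_off = _sticky_matrix(n_states, p_stay)
    T_on = _activated_matrix(n_states, target_state)
    return SyntheticConfig(n_states, n_modes, _default_spectra(n_states, n_modes),
                           T_off=T_off, T_on=T_on, noise_sd=noise_sd)


def chained_config(first: int = 1, second: int = 3, n_states: int = 5,
                   n_modes: int = 10, noise_sd: float = 0.05,
                   p_stay: float = 0.99, dwell_s: float = 3.0,
                   fps: float = 100.0) -> SyntheticConfig:
    """Sequenced line: LED drives state ``first``, which flows into ``second``.

    Emulates run-then-freeze phenotypes: region ``first`` occupancy peaks
    early in the stimulation window, region ``second`` later.
    """
    T_off = _sticky_matrix(n_states, p_stay)
    T_on = np.zeros((n_states, n_states))
    p_leave_first = 1.0 / (dwell_s * fps)  # mean dwell in `first` before chaining
    for s in range(n_states):
        if s == first:
            T_on[s, s] = 1 - p_leave_first
            T_on[s, second] = p_leave_first
        elif s == second:
            T_on[s, s] = 0.999
            T_on[s, first] = 0.001
        else:
            T_on[s, first] = 0.1
            T_on[s, s] = 0.9
    return SyntheticConfig(n_states, n_modes, _default_spectra(n_states, n_modes),
                           T_off=T_off, T_on=T_on, noise_sd=noise_sd)


def context_config(delta: float, context_map: np.ndarray | None = None,
                   n_states: int = 5, n_modes: int = 10,
                   noise_sd: float = 0.05, p_stay: float = 0.99) -> SyntheticConfig:
    """Context-dependent line: evoked state depends on the pre-onset state.

    At each onset the evoked target is the context map of the pre-onset
    state with probability ``delta`` and an independent uniform draw
    otherwise, so ``delta`` injects a controlled amount of mutual
    information: zero at ``delta = 0``, the full pre-state entropy at
    ``delta = 1`` with a permutation context map. The LED-off chain is only
    moderately sticky (1 s mean dwell) so the controls' pre/post behavior
    decorrelates over the stimulation gap.
    """
    if context_map is None:
        context_map = (np.arange(n_states) + 1) % n_states  # cyclic permutation
    T_off = _sticky_matrix(n_states, p_stay)
    T_on = _sticky_matrix(n_states, 0.998)  # unused while a target is held
    return SyntheticConfig(n_states, n_modes, _default_spectra(n_states, n_modes),
                           T_off=T_off, T_on=T_on, context_map=context_map,
                           delta=delta, noise_sd=noise_sd)


def control_of(config: SyntheticConfig) -> SyntheticConfig:
    """Control arm of a line: the LED has no effect (T_on = T_off, delta 0)."""
    return replace(config, T_on=config.T_off.copy(), delta=0.0, context_map=None)


# ---------------------------------------------------------------------------
# state simulation
# ---------------------------------------------------------------------------

def simulate_states(config: SyntheticConfig, schedule: StimulusSchedule,
                    seed: int, role: str = "experimental") -> GroundTruth:
    """Simulate the latent Markov chain for one fly.

    Uses ``T_off`` during LED-off frames and ``T_on`` (or, for context
    lines, the per-trial delta-mixed evoked target) during LED-on frames;
    see ``_simulate_chains`` for the exact construction. Control flies
    ignore the LED entirely.
    """
    states, targets = _simulate_chains(config, schedule,
                                       np.random.default_rng(seed),
                                       n_chains=1, roles=[role])
    return GroundTruth(
        state_sequence=states[0],
        evoked_state_by_context=None if config.context_map is None else config.context_map.copy(),
        role=role,
        pre_onset_states=states[0, np.maximum(schedule.onset_frames - 1, 0)],
        evoked_targets=targets[0],
    )


def _simulate_chains(config: SyntheticConfig, schedule: StimulusSchedule,
                     rng: np.random.Generator, n_chains: int,
                     roles: list[str]):
    """Vectorized frame-resolution simulation of several flies at once.

    Lines without a context map follow ``T_off`` during LED-off frames and
    ``T_on`` during LED-on frames. Context lines instead draw a per-trial
    evoked target at each onset — the context map of the pre-stimulus state
    (read ``context_anchor_s`` seconds before the onset, i.e. at the start
    of the analysis pre-window) with probability delta, a draw from
    ``evoked_base`` otherwise — and hold it for the stimulation window, so
    delta interpolates between a context-independent (delta = 0) and a
    deterministic pre-state-conditioned (delta = 1) evoked response.
    Control flies ignore the LED entirely.

    Returns ``(states, targets)`` with targets shape (n_chains, n_cycles),
    -1 where no target draw applies.
    """
    S = config.n_states
    T = schedule.n_frames
    led = schedule.led_mask()
    onset_set = set(int(o) for o in schedule.onset_frames)
    onset_index = {int(o): n for n, o in enumerate(schedule.onset_frames)}
    is_context = config.context_map is not None

    cum_off = np.cumsum(config.T_off, axis=1)
    cum_on = np.cumsum(config.T_on, axis=1)
    cum_base = (np.cumsum(config.evoked_base) if is_context else None)
    is_ctrl = np.array([r == "control" for r in roles])

    mu_off = stationary_distribution(config.T_off)
    states = np.empty((n_chains, T), dtype=np.int16)
    s = rng.choice(S, size=n_chains, p=mu_off).astype(np.int16)
    states[:, 0] = s
    targets = np.full((n_chains, schedule.n_cycles), -1, dtype=np.int16)

    anchor_frames = int(round(config.context_anchor_s * schedule.fps))
    current_target = np.full(n_chains, -1, dtype=np.int16)
    u_all = rng.random((T - 1, n_chains))
    u_draw = rng.random((schedule.n_cycles, n_chains))
    u_base = rng.random((schedule.n_cycles, n_chains))
    for t in range(1, T):
        # an onset at frame 0 has no pre-stimulus history; anchor at frame 0
        at_onset = t in onset_set or (t == 1 and 0 in onset_set)
        if at_onset and is_context:
            n = onset_index[t if t in onset_set else 0]
            onset = t if t in onset_set else 0
            s_pre = states[:, max(onset - anchor_frames, 0)]
            ctx = config.context_map[s_pre]
            base = (cum_base < u_base[n][:, None]).sum(axis=1).astype(np.int16)
            current_target = np.where(u_draw[n] < config.delta, ctx, base)
            targets[:, n] = np.where(is_ctrl, -1, current_target)
        if led[t]:
            if is_context:
                s = np.where(is_ctrl,
                             (cum_off[s] < u_all[t - 1][:, None]).sum(axis=1),
                             current_target).astype(np.int16)
            else:
                rows = np.where(is_ctrl[:, None], cum_off[s], cum_on[s])
                s = (rows < u_all[t - 1][:, None]).sum(axis=1).astype(np.int16)
        else:
            s = (cum_off[s] < u_all[t - 1][:, None]).sum(axis=1).astype(np.int16)
        states[:, t] = s
    return states, targets


def simulate_session(config: SyntheticConfig, schedule: StimulusSchedule,
                     seed: int, n_experimental: int = 6,
                     n_control: int = 6) -> list[GroundTruth]:
    """Simulate a 12-fly session (default 6 experimental + 6 control).

    Control flies run the same chain with the LED having no effect.
    """
    roles = ["experimental"] * n_experimental + ["control"] * n_control
    rng = np.random.default_rng(seed)
    states, targets = _simulate_chains(config, schedule, rng, len(roles), roles)
    out = []
    for i, role in enumerate(roles):
        out.append(GroundTruth(
            state_sequence=states[i],
            evoked_state_by_context=None if config.context_map is None else config.context_map.copy(),
            role=role,
            pre_onset_states=states[i, np.maximum(schedule.onset_frames - 1, 0)],
            evoked_targets=targets[i],
        ))
    return out


# ---------------------------------------------------------------------------
# posture-mode synthesis
# ---------------------------------------------------------------------------

def synthesize_posture(ground_truth: GroundTruth, config: SyntheticConfig,
                       seed: int, fps: float = 100.0) -> np.ndarray:
    """Render the latent states as posture-mode time series.

    Within each bout (maximal run of a constant state) mode m carries
    ``sum_k a_k sin(2 pi f_k t / fps + phase_k)`` over the state's triples on
    that mode, with phases randomized per bout so wavelet amplitudes are
    stable within bouts, plus additive Gaussian noise.
    """
    config.validate_frequencies(fps)
    rng = np.random.default_rng(seed)
    states = ground_truth.state_sequence
    T = len(states)
    modes = np.zeros((T, config.n_modes))

    changes = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], changes))
    stops = np.concatenate((changes, [T]))
    for t0, t1 in zip(starts, stops):
        s = int(states[t0])
        t = np.arange(t0, t1)
        for (m, f, a) in config.state_spectra[s]:
            phase = rng.uniform(0, 2 * np.pi)
            modes[t0:t1, m] += a * np.sin(2 * np.pi * f * t / fps + phase)
    if config.noise_sd > 0:
        modes += rng.normal(0, config.noise_sd, size=modes.shape)
    return modes


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedMovie:
    frames: np.ndarray       # (T, H, W) uint8
    valid: np.ndarray        # (T,) bool, False where the fly left the frame
    centroids: np.ndarray    # (T, 2) float (x, y)
    angles: np.ndarray       # (T,) degrees, global body orientation
    led_log: np.ndarray      # (n_rows, 2) int: frame index, LED state
    fps: float


def render_movie(ground_truth: GroundTruth, config: SyntheticConfig, seed: int,
                 size: int = 96, fps: float = 100.0, n_frames: int | None = None,
                 schedule: StimulusSchedule | None = None,
                 rotation_step_sd: float = 0.0, translation_step_sd: float = 0.0,
                 log_every: int = 2) -> RenderedMovie:
    """Draw a cartoon fly (ellipse body + oscillating appendage blobs).

    Appendage angles follow the synthetic posture-mode series; a global
    rotation/translation random walk emulates the animal wandering. Frames
    where the fly would leave the image are flagged invalid rather than
    raising. The LED log is emitted in the io_cli text dialect (one row
    every ``log_every`` frames, mirroring the acquisition software that
    sampled the light tables every 2-3 frames).
    """
    if size < 64:
        raise ValueError("image size must be at least 64 x 64")
    modes = synthesize_posture(ground_truth, config, seed, fps=fps)
    T = len(modes) if n_frames is None else min(n_frames, len(modes))
    rng = np.random.default_rng(seed + 1)

    body_a, body_b = size * 0.18, size * 0.075   # body semi-axes (long axis vertical)
    leg_r = max(2, int(size * 0.035))
    leg_dist = size * 0.26

    angles = np.cumsum(rng.normal(0, rotation_step_sd, size=T))
    steps = rng.normal(0, translation_step_sd, size=(T, 2))
    centroids = size / 2 + np.cumsum(steps, axis=0)

    frames = np.zeros((T, size, size), dtype=np.uint8)
    valid = np.ones(T, dtype=bool)
    margin = leg_dist + leg_r + 2
    for t in range(T):
        cx, cy = centroids[t]
        if not (margin <= cx <= size - margin and margin <= cy <= size - margin):
            valid[t] = False
            continue
        theta = np.deg2rad(angles[t])
        img = frames[t]
        rr, cc = _draw_ellipse(cy, cx, body_a, body_b, shape=img.shape,
                               rotation=theta)
        img[rr, cc] = 200
        # head blob marks the anterior end (head-up at zero rotation)
        hy = cy - (body_a * 0.9) * np.cos(theta)
        hx = cx - (body_a * 0.9) * np.sin(theta)
        rr, cc = _draw_disk((hy, hx), max(2, int(size * 0.05)), shape=img.shape)
        img[rr, cc] = 200
        # appendages: angle oscillates with the first few posture modes
        n_app = min(4, config.n_modes)
        for k in range(n_app):
            base = (-60 - 25 * k) if k % 2 == 0 else (60 + 25 * (k - 1))
            wob = 25.0 * np.tanh(modes[t, k])
            phi = np.deg2rad(base + wob) + theta
            ly = cy - leg_dist * np.cos(phi)
            lx = cx - leg_dist * np.sin(phi)
            rr, cc = _draw_disk((ly, lx), leg_r, shape=img.shape)
            img[rr, cc] = 80
    led = (schedule.led_mask()[:T].astype(int) if schedule is not None
           else np.zeros(T, dtype=int))
    rows = np.arange(0, T, log_every)
    led_log = np.column_stack([rows, led[rows]])
    return RenderedMovie(frames=frames, valid=valid, centroids=centroids,
                         angles=angles, led_log=led_log, fps=fps)


# ---------------------------------------------------------------------------
# exact-enumeration oracles over the known chain
# ---------------------------------------------------------------------------

def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (leading left eigenvector)."""
    vals, vecs = np.linalg.eig(T.T)
    i = np.argmin(np.abs(vals - 1.0))
    mu = np.real(vecs[:, i])
    mu = np.abs(mu)
    return mu / mu.sum()


def evoked_distribution(config: SyntheticConfig, pre_state: int,
                        horizon_frames: int = 100) -> np.ndarray:
    """Distribution of the evoked state given the pre-onset state.

    Context lines: the trial-level target draw, ``delta`` on the context
    map of the pre-state and ``1 - delta`` on the base distribution. Other
    lines: the LED-on chain propagated for ``horizon_frames``.
    """
    S = config.n_states
    if config.context_map is not None:
        v = (1 - config.delta) * config.evoked_base.copy()
        v[config.context_map[pre_state]] += config.delta
        return v
    e = np.zeros(S)
    e[pre_state] = 1.0
    return e @ np.linalg.matrix_power(config.T_on, horizon_frames)


def exact_state_mi(config: SyntheticConfig, horizon_frames: int = 100) -> float:
    """MI (bits) between the pre-onset state and the evoked state.

    Computed by exact enumeration over the known chain: pre-onset state
    drawn from the LED-off stationary distribution, evoked state from
    ``evoked_distribution``.
    """
    mu = stationary_distribution(config.T_off)
    joint = np.stack([mu[s] * evoked_distribution(config, s, horizon_frames)
                      for s in range(config.n_states)])
    return _mi_of_joint(joint)


def _mi_of_joint(joint: np.ndarray) -> float:
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def analytic_context_mi(config: SyntheticConfig, schedule: StimulusSchedule,
                        pre_window: tuple[float, float] = (-1.5, -0.5),
                        label_of_state: np.ndarray | None = None) -> float:
    """Asymptotic MI between the pre-window density and the evoked label.

    Assumes each state occupies its own disjoint territory in the behavior
    map, in which case the within-territory density shape cancels from the
    MI integral and the exact value depends only on the window-averaged
    state-occupancy weights conditioned on the pre-onset state,

        w(s | s_pre) = mean_tau P(S_{onset-tau} = s | S_{onset-1} = s_pre),

    evaluated by transition-matrix powers under the stationary LED-off
    chain, combined with the trial-level evoked-label distribution
    ``p(label | s_pre)`` implied by delta, the context map and the base
    evoked distribution. ``label_of_state`` maps each state to its region
    label (default: identity — one region per state).
    """
    if config.context_map is None:
        raise ValueError("the analytic window-MI oracle requires a context line")
    S = config.n_states
    fps = schedule.fps
    mu = stationary_distribution(config.T_off)
    if label_of_state is None:
        label_of_state = np.arange(S)
    labels = np.asarray(label_of_state)

    f0 = int(round(-pre_window[1] * fps))   # nearest window frame before onset
    f1 = int(round(-pre_window[0] * fps))
    A = int(round(config.context_anchor_s * fps))
    if A < f1:
        raise ValueError("context anchor must lie at or before the pre-window start")
    # window frames are onset-f1 ... onset-f0-1; offsets forward from the
    # anchor frame (onset-A) are therefore A-f1 ... A-f0-1
    taus = np.arange(A - f1, A - f0)

    W = np.zeros((S, S))  # W[s_pre, s] = window occupancy weight
    P = np.linalg.matrix_power(config.T_off, int(taus[0])) if taus[0] else np.eye(S)
    step = int(taus[0])
    for tau in taus:
        while step < tau:
            P = P @ config.T_off
            step += 1
        W += P
    W /= len(taus)

    # p(label | s_pre) from the trial-level target draw
    uniq = np.unique(labels)
    joint = np.zeros((len(uniq), S))  # (label, territory-state)
    for s_pre in range(S):
        p_label = np.zeros(len(uniq))
        for s_ev in range(S):
            k = int(np.searchsorted(uniq, labels[s_ev]))
            p = (1 - config.delta) * config.evoked_base[s_ev]
            if config.context_map[s_pre] == s_ev:
                p += config.delta
            p_label[k] += p
        joint += mu[s_pre] * p_label[:, None] * W[s_pre][None, :]
    return _mi_of_joint(joint)
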