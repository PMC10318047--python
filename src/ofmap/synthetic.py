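"""Synthetic observational-fear sessions with planted ground truth.

Every downstream stage of the pipeline (behavior mapping, sequence
statistics, calcium-event processing, neuron annotation, decoding) is tested
against sessions generated here, because the real recordings are not
redistributable.  The generator plants and records:

* a latent behavioral mode sequence (first-order Markov chain on the 2-s
  grid, with higher self-transition probability during conditioning),
* a 13-point pose track rendered from per-mode anchors and motion scales,
* a freezing trace derived deterministically from 2-s motion energy, with a
  mobility boost in the shock phase so freezing dips at shock timing,
* calcium dF/F traces from Poisson events convolved with an exponential
  kernel, with cells assigned to tuning classes (shock-activated /
  shock-suppressed / freezing-positive / freezing-negative /
  cluster-specific / background).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical seeds give identical
sessions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .session import CHUNK_S, SessionLayout, ShockSchedule, make_shock_schedule
from .tracking import BODY_POINTS, FreezingTrace, PoseTrack, write_pose_table

log = logging.getLogger(__name__)

CELL_CLASSES = (
    "shock_activated",
    "shock_suppressed",
    "freezing_pos",
    "freezing_neg",
    "cluster_specific",
    "background",
)


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Latent behavioral-mode generator settings.

    Modes live on the 2-s grid; 10-s bout structure emerges by composition.
    ``mode_anchors`` are (x, y) arena positions (px); ``mode_motion_px`` the
    per-frame random-walk scale of each mode.  Defaults plant eight modes —
    two high-mobility "locomotion" modes and six low-mobility "place" modes —
    with self-transition probability rising from 0.5 (habituation) to 0.9
    (conditioning), and a 3x mobility boost during the 2-s shock phase so
    that freezing is anti-phase-locked to shock onsets.
    """

    n_modes: int = 8
    persistence_hab: float = 0.5
    persistence_cond: float = 0.9
    mode_anchors: tuple[tuple[float, float], ...] | None = None
    mode_motion_px: tuple[float, ...] | None = None
    shock_phase_mobility_boost: float = 3.0
    shock_response_latency_s: float = 0.0
    jitter_px: float = 1.5
    freezing_motion_scale_px: float = 1.0

    def __post_init__(self) -> None:
        if self.n_modes < 2:
            raise ValueError("need at least 2 behavioral modes")
        for p in (self.persistence_hab, self.persistence_cond):
            if not 0.0 <= p <= 1.0:
                raise ValueError("persistence probabilities must lie in [0, 1]")
        if self.mode_anchors is not None and len(self.mode_anchors) != self.n_modes:
            raise ValueError("mode_anchors length must equal n_modes")
        if self.mode_motion_px is not None and len(self.mode_motion_px) != self.n_modes:
            raise ValueError("mode_motion_px length must equal n_modes")

    def anchors(self, layout: SessionLayout) -> np.ndarray:
        if self.mode_anchors is not None:
            return np.asarray(self.mode_anchors, dtype=float)
        # spread anchors over a grid covering the arena interior
        w, h = layout.arena_w_px, layout.arena_h_px
        n_cols = int(np.ceil(np.sqrt(self.n_modes)))
        n_rows = int(np.ceil(self.n_modes / n_cols))
        xs = np.linspace(0.15 * w, 0.85 * w, n_cols)
        ys = np.linspace(0.25 * h, 0.75 * h, n_rows)
        grid = [(x, y) for y in ys for x in xs]
        return np.asarray(grid[: self.n_modes], dtype=float)

    def motion_scales(self) -> np.ndarray:
        if self.mode_motion_px is not None:
            return np.asarray(self.mode_motion_px, dtype=float)
        # first two modes locomote, the rest are near-stationary
        scales = np.full(self.n_modes, 0.5)
        scales[: min(2, self.n_modes)] = 4.0
        return scales


@dataclass(frozen=True)
class CellGenConfig:
    """Calcium-trace generator settings.

    ``fractions`` assign disjoint tuning classes; the remainder is
    background.  Rates are multiplicatively modulated by the class covariate
    (shock phase, freezing rate, or occupancy of a target latent mode) with
    factor ``modulation_depth``.
    """

    n_cells: int = 100
    fractions: dict = field(
        default_factory=lambda: {
            "shock_activated": 0.10,
            "shock_suppressed": 0.10,
            "freezing_pos": 0.10,
            "freezing_neg": 0.10,
            "cluster_specific": 0.10,
        }
    )
    base_event_rate: float = 0.2  # events / s
    modulation_depth: float = 5.0
    kernel_decay_s: float = 1.0
    noise_sd: float = 0.05
    fov_px: float = 300.0
    clustered_classes: tuple[str, ...] = ()  # classes with spatially contiguous centroids

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        bad = set(self.fractions) - set(CELL_CLASSES)
        if bad:
            raise ValueError(f"unknown cell classes: {sorted(bad)}")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        if self.base_event_rate < 0:
            raise ValueError("base_event_rate must be >= 0")


@dataclass
class SyntheticSession:
    """A complete generated session plus its ground truth."""

    pose: PoseTrack
    freezing: FreezingTrace
    calcium: np.ndarray  # (cells, imaging frames) dF/F
    centroids: np.ndarray  # (cells, 2)
    schedule: ShockSchedule
    layout: SessionLayout
    truth_modes: np.ndarray  # latent mode per 2-s chunk
    truth_cell_class: np.ndarray  # per-cell class label (str)
    truth_cell_mode: np.ndarray  # target mode for cluster_specific cells (-1 otherwise)
    truth_event_frames: list  # per-cell planted event frame indices


# ---------------------------------------------------------------------------
# Latent behavior


def simulate_state_sequence(
    cfg: BehaviorGenConfig, layout: SessionLayout, rng: np.random.Generator
) -> np.ndarray:
    """First-order Markov latent mode sequence, one mode per 2-s chunk.

    The self-transition probability switches from ``persistence_hab`` to
    ``persistence_cond`` at the habituation/conditioning boundary; off-
    diagonal mass is uniform over the other modes.
    """
    K = cfg.n_modes
    n = layout.n_chunks
    n_hab = layout.n_habituation_chunks
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.integers(K)
    u = rng.random(n - 1)
    jumps = rng.integers(0, K - 1, size=n - 1)
    for t in range(1, n):
        p_stay = cfg.persistence_hab if t < n_hab else cfg.persistence_cond
        if u[t - 1] < p_stay:
            states[t] = states[t - 1]
        else:
            j = jumps[t - 1]
            states[t] = j if j < states[t - 1] else j + 1
    return states


def render_pose_track(
    states: np.ndarray,
    cfg: BehaviorGenConfig,
    layout: SessionLayout,
    rng: np.random.Generator,
    schedule: ShockSchedule | None = None,
) -> PoseTrack:
    """Render a 13-point pose track from a latent mode sequence.

    A rigid skeleton template is anchored at a body position that performs a
    mean-reverting random walk toward the active mode's anchor, with step
    scale = the mode's motion scale (boosted by
    ``shock_phase_mobility_boost`` during the 2-s shock phase).  Gaussian
    jitter is added per point per frame; coordinates are clipped to the
    arena; likelihoods are 1.
    """
    fpc = int(round(CHUNK_S * layout.behavior_hz))
    n_frames = layout.n_behavior_frames
    if states.size * fpc != n_frames:
        raise ValueError("state sequence length inconsistent with layout")

    anchors = cfg.anchors(layout)
    scales = cfg.motion_scales()

    shock_chunk = np.zeros(states.size, dtype=bool)
    if schedule is not None and schedule.indicator_2s.size:
        n_hab = layout.n_habituation_chunks
        lag = int(round(cfg.shock_response_latency_s / CHUNK_S))
        idx = np.flatnonzero(schedule.indicator_2s) + n_hab + lag
        idx = idx[idx < states.size]
        shock_chunk[idx] = True

    # template offsets (px) for a mouse facing +x: head cluster forward,
    # trunk at origin, tail behind and slightly lower in the image (larger y
    # is lower; back center kept above tail root per camera geometry)
    template = np.array(
        [
            (14.0, 0.0),   # nose
            (9.0, 3.5),    # right ear
            (9.0, -3.5),   # left ear
            (11.0, 2.0),   # right eye
            (11.0, -2.0),  # left eye
            (10.0, 0.0),   # head top
            (5.0, 4.0),    # right hand
            (5.0, -4.0),   # left hand
            (0.0, 0.0),    # back center
            (-4.0, 4.5),   # right foot
            (-4.0, -4.5),  # left foot
            (-8.0, 0.0),   # tail root
            (-16.0, 0.0),  # tail tip
        ]
    )
    assert template.shape[0] == len(BODY_POINTS)

    pos = np.empty((n_frames, 2))
    p = anchors[states[0]].astype(float).copy()
    steps = rng.standard_normal((n_frames, 2))
    for f in range(n_frames):
        c = f // fpc
        m = states[c]
        scale = scales[m] * (cfg.shock_phase_mobility_boost if shock_chunk[c] else 1.0)
        p = p + 0.08 * (anchors[m] - p) + scale * steps[f]
        p[0] = np.clip(p[0], 20.0, layout.arena_w_px - 20.0)
        p[1] = np.clip(p[1], 20.0, layout.arena_h_px - 20.0)
        pos[f] = p

    coords = pos[:, None, :] + template[None, :, :]
    coords += cfg.jitter_px * rng.standard_normal(coords.shape)
    coords[:, :, 0] = np.clip(coords[:, :, 0], 0.0, layout.arena_w_px)
    coords[:, :, 1] = np.clip(coords[:, :, 1], 0.0, layout.arena_h_px)
    lik = np.ones((n_frames, len(BODY_POINTS)))
    return PoseTrack(coords=coords, likelihood=lik, frame_rate_hz=layout.behavior_hz)


def freezing_from_motion(
    pose: PoseTrack, cfg: BehaviorGenConfig, layout: SessionLayout
) -> FreezingTrace:
    """Deterministic monotone map from 2-s back-center motion energy to a
    freezing rate: freezing = exp(-motion / scale), so more motion means
    strictly less freezing.  The back-center path is boxcar-smoothed over 5
    frames first so that tracking jitter does not swamp true locomotion."""
    from scipy.ndimage import uniform_filter1d

    fpc = int(round(CHUNK_S * layout.behavior_hz))
    n_chunks = pose.n_frames // fpc
    x = pose.coords[: n_chunks * fpc, 8, :]  # back center
    x = uniform_filter1d(x, size=5, axis=0, mode="nearest")
    disp = np.linalg.norm(np.diff(x, axis=0, prepend=x[:1]), axis=1)
    motion = disp.reshape(n_chunks, fpc).mean(axis=1)
    values = np.exp(-motion / cfg.freezing_motion_scale_px)
    return FreezingTrace(values=values, source="motion_proxy")


# ---------------------------------------------------------------------------
# Calcium


def _class_covariate(
    cls: str,
    target_mode: int,
    states: np.ndarray,
    freezing: np.ndarray,
    shock_chunk: np.ndarray,
) -> np.ndarray:
    """Per-2-s-chunk drive in [0, 1] for a tuning class."""
    if cls == "shock_activated":
        return shock_chunk.astype(float)
    if cls == "shock_suppressed":
        return shock_chunk.astype(float)  # suppressive sign applied by caller
    if cls == "freezing_pos":
        return freezing
    if cls == "freezing_neg":
        return 1.0 - freezing
    if cls == "cluster_specific":
        return (states == target_mode).astype(float)
    return np.zeros_like(freezing)


def simulate_calcium(
    states: np.ndarray,
    freezing: FreezingTrace,
    schedule: ShockSchedule,
    cellcfg: CellGenConfig,
    layout: SessionLayout,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list]:
    """Simulate dF/F traces for a population with planted tuning classes.

    Per cell: an inhomogeneous Poisson event train at ``base_event_rate``,
    multiplied by ``modulation_depth`` when the class covariate is active
    (divided by it for suppressive classes), convolved with an exponential
    kernel of decay ``kernel_decay_s`` and summed with Gaussian noise.

    Returns (dff, centroids, class labels, target modes, event frame lists).
    """
    n_cells = cellcfg.n_cells
    n_frames = layout.n_imaging_frames
    fpc = int(round(CHUNK_S * layout.imaging_hz))
    n_chunks = layout.n_chunks
    if states.size != n_chunks or len(freezing) != n_chunks:
        raise ValueError("covariate lengths inconsistent with layout")

    # class assignment
    labels = []
    for cls, frac in cellcfg.fractions.items():
        labels += [cls] * int(round(frac * n_cells))
    labels += ["background"] * (n_cells - len(labels))
    labels = np.array(labels[:n_cells], dtype=object)

    shock_chunk = np.zeros(n_chunks, dtype=bool)
    n_hab = layout.n_habituation_chunks
    shock_chunk[n_hab:] = schedule.indicator_2s.astype(bool)

    target_modes = np.full(n_cells, -1, dtype=np.int64)
    n_modes = int(states.max()) + 1 if states.size else 1
    for i in np.flatnonzero(labels == "cluster_specific"):
        target_modes[i] = rng.integers(n_modes)

    # centroids
    centroids = rng.uniform(0.0, cellcfg.fov_px, size=(n_cells, 2))
    for cls in cellcfg.clustered_classes:
        members = np.flatnonzero(labels == cls)
        if members.size:
            center = rng.uniform(0.25 * cellcfg.fov_px, 0.75 * cellcfg.fov_px, size=2)
            centroids[members] = center + rng.normal(
                0.0, 0.04 * cellcfg.fov_px, size=(members.size, 2)
            )

    dff = np.zeros((n_cells, n_frames))
    if n_cells == 0:
        return dff, centroids, labels, target_modes, []

    t_kernel = np.arange(0, int(np.ceil(5 * cellcfg.kernel_decay_s * layout.imaging_hz)) + 1)
    kernel = np.exp(-t_kernel / (cellcfg.kernel_decay_s * layout.imaging_hz))

    base_p = cellcfg.base_event_rate / layout.imaging_hz  # per-frame event prob
    depth = cellcfg.modulation_depth
    event_frames: list = []
    n_clipped = 0
    for i in range(n_cells):
        cov = _class_covariate(labels[i], target_modes[i], states, freezing.values, shock_chunk)
        if labels[i] == "shock_suppressed":
            gain = 1.0 + (1.0 / depth - 1.0) * cov
        else:
            gain = 1.0 + (depth - 1.0) * cov
        p = base_p * np.repeat(gain, fpc)[:n_frames]
        neg = p < 0
        if neg.any():
            n_clipped += int(neg.sum())
            p = np.clip(p, 0.0, None)
        ev = np.flatnonzero(rng.random(n_frames) < p)
        event_frames.append(ev)
        if ev.size:
            train = np.zeros(n_frames)
            amps = 1.0 + 0.2 * rng.standard_normal(ev.size)
            train[ev] = np.abs(amps)
            dff[i] = np.convolve(train, kernel)[:n_frames]
    if n_clipped:
        log.warning("clipped %d negative per-frame rates to 0", n_clipped)
    if cellcfg.noise_sd > 0:
        dff += cellcfg.noise_sd * rng.standard_normal(dff.shape)
    return dff, centroids, labels, target_modes, event_frames


# ---------------------------------------------------------------------------
# Bundling


def generate_session(
    layout: SessionLayout | None = None,
    cfg: BehaviorGenConfig | None = None,
    cellcfg: CellGenConfig | None = None,
    seed: int = 0,
) -> SyntheticSession:
    """Generate a full synthetic OF session; identical seeds give identical
    sessions."""
    layout = layout or SessionLayout()
    cfg = cfg or BehaviorGenConfig()
    cellcfg = cellcfg or CellGenConfig()

    ss = np.random.SeedSequence(seed)
    rng_beh, rng_pose, rng_cal = (np.random.default_rng(s) for s in ss.spawn(3))

    schedule = make_shock_schedule(layout)
    states = simulate_state_sequence(cfg, layout, rng_beh)
    pose = render_pose_track(states, cfg, layout, rng_pose, schedule=schedule)
    freezing = freezing_from_motion(pose, cfg, layout)
    dff, centroids, labels, target_modes, event_frames = simulate_calcium(
        states, freezing, schedule, cellcfg, layout, rng_cal
    )
    return SyntheticSession(
        pose=pose,
        freezing=freezing,
        calcium=dff,
        centroids=centroids,
        schedule=schedule,
        layout=layout,
        truth_modes=states,
        truth_cell_class=labels,
        truth_cell_mode=target_modes,
        truth_event_frames=event_frames,
    )


def write_session(session: SyntheticSession, out_dir: str | Path) -> dict:
    """Write a session to disk: pose as DeepLabCut-layout CSV, calcium +
    centroids as HDF5, freezing / schedule / truth as JSON.  Returns a
    manifest of written paths."""
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pose_path = out / "pose.csv"
    write_pose_table(session.pose, pose_path)

    cal_path = out / "calcium.h5"
    with h5py.File(cal_path, "w") as f:
        f.create_dataset("dff", data=session.calcium)
        f.create_dataset("centroids", data=session.centroids)
        f.attrs["imaging_hz"] = session.layout.imaging_hz

    freezing_path = out / "freezing.txt"
    np.savetxt(freezing_path, session.freezing.values)

    meta_path = out / "session.json"
    meta = {
        "layout": {
            "habituation_s": session.layout.habituation_s,
            "conditioning_s": session.layout.conditioning_s,
            "shock_on_s": session.layout.shock_on_s,
            "shock_period_s": session.layout.shock_period_s,
            "behavior_hz": session.layout.behavior_hz,
            "imaging_hz": session.layout.imaging_hz,
            "arena_w_px": session.layout.arena_w_px,
            "arena_h_px": session.layout.arena_h_px,
            "demonstrator_side": session.layout.demonstrator_side,
        },
        "schedule": {
            "onsets": session.schedule.onsets.tolist(),
            "indicator_2s": session.schedule.indicator_2s.tolist(),
        },
        "truth": {
            "modes": session.truth_modes.tolist(),
            "cell_class": list(session.truth_cell_class),
            "cell_mode": session.truth_cell_mode.tolist(),
        },
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return {
        "pose": str(pose_path),
        "calcium": str(cal_path),
        "freezing": str(freezing_path),
        "meta": str(meta_path),
    }
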