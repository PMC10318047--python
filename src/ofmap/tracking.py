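"""Pose-track I/O and post-processing.

Consumes markerless-tracking exports (DeepLabCut table layout: a 3-row header
of scorer / bodyparts / coords with x, y, likelihood columns per body point)
for the 13-point mouse skeleton, applies the standard post-processing chain
(median filter, likelihood-gated linear interpolation, tail-root geometric
restriction), and derives per-bout speed and a motion-energy freezing proxy.

Coordinate convention: video pixels, origin top-left, y increasing downward,
0-based frames.  "Above" in the arena therefore means smaller y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .session import CHUNK_S

log = logging.getLogger(__name__)

#: Canonical 13 body points, in storage order.
BODY_POINTS: tuple[str, ...] = (
    "nose",
    "right ear",
    "left ear",
    "right eye",
    "left eye",
    "head top",
    "right hand",
    "left hand",
    "back center",
    "right foot",
    "left foot",
    "tail root",
    "tail tip",
)

BACK_CENTER = BODY_POINTS.index("back center")
TAIL_ROOT = BODY_POINTS.index("tail root")


@dataclass
class PoseTrack:
    """Per-frame coordinates and likelihoods for the 13 body points.

    coords: (frames, 13, 2) float array of (x, y) pixels.
    likelihood: (frames, 13) in [0, 1].
    """

    coords: np.ndarray
    likelihood: np.ndarray
    frame_rate_hz: float
    points: tuple[str, ...] = BODY_POINTS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.points), 2):
            raise ValueError(f"coords must be (frames, {len(self.points)}, 2)")
        if self.likelihood.shape != self.coords.shape[:2]:
            raise ValueError("likelihood shape must match coords frames x points")
        if self.coords.shape[0] == 0:
            raise ValueError("track has no frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class FreezingTrace:
    """Per-2-s-chunk freezing rate in [0, 1]."""

    values: np.ndarray
    source: str = "external"  # 'external' or 'motion_proxy'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("freezing trace must be 1-D")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("freezing rates must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# I/O


def write_pose_table(track: PoseTrack, path: str | Path, scorer: str = "ofmap") -> None:
    """Write a track in the DeepLabCut export layout (CSV or HDF5 by suffix)."""
    path = Path(path)
    cols = pd.MultiIndex.from_product(
        [[scorer], list(track.points), ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"],
    )
    n = track.n_frames
    data = np.empty((n, len(track.points) * 3))
    data[:, 0::3] = track.coords[:, :, 0]
    data[:, 1::3] = track.coords[:, :, 1]
    data[:, 2::3] = track.likelihood
    df = pd.DataFrame(data, columns=cols)
    if path.suffix in (".h5", ".hdf5"):
        df.to_hdf(path, key="df_with_missing", mode="w")
    else:
        df.to_csv(path)


def read_pose_table(
    path: str | Path,
    dialect: str | None = None,
    frame_rate_hz: float = 7.5,
) -> PoseTrack:
    """Read a pose table in DeepLabCut layout.

    ``dialect`` is 'csv' or 'h5'; inferred from the suffix when None.  The
    header must name all 13 expected body points (order-insensitive); extra
    points are ignored with a warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = "h5" if path.suffix in (".h5", ".hdf5") else "csv"
    if dialect == "h5":
        df = pd.read_hdf(path)
    elif dialect == "csv":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.columns.nlevels != 3:
        raise ValueError("malformed header: expected 3 levels (scorer/bodyparts/coords)")

    present = list(dict.fromkeys(df.columns.get_level_values(1)))
    missing = [p for p in BODY_POINTS if p not in present]
    if missing:
        raise ValueError(f"pose table is missing required body point(s): {missing}")
    extra = [p for p in present if p not in BODY_POINTS]
    if extra:
        log.warning("ignoring unknown body point(s): %s", extra)

    scorer = df.columns.get_level_values(0)[0]
    n = len(df)
    coords = np.empty((n, len(BODY_POINTS), 2))
    lik = np.empty((n, len(BODY_POINTS)))
    for i, p in enumerate(BODY_POINTS):
        coords[:, i, 0] = df[(scorer, p, "x")].to_numpy(dtype=float)
        coords[:, i, 1] = df[(scorer, p, "y")].to_numpy(dtype=float)
        lik[:, i] = df[(scorer, p, "likelihood")].to_numpy(dtype=float)
    log.info("read %d frames x %d points from %s", n, len(BODY_POINTS), path)
    return PoseTrack(coords=coords, likelihood=lik, frame_rate_hz=frame_rate_hz)


def read_freezing_trace(path: str | Path) -> FreezingTrace:
    """Read an externally computed freezing trace (single-column text or JSON)."""
    path = Path(path)
    if path.suffix == ".json":
        import json

        values = np.asarray(json.loads(path.read_text()), dtype=float)
    else:
        values = np.loadtxt(path, ndmin=1)
    log.info("read freezing trace of %d chunks from %s", values.size, path)
    return FreezingTrace(values=values, source="external")


# ---------------------------------------------------------------------------
# Post-processing


def _interpolate_low_likelihood(
    series: np.ndarray, confident: np.ndarray
) -> np.ndarray:
    """Replace non-confident samples by linear interpolation between the
    nearest confident neighbours; edges hold the nearest confident value."""
    if confident.all():
        return series
    idx = np.flatnonzero(confident)
    if idx.size == 0:
        raise ValueError("point confident in zero frames; cannot interpolate")
    out = series.copy()
    bad = np.flatnonzero(~confident)
    out[bad] = np.interp(bad, idx, series[idx])
    return out


def postprocess_track(
    track: PoseTrack,
    p_thresh: float = 0.999,
    median_window: int = 5,
    order: str = "filter_then_interp",
    tail_rule: bool = True,
) -> PoseTrack:
    """Standard pose post-processing.

    1. Median filter each coordinate series (window ``median_window``, odd).
    2. Frames with likelihood < ``p_thresh`` are replaced by linear
       interpolation between the nearest confident frames (edge frames hold
       the nearest confident value).
    3. Geometric restriction: where the tail-root y exceeds the back-center y
       (tail root rendered below the back center), the tail-root y is clamped
       to the back-center y.

    ``order`` selects whether the median filter runs before or after
    interpolation ('filter_then_interp' | 'interp_then_filter').
    """
    if median_window % 2 == 0:
        raise ValueError("median_window must be odd")
    if order not in ("filter_then_interp", "interp_then_filter"):
        raise ValueError(f"unknown order {order!r}")

    coords = track.coords.copy()
    confident = track.likelihood >= p_thresh
    n_interp = int((~confident).sum())
    if n_interp:
        log.info(
            "interpolating %d of %d point-frames (%.2f%%) below likelihood %g",
            n_interp,
            confident.size,
            100 * n_interp / confident.size,
            p_thresh,
        )

    def median_pass(c: np.ndarray) -> np.ndarray:
        if median_window > 1:
            # filter along time only; edges replicate the nearest frame
            c = median_filter(c, size=(median_window, 1, 1), mode="nearest")
        return c

    def interp_pass(c: np.ndarray) -> np.ndarray:
        for p in range(c.shape[1]):
            for d in range(2):
                c[:, p, d] = _interpolate_low_likelihood(c[:, p, d], confident[:, p])
        return c

    if order == "filter_then_interp":
        coords = interp_pass(median_pass(coords))
    else:
        coords = median_pass(interp_pass(coords))

    if tail_rule:
        too_low = coords[:, TAIL_ROOT, 1] > coords[:, BACK_CENTER, 1]
        coords[too_low, TAIL_ROOT, 1] = coords[too_low, BACK_CENTER, 1]

    lik = np.ones_like(track.likelihood)
    return replace(track, coords=coords, likelihood=lik)


def rescale_track(track: PoseTrack, factor: float) -> PoseTrack:
    """Divide all coordinates by ``factor`` (e.g. 2 to map 640x480 video onto
    the 320x240 frame size).  Likelihoods are unchanged."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return replace(track, coords=track.coords / factor, likelihood=track.likelihood.copy())


def compute_speed(track: PoseTrack, bout_s: float = 2.0, signed: bool = False) -> np.ndarray:
    """Per-bout speed: sum over the bout of frame-to-frame back-center x
    differences (absolute values by default; ``signed`` sums raw differences,
    which cancel for oscillatory motion)."""
    fpb = bout_s * track.frame_rate_hz
    if abs(fpb - round(fpb)) > 1e-9:
        raise ValueError(
            f"bout of {bout_s} s is not a whole number of frames at {track.frame_rate_hz} Hz"
        )
    fpb = int(round(fpb))
    n_bouts = track.n_frames // fpb
    if n_bouts * fpb != track.n_frames:
        raise ValueError(
            f"track length {track.n_frames} is not divisible by {fpb} frames/bout"
        )
    x = track.coords[: n_bouts * fpb, BACK_CENTER, 0].reshape(n_bouts, fpb)
    dx = np.diff(x, axis=1)
    return dx.sum(axis=1) if signed else np.abs(dx).sum(axis=1)


def compute_freezing_proxy(
    track: PoseTrack,
    motion_threshold: float = 0.5,
    min_bout_s: float = 0.5,
) -> FreezingTrace:
    """Motion-energy freezing proxy.

    Per-frame motion energy is the mean inter-frame displacement over all 13
    points; runs of at least ``min_bout_s`` below ``motion_threshold`` count
    as freezing, and the per-2-s-chunk freezing rate is the fraction of
    freezing frames in the chunk.  This proxy exists so synthetic and legacy
    sessions run end-to-end; an externally supplied trace always takes
    precedence in the pipeline.
    """
    disp = np.linalg.norm(np.diff(track.coords, axis=0), axis=2).mean(axis=1)
    motion = np.concatenate([[disp[0]] if disp.size else [0.0], disp])
    still = motion < motion_threshold

    min_run = max(1, int(round(min_bout_s * track.frame_rate_hz)))
    freezing = np.zeros_like(still)
    i = 0
    n = still.size
    while i < n:
        if still[i]:
            j = i
            while j < n and still[j]:
                j += 1
            if j - i >= min_run:
                freezing[i:j] = True
            i = j
        else:
            i += 1

    fpc = int(round(CHUNK_S * track.frame_rate_hz))
    n_chunks = track.n_frames // fpc
    rates = freezing[: n_chunks * fpc].reshape(n_chunks, fpc).mean(axis=1)
    return FreezingTrace(values=rates, source="motion_proxy")
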