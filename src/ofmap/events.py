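"""Calcium-event processing: peak detection, 2-s binning, z-scoring.

Events are detected per cell as one peak per contiguous excursion of the
dF/F trace above mean + 2.5 SD of that cell's full-session trace (threshold
in per-cell SD units, so detection is invariant to affine rescaling of a
trace).  Event counts in half-open 2-s bins form the event-rate matrix (450
bins for a 900-s session); z-scored traces feed only shock-triggered
averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .session import CHUNK_S, SessionLayout

log = logging.getLogger(__name__)


@dataclass
class CalciumTraces:
    """Per-cell dF/F traces with centroids."""

    dff: np.ndarray  # (cells, frames)
    frame_rate_hz: float
    cell_ids: np.ndarray | None = None
    centroids: np.ndarray | None = None  # (cells, 2)

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        if not np.isfinite(self.dff).all():
            raise ValueError("dF/F traces contain non-finite values")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.n_cells)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (self.n_cells, 2):
                raise ValueError("centroids must be (cells, 2)")

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class EventRateMatrix:
    """Cells x 2-s-bin event counts."""

    counts: np.ndarray
    bin_s: float = CHUNK_S
    cell_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if (self.counts < 0).any():
            raise ValueError("event counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def read_calcium(path: str | Path, frame_rate_hz: float = 25.0) -> CalciumTraces:
    """Read dF/F traces from HDF5 ('dff' + optional 'centroids' datasets) or
    delimited text (cells x frames)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            dff = f["dff"][()]
            centroids = f["centroids"][()] if "centroids" in f else None
            fr = float(f.attrs.get("imaging_hz", frame_rate_hz))
        return CalciumTraces(dff=dff, frame_rate_hz=fr, centroids=centroids)
    dff = np.loadtxt(path, delimiter=None, ndmin=2)
    return CalciumTraces(dff=dff, frame_rate_hz=frame_rate_hz)


def detect_events(
    traces: CalciumTraces, sd_mult: float = 2.5, robust: bool = False
) -> list[np.ndarray]:
    """Per-cell calcium-event frame indices.

    Threshold = mean + ``sd_mult`` x SD of the cell's full-session trace (SD
    over all frames, events included; ``robust`` switches to median + sd_mult
    x 1.4826 MAD).  One event per contiguous supra-threshold excursion, at
    the excursion's maximum.  Zero-variance traces yield zero events.
    """
    raster: list[np.ndarray] = []
    for i in range(traces.n_cells):
        x = traces.dff[i]
        if robust:
            center = np.median(x)
            scale = 1.4826 * np.median(np.abs(x - center))
        else:
            center = x.mean()
            scale = x.std()
        if scale == 0:
            log.info("cell %d has zero-variance trace; no events", i)
            raster.append(np.array([], dtype=np.int64))
            continue
        above = x > center + sd_mult * scale
        if not above.any():
            raster.append(np.array([], dtype=np.int64))
            continue
        edges = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if above[0]:
            starts = np.concatenate([[0], starts])
        if above[-1]:
            ends = np.concatenate([ends, [above.size]])
        peaks = np.array(
            [s + int(np.argmax(x[s:e])) for s, e in zip(starts, ends)], dtype=np.int64
        )
        raster.append(peaks)
    return raster


def bin_events(
    raster: list[np.ndarray], layout: SessionLayout, frame_rate_hz: float | None = None
) -> EventRateMatrix:
    """Count events in half-open 2-s bins [2k, 2k+2) seconds.

    Total events are conserved: counts.sum() equals the raster size.
    """
    fr = frame_rate_hz if frame_rate_hz is not None else layout.imaging_hz
    n_bins = layout.n_chunks
    fpb = CHUNK_S * fr
    counts = np.zeros((len(raster), n_bins), dtype=np.int64)
    for i, ev in enumerate(raster):
        if ev.size == 0:
            continue
        bins = (np.asarray(ev) / fpb).astype(np.int64)
        if bins.min() < 0 or bins.max() >= n_bins:
            raise ValueError(f"cell {i} has event frames outside the session")
        np.add.at(counts[i], bins, 1)
    return EventRateMatrix(counts=counts)


def zscore_traces(traces: CalciumTraces) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each cell's trace over the full session.

    Returns (z, kept) where ``kept`` flags cells with positive SD; zero-SD
    cells are excluded (their rows are NaN) and logged.
    """
    mu = traces.dff.mean(axis=1, keepdims=True)
    sd = traces.dff.std(axis=1, keepdims=True)
    kept = sd[:, 0] > 0
    if not kept.all():
        log.info("excluding %d zero-SD cells from z-scoring", int((~kept).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (traces.dff - mu) / sd
    z[~kept] = np.nan
    return z, kept
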