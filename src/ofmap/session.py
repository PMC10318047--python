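"""Session layout and shock schedule.

An observational-fear (OF) session is a habituation period with no shocks
followed by a conditioning period in which the demonstrator receives a brief
foot shock at a fixed period (default: 2 s shock every 10 s, 60 shocks over
600 s, after 300 s of habituation).  Behavior video runs at 7.5 Hz and
calcium imaging at 25 Hz; all downstream statistics operate on a 2-s grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Width of the analysis chunk (seconds). Freezing rates, event rates and the
#: shock indicator are all defined on this grid.
CHUNK_S = 2.0


@dataclass(frozen=True)
class SessionLayout:
    """Timing and geometry of one OF session.

    Defaults reproduce the standard paradigm: 300 s habituation, 600 s
    conditioning with a 2-s shock every 10 s, behavior tracked at 7.5 Hz in a
    320 x 240 px arena and imaging at 25 Hz.
    """

    habituation_s: float = 300.0
    conditioning_s: float = 600.0
    shock_on_s: float = 2.0
    shock_period_s: float = 10.0
    behavior_hz: float = 7.5
    imaging_hz: float = 25.0
    arena_w_px: float = 320.0
    arena_h_px: float = 240.0
    demonstrator_side: str = "left"

    def __post_init__(self) -> None:
        if self.habituation_s < 0 or self.conditioning_s < 0:
            raise ValueError("periods must be non-negative")
        if self.habituation_s + self.conditioning_s <= 0:
            raise ValueError("session must have positive duration")
        if not 0 < self.shock_on_s < self.shock_period_s:
            raise ValueError("need 0 < shock_on_s < shock_period_s")
        if self.behavior_hz <= 0 or self.imaging_hz <= 0:
            raise ValueError("frame rates must be positive")
        if self.demonstrator_side not in ("left", "right"):
            raise ValueError(
                f"demonstrator_side must be 'left' or 'right', got {self.demonstrator_side!r}"
            )

    @property
    def total_s(self) -> float:
        return self.habituation_s + self.conditioning_s

    @property
    def n_behavior_frames(self) -> int:
        return int(round(self.total_s * self.behavior_hz))

    @property
    def n_imaging_frames(self) -> int:
        return int(round(self.total_s * self.imaging_hz))

    @property
    def n_chunks(self) -> int:
        """Number of 2-s chunks in the whole session."""
        return int(round(self.total_s / CHUNK_S))

    @property
    def n_habituation_chunks(self) -> int:
        return int(round(self.habituation_s / CHUNK_S))

    @property
    def n_conditioning_chunks(self) -> int:
        return int(round(self.conditioning_s / CHUNK_S))

    @property
    def n_shocks(self) -> int:
        return int(round(self.conditioning_s / self.shock_period_s))

    @property
    def chunks_per_period(self) -> int:
        """2-s chunks per shock cycle (5 for a 10-s period)."""
        return int(round(self.shock_period_s / CHUNK_S))


@dataclass(frozen=True)
class ShockSchedule:
    """Shock onsets and the 2-s shock indicator over the conditioning period.

    ``indicator_2s`` concatenates, per shock cycle, a single 1 (the shock
    chunk) followed by ``shock_period_s / 2 - 1`` zeros — the repeating
    1-0-0-0-0 pattern for the default layout.
    """

    onsets: np.ndarray  # shock onset times (s), strictly increasing
    indicator_2s: np.ndarray  # int8, one entry per conditioning chunk
    layout: SessionLayout = field(repr=False, default=SessionLayout())

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        ind = np.asarray(self.indicator_2s, dtype=np.int8)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "indicator_2s", ind)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("shock onsets must be strictly increasing")

    @property
    def n_shocks(self) -> int:
        return int(self.onsets.size)


def make_shock_schedule(layout: SessionLayout) -> ShockSchedule:
    """Build the shock schedule implied by a session layout.

    One shock per ``shock_period_s``, the first at the start of conditioning.
    Rejects layouts whose conditioning period is not an integer number of
    shock periods.
    """
    n_periods = layout.conditioning_s / layout.shock_period_s
    if abs(n_periods - round(n_periods)) > 1e-9:
        raise ValueError(
            f"conditioning period ({layout.conditioning_s} s) is not an integer "
            f"number of shock periods ({layout.shock_period_s} s): "
            f"{n_periods:.4f} periods"
        )
    n = int(round(n_periods))
    onsets = layout.habituation_s + layout.shock_period_s * np.arange(n)
    block = np.zeros(layout.chunks_per_period, dtype=np.int8)
    if n > 0:
        block[0] = 1
    indicator = np.tile(block, n)
    return ShockSchedule(onsets=onsets, indicator_2s=indicator, layout=layout)


def chunk_period_tags(layout: SessionLayout) -> np.ndarray:
    """Per-2-s-chunk period tag: 'habituation' or 'conditioning'."""
    tags = np.empty(layout.n_chunks, dtype=object)
    tags[: layout.n_habituation_chunks] = "habituation"
    tags[layout.n_habituation_chunks:] = "conditioning"
    return tags
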