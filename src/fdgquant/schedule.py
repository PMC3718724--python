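"""Acquisition frame timing for dynamic PET scans.

A dynamic scan is binned into contiguous frames; all timing here is in
seconds from injection.  The default schedule is the 60-min, 35-frame
protocol used for the mouse studies this package models: frames start very
short (1 s and 0.5 s) to resolve the bolus and lengthen to 900 s at late
times, plus a trailing 51-s frame to close the hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "make_default_schedule", "DEFAULT_FRAME_GROUPS"]

#: (count, duration_s) groups of the 60-min mouse protocol, in order.
DEFAULT_FRAME_GROUPS: tuple[tuple[int, float], ...] = (
    (4, 1.0),
    (15, 0.5),
    (1, 2.0),
    (1, 4.0),
    (1, 6.0),
    (1, 15.0),
    (3, 30.0),
    (1, 60.0),
    (1, 120.0),
    (3, 180.0),
    (3, 900.0),
    (1, 51.0),
)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous list of (start, duration) frames in seconds."""

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("schedule needs at least one frame")
        starts = np.array([f[0] for f in self.frames], dtype=float)
        durs = np.array([f[1] for f in self.frames], dtype=float)
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if starts[0] != 0.0:
            raise ValueError("first frame must start at t=0")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1]):
            raise ValueError("frames must be contiguous")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames], dtype=float)

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames], dtype=float)

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.starts_s + 0.5 * self.durations_s

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.durations_s.sum())

    def frames_within(self, t_max_s: float) -> "FrameSchedule":
        """Sub-schedule of frames ending at or before ``t_max_s``."""
        kept = tuple(f for f in self.frames if f[0] + f[1] <= t_max_s + 1e-9)
        if not kept:
            raise ValueError(f"no frame ends before {t_max_s} s")
        return FrameSchedule(kept)


def make_default_schedule() -> FrameSchedule:
    """Expand the standard 12-group protocol into its 35 individual frames."""
    frames: list[tuple[float, float]] = []
    t = 0.0
    for count, dur in DEFAULT_FRAME_GROUPS:
        for _ in range(count):
            frames.append((t, dur))
            t += dur
    return FrameSchedule(tuple(frames))
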