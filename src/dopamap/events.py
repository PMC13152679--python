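"""Spontaneous-event detection and event-triggered response quantification.

Retinal waves are detected on the (filtered, bleach-corrected) calcium
trace by z-scoring against the full-trace mean and SD and keeping local
maxima that exceed z = 3, with events forced apart by at least 10 s (the
larger peak wins a conflict; ties go to the earlier frame).  Triggered
averages collect a 60 s window centered on the frame *prior* to each event
peak, identically for both channels, so cross-channel coupling can be read
off the same trigger frames.  The response amplitude is the difference
between 3 s-smoothed peak values in the 10 s windows after and before the
trigger.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import Trace

logger = logging.getLogger(__name__)

__all__ = [
    "EventCatalog",
    "TriggeredAverage",
    "detect_waves",
    "triggered_average",
    "quantify_response",
]


@dataclass
class EventCatalog:
    """Detected event peak frames with the detection parameters used."""

    event_frames: np.ndarray
    kind: str = "wave"
    z_threshold: float = 3.0
    min_separation_s: float = 10.0
    z_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.event_frames = np.asarray(self.event_frames, dtype=int)

    def __len__(self) -> int:
        return len(self.event_frames)


def detect_waves(
    ca: Trace, z: float = 3.0, min_sep: float = 10.0, kind: str = "wave"
) -> EventCatalog:
    """Detect spontaneous waves on a calcium trace.

    The trace is z-scored with its full-trace mean and sample SD; candidate
    events are strict local maxima whose z-score exceeds ``z``.  Candidates
    closer than ``min_sep`` seconds are resolved by keeping the larger
    (earlier frame on ties).  The trace should already be filtered and
    baseline-processed per the preprocessing defaults.
    """
    v = ca.values
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance trace: no events detectable", stacklevel=2)
        return EventCatalog(np.array([], dtype=int), kind, z, min_sep,
                            z_values=np.array([]))
    zs = (v - v.mean()) / sd
    interior = np.arange(1, len(v) - 1)
    is_peak = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
    cand = interior[is_peak & (zs[interior] > z)]
    # greedy suppression: largest first, earlier frame on ties
    order = sorted(cand, key=lambda i: (-zs[i], i))
    min_gap = min_sep * ca.frame_rate
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_gap for j in kept):
            kept.append(int(i))
    kept.sort()
    frames = np.array(kept, dtype=int)
    return EventCatalog(frames, kind, z, min_sep, z_values=zs[frames])


@dataclass
class TriggeredAverage:
    """Windowed per-event segments and their mean, aligned to triggers.

    The trigger of each event is the frame prior to its peak; offsets are
    seconds relative to that trigger.
    """

    time_offsets: np.ndarray
    segments: np.ndarray  # (n_events_used, window_frames)
    mean: np.ndarray
    sd: np.ndarray
    n_events_used: int
    n_events_dropped: int
    frame_rate: float
    window_s: float


def triggered_average(
    trace: Trace, events: EventCatalog, window: float = 60.0
) -> TriggeredAverage:
    """Average trace segments in a window centered on each event trigger.

    Each event contributes the segment centered on (event_frame − 1),
    spanning window/2 on each side.  Events whose full window would run off
    either end of the trace are dropped and counted.  Apply to several
    channels with the same catalog to compare their coupled responses.
    """
    if len(events) == 0:
        raise ValueError("event catalog is empty")
    half = int(round((window / 2.0) * trace.frame_rate))
    if half < 1:
        raise ValueError("window shorter than one frame")
    n = len(trace)
    segments = []
    dropped = 0
    for f in events.event_frames:
        c = int(f) - 1  # frame prior to the peak
        if c - half < 0 or c + half >= n:
            dropped += 1
            continue
        segments.append(trace.values[c - half : c + half + 1])
    if not segments:
        raise ValueError(
            f"all {len(events)} events dropped: windows of ±{half} frames do "
            f"not fit inside a {n}-frame trace"
        )
    seg = np.stack(segments)
    offsets = np.arange(-half, half + 1) / trace.frame_rate
    sd = seg.std(axis=0, ddof=1) if len(seg) > 1 else np.zeros(seg.shape[1])
    return TriggeredAverage(
        time_offsets=offsets,
        segments=seg,
        mean=seg.mean(axis=0),
        sd=sd,
        n_events_used=len(seg),
        n_events_dropped=dropped,
        frame_rate=trace.frame_rate,
        window_s=window,
    )


def _smoothed_peak(
    offsets: np.ndarray,
    mean: np.ndarray,
    win_mask: np.ndarray,
    peak_win: float,
) -> float:
    """Peak frame inside the flank window, replaced by the mean of the
    peak-centered window clipped to the flank."""
    idx = np.nonzero(win_mask)[0]
    pk = idx[np.argmax(mean[idx])]
    half = peak_win / 2.0
    around = win_mask & (np.abs(offsets - offsets[pk]) <= half + 1e-12)
    clipped = int(np.sum(np.abs(offsets - offsets[pk]) <= half + 1e-12) - np.sum(around))
    if clipped:
        logger.info("quantify_response: peak window clipped by %d frames", clipped)
    return float(mean[around].mean())


def quantify_response(
    ta: TriggeredAverage, peak_win: float = 3.0, flank_win: float = 10.0
) -> float:
    """Event response amplitude from a triggered average (ΔF/F units).

    In the ``flank_win`` seconds before the trigger and after it, the peak
    of the mean trace is found and replaced by the mean over a ``peak_win``
    window centered on it (clipped to the flank); the response is the
    after-value minus the before-value.  Invariant to adding a constant to
    the trace; scales linearly with the trace.
    """
    if ta.window_s < 2.0 * flank_win:
        raise ValueError(
            f"triggered-average window ({ta.window_s} s) shorter than two "
            f"flanks of {flank_win} s"
        )
    off = ta.time_offsets
    before = (off >= -flank_win) & (off < 0)
    after = (off > 0) & (off <= flank_win)
    if not before.any() or not after.any():
        raise ValueError("flank windows exceed the triggered-average span")
    return _smoothed_peak(off, ta.mean, after, peak_win) - _smoothed_peak(
        off, ta.mean, before, peak_win
    )
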