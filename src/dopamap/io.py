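"""Core containers and file I/O for movie stacks and traces.

A movie is a T×Y×X intensity stack from one spectral channel, stored on disk
as a multi-page grayscale TIFF next to a JSON sidecar holding the acquisition
metadata (frame rate, pixel size, channel label, stimulus frames, seed).
Traces are one-dimensional time series exported as CSV with columns
``frame, time_s, value``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MovieStack",
    "Trace",
    "read_movie",
    "write_movie",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass
class MovieStack:
    """A T×Y×X intensity movie from one spectral channel.

    Parameters
    ----------
    data : ndarray, shape (T, Y, X)
        Non-negative intensities (raw counts or ΔF/F, depending on stage).
    frame_rate : float
        Acquisition rate in Hz.
    pixel_size : float
        Pixel pitch in µm/pixel.
    channel : str
        Channel label (e.g. ``"visible"`` or ``"nir"``).
    stim_frames : tuple of int, optional
        Frame indices at which stimuli were delivered, strictly increasing.
    """

    data: np.ndarray
    frame_rate: float
    pixel_size: float = 1.0
    channel: str = ""
    stim_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be T×Y×X, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        sf = tuple(int(f) for f in self.stim_frames)
        if any(b <= a for a, b in zip(sf, sf[1:])):
            raise ValueError("stim_frames must be strictly increasing")
        if sf and (sf[0] < 0 or sf[-1] >= self.data.shape[0]):
            raise ValueError("stim_frames must lie within the movie")
        self.stim_frames = sf

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds (frame i at t = i / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def mean_trace(self) -> "Trace":
        """Spatial mean over the full field, per frame."""
        return Trace(self.data.mean(axis=(1, 2)), self.frame_rate)

    def with_data(self, data: np.ndarray) -> "MovieStack":
        return dataclasses.replace(self, data=data)


@dataclass
class Trace:
    """A single time series sampled at a fixed frame rate.

    ``t0_frame`` records which frame index time zero refers to; values are
    whatever unit the producing stage defines (counts or ΔF/F).
    """

    values: np.ndarray
    frame_rate: float
    t0_frame: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Times in seconds relative to ``t0_frame``."""
        return (np.arange(len(self.values)) - self.t0_frame) / self.frame_rate

    def with_values(self, values: np.ndarray) -> "Trace":
        return dataclasses.replace(self, values=values)


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_movie(movie: MovieStack, path: str | Path, seed: int | None = None) -> Path:
    """Write a movie as multi-page grayscale TIFF plus a JSON metadata sidecar.

    Returns the TIFF path; the sidecar sits next to it with a ``.json`` suffix.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.data, photometric="minisblack")
    sidecar = {
        "frame_rate_hz": movie.frame_rate,
        "pixel_size_um": movie.pixel_size,
        "channel": movie.channel,
        "stim_frames": list(movie.stim_frames),
        "seed": seed,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a multi-page TIFF movie and its JSON sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:  # single page: promote, though it will fail the T>=2 check
        data = data[None]
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sidecar_file} not found next to {path}"
        )
    meta = json.loads(sidecar_file.read_text())
    return MovieStack(
        data=data,
        frame_rate=float(meta["frame_rate_hz"]),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        channel=str(meta.get("channel", "")),
        stim_frames=tuple(meta.get("stim_frames") or ()),
    )


def write_trace_csv(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(trace)),
            "time_s": trace.times,
            "value": trace.values,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path: str | Path, frame_rate: float | None = None) -> Trace:
    """Read a ``frame, time_s, value`` CSV; frame rate is inferred from time_s
    unless given explicitly."""
    df = pd.read_csv(path)
    if frame_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError("cannot infer frame rate from time_s column")
        frame_rate = 1.0 / float(np.mean(dt))
    t0_frame = int(np.argmin(np.abs(df["time_s"].to_numpy())))
    return Trace(df["value"].to_numpy(), frame_rate, t0_frame=t0_frame)
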