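"""Shared in-memory containers used across the pipeline.

Coordinate convention (all modules): 0-based, ``x`` = column, ``y`` = row,
origin at the top-left pixel corner; pixel centers sit at half-integer-free
integer coordinates (pixel (0, 0) has its center at x=0, y=0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameStack", "LandmarkTrack"]


@dataclass
class FrameStack:
    """An ordered stack of 8-bit RGB frames at a fixed frame rate.

    Attributes
    ----------
    frames
        ``(T, H, W, 3)`` uint8 array.
    frame_rate
        Frames per second.
    """

    frames: np.ndarray
    frame_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be (T, H, W, 3)")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be uint8 RGB")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return self.frames.shape[2], self.frames.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class LandmarkTrack:
    """Per-frame 2D coordinates of K facial points.

    ``points`` is ``(T, K, 2)`` float with columns (x, y); frames where the
    face was not found carry NaN rows.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[-1] != 2:
            raise ValueError("points must be (T, K, 2)")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[1]

    def valid_frames(self) -> np.ndarray:
        """Boolean mask of frames where all landmarks are finite."""
        return np.isfinite(self.points).all(axis=(1, 2))
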