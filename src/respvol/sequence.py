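"""Depth-frame containers and their validity rules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """A container violates its invariants."""


@dataclass
class DepthFrame:
    """One single-channel depth image.

    ``values`` holds depth in millimetres; 0 marks an invalid pixel (no
    sensor return) and is excluded from all energies and volume sums.
    ``timestamp`` is seconds from sequence start.
    """

    values: np.ndarray
    timestamp: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("depth frame must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValidationError("depth frame contains non-finite values")
        if (self.values < 0).any():
            raise ValidationError("depth values must be non-negative")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def valid(self) -> np.ndarray:
        return self.values > 0


@dataclass
class DepthSequence:
    """Ordered depth frames with a nominal frame rate.

    Timestamps must be strictly increasing, all frames the same shape,
    and the nominal frame rate must match the median timestamp spacing
    within 10%.
    """

    frames: list[DepthFrame]
    frame_rate: float

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValidationError("sequence has no frames")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        shape = self.frames[0].values.shape
        for f in self.frames:
            if f.values.shape != shape:
                raise ValidationError(
                    f"inconsistent frame shapes: {f.values.shape} vs {shape}"
                )
        ts = self.timestamps
        if len(ts) > 1:
            if not (np.diff(ts) > 0).all():
                raise ValidationError("timestamps must be strictly increasing")
            spacing = float(np.median(np.diff(ts)))
            nominal = 1.0 / self.frame_rate
            if abs(spacing - nominal) > 0.1 * nominal:
                raise ValidationError(
                    f"median timestamp spacing {spacing:.4g}s deviates >10% "
                    f"from nominal {nominal:.4g}s"
                )

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].values.shape

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_array(cls, depths: np.ndarray, frame_rate: float,
                   timestamps: np.ndarray | None = None) -> "DepthSequence":
        """Build a sequence from a (k, H, W) depth stack."""
        depths = np.asarray(depths, dtype=float)
        if depths.ndim != 3:
            raise ValidationError("depth stack must be 3-D (frames, rows, cols)")
        if timestamps is None:
            timestamps = np.arange(depths.shape[0]) / frame_rate
        frames = [DepthFrame(values=d, timestamp=float(t)) for d, t in zip(depths, timestamps)]
        return cls(frames=frames, frame_rate=frame_rate)

    def to_array(self) -> np.ndarray:
        return np.stack([f.values for f in self.frames])
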