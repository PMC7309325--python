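"""Volume estimation: per-frame masked depth differences to breaths.

The per-frame volume increment over the respiration-related region R is

    V = sum_{r in R} (U(r) - L(r)) * C(d(r))^2   [mm^3]

with U/L the current/previous depth frame and C(d) = 0.0041 d + 0.0046
the depth-dependent physical side length (mm) of one pixel, so C^2 is the
pixel's footprint area.  The series {V(t)} is the respiratory volume
waveform; its running sum (the cumulative waveform) is the volume
trajectory on which breaths are read: a tidal volume is the rise from a
valley to the following peak of the cumulative series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .temporal import difference_image

MM3_PER_ML = 1000.0


@dataclass
class PixelCalibration:
    """Linear pixel-size model C(d) = slope * d + intercept (mm per pixel)."""

    slope: float = 0.0041
    intercept: float = 0.0046

    def __post_init__(self):
        if self.intercept <= 0 or self.slope < 0:
            raise ValueError("calibration must give C(d) > 0 for all d >= 0")


def pixel_length(d, cal: PixelCalibration | None = None):
    """Physical side length (mm) of a pixel at depth ``d`` mm."""
    if cal is None:
        cal = PixelCalibration()
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("depth must be non-negative")
    out = cal.slope * d + cal.intercept
    return float(out) if out.ndim == 0 else out


@dataclass
class Breath:
    """One detected breath on the cumulative waveform."""

    valley_index: int
    peak_index: int
    valley_time: float
    peak_time: float
    tidal_ml: float


@dataclass
class VolumeWaveform:
    """Respiratory volume waveform.

    ``values`` is the per-frame difference series V(t) (mL); ``cumulative``
    its running sum (the volume trajectory, mL); both share ``times``.
    """

    times: np.ndarray
    values: np.ndarray
    cumulative: np.ndarray
    breaths: list[Breath] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if len(self.times) != len(self.values) or len(self.times) != len(self.cumulative):
            raise ValueError("times/values/cumulative lengths differ")

    @property
    def tidal_volumes(self) -> np.ndarray:
        return np.array([b.tidal_ml for b in self.breaths])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "volume_ml": self.values, "cumulative_ml": self.cumulative}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VolumeWaveform":
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(),
            values=df["volume_ml"].to_numpy(),
            cumulative=df["cumulative_ml"].to_numpy(),
        )

    def breaths_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "valley_t": b.valley_time,
                    "peak_t": b.peak_time,
                    "tidal_ml": b.tidal_ml,
                }
                for b in self.breaths
            ]
        )


def frame_volume(
    current: np.ndarray,
    previous: np.ndarray,
    R: np.ndarray,
    cal: PixelCalibration | None = None,
    sign: str = "inhale_positive",
) -> float:
    """Volume increment (mL) over the mask R between two frames.

    The depth difference follows ``sign`` (inhale-positive by default)
    and invalid pixels (0 in either frame) contribute nothing.  The pixel
    area C^2 is evaluated at the mean of the two frames' depths: using a
    single noisy frame would correlate the noise inside C^2 with the same
    noise in the difference (E[n * C^2(d + n)] > 0) and bias every frame's
    volume by a fixed amount, which integrates into a severe drift; the
    symmetric average cancels that correlation exactly.
    """
    if cal is None:
        cal = PixelCalibration()
    current = np.asarray(current, dtype=float)
    previous = np.asarray(previous, dtype=float)
    R = np.asarray(R).astype(bool)
    if R.shape != current.shape:
        raise ValueError("mask shape does not match frame shape")
    if not R.any():
        warnings.warn("empty respiration-related region; volume is 0", stacklevel=2)
        return 0.0
    diff = difference_image(current, previous, sign)
    both = (current > 0) & (previous > 0)
    d_ref = np.where(both, 0.5 * (current + previous), current)
    c = pixel_length(d_ref, cal)
    return float((diff[R] * c[R] ** 2).sum() / MM3_PER_ML)


def build_waveform(
    seq,
    masks: list[np.ndarray],
    cal: PixelCalibration | None = None,
    sign: str = "inhale_positive",
    detrend: bool = False,
) -> VolumeWaveform:
    """Assemble the volume waveform from a sequence and per-pair masks.

    ``masks`` holds one respiration-region mask per consecutive frame
    pair.  The cumulative series starts at 0 at the first frame; optional
    linear detrending removes slow drift from the cumulative series (off
    by default).
    """
    frames = seq.frames
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    if len(masks) != len(frames) - 1:
        raise ValueError(
            f"expected {len(frames) - 1} masks (one per frame pair), got {len(masks)}"
        )
    vols = np.zeros(len(frames))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in range(1, len(frames)):
            vols[t] = frame_volume(
                frames[t].values, frames[t - 1].values, masks[t - 1], cal, sign
            )
    cumulative = np.cumsum(vols)
    if detrend:
        cumulative = sp_signal.detrend(cumulative, type="linear")
    return VolumeWaveform(times=seq.timestamps, values=vols, cumulative=cumulative)


def detect_breaths(
    wave: VolumeWaveform,
    min_duration: float = 1.0,
    min_prominence: float = 50.0,
) -> list[Breath]:
    """Detect breaths as valley-to-peak excursions of the cumulative series.

    Peaks and valleys with prominence below ``min_prominence`` (mL) are
    ignored, as are breaths shorter than ``min_duration`` (s).  The
    detected breaths are also stored on ``wave.breaths``.
    """
    cum = wave.cumulative
    if len(cum) < 3:
        wave.breaths = []
        return []
    dt = float(np.median(np.diff(wave.times)))
    distance = max(1, int(round(min_duration / dt)))
    peaks, _ = sp_signal.find_peaks(cum, prominence=min_prominence, distance=distance)
    valleys, _ = sp_signal.find_peaks(-cum, prominence=min_prominence, distance=distance)
    # the leading/trailing samples can be extrema of the breath cycle too
    if len(peaks) and (not len(valleys) or valleys[0] > peaks[0]):
        if cum[0] < cum[peaks[0]] - min_prominence:
            valleys = np.concatenate([[0], valleys])
    breaths: list[Breath] = []
    for v in valleys:
        after = peaks[peaks > v]
        if not len(after):
            continue
        p = int(after[0])
        nxt = valleys[valleys > v]
        if len(nxt) and nxt[0] < p:
            continue  # a deeper valley precedes this peak
        if wave.times[p] - wave.times[v] < min_duration:
            continue
        tidal = float(cum[p] - cum[int(v)])
        if tidal < min_prominence:
            continue
        breaths.append(
            Breath(
                valley_index=int(v),
                peak_index=p,
                valley_time=float(wave.times[int(v)]),
                peak_time=float(wave.times[p]),
                tidal_ml=tidal,
            )
        )
    if not breaths:
        warnings.warn("no complete breath detected", stacklevel=2)
    wave.breaths = breaths
    return breaths
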