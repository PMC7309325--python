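"""Reading and writing depth sequences and masks.

Two containers are supported: a directory of 16-bit grayscale PNGs plus a
JSON sidecar (``sequence.json`` carrying frame rate, depth scale and
timestamps) for interoperability, and a single ``.npz`` archive for
speed.  The archive round-trips bit-exactly; the PNG container stores
integer counts at the sidecar's mm-per-unit scale, so it is exact for
quantized sensor data.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .sequence import DepthSequence, ValidationError

SIDECAR = "sequence.json"


class FormatError(ValueError):
    """The on-disk container is malformed or incomplete."""


class RangeError(ValueError):
    """A depth value does not fit the 16-bit PNG container."""


def write_sequence(seq: DepthSequence, path, depth_scale: float = 1.0) -> None:
    """Write a sequence to ``path``: ``.npz`` archive or PNG directory.

    For the PNG container, depths are stored as ``round(mm / depth_scale)``
    16-bit counts; values above 65535 counts raise :class:`RangeError`.
    """
    path = Path(path)
    if len(seq.frames) == 0:
        raise ValidationError("refusing to write an empty sequence")
    if path.suffix == ".npz":
        np.savez(
            path,
            depths=seq.to_array(),
            timestamps=seq.timestamps,
            frame_rate=np.array(seq.frame_rate),
        )
        return
    path.mkdir(parents=True, exist_ok=True)
    counts = np.round(seq.to_array() / depth_scale)
    if (counts > 65535).any():
        raise RangeError(
            f"depth exceeds 16-bit range at scale {depth_scale} mm/unit"
        )
    for i, frame in enumerate(counts.astype(np.uint16)):
        iio.imwrite(path / f"frame_{i:05d}.png", frame)
    sidecar = {
        "frame_rate": seq.frame_rate,
        "depth_scale_mm": depth_scale,
        "timestamps_s": seq.timestamps.tolist(),
    }
    (path / SIDECAR).write_text(json.dumps(sidecar, indent=1))


def read_sequence(path) -> DepthSequence:
    """Read a sequence written by :func:`write_sequence`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return DepthSequence.from_array(
                data["depths"], float(data["frame_rate"]), data["timestamps"]
            )
    if not path.is_dir():
        raise FormatError(f"{path} is neither an .npz archive nor a directory")
    sidecar_path = path / SIDECAR
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {SIDECAR} in {path}")
    meta = json.loads(sidecar_path.read_text())
    try:
        scale = float(meta["depth_scale_mm"])
        frame_rate = float(meta["frame_rate"])
        timestamps = np.asarray(meta["timestamps_s"], dtype=float)
    except KeyError as exc:
        raise FormatError(f"sidecar missing key {exc}") from exc
    files = sorted(path.glob("frame_*.png"))
    if not files:
        raise FormatError(f"no frame PNGs in {path}")
    frames = [np.asarray(iio.imread(f), dtype=float) * scale for f in files]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValidationError(f"inconsistent frame shapes: {sorted(shapes)}")
    return DepthSequence.from_array(np.stack(frames), frame_rate, timestamps)


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask).astype(bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def write_mask_stack(masks: list[np.ndarray], path) -> None:
    np.savez(Path(path), masks=np.stack([np.asarray(m).astype(bool) for m in masks]))


def read_mask_stack(path) -> list[np.ndarray]:
    with np.load(Path(path)) as data:
        return [m.astype(bool) for m in data["masks"]]
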