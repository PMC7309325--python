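"""End-to-end pipeline: depth sequence -> chest wall -> R_t -> waveform.

Stage order follows the method's design: the shape-prior level set
extracts the chest wall W from the first frame (spatial information);
the region-weighted level set then tracks the respiration-related region
R_t through the difference images (temporal information, optionally with
the adaptive weighting); finally the masked depth differences are
integrated into the volume waveform and breaths.

The ``method`` switch reproduces the three-way comparison:

* ``spatial``  — R_t = W for every frame (spatial information only);
* ``temporal`` — static region weights (no memory of R_{t-1});
* ``adaptive`` — the adaptive region-information function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .sequence import DepthSequence
from .shape_prior import ShapePrior, segment_chest_wall
from .temporal import track_sequence
from .volume import VolumeWaveform, build_waveform, detect_breaths


@dataclass
class PipelineResult:
    chest_wall: np.ndarray
    masks: list[np.ndarray]
    waveform: VolumeWaveform
    info: list[dict] = field(default_factory=list)
    segment_iterations: int = 0


def run_pipeline(
    seq: DepthSequence,
    prior_mask: np.ndarray,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full volume-estimation pipeline on a depth sequence.

    Deterministic given (sequence, prior mask, config): no stage draws
    randomness.  Returns the chest wall mask, the per-frame-pair
    respiration-region masks, and the breath-annotated volume waveform.
    """
    if config is None:
        config = RunConfig()
    prior_mask = np.asarray(prior_mask).astype(bool)
    if prior_mask.shape != seq.shape:
        raise ValueError("prior mask shape does not match frame shape")
    if len(seq) < 2:
        raise ValueError("volume estimation needs at least 2 frames")

    prior = ShapePrior.from_mask(prior_mask, eps=config.eps)
    W, seg_log = segment_chest_wall(
        seq.frames[0].values, prior, config.segment_params()
    )

    if config.method == "spatial":
        masks = [W] * (len(seq) - 1)
        info = [{"frame": t + 1, "area": int(W.sum()), "iterations": 0}
                for t in range(len(seq) - 1)]
    else:
        masks, info = track_sequence(
            seq,
            W,
            config.temporal_params(),
            adaptive=(config.method == "adaptive"),
            sign=config.sign_convention,
        )

    wave = build_waveform(
        seq, masks, config.calibration(), sign=config.sign_convention,
        detrend=config.detrend,
    )
    detect_breaths(wave, config.min_duration_s, config.min_prominence_ml)
    return PipelineResult(
        chest_wall=W,
        masks=masks,
        waveform=wave,
        info=info,
        segment_iterations=len(seg_log),
    )
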