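"""Synthetic breathing-chest phantom with analytically known ground truth.

The scene emulates what a depth camera sees of a seated torso: a flat
background plane, a domed torso surface at arm's length (~45 cm), and
optional arm regions whose depth differs from the torso by only a few
millimetres (the ambiguous-boundary condition that defeats plain
intensity segmentation).  Breathing displaces a smooth envelope patch on
the chest toward the camera:

    depth(x, t) = base(x) - A * env(x) * u(t),    u(t) = (1 - cos(2 pi t / T)) / 2

with ``env`` a flat-topped raised-cosine bump that tapers to zero at the
patch boundary (chest-wall motion has no sharp edge) and A the peak
displacement in mm.  Optional ingredients: a weaker abdominal patch with
a phase lag (abdominal motion trails the rib cage), brief distractor
displacements outside the chest patch (non-respiratory jolts), a slow
whole-body sway (postural drift), Gaussian sensor noise and depth
quantization.

The emitted ground truth is computed from the pre-noise displacement
field: the chest mask, per-frame-pair respiration-region masks (where
the frame-to-frame breathing displacement change exceeds a floor), the
analytic cumulative volume waveform (using the same pixel-size
calibration as the estimator, so calibration cancels in the comparison),
and the analytic per-breath tidal volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sequence import DepthSequence
from .volume import MM3_PER_ML, PixelCalibration, VolumeWaveform


class PhantomConfigError(ValueError):
    """Phantom regions violate the disjointness the truth needs."""


@dataclass
class Distractor:
    """A brief non-respiratory displacement of an elliptical region.

    ``center``/``axes`` are fractions of the frame shape (row, col);
    ``delta_mm`` is the displacement toward the camera while active.
    """

    start_s: float
    duration_s: float
    center: tuple[float, float]
    axes: tuple[float, float]
    delta_mm: float


@dataclass
class PhantomConfig:
    """Scene and schedule of the breathing phantom.

    Geometry is given in fractions of the frame shape so one config
    scales across resolutions.  Defaults: 320 x 240 pixels at 16 fps, a
    torso at 450 mm base depth, a 12 mm peak chest displacement with a
    4 s breathing period (~400 mL tidal volume at this geometry), 1 mm
    depth quantization, no noise, no distractors.
    """

    shape: tuple[int, int] = (240, 320)  # rows, cols
    frame_rate: float = 16.0
    duration_s: float = 20.0
    background_mm: float = 800.0
    torso_center: tuple[float, float] = (0.55, 0.50)
    torso_axes: tuple[float, float] = (0.42, 0.30)
    torso_depth_mm: float = 450.0
    dome_mm: float = 20.0
    arms: bool = False
    arm_offset_mm: float = 3.0
    arm_width: float = 0.08
    chest_center: tuple[float, float] = (0.45, 0.50)
    chest_axes: tuple[float, float] = (0.26, 0.19)
    flat_top: float = 0.6
    amplitude_mm: float = 12.0
    period_s: float = 4.0
    abd_center: tuple[float, float] = (0.76, 0.50)
    abd_axes: tuple[float, float] = (0.11, 0.13)
    abd_scale: float = 0.0
    abd_lag_s: float = 0.0
    distractors: list[Distractor] = field(default_factory=list)
    sway_mm: float = 0.0
    sway_period_s: float = 17.0
    noise_sd_mm: float = 0.0
    quant_mm: float = 1.0
    displacement_floor_mm: float = 0.1
    calibration: PixelCalibration = field(default_factory=PixelCalibration)
    seed: int = 0

    def __post_init__(self):
        if self.amplitude_mm < 0 or self.abd_scale < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.period_s <= 2.0 / self.frame_rate:
            raise ValueError("period must exceed two frame intervals")
        if self.noise_sd_mm < 0 or self.quant_mm < 0:
            raise ValueError("noise and quantization must be >= 0")
        if not 0.0 < self.flat_top < 1.0:
            raise ValueError("flat_top must be in (0, 1)")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a generated sequence."""

    chest_mask: np.ndarray
    torso_mask: np.ndarray
    arm_mask: np.ndarray
    resp_masks: list[np.ndarray]
    waveform: VolumeWaveform
    tidal_ml: float
    breath_count: int
    envelope: np.ndarray


def _ellipse_r2(shape, center, axes):
    rows, cols = np.indices(shape, dtype=float)
    cr = center[0] * shape[0]
    cc = center[1] * shape[1]
    ar = max(axes[0] * shape[0], 1e-9)
    ac = max(axes[1] * shape[1], 1e-9)
    return ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2


def _flat_top_bump(r2: np.ndarray, flat_top: float) -> np.ndarray:
    """1 inside r <= flat_top, raised-cosine taper to 0 at r = 1."""
    r = np.sqrt(r2)
    env = np.zeros_like(r)
    env[r <= flat_top] = 1.0
    band = (r > flat_top) & (r < 1.0)
    env[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - flat_top) / (1.0 - flat_top)))
    return env


def generate(config: PhantomConfig) -> tuple[DepthSequence, PhantomTruth]:
    """Render the phantom sequence and its analytic ground truth.

    Deterministic for a fixed config (including the seed): the same
    config yields a bit-identical sequence.
    """
    shape = config.shape
    rng = np.random.default_rng(config.seed)

    torso_r2 = _ellipse_r2(shape, config.torso_center, config.torso_axes)
    torso = torso_r2 <= 1.0
    dome = np.where(torso, np.sqrt(np.clip(1.0 - torso_r2, 0.0, 1.0)), 0.0)

    arm_mask = np.zeros(shape, dtype=bool)
    if config.arms:
        rows, cols = np.indices(shape)
        cr = config.torso_center[0] * shape[0]
        cc = config.torso_center[1] * shape[1]
        half_w = config.torso_axes[1] * shape[1]
        w = config.arm_width * shape[1]
        band_rows = (rows > cr - 0.35 * shape[0]) & (rows < cr + 0.42 * shape[0])
        left = band_rows & (cols > cc - half_w - w) & (cols < cc - 0.55 * half_w) & ~torso
        right = band_rows & (cols < cc + half_w + w) & (cols > cc + 0.55 * half_w) & ~torso
        arm_mask = left | right

    env = config.amplitude_mm * _flat_top_bump(
        _ellipse_r2(shape, config.chest_center, config.chest_axes), config.flat_top
    )
    env[~torso] = 0.0
    env_abd = np.zeros(shape)
    if config.abd_scale > 0:
        env_abd = (
            config.amplitude_mm
            * config.abd_scale
            * _flat_top_bump(_ellipse_r2(shape, config.abd_center, config.abd_axes),
                             config.flat_top)
        )
        env_abd[~torso] = 0.0
    chest_mask = (env + env_abd) > 0

    if (arm_mask & chest_mask).any():
        raise PhantomConfigError("arm region overlaps the chest (breathing) mask")

    n_frames = max(2, int(round(config.duration_s * config.frame_rate)))
    times = np.arange(n_frames) / config.frame_rate

    distract_masks = []
    for d in config.distractors:
        m = _ellipse_r2(shape, d.center, d.axes) <= 1.0
        if (m & chest_mask).any():
            raise PhantomConfigError("distractor region overlaps the chest mask")
        distract_masks.append(m)

    base = np.full(shape, config.background_mm)
    base[torso] = config.torso_depth_mm - config.dome_mm * dome[torso]
    base[arm_mask] = config.torso_depth_mm + config.arm_offset_mm
    body = torso | arm_mask

    def breath_disp(t: float) -> np.ndarray:
        u = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / config.period_s))
        disp = env * u
        if config.abd_scale > 0:
            u_abd = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t - config.abd_lag_s) / config.period_s))
            disp = disp + env_abd * u_abd
        return disp

    cal = config.calibration
    pix_area = (cal.slope * base + cal.intercept) ** 2

    depths = np.empty((n_frames,) + shape)
    truth_vol = np.empty(n_frames)
    disp_prev = None
    resp_masks: list[np.ndarray] = []
    for i, t in enumerate(times):
        disp = breath_disp(t)
        truth_vol[i] = float((disp * pix_area).sum() / MM3_PER_ML)
        if disp_prev is not None:
            resp_masks.append(
                np.abs(disp - disp_prev) > config.displacement_floor_mm
            )
        disp_prev = disp

        d = base - disp
        if config.sway_mm > 0:
            d = d - np.where(
                body, config.sway_mm * np.sin(2.0 * np.pi * t / config.sway_period_s), 0.0
            )
        for dm, dist in zip(distract_masks, config.distractors):
            if dist.start_s <= t < dist.start_s + dist.duration_s:
                d = d - np.where(dm, dist.delta_mm, 0.0)
        if config.noise_sd_mm > 0:
            d = d + rng.normal(0.0, config.noise_sd_mm, size=shape)
        if config.quant_mm > 0:
            d = np.round(d / config.quant_mm) * config.quant_mm
        depths[i] = np.clip(d, 1.0, None)

    # relative to the first frame, matching the estimator's cumulative series
    truth_vol -= truth_vol[0]
    waveform = VolumeWaveform(
        times=times, values=np.diff(truth_vol, prepend=truth_vol[0]), cumulative=truth_vol
    )

    # analytic tidal volume: peak-to-valley of one cycle, sampled densely
    tt = np.linspace(0.0, config.period_s, 512, endpoint=False)
    cyc = np.array([(breath_disp(t) * pix_area).sum() / MM3_PER_ML for t in tt])
    tidal_ml = float(cyc.max() - cyc.min())
    breath_count = int(np.floor((config.duration_s + 1e-9) / config.period_s))

    seq = DepthSequence.from_array(depths, config.frame_rate, times)
    truth = PhantomTruth(
        chest_mask=chest_mask,
        torso_mask=torso,
        arm_mask=arm_mask,
        resp_masks=resp_masks,
        waveform=waveform,
        tidal_ml=tidal_ml,
        breath_count=breath_count,
        envelope=env + env_abd,
    )
    return seq, truth


_SCENARIOS = ("clean", "arms_attached", "abdominal_weak", "jolt", "noisy")


def scenario(name: str, shape: tuple[int, int] = (120, 160),
             duration_s: float | None = None, seed: int = 0, **overrides) -> PhantomConfig:
    """Preset phantom configurations for the pipeline's stress cases.

    ``clean``         baseline recovery: no arms, no distractors, no noise.
    ``arms_attached`` arms resting against the torso within 5 mm of its
                      depth: the ambiguous-boundary case for the spatial
                      stage.
    ``abdominal_weak`` a weak, phase-lagged abdominal patch whose
                      per-frame change sits below the static motion
                      threshold.
    ``jolt``          brief strong displacements on the arm plus a slow
                      postural sway: the non-respiratory-movement case.
    ``noisy``         sensor-noise robustness (1.5 mm Gaussian + 1 mm
                      quantization).

    Presets default to the 120 x 160 desk scale; pass ``shape`` to change.
    """
    if name not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {_SCENARIOS}")
    # the pixel-size model is native to the 320-column sensor; at a coarser
    # rendering each pixel's physical footprint grows accordingly
    factor = 320.0 / shape[1]
    cal = PixelCalibration(slope=0.0041 * factor, intercept=0.0046 * factor)
    cfg = PhantomConfig(shape=shape, seed=seed, calibration=cal)
    if name == "clean":
        cfg = replace(cfg, duration_s=120.0, arms=False, noise_sd_mm=0.0)
    elif name == "arms_attached":
        cfg = replace(cfg, duration_s=2.0, arms=True, arm_offset_mm=3.0)
    elif name == "abdominal_weak":
        cfg = replace(
            cfg, duration_s=40.0, arms=False, abd_scale=0.3, abd_lag_s=0.5
        )
    elif name == "jolt":
        cfg = replace(
            cfg,
            duration_s=40.0,
            arms=True,
            sway_mm=2.0,
            distractors=[
                Distractor(start_s=10.0, duration_s=0.19, center=(0.55, 0.13),
                           axes=(0.18, 0.055), delta_mm=8.0),
                Distractor(start_s=24.0, duration_s=0.19, center=(0.55, 0.87),
                           axes=(0.18, 0.055), delta_mm=8.0),
            ],
        )
    elif name == "noisy":
        cfg = replace(cfg, duration_s=120.0, arms=True, noise_sd_mm=1.5)
    if duration_s is not None:
        cfg = replace(cfg, duration_s=duration_s)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
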