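"""Run configuration: every tunable of the pipeline in one flat record.

Serializes to a plain ``key = value`` text format and back, losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .levelset import ChanVeseParams
from .shape_prior import SegmentParams
from .temporal import TemporalParams
from .volume import PixelCalibration

METHODS = ("spatial", "temporal", "adaptive")


@dataclass
class RunConfig:
    """Pipeline parameters with their documented valid ranges.

    The level-set weights are dimensionless and act on unit-normalized
    images; ``th`` is the adaptive weight cap (pixels of SDF depth);
    the calibration slope/intercept are the pixel-size model's mm
    coefficients; ``time_offset_s`` is the constant clock shift applied
    to the estimate when evaluating against a reference.
    """

    method: str = "adaptive"
    seed: int = 0
    # Chan-Vese numerics (shared by spatial and temporal stages)
    lambda_in: float = 1.0
    lambda_out: float = 1.0
    mu: float = 0.2
    eps: float = 1.5
    dt: float = 0.5
    max_iter: int = 200
    tol: float = 1e-3
    reinit_every: int = 10
    # spatial stage
    lambda_shape: float = 0.5
    # temporal stage
    lambda_region: float = 1.0
    lambda_out_temporal: float = 1.2
    dt_temporal: float = 1.0
    eps_region: float = 10.0
    th: float = 1.0
    smooth_sigma: float = 2.0
    time_window: int = 3
    growth_band: float = 1.5
    noise_factor: float = 1.8
    retain_floor: float | None = None
    # volume stage
    cal_slope: float = 0.0041
    cal_intercept: float = 0.0046
    sign_convention: str = "inhale_positive"
    detrend: bool = False
    min_duration_s: float = 1.0
    min_prominence_ml: float = 50.0
    # evaluation
    time_offset_s: float = 0.0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.sign_convention not in ("inhale_positive", "camera"):
            raise ValueError("unknown sign convention")
        if self.lambda_shape < 0 or self.lambda_region < 0:
            raise ValueError("lambda weights must be >= 0")
        if self.min_duration_s < 0 or self.min_prominence_ml < 0:
            raise ValueError("breath filters must be >= 0")
        # delegate range checks for the shared numerics
        self.chan_vese_params()
        self.calibration()

    def chan_vese_params(self) -> ChanVeseParams:
        return ChanVeseParams(
            lambda_in=self.lambda_in,
            lambda_out=self.lambda_out,
            mu=self.mu,
            eps=self.eps,
            dt=self.dt,
            max_iter=self.max_iter,
            tol=self.tol,
            reinit_every=self.reinit_every,
        )

    def segment_params(self) -> SegmentParams:
        return SegmentParams(cv=self.chan_vese_params(), lambda_shape=self.lambda_shape)

    def temporal_params(self) -> TemporalParams:
        cv = self.chan_vese_params()
        from dataclasses import replace

        cv = replace(cv, lambda_out=self.lambda_out_temporal, dt=self.dt_temporal,
                     max_iter=120)
        return TemporalParams(
            cv=cv,
            lambda_region=self.lambda_region,
            eps_region=self.eps_region,
            th=self.th,
            smooth_sigma=self.smooth_sigma,
            time_window=self.time_window,
            growth_band=self.growth_band,
            noise_factor=self.noise_factor,
            retain_floor=self.retain_floor,
        )

    def calibration(self) -> PixelCalibration:
        return PixelCalibration(slope=self.cal_slope, intercept=self.cal_intercept)

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            import ast

            kwargs[key] = ast.literal_eval(value.strip())
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())
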