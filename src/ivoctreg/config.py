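"""Run configuration: every tunable of the registration pipeline in one place.

Hyperparameters that would normally be tuned on a validation set (smoothing
width, DTW feature weights, NCC channel weights, shape-regularization
strength) are all exposed here with documented defaults; a YAML/JSON file
can override any subset and is fully validated before any stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

from .circumferential import DEFAULT_CHANNEL_WEIGHTS, DEFAULT_LAMBDA_SHAPE, DEFAULT_MAX_STEP_DEG
from .dtw import DEFAULT_WEIGHTS
from .errors import SchemaError
from .phantom import PhantomConfig


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; defaults reproduce the built-in demo."""

    sigma_frames: float = 2.0  # longitudinal Gaussian smoothing width, frames
    dtw_weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS
    dtw_band: float | None = None  # optional Sakoe-Chiba half-width, retained frames
    ncc_channel_weights: tuple[float, float, float] = DEFAULT_CHANNEL_WEIGHTS
    lambda_shape: float = DEFAULT_LAMBDA_SHAPE
    max_step_deg: float = DEFAULT_MAX_STEP_DEG
    landmark_rule: str = "both"  # feature required in both modalities, or "either"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.sigma_frames < 0:
            raise SchemaError("sigma_frames must be >= 0")
        if len(tuple(self.dtw_weights)) != 4 or any(w < 0 for w in self.dtw_weights):
            raise SchemaError("dtw_weights must be 4 nonnegative numbers")
        if not any(w > 0 for w in self.dtw_weights):
            raise SchemaError("dtw_weights must include at least one positive weight")
        if self.dtw_band is not None and self.dtw_band < 0:
            raise SchemaError("dtw_band must be >= 0 or null")
        if len(tuple(self.ncc_channel_weights)) != 3 or any(
            w < 0 for w in self.ncc_channel_weights
        ):
            raise SchemaError("ncc_channel_weights must be 3 nonnegative numbers")
        if sum(self.ncc_channel_weights) <= 0:
            raise SchemaError("ncc_channel_weights must sum to > 0")
        if self.lambda_shape < 0:
            raise SchemaError("lambda_shape must be >= 0")
        if self.max_step_deg < 0:
            raise SchemaError("max_step_deg must be >= 0")
        if self.landmark_rule not in ("both", "either"):
            raise SchemaError("landmark_rule must be 'both' or 'either'")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise SchemaError("config document must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        data = dict(data)
        if "phantom" in data and isinstance(data["phantom"], dict):
            pknown = {f.name for f in fields(PhantomConfig)}
            punknown = set(data["phantom"]) - pknown
            if punknown:
                raise SchemaError(
                    f"unknown phantom config key(s): {', '.join(sorted(punknown))}"
                )
            for key in ("branch_width_deg", "calcium_arc_deg"):
                if key in data["phantom"]:
                    data["phantom"][key] = tuple(data["phantom"][key])
            data["phantom"] = PhantomConfig(**data["phantom"])
        for key in ("dtw_weights", "ncc_channel_weights"):
            if key in data:
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"invalid config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dtw_weights"] = list(self.dtw_weights)
        d["ncc_channel_weights"] = list(self.ncc_channel_weights)
        d["phantom"]["branch_width_deg"] = list(self.phantom.branch_width_deg)
        d["phantom"]["calcium_arc_deg"] = list(self.phantom.calcium_arc_deg)
        return d
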