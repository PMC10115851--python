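"""Pipeline configuration: defaults, YAML files and overrides.

Every tunable of the pipeline has a documented default equal to the
published operating point where one exists (scale factor 200, Gaussian
sigma 0.5, 50 MI bins, gradient-descent step 1 for 50 iterations with
convergence 1e-6 over a window of 10, elastic tolerance 1e-5 for 15
iterations, B-spline grid 8 or 1 voxels, mask dilation 10 or 1 voxels,
K = 3 tissue classes), so the pipeline runs with no per-case tuning.
Values may be overridden from a YAML file; command-line flags override
file values, which override defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import InputError
from .intensity import HistogramMatchConfig
from .locator import LocatorConfig
from .registration import ElasticConfig, RigidConfig

__all__ = ["ExtractionOptions", "PipelineConfig", "TissueOptions"]


@dataclass(frozen=True)
class ExtractionOptions:
    keep_largest_component: bool = True
    max_hole_voxels: int = 27
    enable_centering: bool = True
    enable_elastic: bool = True


@dataclass(frozen=True)
class TissueOptions:
    k: int = 3
    contrast: str = "t1_like"


@dataclass
class PipelineConfig:
    """Aggregated configuration of every pipeline stage."""

    histogram_matching: HistogramMatchConfig = field(default_factory=HistogramMatchConfig)
    locator: LocatorConfig = field(default_factory=LocatorConfig)
    rigid: RigidConfig = field(default_factory=RigidConfig)
    elastic: ElasticConfig | None = None  # None -> pick regime from the target
    extraction: ExtractionOptions = field(default_factory=ExtractionOptions)
    tissue: TissueOptions = field(default_factory=TissueOptions)
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        blocks = {
            "histogram_matching": HistogramMatchConfig,
            "locator": LocatorConfig,
            "rigid": RigidConfig,
            "elastic": ElasticConfig,
            "extraction": ExtractionOptions,
            "tissue": TissueOptions,
        }
        for key, value in raw.items():
            if key in ("seed", "verbosity"):
                kwargs[key] = int(value)
            elif key in blocks:
                if not isinstance(value, dict):
                    raise InputError(f"config block {key!r} must be a mapping")
                known = {f.name for f in dataclasses.fields(blocks[key])}
                unknown = set(value) - known
                if unknown:
                    raise InputError(f"unknown keys in config block {key!r}: {sorted(unknown)}")
                kwargs[key] = blocks[key](**value)
            else:
                raise InputError(f"unknown config block {key!r}")
        return cls(**kwargs)

    def snapshot(self) -> dict:
        """JSON-serializable copy of the full configuration."""
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if hasattr(obj, "value"):
                return obj.value
            return obj
        return {
            "histogram_matching": enc(self.histogram_matching),
            "locator": enc(self.locator),
            "rigid": enc(self.rigid),
            "elastic": enc(self.elastic) if self.elastic else "auto",
            "extraction": enc(self.extraction),
            "tissue": enc(self.tissue),
            "seed": self.seed,
        }
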