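"""Run configuration: a flat YAML file describing one restoration pipeline.

A run is: obtain an image (phantom spec or input path) → corrupt with
multiplicative noise → denoise with one of the four methods → evaluate.
The manifest written next to the outputs contains every parameter plus the
seed, so a run is bit-identically reproducible from its manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .baselines import M1Params, M3Params, M4Params
from .elastica import ElasticaParams
from .noise import NoiseSpec

__all__ = ["RunConfig", "load_config", "write_manifest"]

_PARAM_CLASSES = {"m1": M1Params, "m2": ElasticaParams, "m3": M3Params, "m4": M4Params}


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    method: str = "m2"
    input_path: Optional[str] = None
    phantom: Optional[dict] = None  # {"kind": "shapes"|"ramp"|"texture", ...}
    noise: dict = field(default_factory=lambda: {"family": "uniform_speckle", "sigma2": 0.1})
    method_params: dict = field(default_factory=dict)
    seed: int = 0
    floor: float = 1.0
    spacing: float = 10.0
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.method not in _PARAM_CLASSES:
            raise ValueError(f"method: must be one of {sorted(_PARAM_CLASSES)}")
        if (self.input_path is None) == (self.phantom is None):
            raise ValueError("exactly one of input_path / phantom must be set")
        NoiseSpec(**{**self.noise, "seed": self.seed})  # validate noise block
        self.build_params()  # validate method block

    def build_params(self):
        cls = _PARAM_CLASSES[self.method]
        kwargs = dict(self.method_params)
        if self.method in ("m1", "m2"):
            kwargs.setdefault("spacing", self.spacing)
        return cls(**kwargs)

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(**{**self.noise, "seed": self.seed})


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def write_manifest(config: RunConfig, out_dir) -> Path:
    """Write the reproducibility manifest (all parameters + seed) as JSON."""
    out = Path(out_dir) / "manifest.json"
    payload = asdict(config)
    payload["method_params_resolved"] = asdict(config.build_params())
    out.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out
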