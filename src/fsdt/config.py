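"""Pipeline configuration: one YAML-serializable object holding every
threshold and stage parameter; no threshold is hard-coded elsewhere."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from fsdt.cnn import ModelConfig
from fsdt.phantom import PhantomConfig

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Malformed configuration (unknown or invalid keys)."""


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the detection pipeline, serialized losslessly to YAML."""

    grid_rows: int = 2
    grid_cols: int = 5
    denoise_method: str = "median"
    denoise_radius: int = 1
    tail_fraction: float = 0.05
    u_floor: float = 0.02
    tau_seg: float = 0.5
    theta_img: float = 0.1
    margin: float = 0.2
    min_overlap_px: int = 10
    seed: int = 0
    version: str = "1"
    model: ModelConfig = field(default_factory=ModelConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_cls, payload, path):
            known = {f.name: f for f in fields(dc_cls)}
            unknown = set(payload) - set(known)
            if unknown:
                raise ConfigError(
                    f"unknown config key(s) {sorted(unknown)} under '{path or 'root'}'")
            kwargs = {}
            for key, value in payload.items():
                if known[key].name == "model":
                    kwargs[key] = build(ModelConfig, value or {}, f"{path}model.")
                elif known[key].name == "phantom":
                    value = dict(value or {})
                    for pair_key in ("head_axis_fractions", "tumor_count_range",
                                     "tumor_radius_range", "tumor_contrast_range"):
                        if pair_key in value and value[pair_key] is not None:
                            value[pair_key] = tuple(value[pair_key])
                    kwargs[key] = build(PhantomConfig, value, f"{path}phantom.")
                else:
                    kwargs[key] = value
            return dc_cls(**kwargs)

        try:
            return build(cls, data or {}, "")
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
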