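"""Run configuration: one serialisable object from which a simulation is
bitwise reproducible given its seed."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ModelParams, ConfigurationError
from .woundgen import WoundSpec

__all__ = ["RunConfig", "load_config"]

_TOP_KEYS = {"params", "wound", "seed", "tissue_kind", "out"}


@dataclass
class RunConfig:
    """A run configuration; ``wound`` is None when the wound should be
    derived from the params block (circle of ``wound_radius``, or an
    ellipse when ``wound_aspect`` != 1)."""

    params: ModelParams = field(default_factory=ModelParams)
    wound: WoundSpec | None = None
    seed: int = 0
    tissue_kind: str = "voronoi"
    out: str | None = None

    def derived(self) -> dict:
        """Echo of derived quantities for logging/validation."""
        p = self.params
        return {"gamma": p.gamma, "p0": p.p0, "k_s": p.k_s,
                "node_spacing": p.node_spacing}

    def to_dict(self) -> dict:
        wound = None
        if self.wound is not None:
            wound = {"shape": self.wound.shape, "radius": self.wound.radius,
                     "area": self.wound.area, "aspect": self.wound.aspect,
                     "lobes": self.wound.lobes, "depth": self.wound.depth,
                     "center": list(self.wound.center)}
        return {"params": self.params.to_dict(), "wound": wound,
                "seed": self.seed, "tissue_kind": self.tissue_kind,
                "out": self.out}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        params = ModelParams.from_dict(d.get("params", {}) or {})
        wound = (WoundSpec.from_dict(d["wound"]) if d.get("wound") else None)
        return cls(params=params, wound=wound, seed=int(d.get("seed", 0)),
                   tissue_kind=str(d.get("tissue_kind", "voronoi")),
                   out=d.get("out"))


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration; unknown keys are rejected and
    values may carry unit suffixes (``k_p: "4/hr"``)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text) or {}
    else:
        data = json.loads(text) if text.strip() else {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    return RunConfig.from_dict(data)
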