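"""Run configuration: one structured YAML file drives every pipeline stage."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from xrfquant.calibrate import NetSpec, TrainConfig
from xrfquant.errors import ConfigError
from xrfquant.simulate import DetectorModel
from xrfquant.spectra import RegionSpec


@dataclass
class RunConfig:
    outdir: Path = Path("runs/default")
    seed: int = 0
    regions: RegionSpec = field(
        default_factory=lambda: RegionSpec([(10.35, 10.70), (12.40, 12.85)]))
    detector: DetectorModel = field(default_factory=DetectorModel)
    net: NetSpec = field(default_factory=NetSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    z_threshold: float = 2.5
    agreement_threshold_pct: float = 20.0
    limits_n: int = 3

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.agreement_threshold_pct <= 0:
            raise ConfigError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        if "outdir" in raw:
            kwargs["outdir"] = Path(raw["outdir"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "regions" in raw:
            kwargs["regions"] = RegionSpec(raw["regions"])
        if "detector" in raw:
            kwargs["detector"] = DetectorModel(**raw["detector"])
        if "net" in raw:
            d = dict(raw["net"])
            if "hidden_sizes" in d:
                d["hidden_sizes"] = tuple(d["hidden_sizes"])
            kwargs["net"] = NetSpec(**d)
        if "train" in raw:
            t = dict(raw["train"])
            t["learning_rate"] = float(t.get("learning_rate", 1e-5))
            kwargs["train"] = TrainConfig(**t)
        for key in ("z_threshold", "agreement_threshold_pct", "limits_n"):
            if key in raw:
                kwargs[key] = type(getattr(cls(), key))(raw[key])
        unknown = set(raw) - {"outdir", "seed", "regions", "detector", "net",
                              "train", "z_threshold",
                              "agreement_threshold_pct", "limits_n"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "regions": [list(w) for w in self.regions.windows],
            "detector": vars(self.detector).copy(),
            "net": {"hidden_sizes": list(self.net.hidden_sizes),
                    "activation": self.net.activation,
                    "dropout_p": self.net.dropout_p,
                    "n_outputs": self.net.n_outputs},
            "train": {"learning_rate": self.train.learning_rate,
                      "n_epochs": self.train.n_epochs,
                      "eval_every": self.train.eval_every,
                      "seed": self.train.seed},
            "z_threshold": self.z_threshold,
            "agreement_threshold_pct": self.agreement_threshold_pct,
            "limits_n": self.limits_n,
        }

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
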