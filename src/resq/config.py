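"""Run configuration: schema-validated YAML with documented defaults.

Every numeric default that is not forced by the method itself lives here
in one place: headline graph settings (4.5 Å neighbor cutoff, 5.0 Å Cα
cutoff, 25 features, uniform edge weights) and SGD hyperparameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from resq.crf import SGDHyper
from resq.graph import EDGE_CLASSES

VALID_FEATURE_SETS = (25, 5)
VALID_WEIGHT_MODES = ("uniform", "ss", "grid")


@dataclass
class RunConfig:
    neighbor_cutoff: float = 4.5
    ca_cutoff: float = 5.0
    feature_set: int = 25
    weight_mode: str = "uniform"
    edge_weights: dict[str, float] = field(default_factory=lambda: {c: 1.0 for c in EDGE_CLASSES})
    learning_rate: float = 0.05
    epochs: int = 50
    l2_penalty: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neighbor_cutoff <= 0:
            raise ValueError(f"neighbor_cutoff must be positive, got {self.neighbor_cutoff}")
        if self.ca_cutoff <= 0:
            raise ValueError(f"ca_cutoff must be positive, got {self.ca_cutoff}")
        if self.feature_set not in VALID_FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {VALID_FEATURE_SETS}")
        if self.weight_mode not in VALID_WEIGHT_MODES:
            raise ValueError(f"weight_mode must be one of {VALID_WEIGHT_MODES}")
        unknown = set(self.edge_weights) - set(EDGE_CLASSES)
        if unknown:
            raise ValueError(f"unknown edge classes in edge_weights: {sorted(unknown)}")
        for c, w in self.edge_weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"edge weight for {c} must be in [0, 1], got {w}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def hyper(self) -> SGDHyper:
        return SGDHyper(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            l2_penalty=self.l2_penalty,
            seed=self.seed,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
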