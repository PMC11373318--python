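"""Run configuration: hyperparameters, marker panel, geometry, validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: Default 38-marker Hyperion panel (glioma-oriented: tumour, immune,
#: vascular and nuclear markers). Order defines the expression vector layout.
DEFAULT_MARKERS: tuple[str, ...] = (
    "SMAa", "CDK4", "NESTIN", "GFAP", "SOX2", "SOX10", "OLIG2", "EGFR",
    "PDGFRA", "cMYC", "MET", "P53", "PTEN", "ATRX", "IDH1R132H", "Ki67",
    "VIM", "CD44", "CD68", "CD74", "IBA1", "P2Y12", "TMEM119", "CD163",
    "CD14", "CD16", "CD11b", "HLA-DR", "CD3", "CD4", "CD8a", "CD20",
    "CD45", "CD56", "CD31", "FOXP3", "DNA1", "DNA3",
)

FID_EMBEDDINGS = ("seeded_random_conv", "handcrafted", "external_pretrained")


class ConfigError(ValueError):
    """A run-configuration field violates an invariant."""


@dataclass
class RunConfig:
    """Hyperparameters and geometry for a training/evaluation run.

    Defaults follow the published training setup: Adam with learning rate
    1e-4 and first-moment decay 0.5, batch size 16, loss weights
    lambda1 = lambda2 = 1 and lambda3 = 0.01, 256 px context patches centred
    on 128 px expression spots, and a 38-marker panel.
    """

    patch_size_px: int = 256
    spot_size_px: int = 128
    noise_dim: int = 128
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 0.01
    learning_rate: float = 1e-4
    adam_beta1: float = 0.5
    batch_size: int = 16
    epochs: int = 5
    seed: int = 0
    marker_names: tuple[str, ...] = field(default_factory=lambda: DEFAULT_MARKERS)
    fid_embedding: str = "seeded_random_conv"

    def __post_init__(self):
        self.marker_names = tuple(self.marker_names)
        self.validate()

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def validate(self) -> None:
        import math

        if self.patch_size_px < self.spot_size_px:
            raise ConfigError(
                f"patch_size_px ({self.patch_size_px}) must be >= "
                f"spot_size_px ({self.spot_size_px})")
        for name in ("patch_size_px", "spot_size_px"):
            if getattr(self, name) % 2 != 0 or getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive even integer")
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if not (0 <= self.adam_beta1 < 1):
            raise ConfigError("adam_beta1 must lie in [0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be a positive integer")
        if self.epochs < 1:
            raise ConfigError("epochs must be a positive integer")
        if self.noise_dim < 1:
            raise ConfigError("noise_dim must be a positive integer")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ConfigError("marker_names must be unique")
        if self.fid_embedding not in FID_EMBEDDINGS:
            raise ConfigError(
                f"fid_embedding must be one of {FID_EMBEDDINGS}, "
                f"got {self.fid_embedding!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_names"] = list(self.marker_names)
        return d


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unspecified fields take the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
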