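"""Validated run configuration for the command-line workflows."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .network import NetworkConfig


class NetworkSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    embed_dim: int = 256
    message_rounds: int = 2
    fc_dim: int = 256
    condensed_dim: int = 32
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3

    def to_network_config(self, seed: int) -> NetworkConfig:
        return NetworkConfig(seed=seed, **self.model_dump())


class RunConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""
    model_config = ConfigDict(extra="forbid")

    ligand_dir: str | None = None
    pocket_dir: str | None = None
    index_file: str | None = None
    mode: str = "train"
    network: NetworkSettings = Field(default_factory=NetworkSettings)
    tune: bool = False
    k: int = 10
    seed: int = 0
    z_threshold: float = 3.0
    filter_outliers: bool = True
    keep_ic50: bool = False
    pocket_radius: float = 6.0
    output_dir: str = "seqbind_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(out_dir, config: RunConfig, extra: dict | None = None) -> None:
    """Reproducibility manifest: config hash, seed and library versions."""
    import numpy
    import sklearn
    import xgboost

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"numpy": numpy.__version__, "sklearn": sklearn.__version__,
                     "xgboost": xgboost.__version__},
    }
    if extra:
        manifest.update(extra)
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
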