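"""Config file parsing (JSON/YAML), packaged default configs and run
manifests.

JSON is the canonical emitted format; YAML is accepted on input,
detected by file extension.  Two configs ship with the package:

* ``paper_defaults`` — the model parameterization of the soybean-aphid /
  milkweed-aphid / *A. certus* system;
* ``paper_like`` — the synthetic-study generator truth.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import yaml

from .params import InvalidParameterError, ModelParams
from .synth import GeneratorConfig

__all__ = [
    "load_config",
    "dump_config",
    "load_model_params",
    "save_model_params",
    "paper_defaults_config",
    "paper_like_generator_config",
    "load_generator_config",
    "write_manifest",
]


def load_config(path) -> dict:
    """Read a JSON (.json) or YAML (.yaml/.yml) mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    elif path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        raise InvalidParameterError(
            f"unrecognized config extension {path.suffix!r} (use .json/.yaml/.yml)"
        )
    if not isinstance(data, dict):
        raise InvalidParameterError(f"config {path} is not a mapping")
    return data


def dump_config(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def _packaged(name: str) -> dict:
    with resources.files("eggsink.configs").joinpath(name).open() as fh:
        return json.load(fh)


def paper_defaults_config() -> dict:
    """Flat model-parameter config with the packaged default values."""
    return _packaged("paper_defaults.json")


def paper_like_generator_config() -> dict:
    """Packaged generator truth for the synthetic study."""
    return _packaged("paper_like.json")


def load_model_params(path=None) -> ModelParams:
    """Model parameters from a config file, or the packaged defaults."""
    cfg = load_config(path) if path is not None else paper_defaults_config()
    return ModelParams.from_flat_dict(cfg)


def save_model_params(params: ModelParams, path) -> None:
    dump_config(params.to_flat_dict(), path)


def load_generator_config(path=None, seed: int | None = None) -> GeneratorConfig:
    cfg = load_config(path) if path is not None else paper_like_generator_config()
    gc = GeneratorConfig.from_dict(cfg)
    return gc.with_seed(seed) if seed is not None else gc


def write_manifest(
    out_path, command: str, config: dict, seed: int | None, outputs: list
) -> dict:
    """Record what a run did: command, config hash, seed, version, outputs."""
    from . import __version__

    manifest = {
        "command": command,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(p) for p in outputs],
    }
    Path(out_path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
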