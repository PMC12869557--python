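"""Run configuration, overrides and provenance manifests shared by the CLI.

A run is described by a YAML config (any subset of keys; defaults fill the
rest), optionally modified by dotted-path overrides, and every run writes
a manifest recording the resolved config tree, package version, seed,
timestamps and SHA-256 digests of its output files — enough to re-run a
deterministic stage bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .materials import default_constants

__all__ = ["load_config", "apply_overrides", "RunManifest", "write_manifest"]


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a YAML run config; a missing argument yields an empty config."""
    if path is None:
        return {}
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    with open(p, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping at top level")
    return data


def apply_overrides(config: dict[str, Any], overrides: list[str]) -> dict[str, Any]:
    """Apply ``key.path=value`` assignments; values parsed as YAML scalars."""
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override must look like key.path=value, got {item!r}")
        dotted, raw = item.split("=", 1)
        keys = dotted.strip().split(".")
        node = config
        for key in keys[:-1]:
            node = node.setdefault(key, {})
            if not isinstance(node, dict):
                raise ValueError(f"cannot descend into non-mapping at {key!r}")
        node[keys[-1]] = yaml.safe_load(raw)
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Provenance record for one CLI run."""

    def __init__(self, command: str, config: dict[str, Any], seed: int | None = None):
        self.command = command
        self.config = config
        self.seed = seed
        self.started = datetime.now(timezone.utc).isoformat()
        self.outputs: dict[str, str] = {}

    def register_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[p.name] = _sha256(p)

    def as_dict(self) -> dict[str, Any]:
        return {
            "command": self.command,
            "package": "organoflux",
            "version": __version__,
            "seed": self.seed,
            "started_utc": self.started,
            "finished_utc": datetime.now(timezone.utc).isoformat(),
            "config": self.config,
            "constants": default_constants(),
            "outputs": self.outputs,
        }


def write_manifest(manifest: RunManifest, directory: str | Path) -> Path:
    path = Path(directory) / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest.as_dict(), fh, indent=2, default=str)
    return path
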