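"""Run manifests and delimited table I/O.

Every CLI command writes its outputs into a result directory containing
exactly one ``manifest.yaml`` sufficient to re-run the command: the command
line, a SHA-256 digest of the resolved configuration, seeds and iteration
counts, the package version and a timestamp.  Tables are UTF-8 CSV with a
header row; floats are written at full repr precision so re-parsing an
emitted table recovers the in-memory values.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__

__all__ = ["RunManifest", "write_table", "read_table", "config_digest"]


def config_digest(resolved_config_yaml: str) -> str:
    return hashlib.sha256(resolved_config_yaml.encode()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_digest: str
    seed: int | None = None
    iterations: int | None = None
    extra: Mapping[str, Any] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.yaml"
        payload = dataclasses.asdict(self)
        payload["extra"] = dict(payload["extra"])
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
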