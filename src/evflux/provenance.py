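"""Machine-readable run manifests.

Every CLI run writes one JSON manifest next to its outputs recording
the subcommand, the full parameter set, every seed, SHA-256 digests of
the inputs, per-stage record counts, the tool version and a timestamp —
enough to replay the run exactly.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    subcommand: str
    parameters: dict = dc_field(default_factory=dict)
    seed: int | None = None
    inputs: dict = dc_field(default_factory=dict)  # path -> sha256
    counts: dict = dc_field(default_factory=dict)  # stage -> records
    version: str = ""
    timestamp: str = ""

    def record_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def record_count(self, stage: str, n: int) -> None:
        self.counts[stage] = int(n)

    def write(self, path: str | Path) -> Path:
        from . import __version__

        self.version = self.version or __version__
        self.timestamp = self.timestamp or (
            _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"))
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))
        return path
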