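"""Structured line-delimited run logging and the run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger("delaystand")

__all__ = ["log_context", "RunManifest", "file_digest"]


def log_context(stage: str, **params) -> dict:
    """Emit one structured log entry for an analysis stage; returns the record."""
    record = {"stage": stage, **params}
    logger.info(json.dumps(record, default=str, sort_keys=True))
    return record


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    experiment: str
    seed: int
    configs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = ""

    def record_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str,
                                         sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()
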