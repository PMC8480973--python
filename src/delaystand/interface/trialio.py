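"""Trial record container and lossless CSV + JSON-sidecar round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialRecord", "SchemaError", "read_trial", "write_trial", "CHANNELS"]

#: canonical channel order; time_s is mandatory, the rest optional but typed
CHANNELS = ("time_s", "theta_deg", "theta_dot_dps", "torque_nm",
            "delay_ms", "evs_ma", "emg_au", "button")


class SchemaError(ValueError):
    """A trial file violated the tabular schema; the message names the column."""


@dataclass
class TrialRecord:
    """Synchronously sampled multichannel trial: the universal exchange object."""

    fs: float
    time_s: np.ndarray
    theta_deg: np.ndarray | None = None
    theta_dot_dps: np.ndarray | None = None
    torque_nm: np.ndarray | None = None
    delay_ms: np.ndarray | None = None
    evs_ma: np.ndarray | None = None
    emg_au: np.ndarray | None = None
    button: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in CHANNELS:
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr)
            setattr(self, name, arr)
            if len(arr) != n:
                raise SchemaError(
                    f"column '{name}' has length {len(arr)}, expected {n} (time_s)"
                )
        if n > 1 and np.any(np.diff(self.time_s) <= 0):
            raise SchemaError("column 'time_s' is not strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def to_frame(self) -> pd.DataFrame:
        cols = {name: getattr(self, name) for name in CHANNELS
                if getattr(self, name) is not None}
        return pd.DataFrame(cols)


def write_trial(trial: TrialRecord, path: str | Path) -> Path:
    """Write CSV channels plus a ``.json`` sidecar with fs and metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trial.to_frame().to_csv(path, index=False, float_format="%.10g")
    sidecar = {"fs": trial.fs, "meta": _jsonable(trial.meta)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trial(path: str | Path) -> TrialRecord:
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError("missing column 'time_s'")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar '{sidecar_path.name}' (sample rate unknown)")
    sidecar = json.loads(sidecar_path.read_text())
    fs = float(sidecar["fs"])
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.median(np.diff(t))
        if abs(dt - 1.0 / fs) > 0.01 / fs:
            raise SchemaError(
                f"column 'time_s' spacing {dt:.6g}s disagrees with sidecar fs={fs}"
            )
    kwargs = {name: df[name].to_numpy() for name in CHANNELS if name in df.columns}
    return TrialRecord(fs=fs, meta=sidecar.get("meta", {}), **kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
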