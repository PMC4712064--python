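"""CSV/JSON persistence for recordings, tables and run artifacts.

Recordings are stored as a two-column CSV (header = channel labels, one row
per sample, UTF-8, comma separator, '.' decimal) with a JSON sidecar
carrying the sampling rate, block schedule, simulation config and seed.
Every pipeline artifact gets a sidecar with provenance (config hash, seed,
package version) so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BlockSchedule, EmgRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_table",
    "ParseError",
    "provenance",
    "config_hash",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def save_recording(
    rec: EmgRecording,
    path: str | Path,
    schedule: BlockSchedule | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    path = Path(path)
    pd.DataFrame(rec.channels).to_csv(path, index=False, float_format="%.6f")
    meta: dict = {"sampling_rate": rec.sampling_rate, "n_samples": rec.n_samples}
    if schedule is not None:
        meta["schedule"] = schedule.to_dict()
    if config is not None:
        meta["config"] = config
    if seed is not None:
        meta["seed"] = seed
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_recording(path: str | Path) -> tuple[EmgRecording, dict]:
    """Read a recording CSV (+ sidecar if present); returns (recording, meta)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        names = header.split(",")
        if len(names) < 1 or any(not n for n in names):
            raise ParseError(f"{path}:1: malformed header {header!r}")
        columns: list[list[float]] = [[] for _ in names]
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(names):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(names)} fields, got {len(parts)}"
                )
            try:
                for col, val in zip(columns, parts):
                    col.append(float(val))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    fs = float(meta.get("sampling_rate", 512.0))
    rec = EmgRecording(
        channels={n: np.asarray(c) for n, c in zip(names, columns)},
        sampling_rate=fs,
    )
    return rec, meta


def save_table(
    table: pd.DataFrame, path: str | Path, provenance_meta: dict | None = None
) -> None:
    path = Path(path)
    table.to_csv(path, index=False)
    if provenance_meta is not None:
        sidecar_path(path).write_text(json.dumps(provenance_meta, indent=1))


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(config: dict, seed: int) -> dict:
    from . import __version__

    return {
        "config_hash": config_hash(config),
        "seed": seed,
        "affectemg_version": __version__,
    }
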