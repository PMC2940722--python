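"""Tab-separated serialization of spikes, MUA and result tables.

Spike events travel as TSV with a ``#``-prefixed key=value header block
holding the metadata needed to reinterpret them (pool index ranges, trial
count, trial length, seeds).  Any pipeline stage accepts files written by
either the simulator or the surrogate generator — they share this schema.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StructuralError
from .netsim import SpikeData

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_table",
    "write_manifest",
    "config_hash",
    "read_flat_config",
]

_SPIKE_COLUMNS = ["trial", "neuron_id", "pool", "time_ms"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_spikes(spikes: SpikeData, path: str | Path) -> None:
    """Write spike events as TSV with a metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in spikes.metadata.items():
            fh.write(f"# {key}={json.dumps(_jsonable(value))}\n")
        fh.write("\t".join(_SPIKE_COLUMNS) + "\n")
        ev = spikes.events
        for trial, nid, pool, t in zip(
            ev["trial"], ev["neuron_id"], ev["pool"], ev["time_ms"]
        ):
            fh.write(f"{trial}\t{nid}\t{pool}\t{t:.3f}\n")


def read_spikes(path: str | Path) -> SpikeData:
    """Read spike events written by :func:`write_spikes`."""
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            key, _, raw = body.partition("=")
            meta[key.strip()] = json.loads(raw)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        events = pd.read_csv(fh, sep="\t")
    missing = [c for c in _SPIKE_COLUMNS if c not in events.columns]
    if missing:
        raise StructuralError(f"spike table missing columns {missing}")
    if "pool_slices" in meta:
        meta["pool_slices"] = {k: tuple(v) for k, v in meta["pool_slices"].items()}
    return SpikeData(events=events, metadata=meta)


def write_table(df: pd.DataFrame, path: str | Path, footer: dict | None = None) -> None:
    """Write a result table as TSV, with an optional ``#`` footer block."""
    path = Path(path)
    with path.open("w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        if footer:
            for key, value in footer.items():
                fh.write(f"# {key}={json.dumps(_jsonable(value))}\n")


def read_flat_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` text config.

    Blank lines and ``#`` comments are ignored; values are parsed as JSON
    scalars where possible (numbers, booleans, null), otherwise kept as
    strings.
    """
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, raw = line.partition("=")
        if not sep:
            raise StructuralError(f"config line without '=': {line!r}")
        raw = raw.strip()
        try:
            out[key.strip()] = json.loads(raw)
        except json.JSONDecodeError:
            out[key.strip()] = raw
    return out


def config_hash(config) -> str:
    """Stable short hash of a (dataclass) configuration."""
    try:
        import dataclasses

        payload = dataclasses.asdict(config)
    except TypeError:
        payload = dict(config)
    blob = json.dumps(_jsonable(payload), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config, extra: dict | None = None) -> None:
    """Plain-text manifest: config hash, full config, package version."""
    from . import __version__

    path = Path(path)
    import dataclasses

    payload = {
        "config_hash": config_hash(config),
        "config": _jsonable(dataclasses.asdict(config)),
        "ctcflow_version": __version__,
    }
    if extra:
        payload.update(_jsonable(extra))
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
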