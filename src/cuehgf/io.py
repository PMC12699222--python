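"""Readers/writers for the pipeline's on-disk formats.

Formats: trial-sequence TSV, behaviour TSV, epoch container (``.npy`` array
plus ``.json`` sidecar), per-subject fit JSON, window-beta TSV and stats
JSON.  Every artifact embeds a provenance block (seed + config hash); for
TSVs this is a leading ``#`` comment line which readers skip, so
write(read(x)) round-trips the table exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EpochArray

__all__ = [
    "config_hash",
    "write_table",
    "read_sequence",
    "read_behavior",
    "write_epochs",
    "read_epochs",
    "write_json",
    "read_json",
]

SEQUENCE_COLUMNS = ("trial_index", "cue_side", "target_shape", "required_hand",
                    "validity", "block_p_valid", "soa_ms", "iti_ms")
BEHAVIOR_COLUMNS = ("trial_index", "validity", "rt_s", "rs", "correct", "missed")


class SchemaError(ValueError):
    """A file violates its documented schema."""


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_line(provenance: dict | None) -> str:
    return "# provenance: " + json.dumps(provenance or {}, sort_keys=True) + "\n"


def write_table(path, table: pd.DataFrame, provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_line(provenance))
        table.to_csv(fh, sep="\t", index=False)


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def _require_columns(table: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_sequence(path) -> pd.DataFrame:
    table = _read_table(path)
    _require_columns(table, SEQUENCE_COLUMNS, path)
    bad = table[~table["validity"].isin([0, 1])]
    if len(bad):
        raise SchemaError(f"{path}: non-binary validity at line(s) "
                          f"{ (bad.index + 2).tolist()[:5] }")
    if ((table["block_p_valid"] < 0) | (table["block_p_valid"] > 1)).any():
        raise SchemaError(f"{path}: block_p_valid outside [0, 1]")
    return table


def read_behavior(path) -> pd.DataFrame:
    table = _read_table(path)
    _require_columns(table, BEHAVIOR_COLUMNS, path)
    live = table[table["missed"] == 0]
    bad = live[live["rt_s"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: rt_s <= 0 on non-missed trial(s) at line(s) "
                          f"{(bad.index + 2).tolist()[:5]}")
    if not np.allclose(live["rs"], 1.0 / live["rt_s"], rtol=1e-6):
        raise SchemaError(f"{path}: rs must equal 1/rt_s on non-missed trials")
    return table


def write_epochs(path_base, epochs: EpochArray, provenance: dict | None = None) -> None:
    """Write ``<base>.npy`` (float32 voltages) and ``<base>.json`` sidecar."""
    base = Path(path_base)
    np.save(base.with_suffix(".npy"), epochs.data.astype(np.float32))
    sidecar = {
        "dims": ["trial", "channel", "time"],
        "shape": list(epochs.data.shape),
        "srate_hz": epochs.srate_hz,
        "t0_ms": epochs.t0_ms,
        "channel_names": list(epochs.channel_names),
        "provenance": provenance or {},
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_epochs(path_base) -> EpochArray:
    base = Path(path_base)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    for key in ("srate_hz", "t0_ms", "channel_names"):
        if key not in sidecar:
            raise SchemaError(f"{base.with_suffix('.json')}: missing field {key!r}")
    data = np.load(base.with_suffix(".npy")).astype(float)
    return EpochArray(
        data=data, srate_hz=float(sidecar["srate_hz"]),
        t0_ms=float(sidecar["t0_ms"]),
        channel_names=tuple(sidecar["channel_names"]),
    )


def write_json(path, payload: dict, provenance: dict | None = None) -> None:
    out = dict(payload)
    out["provenance"] = provenance or {}
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True, default=float))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
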