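"""HDF5 container I/O: lossless round trips of arrays, tables and metadata."""

from __future__ import annotations

import numpy as np
import h5py

SCHEMA = "spiraldense-container"
SCHEMA_VERSION = 1


def write_container(path, bundle: dict, meta: dict | None = None) -> None:
    """Write a (possibly nested) dict of arrays/scalars/strings to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["schema_version"] = SCHEMA_VERSION
        _write_group(f, bundle)
        if meta:
            g = f.require_group("meta")
            for k, v in meta.items():
                g.attrs[k] = v


def _write_group(group, mapping: dict) -> None:
    for key, value in mapping.items():
        if isinstance(value, dict):
            _write_group(group.require_group(key), value)
        elif isinstance(value, np.ndarray):
            group.create_dataset(key, data=value)
        elif isinstance(value, (bool, int, float, str, np.generic)):
            group.attrs[key] = value
        elif value is None:
            group.attrs[key] = "None"
        else:
            group.create_dataset(key, data=np.asarray(value))


def read_container(path, dataset: str | None = None):
    """Read a container back into nested dicts; or a single dataset by path."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema") != SCHEMA:
            raise ValueError(f"not a {SCHEMA} file: {path}")
        if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema version {f.attrs.get('schema_version')}"
            )
        if dataset is not None:
            return f[dataset][()]
        return _read_group(f)


def _read_group(group) -> dict:
    out = {}
    for k, v in group.attrs.items():
        if k in ("schema", "schema_version"):
            continue
        out[k] = v
    for k, v in group.items():
        out[k] = _read_group(v) if isinstance(v, h5py.Group) else v[()]
    return out
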