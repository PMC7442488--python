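"""Persistence: weight sets and traces in HDF5, tables in CSV, configs in
YAML, run manifests in JSON (with checksums for every artifact)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .circuit_model import Traces
from .connectivity import PATHWAYS, WeightSet
from .errors import ConfigurationError

__all__ = [
    "save_weights", "load_weights", "save_traces", "load_traces",
    "load_config_file", "save_config_file", "write_manifest", "sha256_of",
]


def save_weights(path, weights: WeightSet, attrs: dict | None = None) -> None:
    """Write a weight set to HDF5: one dataset per pathway plus its mask,
    the plastic-pathway list, and optional scalar attributes."""
    with h5py.File(path, "w") as f:
        g = f.create_group("weights")
        m = f.create_group("masks")
        for pw in PATHWAYS:
            g.create_dataset(pw, data=weights.matrix(pw))
            m.create_dataset(pw, data=weights.masks[pw])
        f.attrs["plastic"] = json.dumps(sorted(weights.plastic))
        f.attrs["version"] = __version__
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_weights(path) -> WeightSet:
    with h5py.File(path, "r") as f:
        mats = {f"w_{pw}": f["weights"][pw][...] for pw in PATHWAYS}
        masks = {pw: f["masks"][pw][...].astype(bool) for pw in PATHWAYS}
        plastic = frozenset(json.loads(f.attrs["plastic"]))
    return WeightSet(**mats, masks=masks, plastic=plastic)


def save_traces(path, traces: Traces, windows=None, kinds=None) -> None:
    """Write rate/current traces to HDF5 (datasets time, r_E, r_P, r_S, r_V,
    I_E_syn, I_D_syn, I_D0, calcium, optional phase windows/kinds)."""
    with h5py.File(path, "w") as f:
        for name in ("time", "r_E", "r_P", "r_S", "r_V",
                     "I_E_syn", "I_D_syn", "I_D0", "calcium"):
            f.create_dataset(name, data=getattr(traces, name))
        if windows is not None:
            f.create_dataset("phase_windows", data=np.asarray(windows))
        if kinds is not None:
            f.create_dataset("phase_kinds",
                             data=np.asarray(kinds, dtype=h5py.string_dtype()))


def load_traces(path) -> Traces:
    with h5py.File(path, "r") as f:
        return Traces(*(f[name][...] for name in
                        ("time", "r_E", "r_P", "r_S", "r_V",
                         "I_E_syn", "I_D_syn", "I_D0", "calcium")))


def save_config_file(path, config) -> None:
    """Serialize a (dataclass) configuration to YAML."""
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config),
                                         sort_keys=True))


def load_config_file(path, config_cls):
    """Load a YAML config into ``config_cls``; unknown keys are rejected
    with the offending key path named."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return _build_dataclass(config_cls, raw, key_path=Path(path).name)


def _build_dataclass(cls, raw: dict, key_path: str):
    import typing

    hints = typing.get_type_hints(cls)
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - field_names
    if unknown:
        raise ConfigurationError(
            f"{key_path}: unknown key(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(field_names)}")
    kwargs = {}
    for name, value in raw.items():
        if isinstance(value, dict):
            for cand in (hints[name], *typing.get_args(hints[name])):
                if dataclasses.is_dataclass(cand):
                    value = _build_dataclass(cand, value, f"{key_path}.{name}")
                    break
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{key_path}: {exc}") from exc


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, files: list[str], config_dict: dict,
                   seeds: dict, status: str = "complete") -> Path:
    """Write a JSON manifest referencing every output file with a checksum."""
    outdir = Path(outdir)
    manifest = {
        "version": __version__,
        "status": status,
        "seeds": seeds,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "files": {name: sha256_of(outdir / name) for name in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
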