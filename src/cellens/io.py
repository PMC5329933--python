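"""Plain-text serialization: tab-separated tables with comment headers,
strain panels, annotation maps, and YAML configs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model_core import StrainSpec

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_ensemble",
    "read_ensemble",
    "write_strain_table",
    "read_strain_table",
    "write_annotation",
    "read_annotation",
    "read_process_map",
    "write_process_map",
    "write_manifest",
]


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, meta: Optional[Mapping] = None):
    """Write a TSV with '#'-prefixed metadata lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_ensemble(values: np.ndarray, param_names: Sequence[str], path,
                   meta: Optional[Mapping] = None):
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      columns=list(param_names))
    write_table(df, path, meta)


def read_ensemble(path):
    df = read_table(path)
    return df.to_numpy(float), tuple(df.columns)


def _format_overrides(strain: StrainSpec) -> str:
    if strain.is_wild_type:
        return "-"
    return ";".join(f"{name}={value:g}" for name, value in strain.overrides)


def _parse_overrides(text: str):
    if text in ("-", "", None):
        return ()
    out = []
    for part in str(text).split(";"):
        name, _, value = part.partition("=")
        out.append((name.strip(), float(value)))
    return tuple(out)


def write_strain_table(strains: Sequence[StrainSpec], path,
                       required: Optional[Sequence[int]] = None,
                       meta: Optional[Mapping] = None):
    """Strain panel as a TSV (id, label, overrides[, required])."""
    rows = {
        "id": [s.id for s in strains],
        "label": [s.label for s in strains],
        "overrides": [_format_overrides(s) for s in strains],
    }
    if required is not None:
        rows["required"] = list(required)
    write_table(pd.DataFrame(rows), path, meta)


def read_strain_table(path):
    """Returns (strains, required) where required is None if absent."""
    df = read_table(path)
    strains = tuple(
        StrainSpec(id=int(r["id"]), label=str(r["label"]),
                   overrides=_parse_overrides(r["overrides"]))
        for _, r in df.iterrows())
    required = tuple(int(v) for v in df["required"]) \
        if "required" in df.columns else None
    return strains, required


def write_annotation(annotation: Mapping[str, str], path,
                     meta: Optional[Mapping] = None):
    """Two-column species -> module map."""
    df = pd.DataFrame(sorted(annotation.items()),
                      columns=["species", "module"])
    write_table(df, path, meta)


def read_annotation(path) -> dict:
    df = read_table(path)
    return dict(zip(df["species"].astype(str), df["module"].astype(str)))


def write_process_map(process_map: Mapping[str, Sequence[str]], path,
                      meta: Optional[Mapping] = None):
    """Species -> biological-process multimap, one (species, process) row each."""
    rows = [(sp, proc) for sp, procs in sorted(process_map.items())
            for proc in procs]
    write_table(pd.DataFrame(rows, columns=["species", "process"]), path, meta)


def read_process_map(path) -> dict:
    df = read_table(path)
    out: dict = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["species"]), []).append(str(r["process"]))
    return out


def write_manifest(manifest: Mapping, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(manifest), fh, sort_keys=True)
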