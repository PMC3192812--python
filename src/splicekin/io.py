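"""Readers, writers, configuration and run manifests.

Time-series data are tiny (nine series, tens of time points), so CSV is the
only data format. Configuration files are JSON or YAML with a single schema:
top-level keys ``variant``, ``geometry``, ``rates`` whose fields match the
corresponding dataclasses.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .geometry import GeneGeometry, ValidationError
from .observe import ALL_SPECIES
from .pathway import PathwayVariant, RateSet

COLUMNS = ["experiment", "species", "time_s", "replicate", "value"]


def read_timeseries(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a tidy RT-qPCR time-series CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")
    bad = df[~df["species"].isin(ALL_SPECIES)]
    if len(bad):
        lines = []
        for idx, sp in bad["species"].items():
            hint = difflib.get_close_matches(str(sp), ALL_SPECIES, n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            lines.append(f"line {idx + 2}: unknown species {sp!r}{suggestion}")
        raise ValidationError(f"{path}:\n" + "\n".join(lines[:10]))
    if (df["time_s"] < 0).any():
        rows = df.index[df["time_s"] < 0].tolist()
        raise ValidationError(
            f"{path}: negative time_s at lines {[r + 2 for r in rows[:10]]}")
    return df[COLUMNS].copy()


def write_timeseries(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[COLUMNS].to_csv(path, index=False)


def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def load_config(path: Union[str, Path]
                ) -> tuple[PathwayVariant, GeneGeometry, RateSet]:
    """Load (variant, geometry, rates) from a JSON/YAML config file.

    A variant may be given as ``{"name": "I"}`` (one of the eight named
    pathways) with optional field overrides, or by its mechanism fields.
    """
    raw = _load_structured(Path(path))
    vcfg = dict(raw.get("variant", {}))
    name = vcfg.pop("name", None)
    if name:
        variant = PathwayVariant.from_name(name, **vcfg)
    else:
        variant = PathwayVariant(**vcfg)
    geometry = GeneGeometry(**raw.get("geometry", {}))
    rates = RateSet(**raw.get("rates", {}))
    return variant, geometry, rates


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(path: Union[str, Path], command: str,
                   config: Optional[dict] = None,
                   seeds: Optional[dict] = None,
                   inputs: Optional[list] = None,
                   outputs: Optional[list] = None,
                   extra: Optional[dict] = None) -> dict:
    """Write a JSON run manifest (seeds, config echo, file digests)."""
    manifest: dict[str, Any] = {
        "command": command,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": seeds or {},
        "config": _jsonable(config or {}),
        "inputs": {str(p): _digest(Path(p)) for p in (inputs or [])},
        "outputs": {str(p): _digest(Path(p)) for p in (outputs or [])},
    }
    if extra:
        manifest.update(_jsonable(extra))
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
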