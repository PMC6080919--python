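"""Readers and writers for the pipeline's tables, configs and manifests.

All tables are comma-separated UTF-8 text with a mandatory header and '.'
decimals. Trajectory files use the canonical long format (oocyte,
chromosome, t_s, x_um, y_um, z_um), times in seconds; reports are in
minutes. Configuration files are flat ``key = value`` text with the
exact SimParams field names.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import SimParams, ValidationError

__all__ = [
    "ParseError",
    "TRAJECTORY_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "parse_config",
    "format_config",
    "load_params",
    "save_params",
    "write_manifest",
]

TRAJECTORY_COLUMNS = ["oocyte", "chromosome", "t_s", "x_um", "y_um", "z_um"]


class ParseError(ValueError):
    """Raised for malformed input files, with row/track context."""


def read_trajectories(path) -> pd.DataFrame:
    """Read and validate a trajectory table.

    Rows are returned sorted by (oocyte, chromosome, t_s). Missing
    columns, NaN coordinates and non-monotone frame times within a track
    raise :class:`ParseError` naming the offending rows or track.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    bad = df[TRAJECTORY_COLUMNS].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]  # 1-based incl. header
        raise ParseError(f"{path}: NaN values in file rows {rows}")
    df = df.sort_values(["oocyte", "chromosome", "t_s"], kind="stable", ignore_index=True)
    for (oocyte, chrom), g in df.groupby(["oocyte", "chromosome"]):
        dt = np.diff(g["t_s"].to_numpy())
        if np.any(dt <= 0):
            raise ParseError(
                f"{path}: non-monotone or duplicate times in track "
                f"(oocyte={oocyte}, chromosome={chrom})"
            )
    return df


def write_trajectories(traj: pd.DataFrame, path) -> None:
    """Write a trajectory table in canonical row order at full precision."""
    missing = [c for c in TRAJECTORY_COLUMNS if c not in traj.columns]
    if missing:
        raise ParseError(f"cannot write trajectories: missing columns {missing}")
    out = traj[TRAJECTORY_COLUMNS].sort_values(
        ["oocyte", "chromosome", "t_s"], kind="stable", ignore_index=True
    )
    out.to_csv(path, index=False)


_PARAM_TYPES = {f.name: f.type for f in dataclasses.fields(SimParams)}


def _coerce(name: str, text: str):
    if name not in _PARAM_TYPES:
        raise ParseError(f"unknown parameter {name!r}")
    kind = _PARAM_TYPES[name]
    try:
        if kind == "int":
            return int(text)
        return float(text)
    except ValueError as exc:
        raise ParseError(f"parameter {name!r}: cannot parse value {text!r}") from exc


def parse_config(text: str) -> dict:
    """Parse flat ``key = value`` config text into a SimParams kwargs dict."""
    values = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"config line {lineno}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = _coerce(key.strip(), val.strip())
    return values


def format_config(params: SimParams) -> str:
    lines = [f"{f.name} = {getattr(params, f.name)!r}" for f in dataclasses.fields(SimParams)]
    return "\n".join(lines) + "\n"


def load_params(path=None, overrides: dict | None = None) -> SimParams:
    """Build SimParams from an optional config file plus overrides."""
    values = parse_config(Path(path).read_text()) if path else {}
    for key, val in (overrides or {}).items():
        values[key] = _coerce(key, str(val))
    try:
        return SimParams(**values)
    except ValidationError:
        raise
    except TypeError as exc:
        raise ParseError(str(exc)) from exc


def save_params(params: SimParams, path) -> None:
    Path(path).write_text(format_config(params))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, seed, inputs=(), outputs=(), config=None) -> Path:
    """Write a reproduction manifest (config echo, seed, checksums, version)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "congression",
        "version": __version__,
        "command": command,
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
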