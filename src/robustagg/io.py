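"""Delimited-text matrix I/O, run manifests and logging setup.

Gradient batches travel as headerless delimited text (comma or tab,
auto-detected on read, comma on write), one client row per line.  Writing
uses 17 significant digits so a write/read round trip is loss-free for
float64.  Every CLI result directory also receives a small JSON manifest
(command, config hash, seed, package version, timestamp) sufficient to
re-run it bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "format_vector",
    "RunManifest",
    "write_manifest",
    "setup_logging",
]

log = logging.getLogger("robustagg")


class MatrixParseError(ValueError):
    """Malformed delimited matrix input; the message names the offending line."""


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_matrix(path) -> np.ndarray:
    """Read an (m, p) batch from headerless comma- or tab-delimited text.

    Raises :class:`MatrixParseError` (with a 1-based line number) on empty
    files, ragged rows or non-numeric cells.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    rows = []
    delim = None
    width = None
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        if delim is None:
            delim = _detect_delimiter(raw)
        cells = [c.strip() for c in raw.split(delim)]
        try:
            row = [float(c) for c in cells]
        except ValueError:
            raise MatrixParseError(f"{path}: non-numeric value on line {lineno}") from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise MatrixParseError(
                f"{path}: ragged row on line {lineno} ({len(row)} cells, expected {width})"
            )
        rows.append(row)
    if not rows:
        raise MatrixParseError(f"{path}: empty matrix (no data on line 1)")
    return np.asarray(rows, dtype=float)


def format_vector(v) -> str:
    """One comma-delimited row at 17 significant digits."""
    return ",".join(f"{x:.17g}" for x in np.atleast_1d(np.asarray(v, dtype=float)))


def write_matrix(path, matrix) -> None:
    """Write an (m, p) batch as headerless comma-delimited text (17 sig. digits)."""
    arr = np.atleast_2d(np.asarray(matrix, dtype=float))
    Path(path).write_text("\n".join(format_vector(row) for row in arr) + "\n")


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    package_version: str
    timestamp: str


def _config_hash(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, command: str, config: dict, seed: int) -> RunManifest:
    """Write manifest.json into ``out_dir`` and return the manifest."""
    from . import __version__

    manifest = RunManifest(
        command=command,
        config_hash=_config_hash(config),
        seed=int(seed),
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = asdict(manifest)
    payload["config"] = config
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return manifest


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("robustagg")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())
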