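"""CSV interchange for kinematic signals.

One signal per file: a header row then one row per timestep with columns
``percent_cycle, flexion_deg, adduction_deg, internal_rotation_deg``
(UTF-8, '.' decimal separator). Optional metadata travels in a JSON
sidecar next to the CSV. Parse failures name the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .kinematics import KinematicSignal

__all__ = ["read_signal", "write_signal", "SignalFormatError",
            "REQUIRED_COLUMNS", "CONVENTION"]

REQUIRED_COLUMNS = ("percent_cycle", "flexion_deg", "adduction_deg",
                    "internal_rotation_deg")
CONVENTION = "intrinsic-XYZ, degrees"


class SignalFormatError(ValueError):
    """Malformed signal file; message carries the 1-based line number."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_signal(path) -> KinematicSignal:
    """Read a kinematic signal from CSV (+ optional JSON metadata sidecar)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SignalFormatError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].split(",")]
    if tuple(header) != REQUIRED_COLUMNS:
        raise SignalFormatError(
            f"{path}: line 1: expected header "
            f"{','.join(REQUIRED_COLUMNS)!r}, got {lines[0]!r}")
    grid, angles = [], []
    prev = None
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != 4:
            raise SignalFormatError(
                f"{path}: line {ln}: expected 4 comma-separated values, "
                f"got {len(cells)}")
        try:
            vals = [float(c) for c in cells]
        except ValueError as exc:
            raise SignalFormatError(
                f"{path}: line {ln}: non-numeric cell ({exc})") from exc
        if not all(np.isfinite(vals)):
            raise SignalFormatError(f"{path}: line {ln}: non-finite value")
        if prev is not None and vals[0] <= prev:
            raise SignalFormatError(
                f"{path}: line {ln}: percent_cycle not strictly increasing "
                f"({vals[0]} after {prev})")
        prev = vals[0]
        grid.append(vals[0])
        angles.append(vals[1:])
    if len(grid) < 2:
        raise SignalFormatError(f"{path}: needs at least 2 data rows")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    return KinematicSignal(np.array(grid), np.array(angles), meta)


def write_signal(signal: KinematicSignal, path, *,
                 write_sidecar: bool = True) -> None:
    """Write a signal as CSV; metadata goes to a JSON sidecar.

    Values are written with repr-level precision so that a write/read
    round trip reproduces the angles to better than 1e-12 deg.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(REQUIRED_COLUMNS) + "\n")
        for g, row in zip(signal.cycle_grid, signal.angles):
            fh.write(f"{g:.17g},{row[0]:.17g},{row[1]:.17g},{row[2]:.17g}\n")
    if write_sidecar:
        meta = dict(signal.meta)
        meta.setdefault("convention", CONVENTION)
        _sidecar_path(path).write_text(
            json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8")
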