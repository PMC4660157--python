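"""Trajectory files, run manifests and deterministic test fixtures.

Trajectory tables are plain CSV with a one-line ``#`` header naming the
units of each column, written at full float precision so a
write-then-read round trip is lossless.  Every simulation output directory
gets a JSON manifest (config echo, master seed, package version,
timestamps, output files with row counts) sufficient to re-run the
simulation bit-identically on the same platform; the manifest is written
atomically at the end of the run.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from datetime import datetime, timezone
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = ["write_trajectories", "read_trajectories", "RunManifest",
           "write_manifest", "make_fixture", "TrajectoryFormatError"]

_UNITS_HEADER = ("# step [-], time_s [s], cell [-], beta [-], x [mm], y [mm],"
                 " theta [rad], Yp [uM], m [-], bias [-], state [-]")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file."""


def write_trajectories(records: pd.DataFrame, path) -> None:
    """Write a trajectory table as CSV with a unit-annotated header line."""
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER + "\n")
        records.to_csv(fh, index=False, float_format="%.17g")


def read_trajectories(path) -> pd.DataFrame:
    """Read a trajectory CSV written by :func:`write_trajectories`.

    Raises :class:`TrajectoryFormatError` naming the first malformed line.
    """
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise TrajectoryFormatError(f"{path}: {exc}") from exc
    numeric = [c for c in df.columns if c != "state"]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            # +3: 1-based, units header line, column header line
            line = int(np.argmax(bad.to_numpy())) + 3
            raise TrajectoryFormatError(
                f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = converted if col in ("step", "cell") \
            else converted.astype(float)
    for col in ("step", "cell"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every simulation output."""

    config: Dict
    master_seed: int
    code_version: str
    started_utc: str
    finished_utc: str
    outputs: Dict[str, int]   # file name -> row count

    @classmethod
    def now(cls) -> str:
        return datetime.now(timezone.utc).isoformat()


def write_manifest(manifest: RunManifest, directory) -> str:
    """Atomically write ``manifest.json`` into ``directory``."""
    payload = dataclasses.asdict(manifest)
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        target = os.path.join(directory, "manifest.json")
        os.replace(tmp, target)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return target


def make_fixture(kind: str, seed: int = 0):
    """Small deterministic datasets for metric and I/O tests.

    ``toy_trajectories``: 3 stationary cells x 5 recorded steps with integer
    coordinates (hand-computable distance statistics).
    ``hill_curve``: a 10-point noiseless Hill curve with known (K, n).
    ``uniform_field_cells``: 16 cells scattered by a seeded generator, for
    attraction-count partitions.
    """
    rng = np.random.default_rng(seed)
    if kind == "toy_trajectories":
        cells = [(0, 1.0, 0.0), (1, 0.0, 2.0), (2, -3.0, 0.0)]
        rows = []
        for step in range(0, 5):
            for cid, x, y in cells:
                rows.append({"step": step, "time_s": step * 1.0, "cell": cid,
                             "beta": 1.0, "x": x, "y": y, "theta": 0.0,
                             "Yp": 4.0, "m": 1.0, "bias": 0.2, "state": "run"})
        return pd.DataFrame(rows)
    if kind == "hill_curve":
        K, n = 1e-3, 3.0
        u = np.logspace(-6, -1, 10)
        f = u ** n / (K ** n + u ** n)
        return pd.DataFrame({"upsilon": u, "fraction_serine": f}), (K, n)
    if kind == "uniform_field_cells":
        x = rng.uniform(-2, 2, size=16)
        y = rng.uniform(-2, 2, size=16)
        return pd.DataFrame({"cell": np.arange(16), "beta": 1.0,
                             "x": x, "y": y})
    raise ValueError(f"unknown fixture kind {kind!r}")
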