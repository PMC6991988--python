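"""Readers and writers for landmark, measurement and model files.

Formats are deliberately plain text: per-specimen CSV (k rows x 3 columns),
a wide CSV (one specimen per row, 3k columns interleaved x1,y1,z1,...), a
TPS dialect (``LM3=k`` blocks of whitespace-separated coordinates followed
by ``ID=label``), ASCII vertex-only PLY for 3D viewing, and a versioned
JSON model archive.  Floats are written with 17 significant digits so
write -> read round-trips are bit-exact for doubles.

All indices in files are 1-based, following anatomical-landmark
conventions; the in-memory API is 0-based.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ArchiveVersionError,
    InvalidDimensionError,
    MalformedFileError,
    UnsupportedDimensionError,
)
from .shape_space import ConfigurationMatrix

__all__ = [
    "ARCHIVE_VERSION",
    "ModelArchive",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_tps",
    "write_tps",
    "write_model",
    "read_model",
    "write_ply",
    "read_measurements_csv",
]

ARCHIVE_VERSION = "1"

_F = "{:.17g}".format  # round-trip exact for IEEE doubles


@dataclasses.dataclass
class ModelArchive:
    """Deserialized model archive: everything needed to reuse a fit."""

    version: str
    archetypoid_indices: np.ndarray  # 0-based, as in the API
    archetypoid_ids: list[str]
    alphas: np.ndarray
    rss: float
    seed: int | None
    config: dict
    diagnostics: dict


# ---------------------------------------------------------------------------
# Landmark CSV
# ---------------------------------------------------------------------------


def _parse_specimen_csv(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                if ln == 1:
                    continue  # header row
                raise MalformedFileError(f"{path}: non-numeric cell on line {ln}")
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise MalformedFileError(f"{path}: expected k rows x 3 columns")
    if arr.shape[0] < 3:
        raise MalformedFileError(f"{path}: fewer than 3 landmarks")
    return arr


def read_landmarks_csv(path) -> list[ConfigurationMatrix]:
    """Read an ensemble from per-specimen CSVs or one wide-matrix CSV.

    A directory is read as one specimen per ``*.csv`` file (k rows, x y z
    columns, optional header; id = file stem).  A single file is read as a
    wide matrix: one specimen per row, an optional leading id column, then
    3k numeric columns ordered x1,y1,z1,x2,...
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise MalformedFileError(f"{path}: no .csv files found")
        ensemble = [
            ConfigurationMatrix(_parse_specimen_csv(f), f.stem) for f in files
        ]
        ks = {X.coords.shape[0] for X in ensemble}
        if len(ks) > 1:
            raise InvalidDimensionError(
                f"{path}: inconsistent landmark counts across specimens: {sorted(ks)}"
            )
        return ensemble

    df = pd.read_csv(path, header=None, float_precision="round_trip")
    # optional header row / id column detection
    first_numeric = pd.to_numeric(df.iloc[0], errors="coerce")
    if first_numeric.isna().all():
        df = pd.read_csv(path, float_precision="round_trip")
        df = df.reset_index(drop=True)
    ids = None
    first_col = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if first_col.isna().any():
        ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        raise MalformedFileError(f"{path}: non-numeric cells in landmark matrix")
    arr = vals.to_numpy(dtype=float)
    if arr.shape[1] % 3 != 0 or arr.shape[1] < 9:
        raise MalformedFileError(
            f"{path}: wide matrix needs 3k columns with k >= 3, got {arr.shape[1]}"
        )
    k = arr.shape[1] // 3
    ensemble = []
    for i in range(arr.shape[0]):
        coords = arr[i].reshape(k, 3)
        sid = ids[i] if ids is not None else f"specimen-{i + 1}"
        ensemble.append(ConfigurationMatrix(coords, sid))
    return ensemble


def write_landmarks_csv(ensemble: Sequence[ConfigurationMatrix], path) -> None:
    """Write an ensemble as a wide-matrix CSV (id column + 3k columns)."""
    path = Path(path)
    k = ensemble[0].coords.shape[0]
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in "xyz"]
    with open(path, "w") as fh:
        fh.write("specimen_id," + ",".join(cols) + "\n")
        for X in ensemble:
            flat = X.coords.reshape(-1)
            fh.write(X.specimen_id + "," + ",".join(_F(v) for v in flat) + "\n")


# ---------------------------------------------------------------------------
# TPS dialect
# ---------------------------------------------------------------------------


def read_tps(path) -> list[ConfigurationMatrix]:
    """Read a 3D TPS file: ``LM3=k`` blocks, k coordinate lines, ``ID=``.

    Blank lines are tolerated and ``#`` comment lines ignored; 2D ``LM=``
    blocks raise :class:`UnsupportedDimensionError`.  A block without an ID
    record is auto-labeled with a warning.
    """
    path = Path(path)
    ensemble = []
    coords: list[list[float]] | None = None
    expect = 0
    label: str | None = None

    def flush(block_no: int):
        nonlocal coords, label
        if coords is None:
            return
        if len(coords) != expect:
            raise MalformedFileError(
                f"{path}: block {block_no} declares LM3={expect} but has {len(coords)} lines"
            )
        sid = label
        if sid is None:
            sid = f"specimen-{block_no}"
            warnings.warn(f"{path}: block {block_no} has no ID; labeled {sid!r}", stacklevel=3)
        ensemble.append(ConfigurationMatrix(np.asarray(coords), sid))
        coords, label = None, None

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                flush(len(ensemble) + 1)
                expect = int(line.split("=", 1)[1])
                coords = []
            elif upper.startswith("LM="):
                raise UnsupportedDimensionError(
                    f"{path}: 2D 'LM=' block on line {ln}; only 3D (LM3=) is supported"
                )
            elif upper.startswith("ID="):
                label = line.split("=", 1)[1].strip()
            elif coords is not None and len(coords) < expect:
                parts = line.split()
                if len(parts) != 3:
                    raise MalformedFileError(f"{path}: line {ln} is not 3 coordinates")
                try:
                    coords.append([float(p) for p in parts])
                except ValueError:
                    raise MalformedFileError(f"{path}: non-numeric value on line {ln}")
            else:
                raise MalformedFileError(f"{path}: unexpected content on line {ln}: {line!r}")
    flush(len(ensemble) + 1)
    if not ensemble:
        raise MalformedFileError(f"{path}: no LM3 blocks found")
    return ensemble


def write_tps(ensemble: Sequence[ConfigurationMatrix], path) -> None:
    with open(path, "w") as fh:
        for X in ensemble:
            fh.write(f"LM3={X.coords.shape[0]}\n")
            for row in X.coords:
                fh.write(" ".join(_F(v) for v in row) + "\n")
            fh.write(f"ID={X.specimen_id}\n")


# ---------------------------------------------------------------------------
# Model archive (versioned JSON)
# ---------------------------------------------------------------------------


def write_model(result, config: dict, path) -> None:
    """Serialize a :class:`~adashape.shape_ada.ShapeADAResult` to JSON.

    Indices are stored 1-based in the file; :func:`read_model` converts
    back to the API's 0-based convention.
    """
    idx0 = np.asarray(result.archetypoid_indices)
    payload = {
        "format": "adashape-model",
        "version": ARCHIVE_VERSION,
        "archetypoid_indices_1based": (idx0 + 1).tolist(),
        "archetypoid_ids": [s.specimen_id for s in result.archetypoid_shapes],
        "alphas": result.model.alphas.tolist(),
        "alpha_row_ids": list(result.tangent.row_ids),
        "rss": result.model.rss,
        "seed": result.model.seed,
        "config": config,
        "diagnostics": {
            "n": result.model.alphas.shape[0],
            "p": int(len(idx0)),
            "k": int(result.archetypoid_shapes[0].coords.shape[0]),
            "restarts_used": result.model.restarts_used,
            "gpa_iterations": result.mean.n_iterations,
            "gpa_converged": result.mean.converged,
            "max_tangent_norm": result.max_tangent_norm,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_model(path) -> ModelArchive:
    with open(path) as fh:
        payload = json.load(fh)
    version = str(payload.get("version", "?"))
    if payload.get("format") != "adashape-model" or version != ARCHIVE_VERSION:
        raise ArchiveVersionError(
            f"{path}: expected adashape-model version {ARCHIVE_VERSION}, got {version!r}"
        )
    return ModelArchive(
        version=version,
        archetypoid_indices=np.asarray(payload["archetypoid_indices_1based"], dtype=int) - 1,
        archetypoid_ids=list(payload["archetypoid_ids"]),
        alphas=np.asarray(payload["alphas"], dtype=float),
        rss=float(payload["rss"]),
        seed=payload.get("seed"),
        config=payload.get("config", {}),
        diagnostics=payload.get("diagnostics", {}),
    )


def write_ply(config: ConfigurationMatrix, path) -> None:
    """ASCII vertex-only PLY point cloud of one configuration."""
    k = config.coords.shape[0]
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment specimen {config.specimen_id}\n")
        fh.write(f"element vertex {k}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("end_header\n")
        for row in config.coords:
            fh.write(" ".join(_F(v) for v in row) + "\n")


def read_measurements_csv(path) -> pd.DataFrame:
    """Measurement table: header row, comma-separated, '.' decimal."""
    df = pd.read_csv(path)
    if df.empty:
        raise MalformedFileError(f"{path}: empty measurement table")
    return df
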