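"""Reading and writing connectome matrices, node tables and cohort manifests.

All formats are plain delimited text. Matrices are dense CSV/TSV blocks
with an optional header row/column; node tables and manifests are TSV with
documented headers. Readers validate strictly and reject rather than
silently repair invalid data. Node indexing is 0-based internally; 1-based
ids in files are detected and converted on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import ConnectomeMatrix, InvalidInputError

NODE_COLUMNS = ["node_id", "x", "y", "z", "label", "hemisphere"]
MANIFEST_COLUMNS = ["subject_id", "age", "sc_path", "fc_path"]


@dataclass(frozen=True)
class NodeTable:
    """Node metadata: coordinates (mm), labels, hemisphere, optional RSN."""

    table: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def rsn(self) -> np.ndarray | None:
        return self.table["rsn"].to_numpy() if "rsn" in self.table.columns else None


@dataclass(frozen=True)
class CohortManifest:
    """Cohort listing: one row per subject with age and matrix paths."""

    table: pd.DataFrame
    base_dir: Path

    def __len__(self) -> int:
        return len(self.table)

    def load_subject(self, row_index: int, strict_fc: bool = False):
        """Load (subject_id, age, sc, fc) for one row.

        FC matrices are read with relaxed validation by default so that
        mode-built synthetic cohorts (near- but not exactly unit diagonal)
        and strict correlation matrices are interchangeable.
        """
        row = self.table.iloc[row_index]
        sc = read_matrix(self.base_dir / row["sc_path"], role="structural")
        fc = read_matrix(self.base_dir / row["fc_path"], role="functional", strict=strict_fc)
        return str(row["subject_id"]), float(row["age"]), sc, fc

    def iter_subjects(self):
        for i in range(len(self)):
            yield self.load_subject(i)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def read_matrix(path: str | Path, role: str, strict: bool = True) -> ConnectomeMatrix:
    """Load a dense connectome matrix from delimited text.

    Comma or tab delimited; a non-numeric first row/column is treated as
    header/labels and dropped. The matrix must be square, fully numeric,
    and satisfy the invariants of ``role``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    tokens = [t.strip() for t in first.strip().split(sep)]
    header = 0 if tokens and not all(_is_number(t) for t in tokens if t != "") else None
    df = pd.read_csv(path, sep=sep, header=header)
    if df.shape[1] and not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        df = df.set_index(df.columns[0])
    values = df.to_numpy()
    if values.shape[0] != values.shape[1]:
        raise InvalidInputError(f"{path}: matrix is {values.shape[0]}x{values.shape[1]}, not square")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise InvalidInputError(f"{path}: non-numeric entry ({exc})") from exc
    if np.isnan(values).any():
        bad = np.argwhere(np.isnan(values))[0]
        raise InvalidInputError(f"{path}: NaN at cell {tuple(bad)}")
    try:
        return ConnectomeMatrix(values, role=role, strict=strict)
    except InvalidInputError as exc:
        raise InvalidInputError(f"{path}: {exc}") from exc


def write_matrix(matrix: ConnectomeMatrix | np.ndarray, path: str | Path) -> None:
    """Write a matrix as TSV at full double precision."""
    values = matrix.values if isinstance(matrix, ConnectomeMatrix) else np.asarray(matrix)
    np.savetxt(path, values, delimiter="\t", fmt="%.17g")


def read_nodes(path: str | Path) -> NodeTable:
    """Load a node metadata table (TSV).

    Required columns: node_id, x, y, z, label, hemisphere; optional: rsn.
    Ids must be contiguous (0-based, or 1-based which is converted).
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in NODE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    ids = table["node_id"].to_numpy()
    n = len(table)
    if sorted(ids) == list(range(1, n + 1)):
        table = table.assign(node_id=ids - 1)
        ids = table["node_id"].to_numpy()
    if sorted(ids) != list(range(n)):
        raise InvalidInputError(f"{path}: node ids must be contiguous 0..{n - 1}")
    bad_hemi = set(table["hemisphere"]) - {"L", "R"}
    if bad_hemi:
        raise InvalidInputError(f"{path}: invalid hemisphere labels {sorted(bad_hemi)}")
    return NodeTable(table=table.sort_values("node_id").reset_index(drop=True))


def write_nodes(nodes: NodeTable, path: str | Path) -> None:
    nodes.table.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    """Load a cohort manifest (TSV): subject_id, age, sc_path, fc_path.

    Paths are resolved relative to the manifest's directory and must exist;
    subject ids must be unique and ages finite and nonnegative.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise InvalidInputError(f"{path}: duplicate subject id {dup!r}")
    ages = table["age"].to_numpy(dtype=float)
    if not np.isfinite(ages).all() or (ages < 0).any():
        raise InvalidInputError(f"{path}: ages must be finite and nonnegative")
    base = path.parent
    for col in ("sc_path", "fc_path"):
        for p in table[col]:
            if not (base / p).exists():
                raise InvalidInputError(f"{path}: referenced file not found: {p}")
    return CohortManifest(table=table, base_dir=base)


def write_results(table: pd.DataFrame, path: str | Path, seed: int | None = None,
                  config: dict | None = None) -> None:
    """Write a tidy results TSV plus a JSON sidecar with run metadata.

    The sidecar (<path>.meta.json) records the seed, package version, and a
    hash of the configuration so every run is reproducible from its outputs.
    """
    from . import __version__

    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    config = config or {}
    meta = {
        "seed": seed,
        "version": __version__,
        "config": config,
        "config_hash": hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
    }
    with open(path.with_name(path.name + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
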