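"""Tabular text input/output for cohorts, assignments, and metric tables.

All on-disk formats are tab-separated text.  A subject series file has
regions as rows (first column the region id, e.g. ``ROI_001``) and a
header row of sample indices; the cohort manifest lists subject id, group,
score, and series path; the system map is a two-column region -> system
table.  Round trips preserve values to full float precision.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .community import EnsembleResult, MultilayerAssignment
from .netbuild import SubjectSeries, SupraAdjacency

__all__ = [
    "write_series", "read_series",
    "write_manifest", "read_manifest",
    "write_system_map", "read_system_map",
    "write_assignment", "read_assignment",
    "write_ensemble_manifest",
    "write_table",
    "export_supra",
]

_FLOAT_FMT = "%.17g"


def write_series(subject: SubjectSeries, path: str | Path) -> None:
    df = pd.DataFrame(subject.data, index=subject.region_ids,
                      columns=range(subject.n_samples))
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_series(path: str | Path, group: str = "", score: float | None = None,
                subject_id: str = "") -> SubjectSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"missing values in series file {path}")
    return SubjectSeries(data=df.to_numpy(dtype=float),
                         region_ids=[str(r) for r in df.index],
                         group=group, score=score,
                         subject_id=subject_id or path.stem)


def write_manifest(rows: Sequence[dict], path: str | Path) -> None:
    """Cohort manifest: columns subject, group, score, path."""
    pd.DataFrame(rows, columns=["subject", "group", "score", "path"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_manifest(path: str | Path) -> list[SubjectSeries]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    table = pd.read_csv(path, sep="\t")
    if table["subject"].duplicated().any():
        dup = table.loc[table["subject"].duplicated(), "subject"].iloc[0]
        raise ValueError(f"duplicate subject id in manifest: {dup}")
    subjects = []
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            raise FileNotFoundError(
                f"manifest entry {row.subject} references missing file: {p}")
        score = None if pd.isna(row.score) else float(row.score)
        subjects.append(read_series(p, group=row.group, score=score,
                                    subject_id=row.subject))
    return subjects


def write_system_map(region_ids: Sequence[str], systems: Sequence[str],
                     path: str | Path) -> None:
    pd.DataFrame({"region": list(region_ids), "system": list(systems)}).to_csv(
        path, sep="\t", index=False)


def read_system_map(path: str | Path,
                    region_ids: Sequence[str] | None = None) -> list[str]:
    """System name per region, ordered like ``region_ids`` when given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"system map not found: {path}")
    table = pd.read_csv(path, sep="\t")
    mapping = dict(zip(table["region"].astype(str), table["system"].astype(str)))
    if region_ids is None:
        return [mapping[r] for r in table["region"].astype(str)]
    missing = [r for r in region_ids if r not in mapping]
    if missing:
        raise ValueError(f"system map lacks region {missing[0]}")
    return [mapping[r] for r in region_ids]


def write_assignment(assignment: MultilayerAssignment, path: str | Path) -> None:
    """Labels as TSV: rows = regions, columns = layers, integer ids."""
    pd.DataFrame(assignment.labels,
                 columns=[f"layer_{l + 1}" for l in range(assignment.n_layers)]
                 ).to_csv(path, sep="\t", index=False)


def read_assignment(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=int)


def write_ensemble_manifest(result: EnsembleResult, path: str | Path) -> None:
    pd.DataFrame({"run": range(len(result.runs)),
                  "seed": [r.seed for r in result.runs],
                  "Q": [r.Q for r in result.runs]}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    os.makedirs(Path(path).parent, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def export_supra(supra: SupraAdjacency, path: str | Path) -> None:
    """Supra-adjacency matrix in MatrixMarket sparse text format."""
    scipy.io.mmwrite(str(path), sp.coo_matrix(supra.matrix))
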