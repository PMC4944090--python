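"""Readers and writers for the pipeline's text interchange formats.

All intermediate artifacts are plain text so that every stage can be
inspected and resumed: long-format trajectory CSV, step-table CSV,
tab-separated symbol strings, per-animal matrix CSVs with a JSON sidecar,
descriptor CSVs, and clustering CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import DESCRIPTOR_NAMES
from .exceptions import InputError
from .features import StepTable, _NORM_COLUMNS, _STEP_COLUMNS
from .rle import BinScheme, RLEMatrix
from .similarity import CompositionReport, WormClustering
from .symbolize import StepClusterModel, SymbolString
from .synthetic import Trajectory

TRAJECTORY_COLUMNS = ("animal_id", "group", "t_s", "cx_mm", "cy_mm")


# -- trajectories ----------------------------------------------------------

def write_trajectories(
    trajectories: list[Trajectory],
    out: str | Path,
    per_animal: bool = False,
) -> list[Path]:
    """Write trajectories as CSV: one long-format file, or one file per
    animal when ``per_animal`` (``out`` is then a directory)."""
    out = Path(out)
    frames = [
        pd.DataFrame(
            {
                "animal_id": t.animal_id,
                "group": t.group_label,
                "t_s": t.t_s,
                "cx_mm": t.x_mm,
                "cy_mm": t.y_mm,
            }
        )
        for t in trajectories
    ]
    if per_animal:
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for t, f in zip(trajectories, frames):
            p = out / f"{t.animal_id}.csv"
            f.to_csv(p, index=False)
            paths.append(p)
        return paths
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    return [out]


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read a long-format trajectory CSV back into Trajectory objects."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"trajectory CSV missing columns: {missing}")
    out = []
    for animal_id, sub in df.groupby("animal_id", sort=False):
        groups = sub["group"].unique()
        out.append(
            Trajectory(
                animal_id=str(animal_id),
                group_label=str(groups[0]),
                t_s=sub["t_s"].to_numpy(),
                x_mm=sub["cx_mm"].to_numpy(),
                y_mm=sub["cy_mm"].to_numpy(),
            )
        )
    return out


# -- step tables -----------------------------------------------------------

def write_step_tables(tables: list[StepTable], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for t in tables:
        f = t.steps.copy()
        f.insert(0, "animal_id", t.animal_id)
        f.insert(1, "group", t.group_label)
        f.insert(2, "step_idx", np.arange(1, len(f) + 1))
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_step_tables(path: str | Path) -> list[StepTable]:
    df = pd.read_csv(path)
    out = []
    for animal_id, sub in df.groupby("animal_id", sort=False):
        cols = [c for c in (*_STEP_COLUMNS, *_NORM_COLUMNS)
                if c in sub.columns]
        out.append(
            StepTable(
                animal_id=str(animal_id),
                group_label=str(sub["group"].iloc[0]),
                steps=sub[cols].reset_index(drop=True),
            )
        )
    return out


# -- symbol strings --------------------------------------------------------

def write_symbol_strings(
    strings: list[SymbolString], path: str | Path
) -> Path:
    """One line per animal: ``animal_id<TAB>group<TAB>2212…``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s in strings:
            fh.write(f"{s.animal_id}\t{s.group_label}\t{s.as_text()}\n")
    return path


def read_symbol_strings(path: str | Path) -> list[SymbolString]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            animal_id, group, text = line.split("\t")
            out.append(
                SymbolString(
                    animal_id, group,
                    np.array([int(ch) for ch in text], dtype=int),
                )
            )
    return out


def write_cluster_ranges(model: StepClusterModel, path: str | Path) -> Path:
    """Per-symbol raw feature ranges of a fitted step-cluster model."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    model.per_cluster_ranges.to_csv(path)
    return path


# -- RLE matrices ----------------------------------------------------------

def write_matrix(m: RLEMatrix, csv_path: str | Path) -> tuple[Path, Path]:
    """Matrix CSV (header = column values, first column = symbol) plus a
    JSON sidecar with kind, n_r, n_p and the bin scheme."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        m.P,
        index=pd.Index(m.symbols, name="symbol"),
        columns=[repr(float(v)) for v in m.col_values],
    )
    df.to_csv(csv_path)
    sidecar = csv_path.with_suffix(".json")
    meta = {
        "kind": m.kind,
        "animal_id": m.animal_id,
        "group": m.group_label,
        "n_r": m.n_r,
        "n_p": m.n_p,
        "col_values": [float(v) for v in m.col_values],
        "bins": list(m.bins.edges) if m.bins is not None else None,
        "bins_max_run": m.bins.max_run if m.bins is not None else None,
        "empty_bins": list(m.empty_bins),
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
    return csv_path, sidecar


def read_matrix(csv_path: str | Path) -> RLEMatrix:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col=0)
    with open(csv_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    bins = None
    if meta["bins"] is not None:
        bins = BinScheme(
            tuple(tuple(e) for e in meta["bins"]), meta["bins_max_run"]
        )
    return RLEMatrix(
        kind=meta["kind"],
        P=df.to_numpy(dtype=float),
        col_values=np.array(meta["col_values"], dtype=float),
        n_r=int(meta["n_r"]),
        n_p=int(meta["n_p"]),
        bins=bins,
        empty_bins=tuple(meta["empty_bins"]),
        animal_id=meta["animal_id"],
        group_label=meta["group"],
    )


# -- descriptors and clustering --------------------------------------------

def write_descriptors(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path)
    return path


def read_descriptors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="animal_id")


def write_selection_report(
    kept: dict[str, list[str]],
    correlations: dict[str, pd.DataFrame],
    path: str | Path,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        kind: {
            "kept": kept[kind],
            "correlation": {
                a: {b: correlations[kind].loc[a, b]
                    for b in correlations[kind].columns}
                for a in correlations[kind].index
            },
        }
        for kind in kept
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def write_assignment(
    clustering: WormClustering, groups: pd.Series, path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "animal_id": clustering.assignment.index,
            "group": groups.reindex(clustering.assignment.index).to_numpy(),
            "cluster": clustering.assignment.to_numpy(),
        }
    )
    df.to_csv(path, index=False)
    return path


def write_composition(report: CompositionReport, path: str | Path) -> Path:
    """Composition CSV: per group × cluster, ``share_of_cluster`` with the
    share-of-group in parentheses (plus raw counts columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells = report.cluster_share.copy().astype(object)
    for g in cells.index:
        for c in cells.columns:
            cs = report.cluster_share.loc[g, c]
            gs = report.group_share.loc[g, c]
            cs = 0.0 if pd.isna(cs) else cs
            cells.loc[g, c] = f"{cs:.4f} ({gs:.0%})"
    cells["total_animals"] = report.counts.sum(axis=1)
    cells.to_csv(path)
    return path
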