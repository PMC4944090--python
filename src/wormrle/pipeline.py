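"""End-to-end orchestration: simulate/load → steps → symbols → RLE →
descriptors → animal clustering.

:func:`analyze` runs the whole analysis in memory; :func:`run_pipeline`
additionally reads the configuration, writes every intermediate artifact
(step tables, symbol strings, matrices, descriptors, clustering) and a
manifest JSON recording the configuration hash, seeds and versions, so a
rerun with an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .descriptors import (
    DESCRIPTOR_NAMES,
    compute_descriptors,
    descriptor_table,
    select_descriptors,
)
from .exceptions import EmptyResultWarning, InputError, ParameterError
from .features import StepTable, extract_step_tables
from .rle import (
    MATRIX_KINDS,
    RLEMatrix,
    build_matrix,
    log_transform,
    make_bin_scheme,
    run_length_encode,
)
from .similarity import (
    CompositionReport,
    WormClustering,
    cluster_worms,
    composition_table,
)
from .symbolize import (
    StepClusterModel,
    SymbolString,
    fit_step_clusters,
    symbolize,
)
from .synthetic import SimParams, Trajectory, simulate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "analyze", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of one analysis run.

    ``simulate`` lists ``{"group": .., "n_animals": .., "params": {..}}``
    blocks (SimParams fields); alternatively ``input_csv`` points at a
    long-format trajectory CSV.
    """

    delta_t_s: float = 1.0
    theta_deg: float = 40.0
    k_step: int = 2
    k_path: int = 5
    matrix_kinds: tuple[str, ...] = MATRIX_KINDS
    cluster_matrix_kind: str = "BAMF"
    cluster_features: str | list[str] = "selected"
    correlation_threshold: float = 0.9
    seed: int = 0
    kmeans_restarts: int = 10
    simulate: list[dict] | None = None
    input_csv: str | None = None
    out_dir: str = "wormrle_out"

    def validate(self) -> None:
        if self.delta_t_s <= 0:
            raise ParameterError("delta_t_s must be > 0")
        if not 0.0 < self.theta_deg < 180.0:
            raise ParameterError("theta_deg must be in (0, 180)")
        if not 2 <= self.k_step <= 5:
            raise ParameterError("k_step must be in [2, 5]")
        if self.k_path < 1:
            raise ParameterError("k_path must be >= 1")
        bad = [k for k in self.matrix_kinds if k not in MATRIX_KINDS]
        if bad:
            raise ParameterError(f"unknown matrix kinds: {bad}")
        if self.cluster_matrix_kind not in self.matrix_kinds:
            raise ParameterError(
                "cluster_matrix_kind must be among matrix_kinds"
            )
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise ParameterError("correlation_threshold must be in (0, 1]")
        if self.kmeans_restarts < 1:
            raise ParameterError("kmeans_restarts must be >= 1")
        if self.simulate is None and self.input_csv is None:
            raise ParameterError(
                "either simulate or input_csv must be given"
            )
        if isinstance(self.cluster_features, list):
            bad = [f for f in self.cluster_features
                   if f not in DESCRIPTOR_NAMES]
            if bad:
                raise ParameterError(f"unknown cluster features: {bad}")
        elif self.cluster_features not in ("selected", "all"):
            raise ParameterError(
                "cluster_features must be 'selected', 'all' or a list"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.matrix_kinds, list):
            cfg.matrix_kinds = tuple(cfg.matrix_kinds)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matrix_kinds"] = list(self.matrix_kinds)
        return d

    def sha256(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class PipelineResult:
    """In-memory artifacts of one analysis run."""

    config: PipelineConfig
    trajectories: list[Trajectory]
    step_tables: list[StepTable]
    model: StepClusterModel
    strings: list[SymbolString]
    global_max_run: int
    matrices: dict[str, list[RLEMatrix]]
    descriptor_tables: dict[str, pd.DataFrame]
    selections: dict[str, list[str]]
    clustering: WormClustering
    composition: CompositionReport
    warnings: list[str] = field(default_factory=list)

    @property
    def groups(self) -> pd.Series:
        kind = self.config.cluster_matrix_kind
        return self.descriptor_tables[kind]["group"]


def _cohort_from_config(config: PipelineConfig) -> list[Trajectory]:
    if config.simulate is not None:
        specs = []
        for block in config.simulate:
            try:
                group = block["group"]
                n = int(block["n_animals"])
            except KeyError as e:
                raise ParameterError(
                    f"simulate block missing key {e.args[0]!r}"
                ) from None
            params = SimParams(**block.get("params", {}))
            specs.append((group, params, n))
        return simulate_cohort(specs, seed=config.seed)
    return wio.read_trajectories(config.input_csv)


def encode_cohort(
    strings: list[SymbolString],
    kinds: tuple[str, ...] = MATRIX_KINDS,
    n_symbols: int | None = None,
) -> tuple[dict[str, list[RLEMatrix]], int]:
    """RLE matrices of every requested kind for every animal.

    The AMF column range and the bin scheme are derived from the maximum
    run length across the whole cohort.  Returns (matrices per kind,
    global max run).
    """
    runs = [run_length_encode(s) for s in strings]
    global_max = max((r.max_run for r in runs), default=0)
    if global_max == 0:
        raise InputError("no runs in any symbol string")
    bins = make_bin_scheme(global_max)
    matrices: dict[str, list[RLEMatrix]] = {k: [] for k in kinds}
    for r in runs:
        base: dict[str, RLEMatrix] = {}
        for kind in ("IMF", "AMF", "BAMF", "BAAMF"):
            if kind in kinds or (kind in ("IMF", "AMF")
                                 and kind + "L" in kinds):
                base[kind] = build_matrix(
                    r, kind, global_max_run=global_max, bins=bins
                    if kind in ("BAMF", "BAAMF") else None,
                    n_symbols=n_symbols,
                )
        for kind in kinds:
            if kind.endswith("L"):
                matrices[kind].append(log_transform(base[kind[:-1]]))
            else:
                matrices[kind].append(base[kind])
    return matrices, global_max


def analyze(
    trajectories: list[Trajectory], config: PipelineConfig
) -> PipelineResult:
    """Run the full analysis in memory on a cohort of trajectories."""
    config.validate()
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        step_tables = extract_step_tables(
            trajectories, config.delta_t_s, config.theta_deg
        )
        model = fit_step_clusters(
            step_tables, k=config.k_step, seed=config.seed,
            restarts=config.kmeans_restarts,
        )
        strings = symbolize(step_tables, model)

        nonempty = [s for s in strings if len(s)]
        skipped = [s.animal_id for s in strings if not len(s)]
        if skipped:
            captured.append(
                f"animals without steps skipped from encoding: {skipped}"
            )
        matrices, global_max = encode_cohort(
            nonempty, config.matrix_kinds, n_symbols=config.k_step
        )

        descriptor_tables = {}
        selections = {}
        for kind in config.matrix_kinds:
            vectors = [compute_descriptors(m) for m in matrices[kind]]
            table = descriptor_table(vectors)
            descriptor_tables[kind] = table
            selections[kind] = select_descriptors(
                table, config.correlation_threshold
            )

        kind = config.cluster_matrix_kind
        table = descriptor_tables[kind]
        if config.cluster_features == "selected":
            feats = selections[kind]
        elif config.cluster_features == "all":
            feats = None
        else:
            feats = list(config.cluster_features)
        clustering = cluster_worms(
            table, feats, k=config.k_path, seed=config.seed,
            restarts=config.kmeans_restarts,
        )
        composition = composition_table(clustering, table["group"])

    captured.extend(str(w.message) for w in wrec)
    return PipelineResult(
        config=config,
        trajectories=trajectories,
        step_tables=step_tables,
        model=model,
        strings=strings,
        global_max_run=global_max,
        matrices=matrices,
        descriptor_tables=descriptor_tables,
        selections=selections,
        clustering=clustering,
        composition=composition,
        warnings=captured,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the analysis and write every artifact plus a manifest JSON.

    Returns the manifest.  Rerunning with an identical configuration (same
    seeds) reproduces byte-identical artifact files.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    trajectories = _cohort_from_config(config)
    result = analyze(trajectories, config)

    artifacts: dict[str, str] = {}

    p = wio.write_trajectories(trajectories, out / "trajectories.csv")[0]
    artifacts["trajectories"] = str(p)
    p = wio.write_step_tables(result.step_tables, out / "steps.csv")
    artifacts["steps"] = str(p)
    p = wio.write_symbol_strings(result.strings, out / "symbols.tsv")
    artifacts["symbols"] = str(p)
    p = wio.write_cluster_ranges(result.model, out / "cluster_ranges.csv")
    artifacts["cluster_ranges"] = str(p)

    mat_dir = out / "matrices"
    for kind, mats in result.matrices.items():
        for m in mats:
            wio.write_matrix(m, mat_dir / kind / f"{m.animal_id}.csv")
    artifacts["matrices"] = str(mat_dir)

    correlations = {}
    for kind, table in result.descriptor_tables.items():
        p = wio.write_descriptors(table, out / f"descriptors_{kind}.csv")
        artifacts[f"descriptors_{kind}"] = str(p)
        numeric = [n for n in DESCRIPTOR_NAMES if n in table.columns]
        correlations[kind] = table[numeric].corr(method="pearson")
    p = wio.write_selection_report(
        result.selections, correlations, out / "selection.json"
    )
    artifacts["selection"] = str(p)

    groups = result.groups
    p = wio.write_assignment(result.clustering, groups,
                             out / "assignment.csv")
    artifacts["assignment"] = str(p)
    p = wio.write_composition(result.composition, out / "composition.csv")
    artifacts["composition"] = str(p)

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "wormrle_version": __version__,
        "numpy_version": np.__version__,
        "n_animals": len(trajectories),
        "n_steps": int(sum(t.n_steps for t in result.step_tables)),
        "global_max_run": result.global_max_run,
        "selected_descriptors": result.selections,
        "warnings": result.warnings,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
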