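"""End-to-end orchestration: simulate -> normalize -> release -> cluster ->
integrate -> shed -> report.

Stages communicate through TSV files under the run's output directory, so
each stage can be re-run independently (and from the CLI). A run manifest
records the package version, seeds, thresholds, and SHA-256 digests of the
stage inputs; re-running with the same config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import granulekit
from granulekit import (
    integration,
    preprocess,
    quantio,
    release_analysis,
    shedding,
    synthetic_data,
    temporal_clustering,
)

STAGES = ("simulate", "normalize", "release", "cluster", "integrate", "shed", "report")


class ConfigError(ValueError):
    """Invalid run configuration (CLI maps this to exit code 2)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat key-value run configuration; defaults are the screen's printed
    thresholds where one exists."""

    out_dir: str = "granulekit_run"
    seed: int = 0
    # synthetic world
    n_proteins: int = 400
    noise_cv: float = 0.2
    dropout_rate: float = 0.1
    peptides_per_protein: int = 10
    # release screen
    fc_threshold: float = 1.5
    slope_min: float = 0.0
    # differential testing
    alpha_de: float = 0.01
    alpha_core: float = 0.05
    de_fc_threshold: float = 1.5
    # shedding
    shed_p: float = 0.05
    shed_log2fc: float = 0.6
    # integration
    depletion_delta: float = 20.0
    induction_delta: float = 50.0
    r_threshold: float = 0.8
    # clustering
    fuzzifier: float = 2.0
    c_min: int = 2
    c_max: int = 6

    def validate(self) -> None:
        positive = (
            "fc_threshold", "alpha_de", "alpha_core", "de_fc_threshold",
            "shed_p", "shed_log2fc", "depletion_delta", "induction_delta",
            "r_threshold", "n_proteins", "peptides_per_protein",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fuzzifier <= 1:
            raise ConfigError("fuzzifier must exceed 1")
        if not 2 <= self.c_min <= self.c_max:
            raise ConfigError("need 2 <= c_min <= c_max")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config

    def simulation_config(self) -> synthetic_data.SimulationConfig:
        return synthetic_data.SimulationConfig(
            seed=self.seed,
            n_proteins=self.n_proteins,
            noise_cv=self.noise_cv,
            dropout_rate=self.dropout_rate,
        )


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file missing: {path}")
    return path


def _inputs_dir(config: RunConfig) -> Path:
    return Path(config.out_dir) / "inputs"


def _results_dir(config: RunConfig) -> Path:
    return Path(config.out_dir) / "results"


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=quantio.FLOAT_FORMAT)
    return path


# -- stages --------------------------------------------------------------------


def stage_simulate(config: RunConfig) -> dict:
    sim = config.simulation_config()
    paths = synthetic_data.write_simulation(
        sim, _inputs_dir(config), peptides_per_protein=config.peptides_per_protein
    )
    return {k: str(v) for k, v in paths.items()}


def _load_secretome(config: RunConfig) -> quantio.QuantTable:
    inputs = _inputs_dir(config)
    samples = quantio.read_samples(_require(inputs / "samples_secretome.tsv"))
    return quantio.read_dia_report(_require(inputs / "report_secretome.tsv"), samples)


def _load_cell(config: RunConfig) -> quantio.QuantTable:
    inputs = _inputs_dir(config)
    samples = quantio.read_samples(_require(inputs / "samples_cell.tsv"))
    return quantio.read_quant_matrix(_require(inputs / "quant_cell.tsv"), samples)


def _load_annotations(config: RunConfig) -> quantio.AnnotationSet:
    return quantio.read_annotations(_require(_inputs_dir(config) / "annotations.tsv"))


def stage_normalize(config: RunConfig) -> dict:
    secretome = _load_secretome(config)
    normalized = preprocess.spikein_normalize(
        preprocess.median_normalize(secretome), synthetic_data.SPIKEIN_ID
    )
    results = _results_dir(config)
    results.mkdir(parents=True, exist_ok=True)
    quantio.write_quant_matrix(normalized, results / "quant_secretome_normalized.tsv")

    trajs = []
    for stim in synthetic_data.STIMULI:
        trajs.append(preprocess.fold_change_timecourse(normalized, stim))
    fc = pd.concat(trajs, ignore_index=True)
    fc = fc[fc["protein"] != synthetic_data.SPIKEIN_ID]
    _write(fc, results / "trajectories_fc.tsv")

    cell = _load_cell(config)
    rel = pd.concat(
        [preprocess.relative_percentage(cell, s) for s in synthetic_data.STIMULI],
        ignore_index=True,
    )
    _write(rel, results / "trajectories_relpct.tsv")
    return {
        "quant_secretome_normalized": str(results / "quant_secretome_normalized.tsv"),
        "trajectories_fc": str(results / "trajectories_fc.tsv"),
        "trajectories_relpct": str(results / "trajectories_relpct.tsv"),
    }


def stage_release(config: RunConfig) -> dict:
    results = _results_dir(config)
    fc = pd.read_csv(_require(results / "trajectories_fc.tsv"), sep="\t")
    annotations = _load_annotations(config)
    calls = release_analysis.call_release(
        fc, annotations, fc_threshold=config.fc_threshold, slope_min=config.slope_min
    )
    catalog = release_analysis.combine_conditions(calls, annotations)
    subsets = release_analysis.summarize_granule_subsets(catalog, annotations)
    level2h = release_analysis.release_level_2h(fc, catalog)
    routes = release_analysis.aggregate_secretion_routes(
        catalog.non_canonical, annotations
    )
    route_rows = [
        {"route": flag, "n": info["n"],
         "fraction": info["fraction"]}
        for flag, info in routes["per_route"].items()
    ]
    route_rows.append(
        {"route": "any", "n": routes["n_secreted"],
         "fraction": routes["n_secreted"] / max(routes["n_non_canonical"], 1)}
    )
    _write(calls, results / "release_calls.tsv")
    _write(catalog.to_frame(), results / "release_catalog.tsv")
    _write(subsets, results / "granule_subset_counts.tsv")
    _write(level2h.reset_index(), results / "release_level_2h.tsv")
    _write(pd.DataFrame(route_rows), results / "route_summary.tsv")
    return {
        "n_released": len(catalog),
        "n_canonical": len(catalog.canonical),
        "n_non_canonical": len(catalog.non_canonical),
        "percent_secreted": routes["percent_secreted"],
    }


def stage_cluster(config: RunConfig) -> dict:
    """Cluster z-scored temporal profiles of the differential proteins
    (union across time points) within each stimulated condition."""
    cell = _load_cell(config)
    results = _results_dir(config)
    out = {}
    cluster_tables, centroid_tables = [], []
    times = sorted(cell.samples["time_min"].unique())
    for stim in synthetic_data.STIMULI:
        de_union: set[str] = set()
        for t in times:
            if t == 0:
                continue
            de = preprocess.differential_test(
                cell, stim, t, alpha=config.alpha_de,
                fc_threshold=config.de_fc_threshold,
            )
            de_union |= set(de.loc[de["significant"], "protein"])
        if len(de_union) < config.c_min + 1:
            out[stim] = {"n_proteins": len(de_union), "c": 0}
            continue
        rel = preprocess.relative_percentage(cell, stim)
        rel = rel[rel["protein"].isin(de_union)]
        result = temporal_clustering.cluster_trajectories(
            rel,
            c_range=range(config.c_min, config.c_max + 1),
            m=config.fuzzifier,
            seed=config.seed,
        )
        frame = result.to_frame()
        frame.insert(1, "condition", stim)
        cluster_tables.append(frame)
        cents = result.centroids.rename_axis("cluster").reset_index()
        cents.insert(1, "condition", stim)
        centroid_tables.append(cents)
        out[stim] = {"n_proteins": len(result.proteins), "c": result.c}
    if cluster_tables:
        _write(pd.concat(cluster_tables, ignore_index=True), results / "clusters.tsv")
        _write(pd.concat(centroid_tables, ignore_index=True), results / "centroids.tsv")
    return out


def stage_integrate(config: RunConfig) -> dict:
    results = _results_dir(config)
    rel = pd.read_csv(_require(results / "trajectories_relpct.tsv"), sep="\t")
    fc = pd.read_csv(_require(results / "trajectories_fc.tsv"), sep="\t")
    calls = pd.read_csv(_require(results / "release_calls.tsv"), sep="\t")
    patterns = integration.label_patterns(
        rel, calls,
        depletion_delta=config.depletion_delta,
        induction_delta=config.induction_delta,
    )
    _write(patterns, results / "patterns.tsv")
    # kinetic subtype assignment on the strongest-release condition (PMA-like)
    marker_lists = {
        s: tuple(m for m in markers)
        for s, markers in integration.DEFAULT_MARKERS.items()
    }
    # synthetic runs have no gene-symbol markers; fall back to planted
    # canonical proteins per subset as markers
    annotations = _load_annotations(config)
    fc_pma = fc[fc["condition"] == "PMA"]
    present = set(fc_pma["protein"])
    if not any(m in present for ms in marker_lists.values() for m in ms):
        marker_lists = {
            subset: tuple(
                sorted(
                    p for p in present
                    if subset in annotations.get(p).granule_subsets
                )[:8]
            )
            for subset in quantio.GRANULE_SUBSETS
        }
        marker_lists = {s: m for s, m in marker_lists.items() if m}
    assignments = integration.kinetic_similarity(
        fc_pma, marker_lists, r_threshold=config.r_threshold
    )
    _write(assignments, results / "kinetic_assignments.tsv")
    return {
        "n_patterns": len(patterns),
        "n_assigned": int(assignments["assigned"].sum()),
    }


def stage_shed(config: RunConfig) -> dict:
    inputs = _inputs_dir(config)
    results = _results_dir(config)
    samples = quantio.read_samples(_require(inputs / "samples_shedding.tsv"))
    table = quantio.read_quant_matrix(_require(inputs / "quant_shedding.tsv"), samples)
    annotations = _load_annotations(config)
    membrane = [p for p in table.proteins if annotations.get(p).is_membrane]
    calls_by_stim = {}
    for stim in synthetic_data.STIMULI:
        calls_by_stim[stim] = shedding.call_substrates(
            table, membrane, stim,
            p_threshold=config.shed_p, log2fc_threshold=config.shed_log2fc,
        )
    all_calls = pd.concat(calls_by_stim.values(), ignore_index=True)
    grid = shedding.compare_conditions(calls_by_stim)
    peptides = quantio.read_peptides(_require(inputs / "peptides.tsv"))
    models = {
        p: annotations.get(p).topology
        for p in membrane
        if annotations.get(p).topology is not None
    }
    topo = shedding.topology_calls(peptides, models)
    _write(all_calls, results / "shedding_calls.tsv")
    _write(grid.astype(int).reset_index(), results / "sensitivity_matrix.tsv")
    _write(topo, results / "topology_calls.tsv")
    return {
        "n_membrane": len(membrane),
        "n_substrates": int(grid.any(axis=1).sum()) if len(grid) else 0,
        "n_majority_extracellular": int(topo["majority_extracellular"].sum()),
    }


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def stage_report(config: RunConfig, stage_summaries: dict) -> dict:
    manifest = {
        "package": "granulekit",
        "version": granulekit.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages_completed": list(stage_summaries),
        "stage_summaries": stage_summaries,
        "input_digests": {
            p.name: _sha256(p) for p in sorted(_inputs_dir(config).glob("*.tsv"))
        },
    }
    path = Path(config.out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"manifest": str(path)}


def run_pipeline(config: RunConfig) -> dict:
    """Run all seven stages; any stage failure aborts with the stage name
    and cause. Returns the manifest dict."""
    config.validate()
    summaries: dict = {}
    stage_fns = {
        "simulate": stage_simulate,
        "normalize": stage_normalize,
        "release": stage_release,
        "cluster": stage_cluster,
        "integrate": stage_integrate,
        "shed": stage_shed,
    }
    for stage in STAGES[:-1]:
        try:
            summaries[stage] = stage_fns[stage](config)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    try:
        summaries["report"] = stage_report(config, {**summaries, "report": {}})
    except Exception as exc:
        raise StageError("report", exc) from exc
    manifest_path = Path(config.out_dir) / "manifest.json"
    return json.loads(manifest_path.read_text())
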