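"""Synthetic quantification data with planted ground truth.

The generator emulates the structure of a time-resolved neutrophil
degranulation study: a cellular proteome (control + three stimuli, six time
points, replicated), a single-sample-per-point secretome time course with a
constant-amount spike-in standard and run-level scale distortions, a
stimulus +/- metalloproteinase-inhibitor shedding experiment, and peptide
evidence over membrane-protein topologies. Every downstream classifier has a
planted label to be recovered.

Class templates (noise-free world):

* released proteins: supernatant fold-change vs control rises along a
  saturating curve with half-rise at 30 min, scaled to reach
  ``release_amplitude`` at the last sampled time; their cellular level
  declines linearly from 100% to ``depletion_floor`` (the
  ``released_without_depletion`` class keeps a flat cellular level, like
  azurophilic markers under PMA).
* induced proteins rise linearly in the cell (cytokine-like) and are not
  released.
* shed membrane proteins appear in the supernatant with the release template
  and drop ``inhibitor_effect``-fold under the inhibitor.
* background is flat everywhere.

Noise is multiplicative log-normal with coefficient of variation
``noise_cv``; missingness is completely at random at ``dropout_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from granulekit import quantio
from granulekit.quantio import AnnotationSet, ProteinAnnotation, QuantTable
from granulekit.shedding import INHIBITOR_SUFFIX, TopologyModel

CLASS_LABELS = (
    "released_with_depletion",
    "released_without_depletion",
    "induced_cellular",
    "shed_membrane",
    "background",
)
RELEASED_CLASSES = ("released_with_depletion", "released_without_depletion")

STIMULI = ("LPS", "TNFA", "PMA")
CONTROL = "CONTROL"

SPIKEIN_ID = "PROTA_SPIKE"

# route-prediction prevalence among non-canonical released proteins
# (signal peptide, nonclassical, transmembrane, vesicle)
ROUTE_PROBS = {
    "signal_peptide": 0.204,
    "nonclassical": 0.331,
    "transmembrane": 0.107,
    "vesicle": 0.591,
}

_T_HALF_MIN = 30.0  # half-rise time of the release template


@dataclass
class SimulationConfig:
    """Parameters of the simulated world. Defaults follow the emulated
    study design (time grids, replicate counts, thresholds-compatible effect
    sizes); see docs/methods.md for the rationale of each free choice."""

    seed: int = 0
    n_proteins: int = 1000
    class_fractions: dict = field(
        default_factory=lambda: {
            "released_with_depletion": 0.10,
            "released_without_depletion": 0.05,
            "induced_cellular": 0.05,
            "shed_membrane": 0.05,
            "background": 0.75,
        }
    )
    noise_cv: float = 0.2
    dropout_rate: float = 0.1
    n_replicates_cell: int = 3
    cell_times_min: tuple = (0, 15, 30, 60, 120, 240)
    secretome_times_min: tuple = (0, 5, 15, 30, 60, 120)
    release_amplitude: float = 3.0
    depletion_floor: float = 40.0  # percent of baseline at the last time
    induction_peak: float = 300.0  # percent of baseline at the last time
    spikein_level: float = 1.0e6
    run_scale_range: tuple = (0.5, 2.0)
    inhibitor_effect: float = 2.0
    n_replicates_shedding: int = 3
    exclusion_fraction: float = 0.05  # background tagged mito/ribo/histone
    canonical_fraction: float = 0.5  # released proteins with granule subsets

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        unknown = set(self.class_fractions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class label(s) {sorted(unknown)}")
        for grid in (self.cell_times_min, self.secretome_times_min):
            if len(grid) == 0:
                raise ValueError("empty time grid")
            if grid[0] != 0:
                raise ValueError("time grid must include 0")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError("times must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_replicates_cell < 1:
            raise ValueError("need at least one cell replicate")
        if self.spikein_level <= 0:
            raise ValueError("spikein_level must be positive")
        if self.inhibitor_effect <= 1:
            raise ValueError("inhibitor_effect must exceed 1 (must reduce)")
        if self.release_amplitude <= 1:
            raise ValueError("release_amplitude must exceed 1")


@dataclass
class GroundTruth:
    """Planted labels: one class per protein, plus the annotation table
    (granule subsets, exclusions, topology, route flags) and the per-stimulus
    shedding-substrate flags."""

    labels: pd.Series
    annotations: AnnotationSet
    substrate: pd.DataFrame  # protein x stimulus bool
    config: SimulationConfig

    @property
    def released_proteins(self) -> list[str]:
        return sorted(self.labels.index[self.labels.isin(RELEASED_CLASSES)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for protein in self.labels.index:
            ann = self.annotations.get(protein)
            rows.append(
                {
                    "protein": protein,
                    "class_label": self.labels[protein],
                    "granule_subsets": ";".join(sorted(ann.granule_subsets)) or "-",
                    "is_membrane": int(ann.is_membrane),
                    **{
                        f"substrate_{s}": int(self.substrate.loc[protein, s])
                        for s in self.substrate.columns
                    },
                }
            )
        return pd.DataFrame(rows)


# -- templates ---------------------------------------------------------------


def release_fc_template(config: SimulationConfig, time_min: float) -> float:
    """Supernatant fold-change of a released protein: saturating rise with
    half-rise at 30 min, normalized to hit ``release_amplitude`` at the last
    sampled time."""
    t_max = config.secretome_times_min[-1]
    gain = (time_min / (time_min + _T_HALF_MIN)) / (t_max / (t_max + _T_HALF_MIN))
    return 1.0 + (config.release_amplitude - 1.0) * gain


def cell_percent_template(config: SimulationConfig, label: str, time_min: float) -> float:
    """Cellular relative percentage (of the 0-min baseline) under
    stimulation for a given protein class."""
    t_max = config.cell_times_min[-1]
    frac = time_min / t_max
    if label == "released_with_depletion":
        return 100.0 - (100.0 - config.depletion_floor) * frac
    if label == "induced_cellular":
        return 100.0 + (config.induction_peak - 100.0) * frac
    return 100.0


# -- planting ----------------------------------------------------------------


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"SIM{i:0{width}d}" for i in range(1, n + 1)]


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_proteins over class fractions."""
    fracs = {k: config.class_fractions.get(k, 0.0) for k in CLASS_LABELS}
    raw = {k: config.n_proteins * v for k, v in fracs.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = config.n_proteins - sum(counts.values())
    by_remainder = sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Plant class labels, annotations, topologies, and substrate flags.

    Deterministic from ``config.seed``; shared by all three simulators so
    that cell, secretome, and shedding tables describe the same proteins.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    proteins = _protein_ids(config.n_proteins)
    counts = _class_counts(config)
    label_pool = [lab for lab in CLASS_LABELS for _ in range(counts[lab])]
    order = rng.permutation(config.n_proteins)
    labels = pd.Series(
        [label_pool[i] for i in np.argsort(order)], index=proteins, name="class_label"
    )

    annotations = AnnotationSet()
    substrate = pd.DataFrame(False, index=proteins, columns=list(STIMULI))
    for protein in proteins:
        label = labels[protein]
        granule_subsets: frozenset = frozenset()
        exclusion = "none"
        is_membrane = False
        topology = None
        routes: tuple = ()
        if label in RELEASED_CLASSES:
            if rng.random() < config.canonical_fraction:
                k = 1 + int(rng.random() < 0.25)  # some multi-membership
                granule_subsets = frozenset(
                    rng.choice(quantio.GRANULE_SUBSETS, size=k, replace=False)
                )
            else:
                routes = tuple(
                    flag for flag, p in ROUTE_PROBS.items() if rng.random() < p
                )
        elif label == "shed_membrane":
            is_membrane = True
            granule_subsets = frozenset(
                [str(rng.choice(["GG", "SV", "SG"]))]
            )  # membrane cargo lives in mobilizable granules
            length = int(rng.integers(100, 801))
            tm_start = int(rng.integers(25, length - 45))
            orientation = str(rng.choice(["type_I", "type_II"]))
            topology = TopologyModel(
                protein=protein,
                length=length,
                orientation=orientation,
                tm_spans=((tm_start, tm_start + 20),),
            )
            substrate.loc[protein, :] = True
        elif label == "background":
            if rng.random() < config.exclusion_fraction:
                exclusion = str(rng.choice(["mitochondrial", "ribosomal", "histone"]))
        annotations[protein] = ProteinAnnotation(
            accession=protein,
            granule_subsets=granule_subsets,
            exclusion_class=exclusion,
            is_membrane=is_membrane,
            topology=topology,
            routes=routes,
        )
    return GroundTruth(labels=labels, annotations=annotations, substrate=substrate, config=config)


# -- noise -------------------------------------------------------------------


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit median and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=shape))


def _base_abundance(rng: np.random.Generator, n: int) -> np.ndarray:
    # LFQ-like dynamic range: lognormal around 1e6 spanning ~3 decades
    return 10 ** rng.normal(6.0, 0.5, size=n)


def _apply_dropout(
    values: np.ndarray, rng: np.random.Generator, rate: float
) -> np.ndarray:
    if rate == 0:
        return values
    mask = rng.random(values.shape) < rate
    out = values.copy()
    out[mask] = np.nan
    return out


# -- simulators --------------------------------------------------------------


def simulate_cell_proteome(config: SimulationConfig) -> tuple[QuantTable, GroundTruth]:
    """Cellular proteome: {control + stimuli} x time x replicates."""
    truth = ground_truth(config)
    rng = np.random.default_rng([config.seed, 1])
    proteins = list(truth.labels.index)
    base = _base_abundance(rng, len(proteins))

    conditions = (CONTROL,) + STIMULI
    sample_ids, meta_rows, columns = [], [], []
    for cond in conditions:
        for t in config.cell_times_min:
            for rep in range(1, config.n_replicates_cell + 1):
                sid = f"cell_{cond}_t{t:03d}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"compartment": "cell", "condition": cond, "time_min": t,
                     "replicate": rep}
                )
                if cond == CONTROL:
                    template = np.ones(len(proteins))
                else:
                    template = np.array(
                        [
                            cell_percent_template(config, truth.labels[p], t) / 100.0
                            for p in proteins
                        ]
                    )
                col = base * template * _lognormal_noise(rng, config.noise_cv, len(proteins))
                columns.append(col)
    values = pd.DataFrame(
        np.column_stack(columns), index=proteins, columns=sample_ids
    )
    values.index.name = "protein"
    values[:] = _apply_dropout(values.to_numpy(), rng, config.dropout_rate)
    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    return QuantTable(values, samples), truth


def simulate_secretome(config: SimulationConfig) -> tuple[QuantTable, GroundTruth]:
    """Secretome: one sample per {control + stimuli} x time, a spike-in row
    at fixed amount, and a per-run multiplicative scale distortion drawn from
    ``run_scale_range`` (so normalization is testable)."""
    truth = ground_truth(config)
    rng = np.random.default_rng([config.seed, 2])
    proteins = list(truth.labels.index)
    base = _base_abundance(rng, len(proteins))
    released_like = truth.labels.isin(RELEASED_CLASSES + ("shed_membrane",)).to_numpy()

    conditions = (CONTROL,) + STIMULI
    sample_ids, meta_rows, columns, scales = [], [], [], []
    for cond in conditions:
        for t in config.secretome_times_min:
            sid = f"sup_{cond}_t{t:03d}"
            sample_ids.append(sid)
            meta_rows.append(
                {"compartment": "supernatant", "condition": cond, "time_min": t,
                 "replicate": 1, "spikein_id": SPIKEIN_ID}
            )
            fc = np.ones(len(proteins))
            if cond != CONTROL:
                fc[released_like] = release_fc_template(config, t)
            col = base * fc * _lognormal_noise(rng, config.noise_cv, len(proteins))
            columns.append(col)
            scales.append(rng.uniform(*config.run_scale_range))

    matrix = np.column_stack(columns)
    matrix = _apply_dropout(matrix, rng, config.dropout_rate)
    spike = np.full((1, len(sample_ids)), config.spikein_level)
    matrix = np.vstack([matrix, spike]) * np.asarray(scales)  # run-level distortion
    values = pd.DataFrame(
        matrix, index=proteins + [SPIKEIN_ID], columns=sample_ids
    )
    values.index.name = "protein"
    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    return QuantTable(values, samples), truth


def simulate_shedding_experiment(config: SimulationConfig) -> tuple[QuantTable, GroundTruth]:
    """Inhibitor experiment: per stimulus, arms {stimulus,
    stimulus+GM6001} x replicates at a single time point; planted substrates
    are ``inhibitor_effect``-fold lower under the inhibitor."""
    truth = ground_truth(config)
    rng = np.random.default_rng([config.seed, 3])
    proteins = list(truth.labels.index)
    base = _base_abundance(rng, len(proteins))

    sample_ids, meta_rows, columns = [], [], []
    for stim in STIMULI:
        reduced = truth.substrate[stim].to_numpy()
        for arm, inhibited in ((stim, False), (stim + INHIBITOR_SUFFIX, True)):
            for rep in range(1, config.n_replicates_shedding + 1):
                sid = f"shed_{arm}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"compartment": "supernatant", "condition": arm, "time_min": 60,
                     "replicate": rep, "inhibitor": inhibited}
                )
                level = base.copy()
                if inhibited:
                    level[reduced] = level[reduced] / config.inhibitor_effect
                columns.append(
                    level * _lognormal_noise(rng, config.noise_cv, len(proteins))
                )
    values = pd.DataFrame(np.column_stack(columns), index=proteins, columns=sample_ids)
    values.index.name = "protein"
    values[:] = _apply_dropout(values.to_numpy(), rng, config.dropout_rate)
    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    return QuantTable(values, samples), truth


def simulate_peptides(
    truth: GroundTruth, peptides_per_protein: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Random tryptic-like peptides (7-30 residues) over the membrane
    proteins' topology models.

    The returned frame carries a ``true_domain`` column assigned by
    per-residue enumeration (the generating rule, independent of the
    interval logic in :func:`granulekit.shedding.assign_peptide_domain`).
    """
    rng = np.random.default_rng([seed, 4])
    rows = []
    for protein in truth.labels.index:
        model = truth.annotations.get(protein).topology
        if model is None:
            continue
        for _ in range(peptides_per_protein):
            length = int(rng.integers(7, 31))
            if length > model.length:
                raise ValueError(f"peptide longer than protein {protein}")
            start = int(rng.integers(1, model.length - length + 2))
            end = start + length - 1
            residue_domains = {model.residue_domain(pos) for pos in range(start, end + 1)}
            true_domain = (
                residue_domains.pop() if len(residue_domains) == 1 else "spanning"
            )
            rows.append(
                {"protein": protein, "start": start, "end": end,
                 "true_domain": true_domain}
            )
    return pd.DataFrame(rows, columns=["protein", "start", "end", "true_domain"])


# -- serialization ------------------------------------------------------------


def write_simulation(config: SimulationConfig, out_dir: str | Path,
                     peptides_per_protein: int = 10) -> dict[str, Path]:
    """Generate all tables and write them as the pipeline's input file set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell, truth = simulate_cell_proteome(config)
    secretome, _ = simulate_secretome(config)
    shedding, _ = simulate_shedding_experiment(config)
    peptides = simulate_peptides(truth, peptides_per_protein, seed=config.seed)

    paths = {
        "quant_cell": out_dir / "quant_cell.tsv",
        "samples_cell": out_dir / "samples_cell.tsv",
        "report_secretome": out_dir / "report_secretome.tsv",
        "samples_secretome": out_dir / "samples_secretome.tsv",
        "quant_shedding": out_dir / "quant_shedding.tsv",
        "samples_shedding": out_dir / "samples_shedding.tsv",
        "annotations": out_dir / "annotations.tsv",
        "peptides": out_dir / "peptides.tsv",
        "ground_truth": out_dir / "ground_truth.tsv",
    }
    quantio.write_quant_matrix(cell, paths["quant_cell"])
    quantio.write_samples(cell.samples, paths["samples_cell"])
    quantio.write_dia_report(secretome, paths["report_secretome"])
    quantio.write_samples(secretome.samples, paths["samples_secretome"])
    quantio.write_quant_matrix(shedding, paths["quant_shedding"])
    quantio.write_samples(shedding.samples, paths["samples_shedding"])
    quantio.write_annotations(truth.annotations, paths["annotations"])
    peptides[["protein", "start", "end"]].to_csv(paths["peptides"], sep="\t", index=False)
    truth_frame = truth.to_frame().merge(
        peptides.groupby("protein")["true_domain"]
        .apply(lambda s: ";".join(s))
        .rename("peptide_domains"),
        how="left", left_on="protein", right_index=True,
    )
    truth_frame.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
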