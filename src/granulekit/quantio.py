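"""Tabular I/O and validated quantification containers.

Everything in the pipeline travels as TSV: long-format DIA-NN style reports
(Protein.Group / Run / PG.MaxLFQ), wide protein x sample matrices, a
sample-metadata table, protein annotation tables (granule subsets, exclusion
classes, membrane topology, secretion-route predictions), and peptide
evidence with protein coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from granulekit.shedding import TopologyModel

COMPARTMENTS = ("cell", "supernatant")
CONDITIONS = ("CONTROL", "LPS", "TNFA", "PMA", "POLYIC")
GRANULE_SUBSETS = ("AG", "SG", "GG", "SV")
EXCLUSION_CLASSES = ("mitochondrial", "ribosomal", "histone", "none")
ROUTE_FLAGS = ("signal_peptide", "nonclassical", "transmembrane", "vesicle")

DEFAULT_QUANTITY_COLUMN = "PG.MaxLFQ"
PROTEIN_COLUMN = "Protein.Group"
RUN_COLUMN = "Run"

FLOAT_FORMAT = "%.17g"  # bit-exact float round trip through TSV


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    compartment: str
    condition: str
    time_min: int
    replicate: int = 1
    spikein_id: str | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.time_min < 0:
            raise ValueError("time_min must be non-negative")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


class QuantTable:
    """Protein x sample intensity matrix plus per-sample metadata.

    ``values`` is a float DataFrame (rows = protein accessions, columns =
    sample ids, NaN = missing); ``samples`` is indexed by sample id with
    columns compartment, condition, time_min, replicate (and any extras such
    as an ``inhibitor`` flag for shedding experiments).
    """

    SAMPLE_COLUMNS = ["compartment", "condition", "time_min", "replicate"]

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        values = values.astype(float)
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dupes}")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        missing_meta = [c for c in values.columns if c not in samples.index]
        if missing_meta:
            raise ValueError(f"samples without metadata: {missing_meta}")
        for col in self.SAMPLE_COLUMNS:
            if col not in samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")
        self.values = values
        self.samples = samples.loc[list(values.columns)].copy()
        self.samples.index.name = "sample_id"

    # -- convenience -------------------------------------------------------

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "QuantTable":
        return QuantTable(self.values.copy(), self.samples.copy())

    def subset_samples(self, mask: pd.Series) -> "QuantTable":
        cols = self.samples.index[mask].tolist()
        return QuantTable(self.values[cols], self.samples.loc[cols])

    def select(self, **criteria) -> "QuantTable":
        """Subset samples by metadata equality, e.g. select(condition='LPS')."""
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return self.subset_samples(mask)

    def equals(self, other: "QuantTable", rtol: float = 1e-12) -> bool:
        if list(self.values.index) != list(other.values.index):
            return False
        if list(self.values.columns) != list(other.values.columns):
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        same_nan = np.array_equal(np.isnan(a), np.isnan(b))
        return same_nan and bool(
            np.allclose(np.nan_to_num(a), np.nan_to_num(b), rtol=rtol, atol=0)
        )


@dataclass(frozen=True)
class ProteinAnnotation:
    """Per-protein reference annotation consumed (not recomputed) by the
    pipeline: granule-subset membership from published subcellular
    proteomics, exclusion class, membrane topology, and secretion-route
    predictions (signal peptide, nonclassical, transmembrane, vesicle)."""

    accession: str
    granule_subsets: frozenset = frozenset()
    exclusion_class: str = "none"
    is_membrane: bool = False
    topology: TopologyModel | None = None
    routes: tuple = ()  # subset of ROUTE_FLAGS that are true

    def __post_init__(self) -> None:
        bad = set(self.granule_subsets) - set(GRANULE_SUBSETS)
        if bad:
            raise ValueError(f"malformed granule subset token(s) {sorted(bad)}")
        if self.exclusion_class not in EXCLUSION_CLASSES:
            raise ValueError(f"unknown exclusion class {self.exclusion_class!r}")
        bad = set(self.routes) - set(ROUTE_FLAGS)
        if bad:
            raise ValueError(f"unknown route flag(s) {sorted(bad)}")
        if self.topology is not None and not self.is_membrane:
            raise ValueError("topology present but is_membrane is false")

    @property
    def is_canonical_granule(self) -> bool:
        return len(self.granule_subsets) > 0

    @property
    def predicted_secreted(self) -> bool:
        return len(self.routes) > 0


class AnnotationSet(dict):
    """accession -> ProteinAnnotation; unknown accessions get defaults."""

    def get(self, accession: str, default=None) -> ProteinAnnotation:  # type: ignore[override]
        if accession in self:
            return self[accession]
        return ProteinAnnotation(accession=accession)

    def __missing__(self, accession: str) -> ProteinAnnotation:
        return ProteinAnnotation(accession=accession)


# -- readers ---------------------------------------------------------------


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    samples = samples.set_index("sample_id")
    if samples.index.duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return samples


def read_dia_report(
    path: str | Path,
    samples: pd.DataFrame,
    quantity_column: str = DEFAULT_QUANTITY_COLUMN,
) -> QuantTable:
    """Pivot a long DIA-NN style report to a wide QuantTable.

    A (protein, run) pair absent from the report becomes a missing value.
    Duplicate pairs with conflicting values are a hard error; runs not
    present in the sample metadata are a hard error.
    """
    report = pd.read_csv(path, sep="\t")
    for col in (PROTEIN_COLUMN, RUN_COLUMN, quantity_column):
        if col not in report.columns:
            raise ValueError(f"report {path} lacks column {col!r}")
    unknown = set(report[RUN_COLUMN].unique()) - set(samples.index)
    if unknown:
        raise ValueError(f"runs without sample metadata: {sorted(unknown)}")
    dupes = report.duplicated([PROTEIN_COLUMN, RUN_COLUMN], keep=False)
    if dupes.any():
        conflicting = (
            report[dupes]
            .groupby([PROTEIN_COLUMN, RUN_COLUMN])[quantity_column]
            .nunique()
        )
        conflicting = conflicting[conflicting > 1]
        if len(conflicting):
            pair = conflicting.index[0]
            raise ValueError(
                f"conflicting duplicate rows for protein {pair[0]!r}, run {pair[1]!r}"
            )
        report = report.drop_duplicates([PROTEIN_COLUMN, RUN_COLUMN])
    wide = report.pivot(index=PROTEIN_COLUMN, columns=RUN_COLUMN, values=quantity_column)
    # preserve first-appearance protein order so write -> read is identity
    wide = wide.reindex(
        index=pd.unique(report[PROTEIN_COLUMN]), columns=list(samples.index)
    )
    wide.index.name = "protein"
    wide.columns.name = None
    return QuantTable(wide, samples)


def read_quant_matrix(path: str | Path, samples: pd.DataFrame) -> QuantTable:
    """Read a wide protein x sample TSV (first column = protein)."""
    wide = pd.read_csv(path, sep="\t", index_col=0)
    wide.index.name = "protein"
    return QuantTable(wide, samples)


def _parse_subsets(token) -> frozenset:
    if pd.isna(token) or token in ("", "-", "none"):
        return frozenset()
    parts = [p for p in str(token).split(";") if p]
    return frozenset(parts)


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read the annotation TSV.

    Columns: accession, granule_subsets (';'-joined tokens or '-'),
    exclusion_class, is_membrane (0/1), topology
    ('orientation:length:start-end[;start-end...]' or '-'), and one 0/1
    column per route flag. Only ``accession`` is mandatory.
    """
    table = pd.read_csv(path, sep="\t", dtype={"accession": str})
    if "accession" not in table.columns:
        raise ValueError(f"annotation table {path} lacks 'accession' column")
    annotations = AnnotationSet()
    for row in table.itertuples(index=False):
        acc = row.accession
        is_membrane = bool(int(getattr(row, "is_membrane", 0) or 0))
        topo_token = getattr(row, "topology", None)
        topology = None
        if topo_token is not None and not pd.isna(topo_token) and topo_token not in ("", "-"):
            topology = TopologyModel.from_token(acc, str(topo_token))
            is_membrane = True
        excl = getattr(row, "exclusion_class", "none")
        if pd.isna(excl) or excl == "":
            excl = "none"
        routes = tuple(
            flag for flag in ROUTE_FLAGS if int(getattr(row, flag, 0) or 0)
        )
        annotations[acc] = ProteinAnnotation(
            accession=acc,
            granule_subsets=_parse_subsets(getattr(row, "granule_subsets", None)),
            exclusion_class=str(excl),
            is_membrane=is_membrane,
            topology=topology,
            routes=routes,
        )
    return annotations


def read_peptides(path: str | Path) -> pd.DataFrame:
    peptides = pd.read_csv(path, sep="\t", dtype={"protein": str})
    for col in ("protein", "start", "end"):
        if col not in peptides.columns:
            raise ValueError(f"peptide table {path} lacks column {col!r}")
    return peptides


# -- writers ---------------------------------------------------------------


def annotations_frame(annotations: Mapping[str, ProteinAnnotation]) -> pd.DataFrame:
    rows = []
    for acc in sorted(annotations):
        ann = annotations[acc]
        rows.append(
            {
                "accession": acc,
                "granule_subsets": ";".join(sorted(ann.granule_subsets)) or "-",
                "exclusion_class": ann.exclusion_class,
                "is_membrane": int(ann.is_membrane),
                "topology": ann.topology.to_token() if ann.topology else "-",
                **{flag: int(flag in ann.routes) for flag in ROUTE_FLAGS},
            }
        )
    cols = ["accession", "granule_subsets", "exclusion_class", "is_membrane",
            "topology", *ROUTE_FLAGS]
    return pd.DataFrame(rows, columns=cols)


def write_annotations(annotations: Mapping[str, ProteinAnnotation], path: str | Path) -> None:
    annotations_frame(annotations).to_csv(path, sep="\t", index=False)


def write_quant_matrix(table: QuantTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t")


def write_dia_report(
    table: QuantTable, path: str | Path, quantity_column: str = DEFAULT_QUANTITY_COLUMN
) -> None:
    """Serialize a QuantTable to the long report dialect (missing values are
    simply absent rows)."""
    long = (
        table.values.rename_axis(index=PROTEIN_COLUMN, columns=RUN_COLUMN)
        .stack()
        .rename(quantity_column)
        .reset_index()
    )
    long.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write a dict of result DataFrames as deterministic TSV files.

    Column order is preserved; rewriting the same tables produces identical
    bytes. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        frame = tables[name]
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(path)
    return written
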