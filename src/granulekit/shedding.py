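"""MMP/ADAM shedding-substrate calls and peptide topology mapping.

Substrates are membrane proteins whose soluble (supernatant) level drops
when a broad metalloproteinase inhibitor (GM6001) is present during
stimulation: a two-tailed Welch t test on log2 intensities with p < 0.05 and
log2(stimulus / stimulus+inhibitor) > 0.6. Topology mapping assigns each
MS-detected peptide to the extracellular, transmembrane, or intracellular
region of a single-pass membrane protein; a high extracellular fraction is
the ectodomain-shedding signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from granulekit.quantio import QuantTable

INHIBITOR_SUFFIX = "+GM6001"

PEPTIDE_DOMAINS = ("extracellular", "transmembrane", "intracellular", "spanning")


@dataclass(frozen=True)
class TopologyModel:
    """Single- or multi-pass membrane topology with 1-based inclusive TM spans.

    ``type_I`` orientation puts the N terminus outside the cell, ``type_II``
    puts the C terminus outside.
    """

    protein: str
    length: int
    orientation: str  # "type_I" | "type_II"
    tm_spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.orientation not in ("type_I", "type_II"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.length < 1:
            raise ValueError("protein length must be positive")
        spans = tuple((int(a), int(b)) for a, b in self.tm_spans)
        if not spans:
            raise ValueError("at least one TM span required")
        prev_end = 0
        for a, b in spans:
            if a < 1 or b > self.length or a > b:
                raise ValueError(f"TM span {a}-{b} outside [1, {self.length}]")
            if a <= prev_end:
                raise ValueError("TM spans must be sorted and non-overlapping")
            prev_end = b
        object.__setattr__(self, "tm_spans", spans)

    @property
    def n_terminal_domain(self) -> str:
        return "extracellular" if self.orientation == "type_I" else "intracellular"

    @property
    def c_terminal_domain(self) -> str:
        # single-pass: C-terminal side is the opposite of the N-terminal side
        return "intracellular" if self.orientation == "type_I" else "extracellular"

    def residue_domain(self, position: int) -> str:
        """Domain of one residue; interior loops of multi-pass models are
        'spanning' (ambiguous by design)."""
        if position < 1 or position > self.length:
            raise ValueError(f"residue {position} outside [1, {self.length}]")
        for a, b in self.tm_spans:
            if a <= position <= b:
                return "transmembrane"
        if position < self.tm_spans[0][0]:
            return self.n_terminal_domain
        if position > self.tm_spans[-1][1]:
            return self.c_terminal_domain
        return "spanning"

    def to_token(self) -> str:
        spans = ";".join(f"{a}-{b}" for a, b in self.tm_spans)
        return f"{self.orientation}:{self.length}:{spans}"

    @classmethod
    def from_token(cls, protein: str, token: str) -> "TopologyModel":
        try:
            orientation, length, spans = token.split(":")
            tm = tuple(
                (int(s.split("-")[0]), int(s.split("-")[1]))
                for s in spans.split(";")
                if s
            )
            return cls(protein=protein, length=int(length), orientation=orientation, tm_spans=tm)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed topology token {token!r} for {protein}") from exc


def assign_peptide_domain(model: TopologyModel, start: int, end: int) -> str:
    """Assign a detected peptide (1-based inclusive interval) to a membrane
    domain.

    A peptide fully inside one region gets that region's label; a peptide
    overlapping a TM boundary, or lying in an ambiguous interior loop of a
    multi-pass model, is 'spanning'.
    """
    if start < 1 or end > model.length or start > end:
        raise ValueError(
            f"peptide {start}-{end} outside protein {model.protein} [1, {model.length}]"
        )
    first = model.residue_domain(start)
    if first == "spanning":
        return "spanning"
    for pos in range(start + 1, end + 1):
        if model.residue_domain(pos) != first:
            return "spanning"
    return first


@dataclass
class TopologyCall:
    """Protein-level ectodomain evidence from mapped peptides."""

    protein: str
    n_peptides: int
    domain_counts: dict = field(default_factory=dict)
    ectodomain_fraction: float | None = None

    @property
    def majority_extracellular(self) -> bool:
        return self.ectodomain_fraction is not None and self.ectodomain_fraction > 0.5


def ectodomain_summary(protein: str, domains: Iterable[str]) -> TopologyCall:
    """Fraction of classified (non-spanning) peptides that map to the
    extracellular region.

    Proteins whose every peptide is 'spanning' are unscored
    (``ectodomain_fraction`` is None).
    """
    domains = list(domains)
    if not domains:
        raise ValueError(f"no classified peptides for {protein}")
    counts: dict[str, int] = {}
    for d in domains:
        if d not in PEPTIDE_DOMAINS:
            raise ValueError(f"unknown peptide domain {d!r}")
        counts[d] = counts.get(d, 0) + 1
    n_classified = sum(v for k, v in counts.items() if k != "spanning")
    frac = counts.get("extracellular", 0) / n_classified if n_classified else None
    return TopologyCall(
        protein=protein,
        n_peptides=len(domains),
        domain_counts=counts,
        ectodomain_fraction=frac,
    )


def topology_calls(peptides: pd.DataFrame, models: Mapping[str, TopologyModel]) -> pd.DataFrame:
    """Map a peptide evidence table (columns protein, start, end) onto
    topology models and summarize per protein.

    Proteins without a topology model are skipped.
    """
    rows = []
    for protein, grp in peptides.groupby("protein", sort=True):
        model = models.get(protein)
        if model is None:
            continue
        domains = [
            assign_peptide_domain(model, int(s), int(e))
            for s, e in zip(grp["start"], grp["end"])
        ]
        call = ectodomain_summary(str(protein), domains)
        rows.append(
            {
                "protein": protein,
                "n_peptides": call.n_peptides,
                "n_extracellular": call.domain_counts.get("extracellular", 0),
                "n_transmembrane": call.domain_counts.get("transmembrane", 0),
                "n_intracellular": call.domain_counts.get("intracellular", 0),
                "n_spanning": call.domain_counts.get("spanning", 0),
                "ectodomain_fraction": call.ectodomain_fraction,
                "majority_extracellular": call.majority_extracellular,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein",
            "n_peptides",
            "n_extracellular",
            "n_transmembrane",
            "n_intracellular",
            "n_spanning",
            "ectodomain_fraction",
            "majority_extracellular",
        ],
    )


def call_substrates(
    table: "QuantTable",
    membrane_proteins: Iterable[str],
    stimulus: str,
    p_threshold: float = 0.05,
    log2fc_threshold: float = 0.6,
    adjust: bool = False,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Call MMP/ADAM shedding substrates from a stimulus vs
    stimulus+inhibitor supernatant experiment.

    log2_fc = log2(mean(stimulus) / mean(stimulus+inhibitor)); a substrate
    must be significantly different (two-tailed Welch t on log2 intensities)
    AND reduced under the inhibitor (signed log2_fc above the threshold).
    Proteins with fewer than ``min_replicates`` complete replicates in either
    arm are reported untested. ``adjust=True`` applies Benjamini-Hochberg
    across tested proteins (off by default: the screen uses plain p values).
    """
    membrane = [p for p in membrane_proteins if p in table.values.index]
    meta = table.samples
    stim_cols = meta.index[(meta["condition"] == stimulus)].tolist()
    inhib_cols = meta.index[(meta["condition"] == stimulus + INHIBITOR_SUFFIX)].tolist()
    if not stim_cols or not inhib_cols:
        raise ValueError(f"missing arm for stimulus {stimulus!r}")

    rows = []
    for protein in membrane:
        a = table.values.loc[protein, stim_cols].astype(float).dropna()
        b = table.values.loc[protein, inhib_cols].astype(float).dropna()
        if len(a) < min_replicates or len(b) < min_replicates:
            rows.append(
                {"protein": protein, "stimulus": stimulus, "log2_fc": np.nan,
                 "p": np.nan, "tested": False, "substrate": False}
            )
            continue
        log2_fc = float(np.log2(a.mean() / b.mean()))
        la, lb = np.log2(a.to_numpy()), np.log2(b.to_numpy())
        if np.ptp(la) == 0 and np.ptp(lb) == 0:
            p = 1.0 if la[0] == lb[0] else 0.0
        else:
            p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
        rows.append(
            {"protein": protein, "stimulus": stimulus, "log2_fc": log2_fc,
             "p": p, "tested": True, "substrate": False}
        )
    calls = pd.DataFrame(
        rows, columns=["protein", "stimulus", "log2_fc", "p", "tested", "substrate"]
    )
    pcol = "p"
    if adjust and calls["tested"].any():
        from statsmodels.stats.multitest import multipletests

        tested = calls["tested"].to_numpy()
        adj = np.full(len(calls), np.nan)
        adj[tested] = multipletests(calls.loc[tested, "p"], method="fdr_bh")[1]
        calls["adj_p"] = adj
        pcol = "adj_p"
    calls["substrate"] = (
        calls["tested"]
        & (calls[pcol] < p_threshold)
        & (calls["log2_fc"] > log2fc_threshold)
    )
    return calls


def compare_conditions(calls_by_stimulus: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Protein x stimulus substrate grid (sheddase sensitivity matrix)."""
    if not calls_by_stimulus:
        return pd.DataFrame()
    cols = {}
    for stim, calls in calls_by_stimulus.items():
        cols[stim] = calls.set_index("protein")["substrate"]
    grid = pd.DataFrame(cols).fillna(False).astype(bool)
    grid.index.name = "protein"
    return grid.sort_index()
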