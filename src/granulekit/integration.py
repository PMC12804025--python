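"""Integration of cellular and supernatant kinetics.

Joins each protein's cellular relative-percentage trajectory with its
supernatant fold-change trajectory under the same stimulus and labels the
release pattern (released with/without cellular depletion, induced,
depletion only, unchanged). The visual "concordant decrease" judgment is
made reproducible with explicit numeric stand-ins: depletion means a
negative trend AND a drop of at least ``depletion_delta`` percentage points
below baseline; induction means a positive trend AND a rise of at least
``induction_delta`` points.

Kinetic similarity assigns candidate granule subtypes: a protein whose
z-scored supernatant trajectory correlates strongly (Pearson r >= 0.8 by
default) with the consensus trajectory of a subset's marker proteins is a
candidate member of that subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from granulekit.release_analysis import fit_linear_trend

PATTERN_LABELS = (
    "released_with_depletion",
    "released_without_depletion",
    "induced_cellular",
    "depletion_only",
    "unchanged",
    "unscored",
)

# markers of each granule subset used for the kinetic consensus
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "AG": ("AZU1", "MPO", "ELANE", "PRTN3"),
    "SG": ("LCN2", "LTF", "MMP8", "CHI3L1", "CRISP3", "TCN1", "LRG1", "OLFM4"),
    "GG": ("FCN1", "FGL2", "MMP9", "CAMP", "CHIT1", "CD93", "PGLYRP1"),
    "SV": ("FCGR3B", "CD14", "CD11b"),
}

DEFAULT_DEPLETION_DELTA = 20.0
DEFAULT_INDUCTION_DELTA = 50.0
DEFAULT_R_THRESHOLD = 0.8


@dataclass
class PatternLabel:
    protein: str
    condition: str
    label: str
    evidence: dict


def label_pattern(
    cell_points: Sequence[tuple[float, float]],
    released: bool,
    depletion_delta: float = DEFAULT_DEPLETION_DELTA,
    induction_delta: float = DEFAULT_INDUCTION_DELTA,
) -> tuple[str, dict]:
    """Label one protein/condition from its cellular relative-percentage
    points and its release call.

    Decision table: release flag x {depletion, induction, neither}.
    An undefined cellular trajectory yields 'unscored'.
    """
    t = np.array([p[0] for p in cell_points], dtype=float)
    v = np.array([p[1] for p in cell_points], dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        return "unscored", {"n_points": int(ok.sum())}
    slope = fit_linear_trend(t[ok], v[ok])
    vmin, vmax = float(np.min(v[ok])), float(np.max(v[ok]))
    depleted = slope < 0 and vmin <= 100.0 - depletion_delta
    induced = slope > 0 and vmax >= 100.0 + induction_delta
    evidence = {
        "cell_slope_per_h": slope,
        "cell_min_percent": vmin,
        "cell_max_percent": vmax,
        "released": bool(released),
    }
    if released:
        label = "released_with_depletion" if depleted else "released_without_depletion"
    elif induced:
        label = "induced_cellular"
    elif depleted:
        label = "depletion_only"
    else:
        label = "unchanged"
    return label, evidence


def label_patterns(
    cell_trajectories: pd.DataFrame,
    release_calls: pd.DataFrame,
    depletion_delta: float = DEFAULT_DEPLETION_DELTA,
    induction_delta: float = DEFAULT_INDUCTION_DELTA,
) -> pd.DataFrame:
    """Vectorized labeling over a tidy cellular trajectory frame joined to
    release calls on (protein, condition)."""
    released = release_calls.set_index(["protein", "condition"])["released"]
    rows = []
    for (protein, condition), grp in cell_trajectories.groupby(
        ["protein", "condition"], sort=True
    ):
        if (protein, condition) not in released.index:
            continue
        points = list(zip(grp["time_min"], grp["value"]))
        label, evidence = label_pattern(
            points,
            released=bool(released.loc[(protein, condition)]),
            depletion_delta=depletion_delta,
            induction_delta=induction_delta,
        )
        rows.append(
            {"protein": protein, "condition": condition, "label": label, **evidence}
        )
    return pd.DataFrame(rows)


def _zscore(values: np.ndarray) -> np.ndarray | None:
    sd = values.std(ddof=0)
    if sd == 0 or np.isnan(sd):
        return None
    return (values - values.mean()) / sd


def kinetic_similarity(
    sup_trajectories: pd.DataFrame,
    marker_lists: Mapping[str, Sequence[str]] | None = None,
    r_threshold: float = DEFAULT_R_THRESHOLD,
) -> pd.DataFrame:
    """Assign candidate granule subtypes by similarity of secretion kinetics
    to marker consensus profiles.

    The consensus of a subset is the mean of its markers' z-scored
    fold-change trajectories; a protein is assigned to the best-matching
    subset when the Pearson correlation of its z-scored trajectory with that
    consensus is at or above the threshold. Requires at least three shared
    time points; zero-variance trajectories are unscored.
    """
    marker_lists = dict(marker_lists or DEFAULT_MARKERS)
    matrix = sup_trajectories.pivot_table(
        index="protein", columns="time_min", values="value", aggfunc="mean"
    )
    matrix = matrix.dropna(axis=0)
    if matrix.shape[1] < 3:
        raise ValueError("need at least three shared time points")

    z = {}
    for protein in matrix.index:
        scored = _zscore(matrix.loc[protein].to_numpy())
        if scored is not None:
            z[protein] = scored

    consensus = {}
    for subset, markers in marker_lists.items():
        profiles = [z[m] for m in markers if m in z]
        if not profiles:
            continue
        consensus[subset] = np.mean(profiles, axis=0)
    if not consensus:
        raise ValueError("no marker trajectories found in the input")

    rows = []
    for protein in matrix.index:
        if protein not in z:
            rows.append(
                {"protein": protein, "subset": "", "similarity": np.nan,
                 "assigned": False, "scored": False}
            )
            continue
        sims = {
            subset: float(np.corrcoef(z[protein], cons)[0, 1])
            for subset, cons in consensus.items()
        }
        best = max(sims, key=lambda s: (sims[s], s))
        rows.append(
            {
                "protein": protein,
                "subset": best,
                "similarity": sims[best],
                "assigned": sims[best] >= r_threshold,
                "scored": True,
            }
        )
    return pd.DataFrame(
        rows, columns=["protein", "subset", "similarity", "assigned", "scored"]
    )


def plot_paired_trajectories(
    cell_trajectories: pd.DataFrame,
    sup_trajectories: pd.DataFrame,
    protein: str,
    condition: str,
    ax=None,
):
    """Paired-axis line plot: cellular relative percentage (left axis)
    against supernatant fold change (right axis) for one protein/condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    cell = cell_trajectories.query("protein == @protein and condition == @condition")
    sup = sup_trajectories.query("protein == @protein and condition == @condition")
    ax.plot(cell["time_min"], cell["value"], color="tab:red", marker="o",
            label="cell (% of 0 min)")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("relative percentage (%)", color="tab:red")
    ax2 = ax.twinx()
    ax2.plot(sup["time_min"], sup["value"], color="tab:blue", marker="s",
             label="supernatant FC")
    ax2.set_ylabel("fold change", color="tab:blue")
    ax.set_title(f"{protein} — {condition}")
    return ax
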