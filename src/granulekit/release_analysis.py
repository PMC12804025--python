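"""The released-protein screen.

A protein is called released under a condition when (1) the ordinary
least-squares slope of its supernatant fold-change trajectory over time is
strictly positive and (2) its observed fold change strictly exceeds 1.5 at
one or more post-stimulation time points; mitochondrial, ribosomal, and
histone proteins are then excluded. Per-condition calls are combined by set
union into a release catalog split into canonical granule proteins (present
in published granule references) and non-canonical released proteins, with
granule-subset tallies, the 2-h release-level table, secretion-route
aggregation for the non-canonical set, and the cross-condition consistent
core-set screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from granulekit.quantio import GRANULE_SUBSETS, ROUTE_FLAGS, AnnotationSet
from granulekit.preprocess import trajectory_matrix

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_SLOPE_MIN = 0.0


def fit_linear_trend(time_min: Sequence[float], values: Sequence[float]) -> float:
    """OLS slope of fold change per hour; missing points dropped.

    Returns NaN (undefined) with fewer than two non-missing points or a
    degenerate time axis.
    """
    t = np.asarray(time_min, dtype=float) / 60.0
    y = np.asarray(values, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(t)
    if ok.sum() < 2 or np.ptp(t[ok]) == 0:
        return float("nan")
    return float(stats.linregress(t[ok], y[ok]).slope)


def trend_stats(
    trajectories: pd.DataFrame, use_log_fc: bool = False
) -> pd.DataFrame:
    """Per (protein, condition): fitted slope (per hour) and the maximum
    observed fold change at t > 0.

    The 0-min point carries no stimulation signal (FC ~ 1 by construction)
    and is excluded from the max; it does enter the linear fit.
    ``use_log_fc`` fits the line on log2 FC instead of raw FC.
    """
    rows = []
    for (protein, condition), grp in trajectories.groupby(
        ["protein", "condition"], sort=True
    ):
        t = grp["time_min"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        fit_y = np.log2(y) if use_log_fc else y
        slope = fit_linear_trend(t, fit_y)
        post = y[(t > 0) & ~np.isnan(y)]
        max_fc = float(post.max()) if post.size else float("nan")
        rows.append(
            {
                "protein": protein,
                "condition": condition,
                "slope": slope,
                "max_fc": max_fc,
                "n_points": int((~np.isnan(y)).sum()),
            }
        )
    return pd.DataFrame(
        rows, columns=["protein", "condition", "slope", "max_fc", "n_points"]
    )


def classify_released(
    stats_table: pd.DataFrame,
    annotations: AnnotationSet,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    slope_min: float = DEFAULT_SLOPE_MIN,
) -> pd.DataFrame:
    """Apply the release rule (strict inequalities) then the exclusion list.

    Each call records whether it was excluded and why; a protein with an
    undefined slope is flagged and never released.
    """
    calls = stats_table.copy()
    meets_rule = (
        (calls["slope"] > slope_min)
        & (calls["max_fc"] > fc_threshold)
        & calls["slope"].notna()
        & calls["max_fc"].notna()
    )
    exclusion = calls["protein"].map(
        lambda p: annotations.get(p).exclusion_class
    )
    excluded = exclusion != "none"
    calls["released"] = meets_rule & ~excluded
    calls["excluded"] = meets_rule & excluded  # exclusion applied after the rule
    calls["exclusion_reason"] = np.where(calls["excluded"], exclusion, "")
    calls["undefined_slope"] = calls["slope"].isna()
    return calls


def call_release(
    trajectories: pd.DataFrame,
    annotations: AnnotationSet,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    slope_min: float = DEFAULT_SLOPE_MIN,
    use_log_fc: bool = False,
) -> pd.DataFrame:
    """Fit trends and classify in one step (per condition present in the
    trajectory frame)."""
    return classify_released(
        trend_stats(trajectories, use_log_fc=use_log_fc),
        annotations,
        fc_threshold=fc_threshold,
        slope_min=slope_min,
    )


@dataclass
class ReleaseCatalog:
    """Cross-condition union of released proteins.

    ``membership`` is a protein x condition boolean frame over the union;
    ``classes`` maps each catalog protein to 'canonical_granule' (non-empty
    granule-subset annotation) or 'non_canonical'.
    """

    membership: pd.DataFrame
    classes: pd.Series

    @property
    def proteins(self) -> list[str]:
        return list(self.membership.index)

    @property
    def canonical(self) -> list[str]:
        return list(self.classes.index[self.classes == "canonical_granule"])

    @property
    def non_canonical(self) -> list[str]:
        return list(self.classes.index[self.classes == "non_canonical"])

    def __len__(self) -> int:
        return len(self.membership)

    def to_frame(self) -> pd.DataFrame:
        out = self.membership.astype(int).copy()
        out.insert(0, "class", self.classes)
        return out.rename_axis("protein").reset_index()


def combine_conditions(
    calls: pd.DataFrame | Mapping[str, pd.DataFrame],
    annotations: AnnotationSet,
) -> ReleaseCatalog:
    """Union the per-condition released sets and split the catalog into
    canonical vs non-canonical by granule-subset annotation."""
    if isinstance(calls, Mapping):
        calls = pd.concat(calls.values(), ignore_index=True)
    if calls.empty:
        membership = pd.DataFrame(index=pd.Index([], name="protein"), dtype=bool)
    else:
        released = calls[calls["released"]]
        membership = (
            released.assign(flag=True)
            .pivot_table(index="protein", columns="condition", values="flag",
                         aggfunc="any", fill_value=False)
            .astype(bool)
            .sort_index()
        )
        membership.columns.name = None
    classes = pd.Series(
        [
            "canonical_granule"
            if annotations.get(p).is_canonical_granule
            else "non_canonical"
            for p in membership.index
        ],
        index=membership.index,
        name="class",
    )
    return ReleaseCatalog(membership=membership, classes=classes)


def summarize_granule_subsets(
    catalog: ReleaseCatalog, annotations: AnnotationSet
) -> pd.DataFrame:
    """Count catalog proteins per granule subset (multi-membership counts a
    protein in every subset it belongs to) and per condition."""
    rows = []
    for subset in GRANULE_SUBSETS:
        members = [
            p for p in catalog.proteins
            if subset in annotations.get(p).granule_subsets
        ]
        row = {"subset": subset, "n_total": len(members)}
        for cond in catalog.membership.columns:
            row[f"n_{cond}"] = int(catalog.membership.loc[members, cond].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def per_condition_counts(catalog: ReleaseCatalog) -> pd.Series:
    """Number of catalog proteins released under each condition."""
    return catalog.membership.sum(axis=0).astype(int)


def release_level_2h(
    trajectories: pd.DataFrame, catalog: ReleaseCatalog, time_min: int = 120
) -> pd.DataFrame:
    """Supernatant fold change at 2 h (the release-level summary) for every
    catalog protein x condition; missing trajectory points stay missing."""
    levels = {}
    for condition, grp in trajectories.groupby("condition"):
        matrix = trajectory_matrix(grp)
        if time_min not in matrix.columns:
            raise ValueError(f"no {time_min}-min point for condition {condition!r}")
        levels[condition] = matrix[time_min]
    out = pd.DataFrame(levels).reindex(catalog.proteins)
    out.index.name = "protein"
    return out


def aggregate_secretion_routes(
    non_canonical: Sequence[str], annotations: AnnotationSet
) -> dict:
    """Aggregate secretion-route predictions over the non-canonical released
    set: per-route fractions and the overall predicted-secreted share
    (a protein counts if any of the four route flags is set)."""
    proteins = list(non_canonical)
    n = len(proteins)
    per_route = {}
    for flag in ROUTE_FLAGS:
        hits = sum(flag in annotations.get(p).routes for p in proteins)
        per_route[flag] = {"n": hits, "fraction": hits / n if n else 0.0}
    secreted = sorted(p for p in proteins if annotations.get(p).predicted_secreted)
    return {
        "n_non_canonical": n,
        "per_route": per_route,
        "predicted_secreted": secreted,
        "n_secreted": len(secreted),
        "percent_secreted": int(round(100.0 * len(secreted) / n)) if n else 0,
    }


def consistent_core_set(
    de_results: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Proteins significant (adj_p < alpha) in every condition with the same
    sign of log2 fold change, with that shared direction."""
    if not de_results:
        raise ValueError("no differential results supplied")
    per_condition = []
    for cond, de in de_results.items():
        hits = de[(de["adj_p"] < alpha) & de["tested"] & (de["log2_fc"] != 0)]
        per_condition.append(
            hits.set_index("protein")["log2_fc"].apply(np.sign).rename(cond)
        )
    signs = pd.concat(per_condition, axis=1, join="inner")
    consistent = signs.nunique(axis=1) == 1
    out = pd.DataFrame(
        {
            "protein": signs.index[consistent],
            "direction": np.where(signs.loc[consistent].iloc[:, 0] > 0, "up", "down"),
        }
    ).sort_values("protein", ignore_index=True)
    return out
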