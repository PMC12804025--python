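"""Normalization, trajectory computation, and the differential test.

The secretome is normalized in two steps: per-sample median alignment of
log2 intensities, then rescaling by the relative abundance of the external
spike-in standard (constant-amount protein A added to every sample). Cell
tables are assumed normalized upstream; ``median_normalize`` is available as
a fallback.

Trajectories come in two kinds: supernatant fold-change (stimulated vs
control at each matched time point) and cellular relative percentage
(percent of the 0-min baseline). Both are tidy frames with columns
(protein, condition, kind, time_min, value).

The differential test is a two-tailed Welch t on log2 intensities with
Benjamini-Hochberg adjustment across proteins within one (condition, time)
stratum; variance moderation used by dedicated proteomics packages is
deliberately not reimplemented here (the screens are driven by the
thresholds, not the moderation).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from granulekit.quantio import QuantTable

TRAJECTORY_COLUMNS = ["protein", "condition", "kind", "time_min", "value"]


# -- normalization -----------------------------------------------------------


def median_normalize(table: QuantTable) -> QuantTable:
    """Shift each sample's log2 intensities so its median equals the grand
    median of sample medians. Missing values are preserved. Idempotent."""
    log2 = np.log2(table.values)
    medians = log2.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"all-missing sample(s): {bad}")
    grand = medians.median()
    normalized = 2 ** (log2 - medians + grand)
    return QuantTable(normalized, table.samples)


def spikein_normalize(table: QuantTable, spikein_id: str) -> QuantTable:
    """Divide each sample by the relative abundance of the spike-in standard
    (its intensity over the geometric mean of its intensities across all
    samples). The spike-in row becomes constant; the op is idempotent."""
    if spikein_id not in table.values.index:
        raise ValueError(f"spike-in row {spikein_id!r} not in table")
    spike = table.values.loc[spikein_id]
    if spike.isna().any() or (spike <= 0).any():
        bad = spike.index[spike.isna() | (spike <= 0)].tolist()
        raise ValueError(f"spike-in missing or non-positive in sample(s): {bad}")
    reference = float(np.exp(np.log(spike.to_numpy()).mean()))
    factors = spike / reference
    return QuantTable(table.values / factors, table.samples)


# -- trajectories -------------------------------------------------------------


def _group_means(table: QuantTable, condition: str) -> pd.DataFrame:
    """Protein x time_min matrix of replicate-mean intensities (mean over
    the non-missing replicates; NaN when none observed)."""
    sub = table.select(condition=condition)
    groups = sub.samples.groupby("time_min").groups
    means = {
        t: sub.values[list(cols)].mean(axis=1, skipna=True)
        for t, cols in groups.items()
    }
    out = pd.DataFrame(means)
    return out[sorted(out.columns)]


def _tidy(matrix: pd.DataFrame, condition: str, kind: str) -> pd.DataFrame:
    tidy = (
        matrix.rename_axis(index="protein", columns="time_min")
        .stack(future_stack=True)
        .rename("value")
        .reset_index()
    )
    tidy.insert(1, "condition", condition)
    tidy.insert(2, "kind", kind)
    return tidy[TRAJECTORY_COLUMNS]


def relative_percentage(table: QuantTable, condition: str) -> pd.DataFrame:
    """Cellular relative percentage: 100 x mean LFQ(t) / mean LFQ(0) per
    protein. Proteins with a zero or missing baseline get an all-missing
    (undefined) trajectory rather than an exception."""
    means = _group_means(table, condition)
    if 0 not in means.columns:
        raise ValueError(f"no 0-min baseline for condition {condition!r}")
    baseline = means[0]
    percent = 100.0 * means.div(baseline, axis=0)
    undefined = baseline.isna() | (baseline == 0)
    percent.loc[undefined, :] = np.nan
    return _tidy(percent, condition, "relative_percentage")


def fold_change_timecourse(
    table: QuantTable, condition: str, control_condition: str = "CONTROL"
) -> pd.DataFrame:
    """Supernatant fold change: stimulated over control at each shared time
    point (replicate means in each arm). A point missing in either arm is a
    missing point."""
    stim = _group_means(table, condition)
    ctrl = _group_means(table, control_condition)
    shared = [t for t in stim.columns if t in ctrl.columns]
    if not shared:
        raise ValueError(
            f"no shared time points between {condition!r} and {control_condition!r}"
        )
    fc = stim[shared] / ctrl[shared]
    fc[ctrl[shared] == 0] = np.nan
    return _tidy(fc, condition, "fold_change")


def trajectory_matrix(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy trajectory frame (single condition/kind) to protein x
    time_min."""
    return trajectories.pivot(index="protein", columns="time_min", values="value")


# -- differential test ---------------------------------------------------------


def differential_test(
    table: QuantTable,
    condition: str,
    time_min: int,
    control_condition: str = "CONTROL",
    alpha: float = 0.01,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Two-tailed Welch t test on log2 intensities, stimulated vs control at
    one time point, BH-adjusted across the tested proteins of the stratum.

    significant <=> adj_p <= alpha AND |fold change| >= fc_threshold (on the
    linear scale, i.e. |log2 FC| >= log2(fc_threshold)). Proteins with fewer
    than two complete replicates in either arm are reported untested.
    """
    stim = table.select(condition=condition, time_min=time_min).values
    ctrl = table.select(condition=control_condition, time_min=time_min).values
    if stim.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need at least two replicates per arm")

    a = np.log2(stim.to_numpy())
    b = np.log2(ctrl.to_numpy())
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    tested = (n_a >= 2) & (n_b >= 2)

    with warnings.catch_warnings():
        # untested rows (too few complete replicates) are flagged below
        warnings.simplefilter("ignore")
        log2_fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
        # identical arms with zero variance: no evidence against the null
        zero_var = (np.nanvar(a, axis=1) == 0) & (np.nanvar(b, axis=1) == 0)
    p = np.where(zero_var & (log2_fc == 0), 1.0, p)
    p = np.where(tested, p, np.nan)
    log2_fc = np.where(tested, log2_fc, np.nan)

    adj_p = np.full(len(p), np.nan)
    if tested.any():
        adj_p[tested] = multipletests(p[tested], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "protein": table.values.index,
            "condition": condition,
            "time_min": time_min,
            "log2_fc": log2_fc,
            "p": p,
            "adj_p": adj_p,
            "tested": tested,
        }
    )
    out["significant"] = (
        out["tested"]
        & (out["adj_p"] <= alpha)
        & (np.abs(out["log2_fc"]) >= np.log2(fc_threshold))
    )
    return out
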