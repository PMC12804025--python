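"""Normalization, trajectories, and the differential test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from granulekit import preprocess
from granulekit import synthetic_data as sd
from conftest import make_table, sample_meta
from oracles import brute_force_bh


def simple_table(values_by_protein, n_samples, condition="LPS"):
    meta = [sample_meta(f"s{i}", condition, i * 10) for i in range(n_samples)]
    return make_table(values_by_protein, meta)


class TestMedianNormalize:
    def test_equal_medians_is_identity(self):
        table = simple_table({"P1": [2.0, 2.0], "P2": [8.0, 8.0]}, 2)
        out = preprocess.median_normalize(table)
        assert table.equals(out)

    def test_scaled_sample_restored(self):
        base = {"P1": [2.0], "P2": [8.0], "P3": [4.0]}
        table = simple_table(
            {p: v + [v[0] * 2] for p, v in base.items()}, 2
        )
        out = preprocess.median_normalize(table)
        np.testing.assert_allclose(out.values["s1"], out.values["s0"], rtol=1e-9)

    def test_single_sample_is_identity(self):
        table = simple_table({"P1": [3.0], "P2": [5.0]}, 1)
        assert preprocess.median_normalize(table).equals(table)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        table = simple_table(
            {f"P{i}": list(rng.lognormal(10, 1, 4)) for i in range(30)}, 4
        )
        once = preprocess.median_normalize(table)
        twice = preprocess.median_normalize(once)
        assert once.equals(twice, rtol=1e-9)

    def test_all_missing_sample_rejected(self):
        table = simple_table({"P1": [1.0, np.nan], "P2": [2.0, np.nan]}, 2)
        with pytest.raises(ValueError, match="all-missing"):
            preprocess.median_normalize(table)

    def test_missing_values_preserved(self):
        table = simple_table({"P1": [1.0, np.nan], "P2": [2.0, 4.0], "P3": [3.0, 6.0]}, 2)
        out = preprocess.median_normalize(table)
        assert np.isnan(out.values.loc["P1", "s1"])


class TestSpikeinNormalize:
    def test_constant_spikein_is_identity(self):
        table = simple_table({"SPIKE": [5.0, 5.0], "P1": [1.0, 9.0]}, 2)
        assert preprocess.spikein_normalize(table, "SPIKE").equals(table)

    def test_doubled_spikein_sample_halved(self):
        table = simple_table({"SPIKE": [5.0, 5.0, 10.0], "P1": [4.0, 4.0, 4.0]}, 3)
        out = preprocess.spikein_normalize(table, "SPIKE")
        ratio = out.values.loc["P1", "s2"] / out.values.loc["P1", "s0"]
        np.testing.assert_allclose(ratio, 0.5, rtol=1e-12)

    def test_idempotent_and_spike_cv_zero(self):
        rng = np.random.default_rng(1)
        table = simple_table(
            {"SPIKE": list(rng.uniform(1, 4, 5)),
             **{f"P{i}": list(rng.lognormal(8, 1, 5)) for i in range(10)}},
            5,
        )
        once = preprocess.spikein_normalize(table, "SPIKE")
        spike = once.values.loc["SPIKE"]
        assert spike.std(ddof=0) / spike.mean() < 1e-12
        twice = preprocess.spikein_normalize(once, "SPIKE")
        assert once.equals(twice, rtol=1e-9)

    def test_missing_spikein_names_sample(self):
        table = simple_table({"SPIKE": [5.0, np.nan], "P1": [1.0, 2.0]}, 2)
        with pytest.raises(ValueError, match="s1"):
            preprocess.spikein_normalize(table, "SPIKE")

    def test_noise_free_generator_roundtrip(self, noise_free_config):
        # random run scales, noise-free table: planted fold-change templates
        # recovered within 1e-9 after spike-in normalization
        table, truth = sd.simulate_secretome(noise_free_config)
        norm = preprocess.spikein_normalize(table, sd.SPIKEIN_ID)
        fc = preprocess.trajectory_matrix(
            preprocess.fold_change_timecourse(norm, "PMA")
        )
        for protein in truth.released_proteins:
            expected = [
                sd.release_fc_template(noise_free_config, t) for t in fc.columns
            ]
            np.testing.assert_allclose(fc.loc[protein], expected, rtol=1e-9)


class TestTrajectories:
    def test_relative_percentage_baseline_and_halving(self):
        meta = [sample_meta(f"s{t}", "LPS", t, compartment="cell") for t in (0, 60)]
        table = make_table({"P1": [10.0, 5.0]}, meta)
        rel = preprocess.trajectory_matrix(preprocess.relative_percentage(table, "LPS"))
        assert rel.loc["P1", 0] == 100.0
        assert rel.loc["P1", 60] == 50.0

    def test_relative_percentage_uses_replicate_means(self):
        # replicates {8,10,12} at t vs {10,10,10} at baseline -> 100%
        meta = [
            sample_meta(f"b{r}", "LPS", 0, replicate=r, compartment="cell")
            for r in (1, 2, 3)
        ] + [
            sample_meta(f"t{r}", "LPS", 30, replicate=r, compartment="cell")
            for r in (1, 2, 3)
        ]
        table = make_table({"P1": [10.0, 10.0, 10.0, 8.0, 10.0, 12.0]}, meta)
        rel = preprocess.trajectory_matrix(preprocess.relative_percentage(table, "LPS"))
        assert rel.loc["P1", 0] == 100.0
        assert rel.loc["P1", 30] == 100.0

    def test_zero_baseline_marks_trajectory_undefined(self):
        meta = [sample_meta(f"s{t}", "LPS", t, compartment="cell") for t in (0, 60)]
        table = make_table({"P1": [0.0, 5.0]}, meta)
        rel = preprocess.trajectory_matrix(preprocess.relative_percentage(table, "LPS"))
        assert rel.loc["P1"].isna().all()

    def test_fold_change_equal_arms_is_one(self, two_condition_table):
        fc = preprocess.trajectory_matrix(
            preprocess.fold_change_timecourse(two_condition_table, "LPS")
        )
        assert (fc.loc["P2"] == 1.0).all()

    def test_fold_change_tripled_at_120(self, two_condition_table):
        fc = preprocess.trajectory_matrix(
            preprocess.fold_change_timecourse(two_condition_table, "LPS")
        )
        assert fc.loc["P1", 120] == 3.0

    def test_missing_arm_gives_missing_point(self):
        meta = [sample_meta(f"{c}_{t}", c, t) for c in ("CONTROL", "LPS") for t in (0, 60)]
        table = make_table({"P1": [1.0, np.nan, 2.0, 4.0]}, meta)
        fc = preprocess.trajectory_matrix(preprocess.fold_change_timecourse(table, "LPS"))
        assert np.isnan(fc.loc["P1", 60]) and fc.loc["P1", 0] == 2.0

    def test_no_shared_times_rejected(self):
        meta = [sample_meta("c0", "CONTROL", 0), sample_meta("s5", "LPS", 5)]
        table = make_table({"P1": [1.0, 2.0]}, meta)
        with pytest.raises(ValueError, match="shared time"):
            preprocess.fold_change_timecourse(table, "LPS")


def de_table(stim_values, ctrl_values, n_proteins=None):
    """3v3 single-time table from per-protein replicate lists."""
    meta = [
        sample_meta(f"{c}_r{r}", c, 60, replicate=r, compartment="cell")
        for c in ("CONTROL", "LPS")
        for r in (1, 2, 3)
    ]
    values = {
        p: list(ctrl_values[p]) + list(stim_values[p]) for p in stim_values
    }
    return make_table(values, meta)


class TestDifferentialTest:
    def test_identical_arms_not_significant(self):
        table = de_table(
            {"P1": [4.0, 5.0, 6.0]}, {"P1": [4.0, 5.0, 6.0]}
        )
        de = preprocess.differential_test(table, "LPS", 60)
        row = de.set_index("protein").loc["P1"]
        assert row["p"] > 0.99 and not row["significant"]

    def test_planted_fourfold_shift_significant(self):
        # 4-fold shift, noise_cv=0.05, 3 v 3
        rng = np.random.default_rng(11)
        sigma = np.sqrt(np.log(1.0025))
        stim, ctrl = {}, {}
        for i in range(50):
            base = 1000.0
            shift = 4.0 if i < 5 else 1.0
            ctrl[f"P{i}"] = base * np.exp(rng.normal(0, sigma, 3))
            stim[f"P{i}"] = base * shift * np.exp(rng.normal(0, sigma, 3))
        de = preprocess.differential_test(de_table(stim, ctrl), "LPS", 60)
        hits = de.set_index("protein")
        assert all(hits.loc[f"P{i}", "significant"] for i in range(5))
        assert not hits.loc["P10", "significant"]

    def test_insufficient_replicates_flagged_untested(self):
        table = de_table(
            {"P1": [4.0, np.nan, np.nan]}, {"P1": [4.0, 5.0, 6.0]}
        )
        de = preprocess.differential_test(table, "LPS", 60)
        row = de.set_index("protein").loc["P1"]
        assert not row["tested"] and not row["significant"]

    def test_bh_adjustment_matches_hand_example(self):
        # step-up on {0.01,0.02,0.03,0.2,0.9} -> {0.05,0.05,0.05,0.25,0.9}
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.2, 0.9])
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], [0.05, 0.05, 0.05, 0.25, 0.9]
        )
        np.testing.assert_allclose(brute_force_bh(p), [0.05, 0.05, 0.05, 0.25, 0.9])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_bh_matches_brute_force_property(self, p_values):
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            multipletests(p_values, method="fdr_bh")[1],
            brute_force_bh(p_values),
            rtol=1e-12,
        )

    def test_adj_p_never_below_p(self, default_config):
        table, _ = sd.simulate_cell_proteome(default_config)
        de = preprocess.differential_test(table, "PMA", 240)
        tested = de[de["tested"]]
        assert (tested["adj_p"] >= tested["p"] - 1e-12).all()
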