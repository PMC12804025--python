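"""The released-protein screen: trend fit, rule, exclusions, catalog math."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from granulekit import release_analysis as ra
from granulekit.quantio import AnnotationSet, ProteinAnnotation
from oracles import ols_slope


def annotations_from(**per_protein):
    """Build an AnnotationSet from keyword specs:
    subsets=..., exclusion=..., routes=...."""
    annotations = AnnotationSet()
    for protein, fields in per_protein.items():
        annotations[protein] = ProteinAnnotation(
            accession=protein,
            granule_subsets=frozenset(fields.get("subsets", ())),
            exclusion_class=fields.get("exclusion", "none"),
            routes=tuple(fields.get("routes", ())),
        )
    return annotations


def tidy(protein, condition, points):
    return pd.DataFrame(
        {
            "protein": protein,
            "condition": condition,
            "kind": "fold_change",
            "time_min": [t for t, _ in points],
            "value": [v for _, v in points],
        }
    )


class TestFitLinearTrend:
    def test_constant_series_zero_slope(self):
        assert ra.fit_linear_trend([0, 30, 60, 120], [1.0] * 4) == 0.0

    def test_exact_line_recovers_slope(self):
        t = np.array([0, 30, 60, 120, 240])
        fc = 1 + 0.5 * t / 60.0
        np.testing.assert_allclose(ra.fit_linear_trend(t, fc), 0.5, rtol=1e-12)

    def test_missing_points_dropped(self):
        slope = ra.fit_linear_trend([0, 30, 60], [1.0, np.nan, 2.0])
        np.testing.assert_allclose(slope, 1.0, rtol=1e-12)

    def test_fewer_than_two_points_undefined(self):
        assert np.isnan(ra.fit_linear_trend([0, 30], [1.0, np.nan]))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.choice(np.arange(1, 300), size=6, replace=False)).astype(float)
        y = rng.lognormal(0, 1, 6)
        np.testing.assert_allclose(
            ra.fit_linear_trend(t, y), ols_slope(t / 60.0, y), rtol=1e-12, atol=1e-12
        )


class TestClassifyReleased:
    def stats(self, slope, max_fc, protein="P1"):
        return pd.DataFrame(
            {"protein": [protein], "condition": ["LPS"], "slope": [slope],
             "max_fc": [max_fc], "n_points": [6]}
        )

    def test_rule_application(self):
        calls = ra.classify_released(self.stats(0.2, 1.6), AnnotationSet())
        assert calls["released"].iloc[0]

    def test_negative_slope_not_released(self):
        calls = ra.classify_released(self.stats(-0.1, 2.0), AnnotationSet())
        assert not calls["released"].iloc[0]

    def test_histone_excluded_with_reason(self):
        annotations = annotations_from(P1={"exclusion": "histone"})
        calls = ra.classify_released(self.stats(0.3, 1.6), annotations)
        row = calls.iloc[0]
        assert not row["released"] and row["excluded"]
        assert row["exclusion_reason"] == "histone"

    @pytest.mark.parametrize("slope,max_fc", [(0.0, 2.0), (0.2, 1.5)])
    def test_strict_inequalities_at_boundaries(self, slope, max_fc):
        calls = ra.classify_released(self.stats(slope, max_fc), AnnotationSet())
        assert not calls["released"].iloc[0]

    def test_zero_min_point_excluded_from_max(self):
        # FC=2 at t=0 must not trigger the rule by itself
        traj = tidy("P1", "LPS", [(0, 2.0), (30, 1.1), (60, 1.2), (120, 1.3)])
        stats = ra.trend_stats(traj)
        assert stats["max_fc"].iloc[0] == 1.3

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_threshold_never_adds_proteins(self, seed):
        rng = np.random.default_rng(seed)
        stats = pd.DataFrame(
            {
                "protein": [f"P{i}" for i in range(30)],
                "condition": "LPS",
                "slope": rng.normal(0, 1, 30),
                "max_fc": rng.lognormal(0.3, 0.5, 30),
                "n_points": 6,
            }
        )
        loose = ra.classify_released(stats, AnnotationSet(), fc_threshold=1.5)
        tight = ra.classify_released(stats, AnnotationSet(), fc_threshold=2.0)
        loose_set = set(loose.loc[loose["released"], "protein"])
        tight_set = set(tight.loc[tight["released"], "protein"])
        assert tight_set <= loose_set


CALL_COLUMNS = ["protein", "condition", "slope", "max_fc", "n_points",
                "released", "excluded", "exclusion_reason", "undefined_slope"]


def released_calls(released_by_condition):
    rows = []
    for condition, proteins in released_by_condition.items():
        for protein in proteins:
            rows.append(
                {"protein": protein, "condition": condition, "slope": 1.0,
                 "max_fc": 2.0, "n_points": 6, "released": True,
                 "excluded": False, "exclusion_reason": "",
                 "undefined_slope": False}
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


class TestCatalog:
    def test_union_of_conditions(self):
        calls = released_calls({"LPS": ["A", "B"], "TNFA": ["B", "C"], "PMA": ["C"]})
        catalog = ra.combine_conditions(calls, AnnotationSet())
        assert set(catalog.proteins) == {"A", "B", "C"}

    def test_canonical_split(self):
        calls = released_calls({"LPS": ["A", "B", "C"]})
        annotations = annotations_from(A={"subsets": ("AG",)}, B={}, C={})
        catalog = ra.combine_conditions(calls, annotations)
        assert catalog.canonical == ["A"]
        assert sorted(catalog.non_canonical) == ["B", "C"]
        assert len(catalog) == len(catalog.canonical) + len(catalog.non_canonical)

    def test_removing_a_condition_never_adds_proteins(self):
        calls3 = released_calls({"LPS": ["A"], "TNFA": ["B"], "PMA": ["C"]})
        calls2 = released_calls({"LPS": ["A"], "TNFA": ["B"]})
        annotations = AnnotationSet()
        set3 = set(ra.combine_conditions(calls3, annotations).proteins)
        set2 = set(ra.combine_conditions(calls2, annotations).proteins)
        assert set2 <= set3

    def test_subset_summary_with_multimembership(self):
        calls = released_calls({"LPS": ["A", "B", "C"]})
        annotations = annotations_from(
            A={"subsets": ("AG",)}, B={"subsets": ("AG", "GG")}, C={"subsets": ("SV",)}
        )
        catalog = ra.combine_conditions(calls, annotations)
        counts = ra.summarize_granule_subsets(catalog, annotations).set_index("subset")
        assert counts.loc["AG", "n_total"] == 2
        assert counts.loc["GG", "n_total"] == 1
        assert counts.loc["SV", "n_total"] == 1
        assert counts.loc["SG", "n_total"] == 0

    def test_empty_catalog_all_zero(self):
        catalog = ra.combine_conditions(released_calls({}), AnnotationSet())
        counts = ra.summarize_granule_subsets(catalog, AnnotationSet())
        assert (counts["n_total"] == 0).all()


class TestReleaseLevel2h:
    def test_passes_through_observed_value(self):
        traj = tidy("P1", "LPS", [(0, 1.0), (60, 2.0), (120, 2.4)])
        catalog = ra.combine_conditions(released_calls({"LPS": ["P1"]}), AnnotationSet())
        levels = ra.release_level_2h(traj, catalog)
        assert levels.loc["P1", "LPS"] == 2.4

    def test_missing_point_stays_missing(self):
        traj = tidy("P1", "LPS", [(0, 1.0), (60, 2.0), (120, np.nan)])
        catalog = ra.combine_conditions(released_calls({"LPS": ["P1"]}), AnnotationSet())
        assert np.isnan(ra.release_level_2h(traj, catalog).loc["P1", "LPS"])


class TestSecretionRoutes:
    def test_all_flags_false_gives_zero(self):
        annotations = annotations_from(A={}, B={})
        summary = ra.aggregate_secretion_routes(["A", "B"], annotations)
        assert summary["percent_secreted"] == 0
        assert summary["predicted_secreted"] == []

    def test_fractions_match_brute_force_tally(self):
        rng = np.random.default_rng(5)
        flags = {}
        for i in range(80):
            routes = tuple(
                f for f in ("signal_peptide", "nonclassical", "transmembrane", "vesicle")
                if rng.random() < 0.4
            )
            flags[f"P{i}"] = {"routes": routes}
        annotations = annotations_from(**flags)
        summary = ra.aggregate_secretion_routes(list(flags), annotations)
        expected_any = sum(bool(v["routes"]) for v in flags.values())
        assert summary["n_secreted"] == expected_any
        for flag in ("signal_peptide", "nonclassical", "transmembrane", "vesicle"):
            expected = sum(flag in v["routes"] for v in flags.values())
            assert summary["per_route"][flag]["n"] == expected


def de_frame(protein_signs, condition, adj_p=0.01):
    return pd.DataFrame(
        {
            "protein": list(protein_signs),
            "condition": condition,
            "time_min": 240,
            "log2_fc": [s * 1.0 for s in protein_signs.values()],
            "p": adj_p / 2,
            "adj_p": adj_p,
            "tested": True,
            "significant": True,
        }
    )


class TestConsistentCoreSet:
    def test_consistent_up_in_three_conditions(self):
        de = {c: de_frame({"A": 1, "B": 1}, c) for c in ("LPS", "TNFA", "PMA")}
        de["PMA"] = de_frame({"A": 1, "B": -1}, "PMA")
        core = ra.consistent_core_set(de)
        assert core.set_index("protein").loc["A", "direction"] == "up"
        assert "B" not in set(core["protein"])  # up in 2, down in 1

    def test_non_significant_anywhere_drops_protein(self):
        de = {c: de_frame({"A": 1}, c) for c in ("LPS", "TNFA")}
        de["PMA"] = de_frame({"A": 1}, "PMA", adj_p=0.2)
        assert len(ra.consistent_core_set(de, alpha=0.05)) == 0

    def test_planted_consistent_set_recovered(self):
        # simulated screen at noise_cv=0.05: planted shared up/down proteins
        # recovered exactly at the final time point
        from granulekit import preprocess, synthetic_data as sd
        from conftest import make_table, sample_meta

        rng = np.random.default_rng(19)
        sigma = np.sqrt(np.log(1.0025))
        de = {}
        planted_up = [f"UP{i}" for i in range(5)]
        planted_down = [f"DN{i}" for i in range(5)]
        nulls = [f"N{i}" for i in range(40)]
        for condition in ("LPS", "TNFA", "PMA"):
            meta = [
                sample_meta(f"{c}_r{r}", c, 240, replicate=r, compartment="cell")
                for c in ("CONTROL", condition)
                for r in (1, 2, 3)
            ]
            values = {}
            for p in planted_up + planted_down + nulls:
                shift = 4.0 if p.startswith("UP") else (0.25 if p.startswith("DN") else 1.0)
                ctrl = 1000 * np.exp(rng.normal(0, sigma, 3))
                stim = 1000 * shift * np.exp(rng.normal(0, sigma, 3))
                values[p] = list(ctrl) + list(stim)
            table = make_table(values, meta)
            de[condition] = preprocess.differential_test(table, condition, 240)
        core = ra.consistent_core_set(de, alpha=0.05).set_index("protein")
        assert set(core.index) == set(planted_up + planted_down)
        assert (core.loc[planted_up, "direction"] == "up").all()
        assert (core.loc[planted_down, "direction"] == "down").all()
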