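"""Enrichment screens, set intersection, Venn partitions, over-representation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortevo.datasets_io import GeneSet
from cortevo import screen as scr


def threshold_table(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "contrast", "stage", "p_value", "abundance", "log2fc"]
    )


FIETZ = scr.PUBLISHED_CRITERIA["Fietz"]
POLLEN = scr.PUBLISHED_CRITERIA["Pollen"]
MILLER = scr.PUBLISHED_CRITERIA["Miller"]


class TestThresholdScreen:
    def test_empty_table_yields_empty_set(self):
        table = threshold_table(
            [("g0", c, "wpc13", 1.0, 0.0, 0.0) for c in FIETZ.contrasts]
        ).iloc[:0]
        crit = scr.ScreenCriteria(mode="threshold", contrasts=())
        assert scr.apply_threshold_screen(table, crit).members == frozenset()

    def test_manual_threshold_application(self):
        # gA clears p and abundance in VZ at the single stage; gB fails p
        rows = []
        for g, p, ab in [("gA", 0.005, 2.0), ("gB", 0.02, 5.0)]:
            for c in FIETZ.contrasts:
                rows.append((g, c, "wpc13", p if c == "VZ_vs_CP" else 0.5, ab, 1.0))
        out = scr.apply_threshold_screen(threshold_table(rows), FIETZ)
        assert out.members == frozenset({"gA"})

    def test_abundance_floor_excludes(self):
        rows = [("gA", "VZ_vs_CP", "wpc13", 0.005, 1.0, 1.0)]
        crit = scr.ScreenCriteria(
            mode="threshold", p_max=0.01, min_abundance=1.5, contrasts=("VZ_vs_CP",)
        )
        assert scr.apply_threshold_screen(threshold_table(rows), crit).members == frozenset()

    def test_across_all_stages_is_a_conjunction(self):
        rows = [
            ("gA", "VZ_vs_CP", "wpc13", 0.001, 3.0, 1.0),
            ("gA", "VZ_vs_CP", "wpc14", 0.5, 3.0, 1.0),
        ]
        crit = scr.ScreenCriteria(mode="threshold", p_max=0.01, contrasts=("VZ_vs_CP",))
        assert scr.apply_threshold_screen(threshold_table(rows), crit).members == frozenset()
        relaxed = scr.ScreenCriteria(
            mode="threshold", p_max=0.01, contrasts=("VZ_vs_CP",), across_stages="any"
        )
        assert scr.apply_threshold_screen(threshold_table(rows), relaxed).members == {"gA"}

    def test_negative_fold_change_excluded(self):
        rows = [("gA", "VZ_vs_CP", "wpc13", 0.001, 3.0, -1.0)]
        crit = scr.ScreenCriteria(mode="threshold", p_max=0.01, contrasts=("VZ_vs_CP",))
        assert scr.apply_threshold_screen(threshold_table(rows), crit).members == frozenset()

    def test_missing_contrast_is_configuration_error(self):
        rows = [("gA", "VZ_vs_CP", "wpc13", 0.001, 3.0, 1.0)]
        with pytest.raises(scr.ConfigurationError):
            scr.apply_threshold_screen(threshold_table(rows), FIETZ)

    def test_relaxing_thresholds_never_shrinks_output(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(60):
            rows.append(
                (
                    f"g{i}",
                    "VZ_vs_CP",
                    "wpc13",
                    float(rng.uniform(0, 0.05)),
                    float(rng.uniform(0, 3)),
                    1.0,
                )
            )
        table = threshold_table(rows)
        tight = scr.ScreenCriteria(
            mode="threshold", p_max=0.005, min_abundance=1.5, contrasts=("VZ_vs_CP",)
        )
        loose_p = scr.ScreenCriteria(
            mode="threshold", p_max=0.02, min_abundance=1.5, contrasts=("VZ_vs_CP",)
        )
        loose_ab = scr.ScreenCriteria(
            mode="threshold", p_max=0.005, min_abundance=0.5, contrasts=("VZ_vs_CP",)
        )
        base = scr.apply_threshold_screen(table, tight).members
        assert base <= scr.apply_threshold_screen(table, loose_p).members
        assert base <= scr.apply_threshold_screen(table, loose_ab).members


def corr_rows(gene, corrs, cells=20, sample="sc"):
    return [
        {
            "gene_id": gene,
            "label": label,
            "sample": sample,
            "correlation": corr,
            "detected_cells": cells,
        }
        for label, corr in corrs.items()
    ]


class TestCorrelationScreen:
    def test_manual_rule_application(self):
        table = pd.DataFrame(corr_rows("gA", {"RG": 0.3, "bIP": 0.0, "N": -0.2}))
        assert scr.apply_correlation_screen(table, POLLEN).members == {"gA"}

    def test_detected_cell_floor(self):
        table = pd.DataFrame(corr_rows("gA", {"RG": 0.3, "bIP": 0.0, "N": -0.2}, cells=5))
        assert scr.apply_correlation_screen(table, POLLEN).members == frozenset()

    def test_all_zero_correlations_excluded(self):
        table = pd.DataFrame(corr_rows("gA", {"RG": 0.0, "bIP": 0.0, "N": 0.0}))
        assert scr.apply_correlation_screen(table, POLLEN).members == frozenset()

    def test_neuron_correlation_rule_is_verbatim(self):
        # the published cutoff is corr < 0.03, not corr < 0
        table = pd.DataFrame(corr_rows("gA", {"RG": 0.3, "bIP": 0.0, "N": 0.02}))
        assert scr.apply_correlation_screen(table, POLLEN).members == {"gA"}
        table = pd.DataFrame(corr_rows("gA", {"RG": 0.3, "bIP": 0.0, "N": 0.03}))
        assert scr.apply_correlation_screen(table, POLLEN).members == frozenset()

    def test_pairing_requires_both_samples_of_one_pair(self):
        def miller_table(sample_hits):
            rows = []
            for sample in ("wpc15_a", "wpc15_b", "wpc21_a", "wpc21_b"):
                for zone in ("VZ", "iSVZ", "oSVZ"):
                    corr = 0.6 if (sample in sample_hits and zone == "VZ") else 0.0
                    rows.append(
                        {"gene_id": "gA", "label": zone, "sample": sample, "correlation": corr}
                    )
            return pd.DataFrame(rows)

        paired = miller_table({"wpc21_a", "wpc21_b"})
        unpaired = miller_table({"wpc15_a", "wpc21_b"})
        assert scr.apply_correlation_screen(paired, MILLER).members == {"gA"}
        assert scr.apply_correlation_screen(unpaired, MILLER).members == frozenset()

    def test_missing_label_is_configuration_error(self):
        table = pd.DataFrame(corr_rows("gA", {"RG": 0.3}))
        with pytest.raises(scr.ConfigurationError):
            scr.apply_correlation_screen(table, POLLEN)


sets_strategy = st.lists(
    st.frozensets(st.integers(min_value=0, max_value=25), max_size=15),
    min_size=2,
    max_size=5,
).map(
    lambda mss: [GeneSet(f"s{i}", frozenset(map(str, ms))) for i, ms in enumerate(mss)]
)


class TestSupportTable:
    def test_two_of_five_is_enriched(self):
        sets = [GeneSet(n, frozenset()) for n in ("Fietz", "Pollen", "Miller")]
        sets[0] = GeneSet("Fietz", frozenset({"g1"}))
        sets[1] = GeneSet("Pollen", frozenset({"g1", "g2"}))
        table = scr.build_support_table(sets, min_sets=2)
        assert table.loc["g1", "support"] == 2 and table.loc["g1", "enriched"]
        assert table.loc["g2", "support"] == 1 and not table.loc["g2", "enriched"]
        assert table.loc["g1", "combination"] == "Fietz+Pollen"

    def test_duplicate_dataset_names_rejected(self):
        sets = [GeneSet("a", frozenset()), GeneSet("a", frozenset())]
        with pytest.raises(ValueError, match="duplicate"):
            scr.build_support_table(sets, min_sets=1)

    @settings(max_examples=60, deadline=None)
    @given(sets=sets_strategy)
    def test_support_equals_brute_force_membership_count(self, sets):
        table = scr.build_support_table(sets, min_sets=2)
        for gene in table.index:
            expected = sum(gene in s.members for s in sets)
            assert table.loc[gene, "support"] == expected
            assert table.loc[gene, "enriched"] == (expected >= 2)


class TestVennPartition:
    def test_region_structure_for_five_sets(self):
        sets = [GeneSet(f"s{i}", frozenset()) for i in range(5)]
        regions = scr.venn_partition(sets)
        assert len(regions) == 2**5 - 1
        assert sum(1 for combo in regions if len(combo) == 3) == math.comb(5, 3) == 10
        assert sum(1 for combo in regions if len(combo) == 5) == 1

    @settings(max_examples=60, deadline=None)
    @given(sets=sets_strategy)
    def test_partition_conserves_union(self, sets):
        regions = scr.venn_partition(sets)
        union = set().union(*(s.members for s in sets))
        assert sum(regions.values()) == len(union)
        # regions agree with brute-force exact-membership enumeration
        for combo, count in regions.items():
            brute = sum(
                1
                for g in union
                if {s.name for s in sets if g in s.members} == set(combo)
            )
            assert count == brute

    def test_grouping_by_cardinality(self):
        sets = [
            GeneSet("a", frozenset({"x", "y"})),
            GeneSet("b", frozenset({"y", "z"})),
        ]
        assert scr.venn_partition(sets, by_cardinality=True) == {1: 2, 2: 1}


class TestOverlapMatrix:
    def test_identical_and_disjoint(self):
        a = GeneSet("a", frozenset({"1", "2"}))
        b = GeneSet("b", frozenset({"1", "2"}))
        c = GeneSet("c", frozenset({"3"}))
        mat = scr.overlap_matrix([a, b, c])
        assert mat.loc["a", "b"] == 1.0
        assert mat.loc["a", "c"] == 0.0
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)

    def test_over_min_hand_case(self):
        a = GeneSet("a", frozenset({"a", "b", "c"}))
        b = GeneSet("b", frozenset({"b", "c", "d"}))
        assert scr.overlap_matrix([a, b]).loc["a", "b"] == pytest.approx(2 / 3)
        assert scr.overlap_matrix([a, b], metric="jaccard").loc["a", "b"] == pytest.approx(0.5)

    def test_empty_set_with_over_min_is_an_error(self):
        with pytest.raises(ValueError, match="over_min"):
            scr.overlap_matrix([GeneSet("a", frozenset()), GeneSet("b", frozenset({"x"}))])


def exhaustive_overrep_p(m, term_size, query_size, overlap):
    """P(X >= overlap) by enumerating all query draws from an m-universe."""
    total = math.comb(m, query_size)
    favourable = sum(
        math.comb(term_size, k) * math.comb(m - term_size, query_size - k)
        for k in range(overlap, min(term_size, query_size) + 1)
    )
    return favourable / total


class TestEnrichmentTest:
    def _setup(self, overlap):
        universe = GeneSet("u", frozenset(f"g{i}" for i in range(20)))
        term = {f"g{i}" for i in range(5)}
        query_members = {f"g{i}" for i in range(overlap)} | {
            f"g{i}" for i in range(5, 5 + 5 - overlap)
        }
        return GeneSet("q", frozenset(query_members)), universe, {"T": term}

    def test_hypergeometric_tail_matches_combinatorial_oracle(self):
        query, universe, annotation = self._setup(overlap=4)
        table = scr.enrichment_test(query, universe, annotation)
        expected = exhaustive_overrep_p(20, 5, 5, 4)
        assert table.loc[0, "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        query, universe, annotation = self._setup(overlap=0)
        table = scr.enrichment_test(query, universe, annotation)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_single_term_by_equals_raw(self):
        query, universe, annotation = self._setup(overlap=3)
        table = scr.enrichment_test(query, universe, annotation)
        assert table.loc[0, "p_adjusted"] == pytest.approx(table.loc[0, "p_value"])

    def test_query_outside_universe_rejected(self):
        universe = GeneSet("u", frozenset({"g1"}))
        query = GeneSet("q", frozenset({"gX"}))
        with pytest.raises(ValueError, match="subset"):
            scr.enrichment_test(query, universe, {})

    @settings(max_examples=40, deadline=None)
    @given(
        p=st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30)
    )
    def test_by_dominates_bh_dominates_raw(self, p):
        from statsmodels.stats.multitest import multipletests

        by = scr.benjamini_yekutieli(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(by >= bh - 1e-12)
        assert np.all(bh >= np.asarray(p) - 1e-12)
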