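"""Barcode clone-tracing analysis: enrichment, diversity, correlation, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster

from gradres.barcode import (
    BarcodeTable,
    call_enriched,
    cluster_enriched,
    diversity_table,
    enrichment_threshold,
    replicate_correlation,
    shannon_diversity,
)
from gradres.synthetic import BarcodeSimSpec, generate_barcode_experiment


def _table(counts: dict, roles: dict, ids=None) -> BarcodeTable:
    df = pd.DataFrame(counts)
    if ids is not None:
        df.index = ids
    return BarcodeTable(df, roles)


class TestEnrichmentThreshold:
    def test_most_frequent_baseline_barcode_value(self):
        # averaged baseline max frequency of 0.0077, as in a 10k-read
        # library whose top clone holds 77 reads in both baseline aliquots
        rest = np.full(200, 49)
        rest[: 9923 - 200 * 49] += 1  # spread the remainder, staying below 77
        counts = np.concatenate([[77], rest])
        assert counts.sum() == 10_000 and counts.max() == 77
        t = _table(
            {"baseline_1": counts, "baseline_2": counts, "drug_1": counts},
            {"baseline_1": "baseline", "baseline_2": "baseline", "drug_1": "drug"},
        )
        assert enrichment_threshold(t) == pytest.approx(0.0077)

    def test_elementwise_average_then_max(self):
        t = _table(
            {"baseline_1": [5, 5], "baseline_2": [3, 7], "drug_1": [1, 1]},
            {"baseline_1": "baseline", "baseline_2": "baseline", "drug_1": "drug"},
        )
        assert enrichment_threshold(t) == pytest.approx(0.6)

    def test_single_baseline_uses_its_own_max(self):
        t = _table(
            {"baseline_1": [2, 8], "drug_1": [1, 1]},
            {"baseline_1": "baseline", "drug_1": "drug"},
        )
        assert enrichment_threshold(t) == pytest.approx(0.8)

    def test_no_baseline_rejected(self):
        t = _table({"drug_1": [1, 2]}, {"drug_1": "drug"})
        with pytest.raises(ValueError):
            enrichment_threshold(t)


class TestCallEnriched:
    def test_treated_identical_to_baseline_calls_nothing(self):
        c = [50, 30, 20]
        t = _table(
            {"baseline_1": c, "baseline_2": c, "drug_1": c},
            {"baseline_1": "baseline", "baseline_2": "baseline", "drug_1": "drug"},
        )
        res = call_enriched(t)
        assert len(res.union) == 0

    def test_exactly_at_threshold_not_called(self):
        t = _table(
            {"baseline_1": [60, 40], "drug_1": [60, 40], "drug_2": [61, 39]},
            {"baseline_1": "baseline", "drug_1": "drug", "drug_2": "drug"},
            ids=["a", "b"],
        )
        res = call_enriched(t)
        assert list(res.enriched["drug_1"]) == []
        assert list(res.enriched["drug_2"]) == ["a"]

    def test_depth_rescaling_invariance(self):
        counts = {"baseline_1": [50, 30, 20], "drug_1": [10, 80, 10]}
        roles = {"baseline_1": "baseline", "drug_1": "drug"}
        a = call_enriched(_table(counts, roles))
        b = call_enriched(_table({k: [x * 10 for x in v] for k, v in counts.items()}, roles))
        assert a.threshold == b.threshold
        assert list(a.union) == list(b.union)

    def test_planted_clones_recovered(self):
        spec = BarcodeSimSpec(n_conditions=2)
        table, truth = generate_barcode_experiment(spec, seed=9)
        res = call_enriched(table)
        planted = set(np.concatenate(list(truth.values())))
        assert planted <= set(res.union)  # high growth: all planted called
        assert len(set(res.union) - planted) <= 0.05 * max(len(res.union), 1)


class TestShannonDiversity:
    def test_single_clone_zero_entropy(self):
        assert shannon_diversity([1.0]) == 0.0

    def test_uniform_maximises_at_log_k(self):
        assert shannon_diversity(np.full(100, 0.01)) == pytest.approx(np.log(100))

    def test_direct_formula_on_small_counts(self):
        f = np.array([2, 1, 1]) / 4
        assert shannon_diversity(f) == pytest.approx(1.0397, abs=1e-4)

    def test_zero_frequencies_drop_out(self):
        assert shannon_diversity([0.5, 0.5, 0.0]) == pytest.approx(np.log(2))

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([0.5, 0.2])

    def test_selection_reduces_diversity_in_simulation(self):
        spec = BarcodeSimSpec(n_barcodes=500)
        table, _ = generate_barcode_experiment(spec, seed=4)
        H = diversity_table(table)
        base = H[table.baseline_samples].mean()
        treated = H[table.treated_samples].mean()
        assert treated < base

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), k=st.integers(2, 50))
    def test_permutation_invariance(self, seed, k):
        r = np.random.default_rng(seed)
        f = r.dirichlet(np.ones(k))
        assert shannon_diversity(f) == pytest.approx(
            shannon_diversity(r.permutation(f))
        )


class TestCorrelationStructure:
    @pytest.fixture(scope="class")
    def planted(self):
        spec = BarcodeSimSpec(n_conditions=2, selection_overlap=0.0)
        table, truth = generate_barcode_experiment(spec, seed=12)
        res = call_enriched(table)
        return table, res

    def test_matrix_symmetric_unit_diagonal(self, planted):
        table, res = planted
        corr = replicate_correlation(res, table)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)

    def test_within_condition_exceeds_between(self, planted):
        table, res = planted
        corr = replicate_correlation(res, table)
        within, between = [], []
        for a, b in itertools.combinations(table.treated_samples, 2):
            same = table.condition_of(a) == table.condition_of(b)
            (within if same else between).append(corr.loc[a, b])
        assert np.mean(within) > np.mean(between)

    def test_monotone_transform_gives_perfect_correlation(self):
        t = _table(
            {"baseline_1": [25, 25, 25, 25], "drug_1": [30, 28, 26, 16],
             "drug_2": [35, 30, 27, 8]},
            {"baseline_1": "baseline", "drug_1": "d", "drug_2": "d"},
        )
        res = call_enriched(t)
        assert len(res.union) == 3
        corr = replicate_correlation(res, t)
        # drug_2 frequencies are a strictly increasing transform of drug_1's
        assert corr.loc["drug_1", "drug_2"] == pytest.approx(1.0)

    def test_empty_union_rejected(self):
        c = [5, 5]
        t = _table(
            {"baseline_1": c, "drug_1": c},
            {"baseline_1": "baseline", "drug_1": "drug"},
        )
        with pytest.raises(ValueError):
            replicate_correlation(call_enriched(t), t)


class TestClustering:
    def test_samples_group_by_condition(self):
        spec = BarcodeSimSpec(n_conditions=2, selection_overlap=0.0)
        table, _ = generate_barcode_experiment(spec, seed=21)
        res = call_enriched(table)
        cl = cluster_enriched(res, table)
        top2 = fcluster(cl.sample_linkage, 2, criterion="maxclust")
        conds = [table.condition_of(s) for s in table.treated_samples]
        split = {c: {top2[i] for i, cc in enumerate(conds) if cc == c} for c in set(conds)}
        assert all(len(v) == 1 for v in split.values())  # pure clusters
        assert split["cond1"] != split["cond2"]

    def test_identical_samples_merge_at_zero_distance(self):
        t = _table(
            {"baseline_1": [34, 33, 33], "a_1": [5, 85, 10], "a_2": [5, 85, 10],
             "b_1": [5, 10, 85]},
            {"baseline_1": "baseline", "a_1": "a", "a_2": "a", "b_1": "b"},
        )
        res = call_enriched(t)
        cl = cluster_enriched(res, t)
        assert cl.sample_linkage[0, 2] == pytest.approx(0.0)

    def test_single_barcode_single_leaf(self):
        t = _table(
            {"baseline_1": [60, 40], "drug_1": [20, 80]},
            {"baseline_1": "baseline", "drug_1": "drug"},
            ids=["a", "b"],
        )
        res = call_enriched(t)
        assert list(res.union) == ["b"]
        cl = cluster_enriched(res, t)
        assert cl.barcode_linkage is None
        assert list(cl.barcode_order) == ["b"]


class TestBarcodeTableIO:
    def test_csv_round_trip_preserves_counts_and_roles(self, tmp_path):
        spec = BarcodeSimSpec(n_barcodes=50, sequencing_depth=5000)
        table, _ = generate_barcode_experiment(spec, seed=2)
        path = tmp_path / "bc.csv"
        table.to_csv(path)
        again = BarcodeTable.from_csv(path)
        assert again.counts.equals(table.counts)
        assert again.roles == table.roles

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _table({"baseline_1": [-1, 2]}, {"baseline_1": "baseline"})

    def test_role_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _table({"s1": [1]}, {"s2": "baseline"})
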