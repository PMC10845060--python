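import numpy as np
import pandas as pd
import pytest

from azsearch import (
    run_replicates,
    run_search,
    split_reference_database,
    summarize,
    tabulate_distribution,
)


class TestSplit:
    @pytest.mark.parametrize(
        "n, f, expected",
        [
            (2504, 0.6, (1502, 1002)),  # the canonical forensic-panel split
            (10, 0.6, (6, 4)),
            (5, 0.5, (2, 3)),           # floor convention for the reference
        ],
    )
    def test_partition_sizes(self, n, f, expected):
        ref, db = split_reference_database(n, f, seed=0)
        assert (len(ref), len(db)) == expected

    def test_partition_is_disjoint_and_complete(self):
        ref, db = split_reference_database(100, 0.6, seed=3)
        combined = np.concatenate([ref, db])
        assert len(np.unique(combined)) == 100

    def test_deterministic_given_seed_and_replicate(self):
        a = split_reference_database(50, 0.6, seed=9, replicate_index=2)
        b = split_reference_database(50, 0.6, seed=9, replicate_index=2)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_replicates_differ(self):
        a = split_reference_database(200, 0.6, seed=9, replicate_index=0)
        b = split_reference_database(200, 0.6, seed=9, replicate_index=1)
        assert not np.array_equal(a[1], b[1])

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_out_of_range_raises(self, f):
        with pytest.raises(ValueError):
            split_reference_database(10, f, seed=0)

    def test_too_small_database_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_reference_database(10, 0.95, seed=0)


class TestRunSearch:
    def test_record_count_is_n_choose_2(self, small_panel):
        panel, profiles, _ = small_panel
        result = run_search("true", genotype_profiles=profiles[:4],
                            loci=panel.loci)
        assert result.n_pairs == 6

    def test_integer_records_satisfy_k_identity(self, small_panel):
        panel, profiles, posteriors = small_panel
        for scheme, kwargs in [
            ("true", {"genotype_profiles": profiles}),
            ("called", {"probability_profiles": posteriors}),
        ]:
            r = run_search(scheme, loci=panel.loci, **kwargs)
            assert np.array_equal(r.k, 2 * r.m + r.p)

    def test_canonical_pair_order(self, small_panel):
        panel, profiles, _ = small_panel
        r = run_search("true", genotype_profiles=profiles[:4], loci=panel.loci)
        ids = [pr.individual_id for pr in profiles[:4]]
        expected = [(ids[i], ids[j]) for i in range(4) for j in range(i + 1, 4)]
        assert list(zip(r.id_a, r.id_b)) == expected

    def test_expected_with_point_mass_posteriors_equals_true(self):
        from azsearch import SyntheticPanelConfig, generate_panel

        panel, profiles, posteriors = generate_panel(
            SyntheticPanelConfig(n_individuals=25, n_loci=5, accuracy=1.0,
                                 seed=2))
        rt = run_search("true", genotype_profiles=profiles, loci=panel.loci)
        re_ = run_search("expected", probability_profiles=posteriors,
                         loci=panel.loci)
        assert np.max(np.abs(re_.k - rt.k)) <= 1e-9
        assert np.max(np.abs(re_.m - rt.m)) <= 1e-9
        assert np.max(np.abs(re_.p - rt.p)) <= 1e-9

    def test_full_distribution_expectations_agree_with_linearity(self):
        from azsearch import SyntheticPanelConfig, expected_matches, generate_panel

        panel, _, posteriors = generate_panel(
            SyntheticPanelConfig(n_individuals=6, n_loci=4, accuracy=0.6,
                                 seed=4))
        r = run_search("expected", probability_profiles=posteriors,
                       loci=panel.loci, full_distribution=True)
        assert len(r.distributions) == r.n_pairs
        for idx, dist in enumerate(r.distributions):
            e = expected_matches(dist)
            assert e.e_full == pytest.approx(r.m[idx], abs=1e-10)
            assert e.e_partial == pytest.approx(r.p[idx], abs=1e-10)

    def test_missing_required_inputs_raise(self, small_panel):
        panel, profiles, posteriors = small_panel
        with pytest.raises(ValueError, match="requires genotype"):
            run_search("true", probability_profiles=posteriors)
        with pytest.raises(ValueError, match="requires probability"):
            run_search("expected", genotype_profiles=profiles)

    def test_fewer_than_two_individuals_raises(self, small_panel):
        panel, profiles, _ = small_panel
        with pytest.raises(ValueError, match="at least 2"):
            run_search("true", genotype_profiles=profiles[:1])


class TestTabulate:
    def test_single_pair_histogram(self, small_panel):
        panel, profiles, _ = small_panel
        r = run_search("true", genotype_profiles=profiles[:2], loci=panel.loci)
        hist = tabulate_distribution(r, "alleles")
        assert hist.sum() == pytest.approx(1.0, abs=1e-12)
        assert hist[r.k[0]] == 1.0

    def test_pooling_duplicates_is_idempotent(self, small_panel):
        panel, profiles, _ = small_panel
        r = run_search("true", genotype_profiles=profiles, loci=panel.loci)
        one = tabulate_distribution(r, "full")
        two = tabulate_distribution([r, r], "full")
        pd.testing.assert_series_equal(one, two)

    def test_histogram_masses_sum_to_one(self, small_panel):
        panel, profiles, _ = small_panel
        r = run_search("true", genotype_profiles=profiles, loci=panel.loci)
        for variable in ("alleles", "full", "partial"):
            assert tabulate_distribution(r, variable).sum() == pytest.approx(
                1.0, abs=1e-12)

    def test_expected_scheme_returns_raw_values(self, small_panel):
        panel, _, posteriors = small_panel
        r = run_search("expected", probability_profiles=posteriors,
                       loci=panel.loci)
        values = tabulate_distribution(r, "alleles")
        assert isinstance(values, np.ndarray)
        assert values.shape == (r.n_pairs,)

    def test_mixed_schemes_rejected(self, small_panel):
        panel, profiles, posteriors = small_panel
        rt = run_search("true", genotype_profiles=profiles, loci=panel.loci)
        rc = run_search("called", probability_profiles=posteriors,
                        loci=panel.loci)
        with pytest.raises(ValueError, match="mixed"):
            tabulate_distribution([rt, rc], "alleles")


class TestSummarize:
    def _result_with(self, k):
        from azsearch.search import SearchResult

        k = np.asarray(k)
        n = len(k)
        return SearchResult(scheme="true", replicate_index=0,
                            individual_ids=("x",), id_a=np.array(["a"] * n),
                            id_b=np.array(["b"] * n), k=k,
                            m=np.zeros(n, dtype=int), p=k)

    def test_odd_length_median_and_max(self):
        table = summarize({"true": [self._result_with([1, 2, 3])]})
        assert table.loc[("median", "alleles"), "true"] == 2
        assert table.loc[("maximum", "alleles"), "true"] == 3

    def test_even_length_median_is_midpoint(self):
        table = summarize({"true": [self._result_with([1, 2, 3, 4])]})
        assert table.loc[("median", "alleles"), "true"] == 2.5

    def test_pooling_concatenates_rather_than_averaging(self):
        pooled = summarize({"true": [self._result_with([1, 1]),
                                     self._result_with([5, 5, 5])]})
        # median of [1,1,5,5,5] is 5, not the mean of per-replicate medians
        assert pooled.loc[("median", "alleles"), "true"] == 5


class TestRunReplicates:
    def test_single_replicate_reduces_to_run_search(self, small_panel):
        panel, profiles, posteriors = small_panel
        study = run_replicates(loci=panel.loci, genotype_profiles=profiles,
                               probability_profiles=posteriors,
                               n_replicates=1, base_seed=5)
        ref, db = study.splits[0]
        direct = run_search("true",
                            genotype_profiles=[profiles[i] for i in db],
                            loci=panel.loci)
        r = study.results["true"][0]
        assert np.array_equal(r.k, direct.k)

    def test_same_base_seed_reproduces_records(self, small_panel):
        panel, profiles, posteriors = small_panel
        kwargs = dict(loci=panel.loci, genotype_profiles=profiles,
                      probability_profiles=posteriors, n_replicates=2,
                      base_seed=17)
        a = run_replicates(**kwargs)
        b = run_replicates(**kwargs)
        for scheme in a.results:
            for ra, rb in zip(a.results[scheme], b.results[scheme]):
                assert np.array_equal(ra.id_a, rb.id_a)
                assert np.array_equal(ra.k, rb.k)

    def test_same_splits_shared_across_schemes(self, small_panel):
        panel, profiles, posteriors = small_panel
        study = run_replicates(loci=panel.loci, genotype_profiles=profiles,
                               probability_profiles=posteriors,
                               n_replicates=3, base_seed=1)
        for r in range(3):
            ids = study.results["true"][r].individual_ids
            assert study.results["called"][r].individual_ids == ids
            assert study.results["expected"][r].individual_ids == ids

    def test_pooled_record_count(self, small_panel):
        panel, profiles, posteriors = small_panel
        study = run_replicates(loci=panel.loci, genotype_profiles=profiles,
                               probability_profiles=posteriors,
                               n_replicates=2, base_seed=0)
        n_db = len(study.splits[0][1])
        expected = 2 * n_db * (n_db - 1) // 2
        assert len(study.pooled_frame("true")) == expected
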