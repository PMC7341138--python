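import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from conftest import matrix_from_array
from oracles import brute_peak_matrix

from nucsens import (
    PeakSet,
    apply_sort,
    cluster_average_profiles,
    dominant_sensitive_cluster,
    kmeans_profiles,
    peak_matrix,
    quartiles_by_key,
    sort_by_max_signal,
)


class TestSortByMaxSignal:
    def test_descending_by_row_maximum(self):
        m = matrix_from_array(
            np.array([[5.0, 1.0], [9.0, 0.0], [7.0, 7.0]]),
            genes=["a", "b", "c"],
        )
        assert sort_by_max_signal(m).gene_ids == ["b", "c", "a"]

    def test_ties_break_lexicographically(self):
        m = matrix_from_array(np.ones((3, 2)), genes=["zz", "aa", "mm"])
        assert sort_by_max_signal(m).gene_ids == ["aa", "mm", "zz"]

    def test_matches_argsort_oracle(self, rng):
        vals = rng.uniform(0, 100, (50, 20))
        m = matrix_from_array(vals)
        got = sort_by_max_signal(m).gene_ids
        maxima = vals.max(axis=1)
        want = [m.gene_ids[i] for i in np.argsort(-maxima, kind="stable")]
        assert got == want


class TestQuartiles:
    def test_eight_genes_split_evenly(self):
        genes = list("abcdefgh")
        key = {g: 8 - i for i, g in enumerate(genes)}
        q = quartiles_by_key(genes, key)
        assert [q[g] for g in genes] == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_remainder_goes_to_early_quartiles(self):
        genes = [f"g{i}" for i in range(10)]
        key = {g: 10 - i for i, g in enumerate(genes)}
        q = quartiles_by_key(genes, key)
        sizes = pd.Series(list(q.values())).value_counts()
        assert sizes.to_dict() == {"Q1": 3, "Q2": 3, "Q3": 2, "Q4": 2}

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            quartiles_by_key(["a", "b", "c"], {"a": 1, "b": 2, "c": 3})

    def test_sorted_oracle_on_random_keys(self, rng):
        genes = [f"g{i:03d}" for i in range(100)]
        key = dict(zip(genes, rng.normal(size=100)))
        q = quartiles_by_key(genes, key)
        for qa, qb in [("Q1", "Q2"), ("Q2", "Q3"), ("Q3", "Q4")]:
            lo_a = min(key[g] for g, v in q.items() if v == qa)
            hi_b = max(key[g] for g, v in q.items() if v == qb)
            assert lo_a >= hi_b
        assert pd.Series(list(q.values())).value_counts().eq(25).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(4, 60), st.integers(0, 2**31 - 1))
    def test_partition_invariant(self, n, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        q = quartiles_by_key(genes, dict(zip(genes, rng.normal(size=n))))
        assert set(q) == set(genes)
        sizes = pd.Series(list(q.values())).value_counts()
        assert all(abs(s - n / 4) <= 1 for s in sizes)


class TestKmeans:
    def test_separable_groups_fully_recovered(self):
        rows = np.vstack([np.zeros((5, 6)), np.full((5, 6), 100.0)])
        m = matrix_from_array(rows)
        a = kmeans_profiles(m, k=2, seed=0)
        truth = [0] * 5 + [1] * 5
        assert adjusted_rand_score(truth, a.labels.to_numpy()) == 1.0

    def test_k_equals_n_gives_zero_wcss(self, rng):
        m = matrix_from_array(rng.uniform(0, 1, (6, 4)))
        a = kmeans_profiles(m, k=6, seed=0)
        assert a.inertia == pytest.approx(0.0, abs=1e-9)
        assert len(set(a.labels)) == 6

    def test_k_exceeding_n_rejected(self, rng):
        m = matrix_from_array(rng.uniform(0, 1, (3, 4)))
        with pytest.raises(ValueError):
            kmeans_profiles(m, k=5)

    def test_planted_partition_recovery(self, rng):
        """3 planted profile clusters, center separation >= 5x the
        within-cluster sd: ARI >= 0.8 with 10 restarts."""
        centers = rng.normal(0, 5.0, size=(3, 40))
        truth, rows = [], []
        for c in range(3):
            for _ in range(20):
                rows.append(centers[c] + rng.normal(0, 1.0, size=40))
                truth.append(c)
        a = kmeans_profiles(matrix_from_array(np.array(rows)), k=3, seed=1, n_init=10)
        assert adjusted_rand_score(truth, a.labels.to_numpy()) >= 0.8

    def test_deterministic_given_seed(self, rng):
        m = matrix_from_array(rng.uniform(0, 1, (30, 8)))
        a1 = kmeans_profiles(m, k=3, seed=7)
        a2 = kmeans_profiles(m, k=3, seed=7)
        assert a1.labels.equals(a2.labels)

    def test_na_rows_imputed_and_flagged(self, rng):
        vals = rng.uniform(0, 1, (10, 4))
        vals[3, 2] = np.nan
        m = matrix_from_array(vals)
        a = kmeans_profiles(m, k=2, seed=0)
        assert a.imputed_genes == [m.gene_ids[3]]

    def test_dominant_sensitive_cluster_found_by_band_peak(self):
        centers = np.arange(-970, 971, 10)
        rows = np.zeros((8, len(centers)))
        rows[:4, np.abs(centers + 100) <= 30] = 2.0    # peak at -100
        rows[4:, np.abs(centers - 500) <= 30] = 3.0    # peak at +500
        m = matrix_from_array(rows, centers=centers)
        a = kmeans_profiles(m, k=2, seed=0)
        label = dominant_sensitive_cluster(a, band=(-200, 0))
        members = a.labels[a.labels == label].index
        assert set(members) == set(m.gene_ids[:4])


class TestClusterAverages:
    def test_single_gene_group_is_its_row(self, rng):
        m = matrix_from_array(rng.uniform(0, 1, (3, 4)))
        means, sizes = cluster_average_profiles(
            m, {g: i for i, g in enumerate(m.gene_ids)}
        )
        np.testing.assert_allclose(means.loc[1], m.values.iloc[1])
        assert sizes == {0: 1, 1: 1, 2: 1}

    def test_two_row_mean(self):
        m = matrix_from_array(np.array([[0.0, 2.0], [2.0, 0.0]]))
        means, _ = cluster_average_profiles(m, {g: "x" for g in m.gene_ids})
        np.testing.assert_allclose(means.loc["x"], [1.0, 1.0])

    def test_matches_groupby_oracle(self, rng):
        m = matrix_from_array(rng.normal(size=(20, 6)))
        groups = {g: rng.integers(0, 3) for g in m.gene_ids}
        means, _ = cluster_average_profiles(m, groups)
        want = m.values.groupby(pd.Series(groups)).mean()
        pd.testing.assert_frame_equal(means, want, check_names=False)

    def test_whole_matrix_group_equals_column_means(self, rng):
        m = matrix_from_array(rng.normal(size=(9, 5)))
        means, _ = cluster_average_profiles(m, {g: "all" for g in m.gene_ids})
        np.testing.assert_allclose(means.loc["all"], m.values.mean(axis=0))

    def test_unassigned_gene_rejected(self, rng):
        m = matrix_from_array(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            cluster_average_profiles(m, {m.gene_ids[0]: "x"})


class TestApplySort:
    def test_identity_and_involution(self, rng):
        m = matrix_from_array(rng.normal(size=(6, 4)))
        ident = apply_sort(m, list(m.gene_ids))
        assert ident.values.equals(m.values)
        perm = list(rng.permutation(m.gene_ids))
        sorted_m = apply_sort(m, perm)
        inverse = apply_sort(sorted_m, list(m.gene_ids))
        assert inverse.values.equals(m.values)

    def test_shared_order_contract(self, rng):
        a = matrix_from_array(rng.normal(size=(8, 3)))
        b = matrix_from_array(rng.normal(size=(8, 3)))
        order = sort_by_max_signal(a)
        bs = apply_sort(b, order)
        assert list(bs.values.index) == order.gene_ids

    def test_preserves_row_multiset(self, rng):
        m = matrix_from_array(rng.normal(size=(7, 4)))
        perm = list(rng.permutation(m.gene_ids))
        sorted_m = apply_sort(m, perm)
        got = sorted_m.values.sort_index()
        want = m.values.sort_index()
        assert got.equals(want)

    def test_non_permutation_rejected(self, rng):
        m = matrix_from_array(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            apply_sort(m, m.gene_ids[:-1])


def _peakset(rows, factor="TF"):
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signalValue", "pValue", "qValue", "summit"]
    df = pd.DataFrame(rows, columns=cols)
    return PeakSet(df, factor=factor)


class TestPeakMatrix:
    def test_nfr_peak_hits_central_windows_only(self, tiny_annotation):
        tss = 1000
        peaks = _peakset([["chr1", tss - 45, tss + 45, "p", 0, ".", 8.0, -1, -1, 45]])
        mat = peak_matrix(peaks, tiny_annotation, window=60, step=10)
        row = mat.values.loc["gA"]
        hit = row[row > 0]
        assert (hit == 8.0).all()
        assert abs(np.asarray(hit.index, dtype=float)).max() <= 45 + 30 + 30
        assert (mat.values.loc["gC"] == 0).all()

    def test_no_peaks_zero_matrix(self, tiny_annotation):
        mat = peak_matrix(_peakset([]), tiny_annotation)
        assert (mat.values.to_numpy() == 0).all()

    def test_matches_bruteforce_overlap(self, rng, tiny_annotation):
        rows = []
        for i in range(15):
            chrom = rng.choice(["chr1", "chr2"])
            s = int(rng.integers(0, 5000))
            w = int(rng.integers(20, 400))
            rows.append([chrom, s, s + w, f"p{i}", 0, ".",
                         float(rng.uniform(1, 20)), -1, -1, -1])
        peaks = _peakset(rows)
        got = peak_matrix(peaks, tiny_annotation).values.to_numpy()
        want = brute_peak_matrix(peaks, tiny_annotation)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_binary_mode(self, tiny_annotation):
        tss = 1000
        peaks = _peakset([
            ["chr1", tss - 45, tss + 45, "p1", 0, ".", 8.0, -1, -1, -1],
            ["chr1", tss - 40, tss + 40, "p2", 0, ".", 5.0, -1, -1, -1],
        ])
        mat = peak_matrix(peaks, tiny_annotation, mode="binary")
        assert set(np.unique(mat.values.to_numpy())) <= {0.0, 1.0}
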