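"""Expression transforms, clustering, and the DE intersection filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from lrrkit.expression import (
    filter_de,
    hierarchical_groups,
    kmeans_groups,
    transform,
)
from lrrkit.io import InputError, PipelineConfig


def planted_matrix(rng, sizes, means, n_samples=8):
    rows, truth = {}, []
    i = 0
    for size, mu in zip(sizes, means):
        for _ in range(size):
            rows[f"g{i:03d}"] = 10.0 ** rng.normal(mu, 0.1, n_samples) - 1
            truth.append(mu)
            i += 1
    df = pd.DataFrame.from_dict(rows, orient="index").clip(lower=0)
    return df, truth


class TestTransform:
    def test_zero_maps_to_zero(self):
        df = pd.DataFrame({"s": [0.0]})
        assert transform(df).iloc[0, 0] == 0.0

    def test_fpkm_99_maps_to_two(self):
        df = pd.DataFrame({"s": [99.0]})
        assert transform(df).iloc[0, 0] == pytest.approx(2.0)

    def test_negative_input_rejected(self):
        with pytest.raises(InputError):
            transform(pd.DataFrame({"s": [-1.0]}))

    @given(st.lists(st.integers(0, 10**9), min_size=2, max_size=20,
                    unique=True))
    def test_strictly_order_preserving(self, raw):
        values = [v / 1000.0 for v in raw]
        df = pd.DataFrame({"s": values})
        out = transform(df)["s"]
        order_in = np.argsort(values)
        order_out = np.argsort(out.values)
        assert list(order_in) == list(order_out)


class TestKMeans:
    def test_k1_puts_everything_in_one_group(self, rng):
        df, _ = planted_matrix(rng, [10], [1.0])
        groups = kmeans_groups(transform(df), k=1)
        assert set(groups) == {1}

    def test_same_seed_identical_labels(self, rng):
        df, _ = planted_matrix(rng, [15, 15], [2.2, 0.3])
        log = transform(df)
        a = kmeans_groups(log, k=2, seed=7)
        b = kmeans_groups(log, k=2, seed=7)
        assert a.equals(b)

    def test_separated_clusters_fully_recovered(self, rng):
        df, truth = planted_matrix(rng, [12, 20], [2.2, 0.3])
        groups = kmeans_groups(transform(df), k=2, seed=17)
        assert adjusted_rand_score(truth, groups.values) == 1.0
        # group 1 is the high-expression group by convention
        assert set(groups.iloc[:12]) == {1}

    def test_k_exceeding_genes_rejected(self, rng):
        df, _ = planted_matrix(rng, [3], [1.0])
        with pytest.raises(InputError):
            kmeans_groups(transform(df), k=5)


class TestHierarchical:
    def test_singletons_when_groups_equal_genes(self, rng):
        df, _ = planted_matrix(rng, [5], [1.0])
        groups = hierarchical_groups(transform(df), n_groups=5)
        assert sorted(groups) == [1, 2, 3, 4, 5]

    def test_four_planted_levels_recovered(self, rng):
        df, truth = planted_matrix(rng, [8, 8, 8, 8], [2.6, 1.8, 1.0, 0.2])
        groups = hierarchical_groups(transform(df), n_groups=4)
        assert adjusted_rand_score(truth, groups.values) == 1.0

    def test_gene_order_permutation_invariance(self, rng):
        df, _ = planted_matrix(rng, [8, 8, 8, 8], [2.6, 1.8, 1.0, 0.2])
        log = transform(df)
        base = hierarchical_groups(log, n_groups=4)
        perm = log.sample(frac=1.0, random_state=3)
        shuffled = hierarchical_groups(perm, n_groups=4)
        assert (shuffled.reindex(base.index) == base).all()

    def test_labels_partition_all_genes(self, rng):
        df, _ = planted_matrix(rng, [10, 10], [2.0, 0.5])
        groups = hierarchical_groups(transform(df), n_groups=3)
        assert groups.notna().all() and len(groups) == len(df)


class TestFilterDE:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["gene_id", "contrast_id",
                                           "log2fc", "fdr"])

    def test_gene_passing_both_contrasts_is_kept(self):
        df = self.table([("g", "V991", 2.0, 0.01), ("g", "D07038", 2.0, 0.01)])
        assert filter_de(df) == {"g"}

    def test_gene_passing_one_contrast_dropped_under_intersection(self):
        df = self.table([("g", "V991", 2.0, 0.01),
                         ("g", "D07038", 0.5, 0.01)])
        assert filter_de(df) == set()
        assert filter_de(df, require_all_contrasts=False) == {"g"}

    def test_downregulation_counts_by_magnitude(self):
        df = self.table([("g", "V991", -2.5, 0.001),
                         ("g", "D07038", -1.5, 0.02)])
        assert filter_de(df) == {"g"}

    def test_toy_table_exactly_one_survivor(self):
        rows = []
        specs = {
            "g1": [(2.0, 0.01), (1.8, 0.02)],   # passes both
            "g2": [(2.0, 0.01), (0.5, 0.01)],   # fails lfc in one
            "g3": [(2.0, 0.30), (2.0, 0.01)],   # fails fdr in one
            "g4": [(0.2, 0.50), (0.1, 0.90)],   # null
            "g5": [(1.0, 0.01), (1.0, 0.01)],   # lfc not strictly > 1
            "g6": [(3.0, 0.05), (3.0, 0.01)],   # fdr not strictly < 0.05
        }
        for g, vals in specs.items():
            for c, (lfc, fdr) in zip(["V991", "D07038"], vals):
                rows.append((g, c, lfc, fdr))
        assert filter_de(self.table(rows)) == {"g1"}

    def test_intersection_subset_of_union(self, rng):
        rows = []
        for i in range(50):
            for c in ("V991", "D07038"):
                rows.append((f"g{i}", c, float(rng.normal(0, 2)),
                             float(rng.uniform(0, 1))))
        df = self.table(rows)
        assert filter_de(df) <= filter_de(df, require_all_contrasts=False)

    def test_bad_fdr_rejected(self):
        df = self.table([("g", "V991", 2.0, 1.5)])
        with pytest.raises(InputError):
            filter_de(df)

    def test_planted_de_genes_recovered(self, bundle):
        d, manifest = bundle
        df = pd.read_csv(d / "de_stats.tsv", sep="\t")
        got = sorted(filter_de(df))
        assert got == manifest["expression"]["de_expected_both"]
        any_got = filter_de(df, require_all_contrasts=False)
        assert sorted(any_got) == manifest["expression"]["de_expected_any"]


def test_planted_clusters_recovered_from_bundle(bundle):
    d, manifest = bundle
    from lrrkit.io import read_matrix
    dev = read_matrix(d / "fpkm_development.tsv")
    groups = kmeans_groups(transform(dev), k=2, seed=17)
    truth = [manifest["expression"]["dev_clusters"][g] for g in dev.index]
    assert adjusted_rand_score(truth, groups.values) == 1.0

    stress = read_matrix(d / "fpkm_stress.tsv")
    hgroups = hierarchical_groups(transform(stress), n_groups=4)
    truth = [manifest["expression"]["stress_clusters"][g]
             for g in stress.index]
    assert adjusted_rand_score(truth, hgroups.values) == 1.0
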