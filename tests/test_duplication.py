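"""Gene ordering and the tandem-duplication detector."""

import numpy as np
import pandas as pd
import pytest

from lrrkit.classification import SubfamilyAssignment
from lrrkit.duplication import (
    find_tandem_sets,
    gene_gap,
    order_genes,
    summarize_tandem,
    xi_xii_shares,
)
from lrrkit.io import GeneModel, InputError, PipelineConfig


def make_gene(gene_id, chrom, start, end, scaffold=False):
    return GeneModel(gene_id, chrom, "+", (start, end), [(start, end)],
                     [(start, end - (end - start + 1) % 3, 0)],
                     is_scaffold=scaffold)


def simple_chromosome(positions, chrom="A1"):
    """Genes of length 1000 at the given start positions."""
    return [make_gene(f"{chrom}_g{i}", chrom, p, p + 999)
            for i, p in enumerate(positions)]


def assigned(models, subfam_of):
    return [SubfamilyAssignment(m.gene_id, subfam_of[m.gene_id])
            for m in models if m.gene_id in subfam_of]


class TestOrderGenes:
    def test_ranks_follow_genomic_start(self):
        models = simple_chromosome([100, 90000, 5000])
        idx = order_genes(models)
        assert idx.loc["A1_g0", "rank"] == 0
        assert idx.loc["A1_g2", "rank"] == 1
        assert idx.loc["A1_g1", "rank"] == 2

    def test_shuffled_input_gives_identical_ranks(self, rng):
        models = simple_chromosome(list(range(1000, 100000, 4000)))
        idx1 = order_genes(models)
        shuffled = list(models)
        rng.shuffle(shuffled)
        idx2 = order_genes(shuffled)
        pd.testing.assert_frame_equal(idx1.sort_index(), idx2.sort_index())

    def test_duplicate_gene_id_is_error(self):
        models = [make_gene("g", "A1", 100, 1099),
                  make_gene("g", "A1", 5000, 5999)]
        with pytest.raises(InputError, match="duplicate"):
            order_genes(models)

    def test_empty_input(self):
        assert order_genes([]).empty


def test_gene_gap_overlap_and_distance():
    assert gene_gap(100, 2000, 1500, 3000) == 0
    assert gene_gap(100, 2000, 52_000, 53_000) == 50_000
    assert gene_gap(52_000, 53_000, 100, 2000) == 50_000


class TestFindTandemSets:
    def test_adjacent_pair_within_50kb_forms_a_set(self):
        models = simple_chromosome([10_000, 61_000])
        sets = find_tandem_sets(
            assigned(models, {m.gene_id: "XII" for m in models}),
            order_genes(models))
        assert len(sets) == 1 and sets[0].size == 2

    def test_pair_beyond_200kb_is_rejected(self):
        models = simple_chromosome([10_000, 261_000])
        sets = find_tandem_sets(
            assigned(models, {m.gene_id: "XII" for m in models}),
            order_genes(models))
        assert sets == []

    def test_pair_with_eleven_intervening_genes_is_rejected(self):
        # two XII genes with 11 genes between them, all within 200 kb
        positions = list(range(10_000, 10_000 + 13 * 2000, 2000))
        models = simple_chromosome(positions)
        subfam = {models[0].gene_id: "XII", models[-1].gene_id: "XII"}
        sets = find_tandem_sets(assigned(models, subfam), order_genes(models))
        assert sets == []

    def test_chain_merges_even_when_ends_exceed_window(self):
        # A-B and B-C within 150 kb, A-C at 300 kb: one chained set
        models = simple_chromosome([10_000, 160_000, 310_000])
        sets = find_tandem_sets(
            assigned(models, {m.gene_id: "XII" for m in models}),
            order_genes(models))
        assert len(sets) == 1
        assert sets[0].members == [m.gene_id for m in models]

    def test_different_subfamilies_never_join(self):
        models = simple_chromosome([10_000, 20_000])
        subfam = {models[0].gene_id: "XII", models[1].gene_id: "XI-1"}
        assert find_tandem_sets(assigned(models, subfam),
                                order_genes(models)) == []

    def test_genes_appear_in_at_most_one_set(self, pipeline_result):
        out, _, _ = pipeline_result
        df = pd.read_csv(out / "tandem_sets.tsv", sep="\t")
        members = [g for row in df.members for g in row.split(",")]
        assert len(members) == len(set(members))

    def test_monotone_in_window_parameters(self, rng):
        models, assignments = _random_chromosome(rng, n=120)
        idx = order_genes(models)
        base = _n_tandem_genes(assignments, idx, PipelineConfig())
        wider = _n_tandem_genes(assignments, idx, PipelineConfig(
            tandem_max_distance=400_000, tandem_max_intervening=20))
        assert wider >= base


def _random_chromosome(rng, n=200, chrom="A1"):
    starts = np.cumsum(rng.integers(2_000, 60_000, size=n)) + 10_000
    models = [make_gene(f"{chrom}_g{i:03d}", chrom, int(s), int(s) + 999)
              for i, s in enumerate(starts)]
    subfams = ["XI-1", "XII", "VIII-2", "II"]
    assignments = []
    for m in models:
        if rng.random() < 0.35:
            assignments.append(SubfamilyAssignment(
                m.gene_id, subfams[int(rng.integers(len(subfams)))]))
    return models, assignments


def _n_tandem_genes(assignments, idx, config):
    return sum(t.size for t in find_tandem_sets(assignments, idx, config))


def brute_force_components(models, assignments, config):
    """Independent oracle: exhaustive pair graph + union-find."""
    subfam = {a.gene_id: a.subfamily for a in assignments}
    genes = sorted((m for m in models if m.gene_id in subfam),
                   key=lambda m: m.gene_span[0])
    order = {m.gene_id: i for i, m in enumerate(
        sorted(models, key=lambda m: m.gene_span[0]))}
    parent = {m.gene_id: m.gene_id for m in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            if subfam[a.gene_id] != subfam[b.gene_id]:
                continue
            if abs(order[a.gene_id] - order[b.gene_id]) - 1 > \
                    config.tandem_max_intervening:
                continue
            gap = max(0, b.gene_span[0] - a.gene_span[1])
            if gap > config.tandem_max_distance:
                continue
            parent[find(a.gene_id)] = find(b.gene_id)

    comps = {}
    for m in genes:
        comps.setdefault(find(m.gene_id), set()).add(m.gene_id)
    return sorted(sorted(c) for c in comps.values() if len(c) >= 2)


def test_detector_equals_brute_force_on_random_chromosomes(rng):
    config = PipelineConfig()
    for _ in range(10):
        models, assignments = _random_chromosome(rng, n=150)
        got = sorted(sorted(t.members) for t in find_tandem_sets(
            assignments, order_genes(models), config))
        assert got == brute_force_components(models, assignments, config)


class TestSummaries:
    def test_summary_counts_and_shares(self):
        models = simple_chromosome([10_000, 61_000, 400_000, 451_000])
        subfam = {models[0].gene_id: "XII", models[1].gene_id: "XII",
                  models[2].gene_id: "II", models[3].gene_id: "II"}
        sets = find_tandem_sets(assigned(models, subfam), order_genes(models))
        summary = summarize_tandem(sets)
        assert summary.loc["XII", "n_sets"] == 1
        assert summary.loc["XII", "n_genes"] == 2
        shares = xi_xii_shares(summary)
        assert shares["set_share_pct"] == 50.0
        assert shares["gene_share_pct"] == 50.0

    def test_no_sets_gives_zero_shares(self):
        summary = summarize_tandem([])
        shares = xi_xii_shares(summary)
        assert shares["set_share_pct"] == 0.0
        assert shares["total_sets"] == 0

    def test_planted_arrays_recovered_exactly(self, pipeline_result):
        out, _, manifest = pipeline_result
        df = pd.read_csv(out / "tandem_sets.tsv", sep="\t")
        got = sorted(sorted(x.split(",")) for x in df.members)
        expected = sorted(sorted(a["members"])
                          for a in manifest["tandem_arrays"]
                          if a["within_window"])
        assert got == expected
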