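"""Promoter extraction, IUPAC motif scanning, category aggregation."""

from collections import Counter

import pytest

from lrrkit.classification import SubfamilyAssignment
from lrrkit.io import GeneModel, InputError
from lrrkit.promoter import (
    CisElement,
    categorize_presence,
    default_catalog,
    extract_promoters,
    load_catalog,
    reverse_complement,
    scan_motifs,
    subfamily_cis_enrichment,
)
from lrrkit.simulate import naive_motif_count


def plus_gene(gene_id, start, end, chrom="A1"):
    return GeneModel(gene_id, chrom, "+", (start, end), [(start, end)],
                     [(start, start + 299, 0)])


def minus_gene(gene_id, start, end, chrom="A1"):
    return GeneModel(gene_id, chrom, "-", (start, end), [(start, end)],
                     [(end - 299, end, 0)])


class TestExtractPromoters:
    def test_plus_strand_window(self, rng):
        genome = {"A1": "".join(rng.choice(list("ACGT"), size=4000))}
        model = plus_gene("g", 2001, 2600)
        (seq, truncated), = extract_promoters(genome, [model]).values()
        assert len(seq) == 1500
        assert not truncated
        assert seq == genome["A1"][500:2000]  # genomic 501..2000

    def test_plus_strand_truncated_at_contig_edge(self, rng):
        genome = {"A1": "".join(rng.choice(list("ACGT"), size=4000))}
        model = plus_gene("g", 800, 1399)
        (seq, truncated), = extract_promoters(genome, [model]).values()
        assert truncated
        assert seq == genome["A1"][:799]  # genomic 1..799

    def test_minus_strand_is_reverse_complement_of_downstream(self, rng):
        genome = {"A1": "".join(rng.choice(list("ACGT"), size=5000))}
        model = minus_gene("g", 1001, 2000)
        (seq, truncated), = extract_promoters(genome, [model]).values()
        assert not truncated
        assert seq == reverse_complement(genome["A1"][2000:3500])

    def test_strand_symmetry_on_mirrored_genome(self, rng):
        """A minus-strand gene on the reverse-complemented genome yields the
        same promoter as its plus-strand mirror."""
        n = 6000
        genome = {"A1": "".join(rng.choice(list("ACGT"), size=n))}
        mirror = {"A1": reverse_complement(genome["A1"])}
        fwd = plus_gene("g", 3001, 3600)
        # mirrored gene occupies positions n-3600+1 .. n-3001+1 on '-'
        rev = minus_gene("g", n - 3600 + 1, n - 3001 + 1)
        (seq_f, _), = extract_promoters(genome, [fwd]).values()
        (seq_r, _), = extract_promoters(mirror, [rev]).values()
        assert seq_f == seq_r

    def test_gene_without_cds_skipped_with_warning(self, rng):
        genome = {"A1": "ACGT" * 1000}
        model = GeneModel("g", "A1", "+", (2001, 2600), [(2001, 2600)], [])
        with pytest.warns(UserWarning):
            out = extract_promoters(genome, [model])
        assert out == {}


class TestCatalog:
    def test_default_catalog_loads_and_validates(self):
        catalog = default_catalog()
        assert len(catalog) > 10
        assert all(el.motif and el.category for el in catalog)

    def test_invalid_iupac_symbol_is_hard_error(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("element_id\tmotif\tcategory\nbad\tACGTX\tsome\n")
        with pytest.raises(InputError, match="IUPAC"):
            load_catalog(p)

    def test_empty_motif_rejected(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("element_id\tmotif\tcategory\nbad\t\tsome\n")
        with pytest.raises(InputError):
            load_catalog(p)


class TestScanner:
    def test_empty_catalog_no_matches(self):
        assert scan_motifs({"g": "ACGTACGT"}, []) == []

    def test_simple_match_with_offset(self):
        catalog = [CisElement("tata", "TATA", "core")]
        matches = scan_motifs({"g": "CCTATACC"}, catalog)
        # TATA at offset 2 (+); TATA is its own reverse complement, so the
        # minus strand adds nothing new
        assert [(m.offset, m.strand) for m in matches] == [(2, "+")]

    def test_overlapping_occurrences_all_reported(self):
        catalog = [CisElement("poly", "AAA", "x")]
        matches = scan_motifs({"g": "AAAAA"}, catalog)
        plus = [m for m in matches if m.strand == "+"]
        assert [m.offset for m in plus] == [0, 1, 2]

    def test_minus_strand_occurrence(self):
        # motif TTGACC; its reverse complement GGTCAA sits at offset 1
        catalog = [CisElement("wbox", "TTGACC", "defense")]
        matches = scan_motifs({"g": "AGGTCAAT"}, catalog)
        assert [(m.offset, m.strand) for m in matches] == [(1, "-")]

    def test_degenerate_iupac_codes_match(self):
        catalog = [CisElement("el", "RYN", "x")]
        matches = scan_motifs({"g": "ACG"}, catalog)  # A=R, C=Y, G=N
        assert any(m.offset == 0 and m.strand == "+" for m in matches)

    def test_equivalence_with_naive_sliding_window(self, rng):
        catalog = default_catalog()
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        matches = scan_motifs({"g": seq}, catalog)
        counts = Counter(m.element_id for m in matches)
        for el in catalog:
            assert counts.get(el.element_id, 0) == \
                naive_motif_count(seq, el.motif), el.element_id

    def test_reverse_complement_symmetry(self, rng):
        catalog = default_catalog()
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        fwd = Counter(m.element_id for m in scan_motifs({"g": seq}, catalog))
        rc = Counter(m.element_id for m in scan_motifs(
            {"g": reverse_complement(seq)}, catalog))
        assert fwd == rc


class TestCategories:
    CATALOG = [
        CisElement("abre1", "TTTTTTTT", "ABA response"),
        CisElement("abre2", "CCCCCCCC", "ABA response"),
        CisElement("wbox", "GGGGGGGG", "defense"),
    ]

    def test_no_matches_gives_zero_for_every_category(self):
        table = categorize_presence([], self.CATALOG, ["g1", "g2"])
        assert (table["n_genes"] == 0).all()
        assert (table["pct_genes"] == 0.0).all()

    def test_presence_not_count(self):
        matches = scan_motifs({"g1": "TTTTTTTTACCCCCCCC"}, self.CATALOG)
        table = categorize_presence(matches, self.CATALOG, ["g1", "g2"])
        # two ABA elements in one gene count once
        assert table.loc["ABA response", "n_genes"] == 1
        assert table.loc["ABA response", "pct_genes"] == 50.0
        assert (table["pct_genes"] <= 100.0).all()

    def test_planted_per_gene_counts_recovered(self, bundle):
        d, manifest = bundle
        from lrrkit.io import read_fasta, read_gff3
        genome = read_fasta(d / "genome.fa")
        models = {m.gene_id: m for m in read_gff3(d / "genes.gff3")}
        catalog = default_catalog()
        fam = [models[g] for g in manifest["family_genes"]]
        promoters = extract_promoters(genome, fam)
        matches = scan_motifs(promoters, catalog)
        per = Counter((m.gene_id, m.element_id) for m in matches)
        planted = manifest["promoters"]["planted_counts"]
        for g, elements in planted.items():
            for el, count in elements.items():
                assert per.get((g, el), 0) == count, (g, el)
            extra = {el for (gg, el) in per if gg == g} - set(elements)
            assert not extra, (g, extra)


class TestEnrichment:
    def test_identical_presence_gives_p_one(self):
        catalog = [CisElement("el", "AAAAAAAA", "cat")]
        assignments = [SubfamilyAssignment(f"g{i}", "XII") for i in range(4)]
        matches = scan_motifs({f"g{i}": "AAAAAAAA" for i in range(4)}, catalog)
        df = subfamily_cis_enrichment(matches, catalog, assignments)
        import numpy as np
        assert np.allclose(df["p"], 1.0)

    def test_hypergeometric_tail_matches_enumeration(self):
        # background N=10, K=5 with the category; subfamily n=4 all positive:
        # p = C(5,4)*C(5,0)/C(10,4) = 5/210
        catalog = [CisElement("el", "AAAAAAAA", "cat")]
        promoters = {}
        assignments = []
        for i in range(10):
            sf = "XII" if i < 4 else "III"
            assignments.append(SubfamilyAssignment(f"g{i}", sf))
            promoters[f"g{i}"] = "AAAAAAAA" if i < 5 else "ACGTACGT"
        matches = scan_motifs(promoters, catalog)
        df = subfamily_cis_enrichment(matches, catalog, assignments)
        row = df[(df.subfamily == "XII") & (df.category == "cat")].iloc[0]
        assert row.p == pytest.approx(5 / 210, abs=1e-12)

    def test_planted_enriched_pair_has_smallest_adjusted_p(self, bundle):
        d, manifest = bundle
        from lrrkit.io import read_fasta, read_gff3
        genome = read_fasta(d / "genome.fa")
        models = {m.gene_id: m for m in read_gff3(d / "genes.gff3")}
        catalog = default_catalog()
        fam = [models[g] for g in manifest["family_genes"]]
        matches = scan_motifs(extract_promoters(genome, fam), catalog)
        truth = manifest["tree"]["true_labels"]
        assignments = [SubfamilyAssignment(g, sf) for g, sf in truth.items()]
        df = subfamily_cis_enrichment(matches, catalog, assignments)
        top = df.iloc[0]
        assert [top.subfamily, top.category] == \
            manifest["promoters"]["enriched_pair"]
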