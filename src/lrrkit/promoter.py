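"""Promoter extraction and cis-regulatory element scanning.

The promoter is the 1.5 kb upstream of the translation start codon (first
CDS base in transcription orientation), truncated at contig edges.  A
catalog of IUPAC-degenerate motifs is scanned exactly on both strands;
matches are aggregated into functional categories (presence per gene) and
tested per subfamily for over-representation with a one-sided
hypergeometric test and Benjamini–Hochberg correction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .classification import SubfamilyAssignment
from .io import GeneModel, InputError

__all__ = [
    "IUPAC",
    "CisElement",
    "MotifMatch",
    "load_catalog",
    "default_catalog",
    "reverse_complement",
    "extract_promoters",
    "scan_motifs",
    "categorize_presence",
    "subfamily_cis_enrichment",
]

#: IUPAC nucleotide codes and the base sets they match.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class CisElement:
    element_id: str
    motif: str  # IUPAC string
    category: str


@dataclass(frozen=True)
class MotifMatch:
    gene_id: str
    element_id: str
    offset: int  # 0-based position in the promoter
    strand: str  # "+" | "-"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_motif(element_id: str, motif: str) -> None:
    if not motif:
        raise InputError(f"element {element_id!r}: empty motif")
    bad = set(motif.upper()) - set(IUPAC)
    if bad:
        raise InputError(
            f"element {element_id!r}: invalid IUPAC symbols {sorted(bad)}"
        )


def load_catalog(path) -> list[CisElement]:
    """Load an element_id/motif/category TSV, validating IUPAC alphabets."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"element_id", "motif", "category"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    catalog = []
    for _, row in df.iterrows():
        motif = ("" if pd.isna(row["motif"]) else str(row["motif"])).upper()
        _validate_motif(row["element_id"], motif)
        catalog.append(CisElement(row["element_id"], motif, row["category"]))
    return catalog


def default_catalog() -> list[CisElement]:
    """The packaged cis-element catalog (curated motifs for testing)."""
    ref = resources.files("lrrkit") / "data" / "cis_element_catalog.tsv"
    with resources.as_file(ref) as path:
        return load_catalog(path)


def extract_promoters(
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    length: int = 1500,
) -> dict[str, tuple[str, bool]]:
    """Upstream promoter sequence per gene: gene_id → (sequence, truncated).

    Plus-strand genes take genomic [start−length, start−1]; minus-strand
    genes take (end, end+length] reverse-complemented, so the returned
    sequence always reads 5'→3' toward the start codon.  Genes without CDS
    are skipped with a warning.
    """
    out: dict[str, tuple[str, bool]] = {}
    for m in models:
        if not m.cds_segments:
            warnings.warn(f"{m.gene_id}: no CDS; promoter skipped")
            continue
        chrom_seq = genome[m.chromosome]
        clen = len(chrom_seq)
        if m.strand == "+":
            start_codon = min(s for s, _, _ in m.cds_segments)
            lo = max(1, start_codon - length)
            hi = start_codon - 1
            seq = chrom_seq[lo - 1:hi] if hi >= lo else ""
            truncated = start_codon - length < 1
        else:
            start_codon = max(e for _, e, _ in m.cds_segments)
            lo = start_codon + 1
            hi = min(clen, start_codon + length)
            seq = reverse_complement(chrom_seq[lo - 1:hi]) if hi >= lo else ""
            truncated = start_codon + length > clen
        out[m.gene_id] = (seq.upper(), truncated)
    return out


def _iupac_regex(motif: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in motif
    )
    return re.compile(f"(?=({body}))")


def scan_motifs(
    promoters: Mapping[str, tuple[str, bool] | str],
    catalog: Sequence[CisElement],
) -> list[MotifMatch]:
    """Every exact IUPAC-compatible occurrence on both strands.

    A minus-strand occurrence at offset *o* means the reverse complement of
    the motif appears at promoter positions o..o+len−1.
    """
    matches: list[MotifMatch] = []
    compiled = [
        (el, _iupac_regex(el.motif), _iupac_regex(reverse_complement(el.motif)))
        for el in catalog
    ]
    for gene_id, val in promoters.items():
        seq = val[0] if isinstance(val, tuple) else val
        for el, fwd, rev in compiled:
            for m in fwd.finditer(seq):
                matches.append(MotifMatch(gene_id, el.element_id, m.start(), "+"))
            if el.motif != reverse_complement(el.motif):
                for m in rev.finditer(seq):
                    matches.append(MotifMatch(gene_id, el.element_id, m.start(), "-"))
            else:
                pass  # palindromic motif: both strands coincide
    return matches


def categorize_presence(
    matches: Sequence[MotifMatch],
    catalog: Sequence[CisElement],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Per-category gene presence counts and one-decimal percentages.

    A gene counts once per category when it has ≥ 1 match from any element
    of that category.
    """
    cat_of = {el.element_id: el.category for el in catalog}
    categories = sorted({el.category for el in catalog})
    present: dict[str, set[str]] = {c: set() for c in categories}
    universe_set = set(universe)
    for m in matches:
        if m.gene_id in universe_set:
            present[cat_of[m.element_id]].add(m.gene_id)
    from ._util import round_half_up
    n = len(universe_set)
    return pd.DataFrame({
        "n_genes": [len(present[c]) for c in categories],
        "pct_genes": [float(round_half_up(100.0 * len(present[c]) / n))
                      if n else 0.0 for c in categories],
    }, index=pd.Index(categories, name="category"))


def gene_category_presence(
    matches: Sequence[MotifMatch], catalog: Sequence[CisElement]
) -> dict[str, set[str]]:
    """category → set of genes with ≥1 element of that category."""
    cat_of = {el.element_id: el.category for el in catalog}
    present: dict[str, set[str]] = {el.category: set() for el in catalog}
    for m in matches:
        present[cat_of[m.element_id]].add(m.gene_id)
    return present


def subfamily_cis_enrichment(
    matches: Sequence[MotifMatch],
    catalog: Sequence[CisElement],
    assignments: Sequence[SubfamilyAssignment],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each category in each subfamily.

    Background is the whole family gene set; BH correction is applied across
    all (subfamily, category) tests.
    """
    background = sorted({a.gene_id for a in assignments if not a.is_anchor})
    subfam: dict[str, list[str]] = {}
    for a in assignments:
        if not a.is_anchor:
            subfam.setdefault(a.subfamily, []).append(a.gene_id)
    present = gene_category_presence(matches, catalog)
    n_bg = len(background)
    rows = []
    for sf, genes in sorted(subfam.items()):
        if not genes:
            continue
        for cat in sorted(present):
            hits_bg = present[cat] & set(background)
            k = len(present[cat] & set(genes))
            p = float(hypergeom.sf(k - 1, n_bg, len(hits_bg), len(genes)))
            rows.append((sf, cat, k, len(hits_bg), len(genes), n_bg, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=[
        "subfamily", "category", "overlap", "K_background", "n_subfamily",
        "N_background", "p",
    ])
    if df.empty:
        df["p_adj"] = []
        df["significant"] = []
        return df
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["p_adj"] < alpha
    return df.sort_values(["p_adj", "p"]).reset_index(drop=True)
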