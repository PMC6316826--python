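"""Hypergeometric term enrichment and between-species proportion tests.

Enrichment of GO/KEGG terms in a gene set uses the one-sided upper-tail
hypergeometric probability

    p = sum_{k >= x} C(K, k) C(N-K, n-k) / C(N, n)

with N the background size, K the term's background genes, n the gene-set
size, and x the observed overlap, followed by Benjamini–Hochberg (BH)
correction across tested terms.

Subfamily proportions between two species are compared with Fisher's exact
test (two-sided) on the 2×2 table (in-subfamily vs rest, species A vs B),
again BH-corrected across subfamilies.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .io import InputError

__all__ = [
    "read_term_map",
    "hypergeom_enrich",
    "compare_proportions",
    "ratio_report",
]


def read_term_map(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read gene_id/term_id[/description] TSV into the two term maps."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "term_id"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    gene2terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for _, row in df.iterrows():
        gene2terms.setdefault(row["gene_id"], set()).add(row["term_id"])
        if "description" in df.columns and pd.notna(row.get("description")):
            descriptions[row["term_id"]] = row["description"]
    return gene2terms, descriptions


def hypergeom_enrich(
    gene_set: Sequence[str],
    term_map: Mapping[str, set[str]],
    background: Sequence[str],
    descriptions: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment with BH correction."""
    background = set(background)
    if not background:
        raise InputError("empty background universe")
    gene_set = set(gene_set)
    if not gene_set <= background:
        raise InputError("gene_set is not a subset of the background")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene in background:
            for t in terms:
                term_genes.setdefault(t, set()).add(gene)
    N, n = len(background), len(gene_set)
    rows = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        x = len(term_genes[term] & gene_set)
        p = float(hypergeom.sf(x - 1, N, K, n))
        rows.append((term, x, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "overlap", "K", "n", "N", "p"])
    if df.empty:
        df["p_adj"] = []
        df["significant"] = []
        return df
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["p_adj"] < alpha
    if descriptions:
        df.insert(1, "description", df["term"].map(descriptions).fillna(""))
    return df.sort_values(["p_adj", "p", "term"]).reset_index(drop=True)


def compare_proportions(
    counts_a: Mapping[str, int],
    total_a: int,
    counts_b: Mapping[str, int],
    total_b: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subfamily two-sided Fisher exact comparison of two species."""
    if total_a <= 0 or total_b <= 0:
        raise InputError("species totals must be positive")
    subfamilies = sorted(set(counts_a) | set(counts_b))
    rows = []
    for sf in subfamilies:
        a = int(counts_a.get(sf, 0))
        b = int(counts_b.get(sf, 0))
        if a > total_a or b > total_b:
            raise InputError(f"{sf}: count exceeds total")
        _, p = fisher_exact(
            [[a, total_a - a], [b, total_b - b]], alternative="two-sided"
        )
        rows.append((sf, a, total_a, b, total_b, float(p)))
    df = pd.DataFrame(rows, columns=[
        "subfamily", "count_a", "total_a", "count_b", "total_b", "p",
    ])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["p_adj"] < alpha
    return df


def ratio_report(
    pct_table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Cross-species ratios of subfamily percentage shares.

    ``pct_table`` is the percentage table from
    :func:`lrrkit.classification.percentage_table` (columns ``<sp>_pct``).
    Zero denominators yield NaN (undefined marker).
    """
    out = pd.DataFrame(index=pct_table.index)
    for num, den in pairs:
        num_col, den_col = f"{num}_pct", f"{den}_pct"
        if num_col not in pct_table or den_col not in pct_table:
            raise InputError(f"percentage columns missing for pair {num}/{den}")
        denom = pct_table[den_col].where(pct_table[den_col] != 0)
        out[f"{num}_vs_{den}"] = (pct_table[num_col] / denom).round(2)
    return out
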