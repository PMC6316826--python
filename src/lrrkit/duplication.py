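"""Tandem-duplication detection on chromosome-ordered gene indexes.

Two family genes are tandem neighbours when they share a subfamily and a
chromosome, at most ``tandem_max_intervening`` annotated genes lie between
them, and the gap between their gene spans is at most
``tandem_max_distance``.  Connected components of this neighbour graph with
two or more members form tandem-duplication sets, so chained arrays merge
transitively even when their end members exceed the pairwise window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .classification import SubfamilyAssignment
from .io import GeneModel, InputError, PipelineConfig

__all__ = [
    "TandemSet",
    "order_genes",
    "gene_gap",
    "find_tandem_sets",
    "summarize_tandem",
    "xi_xii_shares",
]

#: Subfamilies whose joint tandem share is reported (the XI/XII expansion).
XI_XII = ("XI-1", "XI-2", "XI-3", "XII")


@dataclass
class TandemSet:
    set_id: str
    subfamily: str
    chromosome: str
    members: list[str]  # ordered by genomic start

    @property
    def size(self) -> int:
        return len(self.members)


def order_genes(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Dense 0-based rank of every annotated gene along its sequence.

    All genes — not only family members — must be present so that
    intervening-gene counts are meaningful.  Scaffolds are indexed
    separately from chromosomes by their own sequence name.
    """
    ids = [m.gene_id for m in models]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate gene ids: {dup}")
    df = pd.DataFrame({
        "gene_id": ids,
        "chromosome": [m.chromosome for m in models],
        "start": [m.gene_span[0] for m in models],
        "end": [m.gene_span[1] for m in models],
        "is_scaffold": [m.is_scaffold for m in models],
    })
    df = df.sort_values(["chromosome", "start", "gene_id"], kind="mergesort")
    df["rank"] = df.groupby("chromosome").cumcount()
    return df.set_index("gene_id")


def gene_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between the closer ends of two gene spans; 0 when overlapping."""
    if a_end < b_start:
        return b_start - a_end
    if b_end < a_start:
        return a_start - b_end
    return 0


def find_tandem_sets(
    assignments: Sequence[SubfamilyAssignment],
    index: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> list[TandemSet]:
    """Connected same-subfamily neighbour clusters of size ≥ 2."""
    config = config or PipelineConfig()
    subfam = {a.gene_id: a.subfamily for a in assignments if not a.is_anchor}
    present = [g for g in subfam if g in index.index]
    graph = nx.Graph()
    graph.add_nodes_from(present)
    by_key: dict[tuple[str, str], list[str]] = {}
    for g in present:
        key = (index.at[g, "chromosome"], subfam[g])
        by_key.setdefault(key, []).append(g)
    for (chrom, sf), genes in by_key.items():
        genes = sorted(genes, key=lambda g: index.at[g, "rank"])
        for i, g1 in enumerate(genes):
            for g2 in genes[i + 1:]:
                intervening = abs(int(index.at[g2, "rank"]) -
                                  int(index.at[g1, "rank"])) - 1
                if intervening > config.tandem_max_intervening:
                    break  # ranks ascending: later genes are farther
                gap = gene_gap(
                    int(index.at[g1, "start"]), int(index.at[g1, "end"]),
                    int(index.at[g2, "start"]), int(index.at[g2, "end"]),
                )
                if gap <= config.tandem_max_distance:
                    graph.add_edge(g1, g2)
    sets: list[TandemSet] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = sorted(comp, key=lambda g: int(index.at[g, "start"]))
        sets.append(TandemSet(
            set_id="",
            subfamily=subfam[members[0]],
            chromosome=str(index.at[members[0], "chromosome"]),
            members=members,
        ))
    sets.sort(key=lambda t: (t.chromosome, int(index.at[t.members[0], "start"])))
    for i, t in enumerate(sets, 1):
        t.set_id = f"TD{i:03d}"
    return sets


def summarize_tandem(
    sets: Sequence[TandemSet],
    assignments: Sequence[SubfamilyAssignment] | None = None,
) -> pd.DataFrame:
    """Per-subfamily tandem counts: n_sets, n_genes, and (when assignments
    are given) the fraction of the subfamily's members that are tandem
    duplicates."""
    rows: dict[str, dict[str, float]] = {}
    for t in sets:
        d = rows.setdefault(t.subfamily, {"n_sets": 0, "n_genes": 0})
        d["n_sets"] += 1
        d["n_genes"] += t.size
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=["n_sets", "n_genes"]).astype(int)
    if assignments is not None and not df.empty:
        sizes = pd.Series(
            [a.subfamily for a in assignments if not a.is_anchor]
        ).value_counts()
        df["subfamily_size"] = sizes.reindex(df.index).fillna(0).astype(int)
        from ._util import round_half_up
        df["pct_tandem"] = round_half_up(
            100.0 * df["n_genes"] / df["subfamily_size"].replace(0, np.nan))
    return df.sort_index()


def xi_xii_shares(summary: pd.DataFrame) -> dict[str, float]:
    """Share (one-decimal %) of tandem sets and genes in subfamilies XI+XII."""
    if summary.empty or summary["n_sets"].sum() == 0:
        return {"set_share_pct": 0.0, "gene_share_pct": 0.0,
                "total_sets": 0, "total_genes": 0}
    from ._util import round_half_up
    in_xi_xii = summary.index.isin(XI_XII)
    total_sets = int(summary["n_sets"].sum())
    total_genes = int(summary["n_genes"].sum())
    return {
        "set_share_pct": float(round_half_up(
            100.0 * summary.loc[in_xi_xii, "n_sets"].sum() / total_sets)),
        "gene_share_pct": float(round_half_up(
            100.0 * summary.loc[in_xi_xii, "n_genes"].sum() / total_genes)),
        "total_sets": total_sets,
        "total_genes": total_genes,
    }
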