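"""Reference-anchored subfamily classification on a phylogeny.

Reference leaves (e.g. Arabidopsis LRR-RLKs of known subfamily) anchor the
clades of a gene tree; every unlabelled leaf inherits the majority anchor
label of the smallest enclosing clade that contains at least one anchor.
Ties are broken by the smallest patristic distance to an anchor of a tied
label; residual ties are flagged ambiguous and take the lexicographically
first label.  Unrooted input trees are midpoint-rooted first.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import dendropy
import pandas as pd

from .io import InputError, PipelineConfig

__all__ = [
    "ReferenceAnchor",
    "SubfamilyAssignment",
    "read_anchors",
    "assign_subfamilies",
    "compare_topologies",
    "tabulate_subfamilies",
    "percentage_table",
]


@dataclass(frozen=True)
class ReferenceAnchor:
    leaf_id: str
    subfamily: str


@dataclass
class SubfamilyAssignment:
    gene_id: str
    subfamily: str
    species: str = ""
    ambiguous: bool = False
    support: float = 1.0
    is_anchor: bool = False


def read_anchors(path, config: PipelineConfig | None = None) -> list[ReferenceAnchor]:
    """Read a leaf_id/subfamily TSV, validating labels against the 21."""
    config = config or PipelineConfig()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"leaf_id", "subfamily"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    anchors = []
    for _, row in df.iterrows():
        if row["subfamily"] not in config.subfamily_labels:
            raise InputError(
                f"{path}: unknown subfamily label {row['subfamily']!r}"
            )
        anchors.append(ReferenceAnchor(row["leaf_id"], row["subfamily"]))
    return anchors


def assign_subfamilies(
    tree: dendropy.Tree,
    anchors: Sequence[ReferenceAnchor],
    species_of: Callable[[str], str] | None = None,
) -> list[SubfamilyAssignment]:
    """Propagate anchor labels to every unlabelled leaf of the tree."""
    if not anchors:
        raise InputError("no reference anchors supplied")
    anchor_label = {a.leaf_id: a.subfamily for a in anchors}
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    # A binary root is taken as a genuine rooting and preserved; a basal
    # multifurcation (the usual unrooted-newick shape) is midpoint-rooted so
    # the clade walk does not depend on where the string happened to start.
    if len(tree.seed_node.child_nodes()) > 2:
        try:
            tree.reroot_at_midpoint(update_bipartitions=False)
        except Exception:
            pass  # degenerate trees stay as parsed

    leaves = list(tree.leaf_node_iter())
    labels_present = {l.taxon.label for l in leaves}
    missing = set(anchor_label) - labels_present
    if missing:
        raise InputError(f"anchor leaves missing from tree: {sorted(missing)}")
    if not set(anchor_label) & labels_present:
        raise InputError("tree contains no anchor leaves")

    pdm = None  # computed lazily, only if a tie must be broken
    taxa = {l.taxon.label: l.taxon for l in leaves}

    def anchor_leaves_under(node) -> list[str]:
        return [l.taxon.label for l in node.leaf_iter()
                if l.taxon.label in anchor_label]

    assignments: list[SubfamilyAssignment] = []
    for leaf in leaves:
        name = leaf.taxon.label
        sp = species_of(name) if species_of else ""
        if name in anchor_label:
            assignments.append(SubfamilyAssignment(
                name, anchor_label[name], sp, ambiguous=False,
                support=1.0, is_anchor=True))
            continue
        node = leaf
        in_clade: list[str] = []
        while node is not None:
            in_clade = anchor_leaves_under(node)
            if in_clade:
                break
            node = node.parent_node
        counts = Counter(anchor_label[a] for a in in_clade)
        top = max(counts.values())
        tied = sorted(lab for lab, c in counts.items() if c == top)
        ambiguous = False
        if len(tied) > 1:
            if pdm is None:
                pdm = tree.phylogenetic_distance_matrix()
            dists = {}
            for lab in tied:
                dists[lab] = min(
                    pdm.patristic_distance(taxa[name], taxa[a])
                    for a in in_clade if anchor_label[a] == lab
                )
            best = min(dists.values())
            closest = sorted(lab for lab, d in dists.items()
                             if abs(d - best) < 1e-12)
            if len(closest) > 1:
                ambiguous = True
            label = closest[0]
        else:
            label = tied[0]
        assignments.append(SubfamilyAssignment(
            name, label, sp, ambiguous=ambiguous,
            support=counts[label] / sum(counts.values())))
    return assignments


def compare_topologies(
    assignments_a: Sequence[SubfamilyAssignment],
    assignments_b: Sequence[SubfamilyAssignment],
) -> dict:
    """Label stability of the same leaves under two alternative trees.

    Returns overall agreement and the per-subfamily agreement (computed over
    the first tree's labels).
    """
    by_a = {a.gene_id: a.subfamily for a in assignments_a}
    by_b = {a.gene_id: a.subfamily for a in assignments_b}
    if set(by_a) != set(by_b):
        raise InputError("leaf sets differ between the two assignments")
    per_sub: dict[str, list[int]] = {}
    agree = 0
    for g, lab in by_a.items():
        same = int(lab == by_b[g])
        agree += same
        per_sub.setdefault(lab, []).append(same)
    return {
        "overall": agree / len(by_a) if by_a else 1.0,
        "per_subfamily": {s: sum(v) / len(v) for s, v in sorted(per_sub.items())},
        "n_leaves": len(by_a),
    }


def tabulate_subfamilies(
    assignments: Sequence[SubfamilyAssignment],
    totals_per_species: Mapping[str, int] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-species subfamily counts and percentages (composition table).

    Percentages are 100·count/total rounded to one decimal; totals default
    to the number of assignments per species.
    """
    config = config or PipelineConfig()
    if not assignments:
        return pd.DataFrame()
    df = pd.DataFrame(
        [(a.species, a.subfamily) for a in assignments if not a.is_anchor]
        or [(a.species, a.subfamily) for a in assignments],
        columns=["species", "subfamily"],
    )
    counts = (
        df.groupby(["species", "subfamily"]).size().unstack(fill_value=0).T
    )
    counts = counts.reindex(
        [s for s in config.subfamily_labels if s in counts.index]
        + [s for s in counts.index if s not in config.subfamily_labels]
    )
    totals = {
        sp: (totals_per_species or {}).get(sp, int(counts[sp].sum()))
        for sp in counts.columns
    }
    return percentage_table(counts, totals)


def percentage_table(
    counts: pd.DataFrame, totals: Mapping[str, int]
) -> pd.DataFrame:
    """Attach one-decimal percentage columns to a subfamily × species table."""
    from ._util import round_half_up

    out = pd.DataFrame(index=counts.index)
    for sp in counts.columns:
        total = totals[sp]
        out[f"{sp}_n"] = counts[sp].astype(int)
        out[f"{sp}_pct"] = round_half_up(100.0 * counts[sp] / total)
    return out
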