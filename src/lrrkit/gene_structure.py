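"""Exon–intron structure of domain regions.

Protein-coordinate domain intervals are projected through the spliced CDS
onto the genome: residue *r* occupies coding nucleotides 3r−2…3r (counting
from the translation start, after skipping the initial phase offset), and a
nucleotide run is split wherever it crosses a CDS segment boundary.  The
number of introns inside a domain is then the number of disjoint genomic
pieces minus one.

Genes are grouped by the exon count of their kinase domain (KD): group A has
the KD on a single exon, group B on two (one intron), group C on three or
more.  Single-exon genes whose subfamily contains multi-intron members are
flagged as retrogene candidates (intron loss via retrotransposition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classification import SubfamilyAssignment
from .io import GeneModel, InputError

__all__ = [
    "StructureProfile",
    "map_protein_to_genome",
    "count_introns_in_region",
    "assign_structure_group",
    "profile_gene",
    "detect_intronless",
    "subfamily_intron_summary",
]


@dataclass
class StructureProfile:
    gene_id: str
    n_exons: int
    kd_exon_count: int
    introns_in_kd: int
    introns_in_ecd: int
    group: str  # A | B | C | unassigned


def _merge_contiguous(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge genomically abutting pieces (no intron between them)."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s == merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def map_protein_to_genome(
    model: GeneModel, protein_interval: tuple[int, int]
) -> list[tuple[int, int]]:
    """Genomic intervals coding for protein residues p..q, sorted by start."""
    p, q = protein_interval
    if p < 1 or q < p:
        raise InputError(f"{model.gene_id}: bad protein interval {p}-{q}")
    segs = model.cds_in_translation_order()
    if not segs:
        raise InputError(f"{model.gene_id}: gene has no CDS")
    offset = segs[0][2]  # initial phase: bases to skip before codon 1
    n1 = offset + 3 * p - 2  # 1-based positions within the spliced CDS
    n2 = offset + 3 * q
    total = model.cds_length
    if n2 > total:
        raise InputError(
            f"{model.gene_id}: interval {p}-{q} beyond protein length "
            f"{(total - offset) // 3}"
        )
    out: list[tuple[int, int]] = []
    pos = 0  # spliced nucleotides consumed so far
    for s, e, _ in segs:
        seg_len = e - s + 1
        lo = max(n1, pos + 1)
        hi = min(n2, pos + seg_len)
        if lo <= hi:
            off_lo, off_hi = lo - pos - 1, hi - pos - 1  # 0-based within segment
            if model.strand == "+":
                out.append((s + off_lo, s + off_hi))
            else:
                out.append((e - off_hi, e - off_lo))
        pos += seg_len
        if pos >= n2:
            break
    return _merge_contiguous(out)


def count_introns_in_region(
    model: GeneModel, genomic_intervals: Sequence[tuple[int, int]]
) -> int:
    """Intron boundaries strictly inside the domain's genomic footprint."""
    merged = _merge_contiguous(list(genomic_intervals))
    return max(len(merged) - 1, 0)


def assign_structure_group(kd_exon_count: int) -> str:
    if kd_exon_count == 0:
        return "unassigned"
    if kd_exon_count == 1:
        return "A"
    if kd_exon_count == 2:
        return "B"
    return "C"


def profile_gene(
    model: GeneModel,
    kd_interval: tuple[int, int] | None,
    tm_start: int | None = None,
) -> StructureProfile:
    """Build a :class:`StructureProfile` for one gene.

    ``kd_interval`` is the kinase domain in protein coordinates; ``tm_start``
    is the first TM residue, which delimits the extracellular domain (ECD)
    as residues 1..tm_start−1.
    """
    kd_count = introns_kd = 0
    if kd_interval is not None:
        kd_pieces = map_protein_to_genome(model, kd_interval)
        kd_count = len(kd_pieces)
        introns_kd = count_introns_in_region(model, kd_pieces)
    introns_ecd = 0
    if tm_start is not None and tm_start > 1:
        ecd_pieces = map_protein_to_genome(model, (1, tm_start - 1))
        introns_ecd = count_introns_in_region(model, ecd_pieces)
    return StructureProfile(
        gene_id=model.gene_id,
        n_exons=model.n_exons,
        kd_exon_count=kd_count,
        introns_in_kd=introns_kd,
        introns_in_ecd=introns_ecd,
        group=assign_structure_group(kd_count),
    )


def detect_intronless(
    profiles: Sequence[StructureProfile],
    assignments: Sequence[SubfamilyAssignment],
) -> list[str]:
    """Retrogene candidates: single-exon genes with multi-intron subfamily mates."""
    subfam = {a.gene_id: a.subfamily for a in assignments}
    witness: dict[str, bool] = {}
    for pr in profiles:
        sf = subfam.get(pr.gene_id)
        if sf is None:
            continue
        if pr.n_exons - 1 >= 2:  # a close homologue with >= 2 introns
            witness[sf] = True
    flagged = [
        pr.gene_id for pr in profiles
        if pr.n_exons == 1 and witness.get(subfam.get(pr.gene_id), False)
    ]
    return sorted(flagged)


def subfamily_intron_summary(
    profiles: Sequence[StructureProfile],
    assignments: Sequence[SubfamilyAssignment],
) -> pd.DataFrame:
    """Mean ± sd intron counts in ECD and KD, per subfamily."""
    subfam = {a.gene_id: a.subfamily for a in assignments}
    rows = [
        (subfam[pr.gene_id], pr.introns_in_ecd, pr.introns_in_kd)
        for pr in profiles if pr.gene_id in subfam
    ]
    if not rows:
        return pd.DataFrame(
            columns=["ecd_mean", "ecd_sd", "kd_mean", "kd_sd", "n"]
        )
    df = pd.DataFrame(rows, columns=["subfamily", "ecd", "kd"])
    g = df.groupby("subfamily")
    out = pd.DataFrame({
        "ecd_mean": g["ecd"].mean(),
        "ecd_sd": g["ecd"].std(ddof=1).fillna(0.0),
        "kd_mean": g["kd"].mean(),
        "kd_sd": g["kd"].std(ddof=1).fillna(0.0),
        "n": g.size(),
    })
    return out.sort_index()
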