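"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are 1-based inclusive (GFF3 convention) throughout
the package; protein coordinates are 1-based inclusive residue positions.
Parsers validate strictly and raise :class:`InputError` rather than silently
dropping rows.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import gffutils
import pandas as pd
import yaml
from Bio import SearchIO, SeqIO

__all__ = [
    "InputError",
    "InvariantError",
    "GeneModel",
    "DomainHit",
    "TMSegment",
    "PipelineConfig",
    "SUBFAMILY_LABELS",
    "CHROMOSOME_PATTERN",
    "read_gff3",
    "write_gff3",
    "read_domain_table",
    "read_similarity_table",
    "read_tm_table",
    "read_newick",
    "read_fasta",
    "write_fasta",
    "read_matrix",
    "write_matrix",
]


class InputError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 2)."""


class InvariantError(RuntimeError):
    """An internal consistency check failed (CLI exit code 3)."""


#: The 21 subfamily labels of the LRR-RLK family used for classification.
#: Subfamilies VI, VII, VIII and XI carry finer sub-splits.
SUBFAMILY_LABELS: tuple[str, ...] = (
    "I", "II", "III", "IV", "V",
    "VI-1", "VI-2", "VII-1", "VII-2", "VIII-1", "VIII-2",
    "IX", "X", "XI-1", "XI-2", "XI-3", "XII",
    "XIII-1", "XIII-2", "XIV", "XV",
)

#: Sequence names matching this pattern are treated as assembled chromosomes
#: (e.g. "A1", "D12", "5"); everything else is flagged as scaffold.
CHROMOSOME_PATTERN = r"^(?:[AD])?[0-9]{1,2}$"


@dataclass
class GeneModel:
    """One gene with its representative transcript's exon/CDS structure."""

    gene_id: str
    chromosome: str
    strand: str
    gene_span: tuple[int, int]
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int, int]]  # (start, end, phase)
    is_scaffold: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)

    @property
    def protein_length(self) -> int:
        phase0 = self.cds_in_translation_order()[0][2]
        return (self.cds_length - phase0) // 3

    def cds_in_translation_order(self) -> list[tuple[int, int, int]]:
        """CDS segments ordered 5'→3' along the mRNA."""
        segs = sorted(self.cds_segments, key=lambda t: t[0])
        return segs if self.strand == "+" else segs[::-1]

    def validate(self) -> None:
        for s, e in self.exons:
            if s > e:
                raise InputError(f"{self.gene_id}: exon interval {s}>{e}")
        for s, e, ph in self.cds_segments:
            if s > e:
                raise InputError(f"{self.gene_id}: CDS interval {s}>{e}")
            if ph not in (0, 1, 2):
                raise InputError(f"{self.gene_id}: CDS phase {ph} not in 0/1/2")
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            raise InputError(f"{self.gene_id}: exons not sorted by start")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise InputError(f"{self.gene_id}: overlapping exons")
        for s, e, _ in self.cds_segments:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise InputError(
                    f"{self.gene_id}: CDS segment {s}-{e} outside exon union"
                )
        phase0 = self.cds_in_translation_order()[0][2] if self.cds_segments else 0
        if self.cds_segments and (self.cds_length - phase0) % 3 != 0:
            raise InputError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible "
                f"by 3 after phase adjustment"
            )
        gs, ge = self.gene_span
        if self.exons and (min(s for s, _ in self.exons) < gs
                           or max(e for _, e in self.exons) > ge):
            raise InputError(f"{self.gene_id}: gene_span does not cover exons")


@dataclass(frozen=True)
class DomainHit:
    """One domain- or similarity-search hit on a protein."""

    protein_id: str
    family_id: str
    evidence: str  # "hmm" | "similarity"
    e_value: float
    ali_start: int
    ali_end: int
    identity_pct: float | None = None

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise InputError(
                f"{self.protein_id}: alignment start {self.ali_start} > "
                f"end {self.ali_end}"
            )
        if not (self.e_value >= 0 and self.e_value == self.e_value
                and self.e_value != float("inf")):
            raise InputError(f"{self.protein_id}: e_value must be finite and >= 0")


@dataclass(frozen=True)
class TMSegment:
    """A predicted transmembrane segment, per predictor."""

    protein_id: str
    predictor: str  # "predictor_a" | "predictor_b"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"{self.protein_id}: TM start > end")


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, in one place.

    Defaults are the values the analysis is defined with: profile-HMM hits
    kept at E ≤ 1e-10, similarity hits at E ≤ 1e-5 and identity > 50%,
    promoters are the upstream 1.5 kb, tandem duplicates are same-subfamily
    neighbours separated by ≤ 10 genes within 200 kb, differential
    expression requires |log2FC| > 1 at FDR < 0.05.
    """

    hmm_evalue_max: float = 1e-10
    sim_evalue_max: float = 1e-5
    sim_identity_min: float = 50.0
    promoter_length: int = 1500
    tandem_max_intervening: int = 10
    tandem_max_distance: int = 200_000
    de_lfc_min: float = 1.0
    de_fdr_max: float = 0.05
    hclust_groups: int = 4
    kmeans_k: int = 2
    log_offset: float = 1.0
    chromosome_pattern: str = CHROMOSOME_PATTERN
    subfamily_labels: tuple[str, ...] = SUBFAMILY_LABELS

    def __post_init__(self) -> None:
        numeric = (
            self.hmm_evalue_max, self.sim_evalue_max, self.sim_identity_min,
            self.promoter_length, self.tandem_max_intervening,
            self.tandem_max_distance, self.de_lfc_min, self.de_fdr_max,
            self.hclust_groups, self.kmeans_k, self.log_offset,
        )
        if any(v <= 0 for v in numeric):
            raise InputError("all PipelineConfig thresholds must be > 0")
        if len(self.subfamily_labels) != 21:
            raise InputError("exactly 21 subfamily labels required")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "subfamily_labels" in data:
            data["subfamily_labels"] = tuple(data["subfamily_labels"])
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _prescan_gff3(path: str | os.PathLike) -> int:
    """Reject malformed intervals up front, naming the offending line."""
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            n_features += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise InputError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise InputError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise InputError(
                    f"{path}: line {lineno}: interval start {start} > end {end}"
                )
    return n_features


def read_gff3(
    path: str | os.PathLike,
    chromosome_pattern: str = CHROMOSOME_PATTERN,
) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features into :class:`GeneModel` records.

    When a gene has several mRNAs, the representative is the one with the
    longest total CDS, ties broken lexicographically by transcript id.
    """
    if _prescan_gff3(path) == 0:
        return []
    chrom_re = re.compile(chromosome_pattern)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        def _cds_len(m):
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))
        rep = sorted(mrnas, key=lambda m: (-_cds_len(m), m.id))[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(rep, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end, int(f.frame) if f.frame not in (".", None) else 0)
            for f in db.children(rep, featuretype="CDS")
        )
        model = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            gene_span=(gene.start, gene.end),
            exons=exons,
            cds_segments=cds,
            is_scaffold=not bool(chrom_re.match(gene.seqid)),
        )
        model.validate()
        models.append(model)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 with one mRNA per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chromosome, m.gene_span[0])):
            gs, ge = m.gene_span
            base = f"{m.chromosome}\tlrrkit\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(f"{base}gene\t{gs}\t{ge}{tail}.\tID={m.gene_id}\n")
            tid = f"{m.gene_id}.t1"
            fh.write(f"{base}mRNA\t{gs}\t{ge}{tail}.\tID={tid};Parent={m.gene_id}\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\tID={tid}.exon{i};Parent={tid}\n")
            for i, (s, e, ph) in enumerate(m.cds_segments, 1):
                fh.write(f"{base}CDS\t{s}\t{e}{tail}{ph}\tID={tid}.cds{i};Parent={tid}\n")


# ---------------------------------------------------------------------------
# Domain / similarity / TM tables
# ---------------------------------------------------------------------------

_TSV_HIT_COLUMNS = ["protein_id", "family_id", "e_value", "ali_start", "ali_end"]


def read_domain_table(path: str | os.PathLike, dialect: str = "domtblout") -> list[DomainHit]:
    """Parse profile-HMM search hits.

    ``dialect="domtblout"`` reads the HMMER per-domain table (the per-domain
    independent E-value is used as the hit's e_value); ``dialect="tsv"``
    reads a generic header-ed table with columns
    protein_id/family_id/e_value/ali_start/ali_end.
    """
    if dialect == "domtblout":
        hits: list[DomainHit] = []
        try:
            for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
                family = qresult.accession or qresult.id
                family = family.split(".")[0]
                for hit in qresult:
                    for hsp in hit:
                        hits.append(DomainHit(
                            protein_id=hit.id,
                            family_id=family,
                            evidence="hmm",
                            e_value=float(hsp.evalue),
                            ali_start=hsp.hit_start + 1,
                            ali_end=hsp.hit_end,
                        ))
        except (ValueError, IndexError) as exc:
            raise InputError(f"{path}: malformed domtblout: {exc}") from exc
        return hits
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            return []
        missing = set(_TSV_HIT_COLUMNS) - set(df.columns)
        if missing:
            raise InputError(f"{path}: missing columns {sorted(missing)}")
        hits = []
        for idx, row in df.iterrows():
            try:
                ev = float(row["e_value"])
            except ValueError as exc:
                raise InputError(
                    f"{path}: row {idx}: non-numeric e-value {row['e_value']!r}"
                ) from exc
            hits.append(DomainHit(
                protein_id=row["protein_id"], family_id=row["family_id"],
                evidence="hmm", e_value=ev,
                ali_start=int(row["ali_start"]), ali_end=int(row["ali_end"]),
            ))
        return hits
    raise InputError(f"unknown domain-table dialect {dialect!r}")


def read_similarity_table(path: str | os.PathLike) -> list[DomainHit]:
    """Parse 12-column blast-tabular similarity hits (evidence='similarity').

    protein_id is the query; query alignment coordinates populate
    ali_start/ali_end; column 3 populates identity_pct.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise InputError(
            f"{path}: expected 12 tab-separated columns, found {df.shape[1]}"
        )
    hits = []
    for idx, row in df.iterrows():
        try:
            ident = float(row[2])
            ev = float(row[10])
        except ValueError as exc:
            raise InputError(f"{path}: row {idx}: non-numeric field") from exc
        hits.append(DomainHit(
            protein_id=str(row[0]), family_id=str(row[1]),
            evidence="similarity", e_value=ev,
            ali_start=int(row[6]), ali_end=int(row[7]),
            identity_pct=ident,
        ))
    return hits


def read_tm_table(path: str | os.PathLike, predictor: str) -> list[TMSegment]:
    """Read a per-protein transmembrane-segment table (protein_id/start/end)."""
    if predictor not in {"predictor_a", "predictor_b"}:
        raise InputError(f"unknown TM predictor {predictor!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    missing = {"protein_id", "start", "end"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return [
        TMSegment(row["protein_id"], predictor, int(row["start"]), int(row["end"]))
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Newick / FASTA / matrices
# ---------------------------------------------------------------------------

def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises various error classes
        raise InputError(f"{path}: cannot parse newick: {exc}") from exc


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise InputError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene × sample TSV matrix keyed by unique gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate gene ids {dups}")
    return df


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "gene_id")
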