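"""End-to-end orchestration of the analysis stages on one input bundle.

Stages run in dependency order — identification → classification →
structure → duplication → promoter → expression (→ term enrichment when a
term map is supplied) — each writing a TSV into the output directory, plus
a ``report.json`` with the gene counts at every filter and a snapshot of
the configuration, so a run can be reproduced bit-for-bit from the report.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classification as cls
from . import duplication as dup
from . import expression as expr
from . import gene_structure as gs
from . import io as lio
from . import promoter as prom
from . import stats as st
from .identification import run_identification

__all__ = ["BundlePaths", "run_pipeline"]


@dataclass
class BundlePaths:
    """Input file locations for one pipeline run (one species/bundle)."""

    gff3: str
    genome: str
    kd_hits: str
    lrr_hits: str
    similarity: str
    tm_a: str
    tm_b: str
    tree: str
    anchors: str
    fpkm_development: str | None = None
    fpkm_stress: str | None = None
    de_stats: str | None = None
    catalog: str | None = None  # None: packaged default catalog
    term_map: str | None = None

    @classmethod
    def from_dir(cls, d: str | os.PathLike) -> "BundlePaths":
        d = Path(d)
        def opt(name):
            p = d / name
            return str(p) if p.exists() else None
        return cls(
            gff3=str(d / "genes.gff3"), genome=str(d / "genome.fa"),
            kd_hits=str(d / "kd.domtblout"), lrr_hits=str(d / "lrr.domtblout"),
            similarity=str(d / "similarity.tsv"),
            tm_a=str(d / "tm_a.tsv"), tm_b=str(d / "tm_b.tsv"),
            tree=str(d / "tree.nwk"), anchors=str(d / "anchors.tsv"),
            fpkm_development=opt("fpkm_development.tsv"),
            fpkm_stress=opt("fpkm_stress.tsv"),
            de_stats=opt("de_stats.tsv"),
            catalog=opt("catalog.tsv"),
            term_map=opt("term_map.tsv"),
        )


def _check_inputs(paths: BundlePaths) -> None:
    required = ["gff3", "genome", "kd_hits", "lrr_hits", "similarity",
                "tm_a", "tm_b", "tree", "anchors"]
    missing = [n for n in required if not os.path.exists(getattr(paths, n))]
    if missing:
        raise lio.InputError(f"missing pipeline inputs: {missing}")


def run_pipeline(
    paths: BundlePaths,
    outdir: str | os.PathLike,
    config: lio.PipelineConfig | None = None,
    seed: int = 17,
    skip_expression: bool = False,
    skip_promoter: bool = False,
) -> dict:
    """Run every stage and write report tables; returns the report dict."""
    config = config or lio.PipelineConfig()
    _check_inputs(paths)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- identification -----------------------------------------------------
    kd = lio.read_domain_table(paths.kd_hits, "domtblout")
    lrr = lio.read_domain_table(paths.lrr_hits, "domtblout")
    sim = lio.read_similarity_table(paths.similarity)
    tm_a = lio.read_tm_table(paths.tm_a, "predictor_a")
    tm_b = lio.read_tm_table(paths.tm_b, "predictor_b")
    results, architectures = run_identification(kd, lrr, sim, tm_a, tm_b, config)
    identified = sorted(r.protein_id for r in results if r.is_lrr_rlk)
    pd.DataFrame([
        {"protein_id": r.protein_id, "is_lrr_rlk": r.is_lrr_rlk,
         "route": r.candidate_route or "",
         "rejection_reason": r.rejection_reason or "",
         "lrr_spans": _fmt(architectures.get(r.protein_id), "lrr_spans"),
         "tm_spans": _fmt(architectures.get(r.protein_id), "tm_spans"),
         "kd_spans": _fmt(architectures.get(r.protein_id), "kd_spans")}
        for r in results
    ]).to_csv(outdir / "identification.tsv", sep="\t", index=False)

    # --- classification -----------------------------------------------------
    tree = lio.read_newick(paths.tree)
    anchors = cls.read_anchors(paths.anchors, config)
    assignments = cls.assign_subfamilies(tree, anchors)
    assignments = [a for a in assignments
                   if a.is_anchor or a.gene_id in set(identified)]
    pd.DataFrame([
        {"gene_id": a.gene_id, "subfamily": a.subfamily,
         "ambiguous": a.ambiguous, "support": round(a.support, 4),
         "is_anchor": a.is_anchor}
        for a in assignments
    ]).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    comp = cls.tabulate_subfamilies(
        [a for a in assignments if not a.is_anchor])
    comp.to_csv(outdir / "subfamily_composition.tsv", sep="\t",
                index_label="subfamily")

    # --- gene structure -----------------------------------------------------
    models = lio.read_gff3(paths.gff3, config.chromosome_pattern)
    by_id = {m.gene_id: m for m in models}
    profiles = []
    for g in identified:
        model = by_id.get(g)
        arch = architectures.get(g)
        if model is None or arch is None:
            continue
        kd_span = arch.kd_spans[0] if arch.kd_spans else None
        tm_start = min(s for s, _ in arch.tm_spans) if arch.tm_spans else None
        profiles.append(gs.profile_gene(model, kd_span, tm_start))
    retro = gs.detect_intronless(profiles, assignments)
    pd.DataFrame([
        {"gene_id": p.gene_id, "n_exons": p.n_exons,
         "kd_exon_count": p.kd_exon_count, "introns_in_kd": p.introns_in_kd,
         "introns_in_ecd": p.introns_in_ecd, "group": p.group,
         "retrogene_candidate": p.gene_id in set(retro)}
        for p in profiles
    ]).to_csv(outdir / "structure_profiles.tsv", sep="\t", index=False)
    gs.subfamily_intron_summary(profiles, assignments).to_csv(
        outdir / "intron_summary.tsv", sep="\t", index_label="subfamily")

    # --- duplication --------------------------------------------------------
    index = dup.order_genes(models)
    tsets = dup.find_tandem_sets(assignments, index, config)
    pd.DataFrame([
        {"set_id": t.set_id, "subfamily": t.subfamily,
         "chromosome": t.chromosome, "size": t.size,
         "members": ",".join(t.members)}
        for t in tsets
    ]).to_csv(outdir / "tandem_sets.tsv", sep="\t", index=False)
    tsummary = dup.summarize_tandem(tsets, assignments)
    tsummary.to_csv(outdir / "tandem_summary.tsv", sep="\t",
                    index_label="subfamily")
    shares = dup.xi_xii_shares(tsummary)

    # --- promoter -----------------------------------------------------------
    n_promoters = n_matches = 0
    if not skip_promoter:
        genome = lio.read_fasta(paths.genome)
        catalog = (prom.load_catalog(paths.catalog) if paths.catalog
                   else prom.default_catalog())
        fam_models = [by_id[g] for g in identified if g in by_id]
        promoters = prom.extract_promoters(genome, fam_models,
                                           config.promoter_length)
        matches = prom.scan_motifs(promoters, catalog)
        n_promoters, n_matches = len(promoters), len(matches)
        presence = prom.categorize_presence(matches, catalog,
                                            list(promoters))
        presence.to_csv(outdir / "promoter_categories.tsv", sep="\t")
        enr = prom.subfamily_cis_enrichment(matches, catalog, assignments)
        enr.to_csv(outdir / "promoter_enrichment.tsv", sep="\t", index=False)

    # --- expression ---------------------------------------------------------
    expr_report = {}
    if not skip_expression and paths.fpkm_development:
        dev = lio.read_matrix(paths.fpkm_development)
        logdev = expr.transform(dev, config.log_offset)
        kgroups = expr.kmeans_groups(logdev, config.kmeans_k, seed=seed)
        kgroups.to_frame().to_csv(outdir / "kmeans_groups.tsv", sep="\t",
                                  index_label="gene_id")
        expr_report["kmeans_group_sizes"] = (
            kgroups.value_counts().sort_index().to_dict())
    if not skip_expression and paths.fpkm_stress:
        stress = lio.read_matrix(paths.fpkm_stress)
        hgroups = expr.hierarchical_groups(
            expr.transform(stress, config.log_offset), config.hclust_groups)
        hgroups.to_frame().to_csv(outdir / "hierarchical_groups.tsv",
                                  sep="\t", index_label="gene_id")
        expr_report["hierarchical_group_sizes"] = (
            hgroups.value_counts().sort_index().to_dict())
    if not skip_expression and paths.de_stats:
        de = pd.read_csv(paths.de_stats, sep="\t")
        de_genes = sorted(expr.filter_de(de, config,
                                         require_all_contrasts=True))
        (outdir / "de_genes.txt").write_text("".join(g + "\n"
                                                     for g in de_genes))
        expr_report["n_de_genes"] = len(de_genes)

    # --- term enrichment (optional input) -----------------------------------
    if paths.term_map:
        term_map, descriptions = st.read_term_map(paths.term_map)
        background = sorted(by_id)
        enr = st.hypergeom_enrich(
            [g for g in identified if g in set(background)],
            term_map, background, descriptions)
        enr.to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False)

    report = {
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
        "counts": {
            "n_genes_annotated": len(models),
            "n_proteins_with_evidence": len(results),
            "n_identified": len(identified),
            "n_classified": len([a for a in assignments if not a.is_anchor]),
            "n_structure_profiles": len(profiles),
            "n_retrogene_candidates": len(retro),
            "n_tandem_sets": len(tsets),
            "n_tandem_genes": int(tsummary["n_genes"].sum())
            if not tsummary.empty else 0,
            "n_promoters_scanned": n_promoters,
            "n_motif_matches": n_matches,
        },
        "tandem_xi_xii_shares": shares,
        "expression": expr_report,
    }
    # invariant: classified/profiled genes cannot exceed the identified set
    n_id = report["counts"]["n_identified"]
    if (report["counts"]["n_classified"] > n_id
            or report["counts"]["n_structure_profiles"] > n_id):
        raise lio.InvariantError("stage gene counts do not reconcile")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _fmt(arch, attr) -> str:
    if arch is None:
        return ""
    return ";".join(f"{s}-{e}" for s, e in getattr(arch, attr))
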