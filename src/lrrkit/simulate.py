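"""Synthetic genome, evidence, tree, promoter and expression generator.

Every input the pipeline consumes can be generated here together with a
ground-truth manifest, so each stage is testable offline against planted
truth: planted LRR-RLK architectures and decoys with known missing-domain
classes, tandem arrays inside and outside the detection window, intronless
retrogene copies, planted promoter motif occurrences, planted expression
clusters and differentially expressed genes.

The default scale (2 chromosomes + 1 scaffold, 300 annotated genes, 60
family genes across 8 subfamilies, 4 within-window tandem arrays plus 2
deliberate near-misses, 2 retrogenes) exercises every rule of the pipeline
in seconds.  All outputs are deterministic given the seed: the same seed
produces byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneModel, write_fasta, write_gff3, write_matrix
from .promoter import IUPAC, CisElement, reverse_complement

__all__ = [
    "SimulationConfig",
    "TandemArraySpec",
    "generate_genome",
    "generate_evidence",
    "generate_tree",
    "generate_promoters_and_expression",
    "generate_bundle",
    "naive_motif_count",
]

#: KD exon-structure class planted per subfamily (A: 1 exon, B: 2, C: 3+),
#: following the observed subfamily structure classes.
SUBFAMILY_GROUP = {
    "VII-1": "A", "XV": "A",
    "III": "B", "IX": "B", "XI-1": "B", "XI-2": "B", "XII": "B",
    "VIII-2": "C",
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Tandem-rule constants mirrored here so planted near-misses are
#: constructed against the same window the detector uses.
TANDEM_MAX_INTERVENING = 10
TANDEM_MAX_DISTANCE = 200_000


@dataclass(frozen=True)
class TandemArraySpec:
    subfamily: str
    size: int
    chromosome_index: int = 0
    gap_range: tuple[int, int] = (5_000, 40_000)
    n_intervening: int = 0
    within_window: bool = True  # False: planted to *fail* the tandem rule


@dataclass
class SimulationConfig:
    chromosome_names: tuple[str, ...] = ("A1", "A2")
    scaffold_names: tuple[str, ...] = ("scaffold_1",)
    n_genes: int = 300
    n_family: int = 60
    n_scaffold_genes: int = 12
    n_scaffold_family: int = 2
    subfamilies: tuple[str, ...] = (
        "III", "IX", "VII-1", "VIII-2", "XI-1", "XI-2", "XII", "XV",
    )
    tandem_arrays: tuple[TandemArraySpec, ...] = (
        TandemArraySpec("XI-1", 4, 0),
        TandemArraySpec("XII", 3, 1),
        TandemArraySpec("VIII-2", 2, 0, n_intervening=2),
        TandemArraySpec("III", 2, 1),
        # near-misses: one pair beyond 200 kb, one pair with >10 intervening
        TandemArraySpec("XII", 2, 0, gap_range=(250_000, 260_000),
                        within_window=False),
        TandemArraySpec("XI-1", 2, 1, n_intervening=12,
                        gap_range=(3_500, 6_000), within_window=False),
    )
    n_retrogenes: int = 2
    retro_subfamilies: tuple[str, ...] = ("XI-1", "III")
    intergenic_gap: tuple[int, int] = (3_500, 12_000)
    min_family_slot_spacing: int = 12  # slots between unrelated same-subfamily genes
    promoter_length: int = 1500


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _sample_cuts(rng, lo: int, hi: int, k: int, min_gap: int = 45) -> list[int]:
    """k sorted cut positions in [lo, hi], pairwise >= min_gap apart."""
    if k == 0:
        return []
    if hi - lo < (k - 1) * min_gap:
        raise ValueError("region too small for requested cuts")
    for _ in range(200):
        cuts = sorted(int(c) for c in rng.integers(lo, hi + 1, size=k))
        if len(set(cuts)) == k and all(
            b - a >= min_gap for a, b in zip(cuts, cuts[1:])
        ):
            return cuts
    raise RuntimeError("could not sample well-spaced cuts")


def _plan_family_protein(rng, subfamily: str, is_retro: bool) -> dict:
    """Plant an LRR–TM–KD protein layout and the exon cut plan."""
    n_lrr = int(rng.integers(1, 3))
    lrr_spans = []
    pos = int(rng.integers(25, 50))
    for _ in range(n_lrr):
        ln = int(rng.integers(90, 180))
        lrr_spans.append((pos, pos + ln - 1))
        pos += ln + int(rng.integers(5, 25))
    tm_s = pos + int(rng.integers(15, 50))
    tm = (tm_s, tm_s + 22)
    kd_s = tm[1] + int(rng.integers(20, 60))
    kd = (kd_s, kd_s + 259)
    length = kd[1] + int(rng.integers(5, 30))

    group = SUBFAMILY_GROUP.get(subfamily, "B")
    # non-retro family genes always carry >= 1 intron, so intronless
    # (retrogene) structure is planted only where the manifest says so
    if is_retro:
        kd_nexons, ecd_introns = 1, 0
    elif group == "A":
        kd_nexons, ecd_introns = 1, int(rng.integers(1, 3))
    elif group == "B":
        kd_nexons, ecd_introns = 2, int(rng.integers(1, 4))
    else:
        kd_nexons, ecd_introns = int(rng.integers(3, 7)), int(rng.integers(2, 6))

    ecd_nt_hi = 3 * (tm_s - 1)
    kd_nt = (3 * kd[0] - 2, 3 * kd[1])
    cuts: list[int] = []
    if ecd_introns:
        cuts += _sample_cuts(rng, 60, ecd_nt_hi - 60, ecd_introns)
    if kd_nexons > 1:
        cuts += _sample_cuts(rng, kd_nt[0] + 30, kd_nt[1] - 31, kd_nexons - 1)
    return {
        "protein_length": length, "lrr_spans": lrr_spans, "tm_span": tm,
        "kd_span": kd, "kd_exon_count": kd_nexons,
        "ecd_intron_count": ecd_introns, "cuts": sorted(cuts),
    }


def _plan_plain_protein(rng) -> dict:
    length = int(rng.integers(150, 600))
    n_exons = int(rng.integers(1, 6))
    total = 3 * length
    cuts: list[int] = []
    if n_exons > 1 and total > (n_exons - 1) * 60 + 120:
        cuts = _sample_cuts(rng, 60, total - 60, n_exons - 1)
    return {"protein_length": length, "cuts": cuts}


def _build_model(rng, gene_id, chrom, strand, start, plan,
                 is_scaffold) -> GeneModel:
    """Lay the spliced CDS (cut plan) onto the genome starting at `start`."""
    total = 3 * plan["protein_length"]
    bounds = [0] + plan["cuts"] + [total]
    seg_lengths = [b - a for a, b in zip(bounds, bounds[1:])]  # translation order
    genomic_lengths = seg_lengths if strand == "+" else seg_lengths[::-1]
    introns = [int(rng.integers(80, 600))
               for _ in range(len(genomic_lengths) - 1)]
    exons = []
    pos = start
    for i, ln in enumerate(genomic_lengths):
        exons.append((pos, pos + ln - 1))
        pos += ln
        if i < len(introns):
            pos += introns[i]
    phases = []
    cum = 0
    for ln in seg_lengths:
        phases.append((3 - cum % 3) % 3)
        cum += ln
    genomic_phases = phases if strand == "+" else phases[::-1]
    cds = [(s, e, ph) for (s, e), ph in zip(exons, genomic_phases)]
    model = GeneModel(
        gene_id=gene_id, chromosome=chrom, strand=strand,
        gene_span=(exons[0][0], exons[-1][1]),
        exons=exons, cds_segments=cds, is_scaffold=is_scaffold,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    config: SimulationConfig | None = None, seed: int = 17
) -> tuple[list[GeneModel], dict[str, str], dict[str, str], dict]:
    """Generate gene models, genome FASTA, protein FASTA and the manifest.

    Tandem-array members and their intervening genes are carved out of the
    ``n_genes`` budget, so the emitted annotation holds exactly ``n_genes``
    genes (``n_genes`` = 0 yields an empty annotation).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]).generate_state(1)[0])

    if config.n_genes == 0:
        manifest = {"seed": seed, "genes": {}, "tandem_arrays": [],
                    "subfamilies": list(config.subfamilies),
                    "retrogenes": [], "family_genes": []}
        return [], {}, {}, manifest
    if config.n_family > config.n_genes:
        raise ValueError("n_family exceeds n_genes")

    array_family = sum(a.size for a in config.tandem_arrays)
    n_scattered = (config.n_family - array_family - config.n_retrogenes
                   - config.n_scaffold_family)
    if n_scattered < 0:
        raise ValueError("family budget too small for arrays/retrogenes")

    n_chrom = len(config.chromosome_names)
    n_chrom_genes = config.n_genes - config.n_scaffold_genes
    per_chrom = [n_chrom_genes // n_chrom] * n_chrom
    per_chrom[0] += n_chrom_genes - sum(per_chrom)
    # reserve room for the array runs (members + intervening genes)
    for spec in config.tandem_arrays:
        ci = spec.chromosome_index % n_chrom
        per_chrom[ci] -= spec.size + (spec.size - 1) * spec.n_intervening
    if any(b < 1 for b in per_chrom):
        raise ValueError("n_genes too small for the requested tandem arrays")

    # scattered family plans, round-robin over subfamilies
    family_plan: list[dict] = []
    for i in range(n_scattered):
        family_plan.append({
            "kind": "family",
            "subfamily": config.subfamilies[i % len(config.subfamilies)],
            "is_retro": False,
        })
    for i in range(config.n_retrogenes):
        family_plan.append({
            "kind": "family",
            "subfamily": config.retro_subfamilies[i % len(config.retro_subfamilies)],
            "is_retro": True,
        })
    rng.shuffle(family_plan)

    spacing = config.min_family_slot_spacing
    chrom_slots: list[list[dict]] = []
    for ci in range(n_chrom):
        fam_queue = [family_plan[j] for j in range(len(family_plan))
                     if j % n_chrom == ci][::-1]
        slots: list[dict] = []
        last_seen: dict[str, int] = {}
        while len(slots) < per_chrom[ci]:
            placed = False
            for j in range(len(fam_queue) - 1, -1, -1):
                plan = fam_queue[j]
                if len(slots) - last_seen.get(plan["subfamily"], -10**9) > spacing:
                    fam_queue.pop(j)
                    slots.append(plan)
                    last_seen[plan["subfamily"]] = len(slots) - 1
                    placed = True
                    break
            if not placed:
                slots.append({"kind": "background"})
        if fam_queue:
            raise RuntimeError("could not place all family genes; "
                               "increase n_genes or reduce spacing")
        # keep the contig-edge (truncated-promoter) slot a background gene
        if ci == 0 and slots and slots[0]["kind"] == "family":
            sf = slots[0]["subfamily"]
            for j in range(1, len(slots)):
                if slots[j]["kind"] != "background":
                    continue
                lo, hi = max(0, j - spacing), min(len(slots), j + spacing + 1)
                if not any(s.get("subfamily") == sf
                           for s in slots[lo:hi]):
                    slots[0], slots[j] = slots[j], slots[0]
                    break
        chrom_slots.append(slots)

    # insert tandem-array runs away from same-subfamily scattered slots
    for ai, spec in enumerate(config.tandem_arrays):
        ci = spec.chromosome_index % n_chrom
        slots = chrom_slots[ci]
        run: list[dict] = []
        for m in range(spec.size):
            if m > 0:
                run.extend({"kind": "background"}
                           for _ in range(spec.n_intervening))
            run.append({
                "kind": "family", "subfamily": spec.subfamily,
                "is_retro": False, "array_index": ai,
                "gap_before": int(rng.integers(*spec.gap_range)) if m else None,
            })
        for s in run:
            s["run_tag"] = ai
        ok_pos = None
        for pos in range(1, len(slots) + 1):  # pos 0 reserved (contig edge)
            if (0 < pos < len(slots)
                    and slots[pos - 1].get("run_tag") is not None
                    and slots[pos - 1].get("run_tag")
                    == slots[pos].get("run_tag")):
                continue  # never split a previously inserted run
            lo = max(0, pos - spacing - 1)
            hi = min(len(slots), pos + spacing + 1)
            if not any(s.get("subfamily") == spec.subfamily
                       for s in slots[lo:hi]):
                ok_pos = pos
                break
        if ok_pos is None:
            raise RuntimeError(f"no room for tandem array {spec}")
        chrom_slots[ci] = slots[:ok_pos] + run + slots[ok_pos:]

    scaffold_slots: list[list[dict]] = []
    scaf_fams = [config.subfamilies[i % len(config.subfamilies)]
                 for i in range(config.n_scaffold_family)]
    for si, name in enumerate(config.scaffold_names):
        slots = [{"kind": "background"}
                 for _ in range(config.n_scaffold_genes)]
        if si == 0:
            step = max(1, config.n_scaffold_genes // (len(scaf_fams) + 1))
            for k, sf in enumerate(scaf_fams):
                idx = min(len(slots) - 1, (k + 1) * step)
                slots[idx] = {"kind": "family", "subfamily": sf,
                              "is_retro": False}
        scaffold_slots.append(slots)

    # --- realize genes ------------------------------------------------------
    models: list[GeneModel] = []
    manifest_genes: dict[str, dict] = {}
    arrays_manifest: dict[int, dict] = {}
    counter = 0

    def realize(seq_name: str, slots: list[dict], is_scaffold: bool,
                truncated_first: bool) -> int:
        nonlocal counter
        cursor = 800 if truncated_first else int(rng.integers(4_000, 9_000))
        for k, slot in enumerate(slots):
            counter += 1
            gene_id = f"GS_g{counter:04d}"
            strand = "+" if (truncated_first and k == 0) else \
                ("+" if rng.random() < 0.5 else "-")
            is_family = slot["kind"] == "family"
            if is_family:
                plan = _plan_family_protein(rng, slot["subfamily"],
                                            slot.get("is_retro", False))
            else:
                plan = _plan_plain_protein(rng)
            model = _build_model(rng, gene_id, seq_name, strand, cursor,
                                 plan, is_scaffold)
            models.append(model)
            rec = {
                "chromosome": seq_name, "strand": strand,
                "start": model.gene_span[0], "end": model.gene_span[1],
                "n_exons": model.n_exons,
                "protein_length": plan["protein_length"],
                "is_family": is_family,
            }
            if is_family:
                rec.update({
                    "subfamily": slot["subfamily"],
                    "is_retro": bool(slot.get("is_retro", False)),
                    "lrr_spans": [list(s) for s in plan["lrr_spans"]],
                    "tm_span": list(plan["tm_span"]),
                    "kd_span": list(plan["kd_span"]),
                    "kd_exon_count": plan["kd_exon_count"],
                    "ecd_intron_count": plan["ecd_intron_count"],
                })
                ai = slot.get("array_index")
                if ai is not None:
                    spec = config.tandem_arrays[ai]
                    arrays_manifest.setdefault(ai, {
                        "subfamily": spec.subfamily, "chromosome": seq_name,
                        "members": [], "within_window": spec.within_window,
                    })["members"].append(gene_id)
            manifest_genes[gene_id] = rec
            gap = None
            if k + 1 < len(slots):
                gap = slots[k + 1].get("gap_before")
            if gap is None:
                gap = int(rng.integers(*config.intergenic_gap))
            cursor = model.gene_span[1] + gap
        return cursor

    seq_lengths: dict[str, int] = {}
    for ci, name in enumerate(config.chromosome_names):
        end = realize(name, chrom_slots[ci], False, truncated_first=(ci == 0))
        seq_lengths[name] = end + 2_000
    for si, name in enumerate(config.scaffold_names):
        end = realize(name, scaffold_slots[si], True, truncated_first=False)
        seq_lengths[name] = end + 2_000

    arrays = [arrays_manifest[k] for k in sorted(arrays_manifest)]
    _assert_no_accidental_arrays(models, manifest_genes, arrays)

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {
        name: bytes(np.take(bases, rng.integers(0, 4, size=ln))).decode()
        for name, ln in seq_lengths.items()
    }
    proteins = {
        m.gene_id: "M" + "".join(
            rng.choice(list(AA_ALPHABET),
                       size=manifest_genes[m.gene_id]["protein_length"] - 1))
        for m in models
    }
    manifest = {
        "seed": seed,
        "genes": manifest_genes,
        "tandem_arrays": arrays,
        "subfamilies": list(config.subfamilies),
        "retrogenes": sorted(g for g, r in manifest_genes.items()
                             if r.get("is_retro")),
        "family_genes": sorted(g for g, r in manifest_genes.items()
                               if r["is_family"]),
        "promoter_length": config.promoter_length,
    }
    return models, genome, proteins, manifest


def _assert_no_accidental_arrays(models, manifest_genes, arrays) -> None:
    """Unintended same-subfamily neighbour pairs must fail the tandem rule."""
    member_to_array = {}
    for i, a in enumerate(arrays):
        for g in a["members"]:
            member_to_array[g] = i
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in sorted(models, key=lambda m: (m.chromosome, m.gene_span[0])):
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom, genes in by_chrom.items():
        fam = [(i, m) for i, m in enumerate(genes)
               if manifest_genes[m.gene_id]["is_family"]]
        for a in range(len(fam)):
            for b in range(a + 1, len(fam)):
                i1, m1 = fam[a]
                i2, m2 = fam[b]
                if i2 - i1 - 1 > TANDEM_MAX_INTERVENING:
                    break
                s1 = manifest_genes[m1.gene_id]["subfamily"]
                s2 = manifest_genes[m2.gene_id]["subfamily"]
                if s1 != s2:
                    continue
                if (member_to_array.get(m1.gene_id) is not None
                        and member_to_array.get(m1.gene_id)
                        == member_to_array.get(m2.gene_id)):
                    continue
                gap = max(0, m2.gene_span[0] - m1.gene_span[1])
                if gap <= TANDEM_MAX_DISTANCE:
                    raise RuntimeError(
                        "accidental tandem adjacency "
                        f"{m1.gene_id}/{m2.gene_id} on {chrom}"
                    )


# ---------------------------------------------------------------------------
# evidence generation
# ---------------------------------------------------------------------------

_DECOY_CLASSES = (
    "not_candidate", "not_candidate",
    "subthreshold", "subthreshold",
    "no_lrr", "no_lrr", "no_kd",
    "no_tm", "no_tm", "bad_order",
)

_DOMTBL_HEADER = (
    "# target name        accession   tlen query name           accession   "
    "qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  "
    "from    to  from    to  from    to  acc description of target\n"
)


def _domtbl_row(protein, plen, family_name, family_acc, flen, evalue, s, e):
    return (f"{protein} - {plen} {family_name} {family_acc} {flen} "
            f"{evalue:.2g} 250.0 0.1 1 1 {evalue:.2g} {evalue:.2g} 240.0 0.1 "
            f"1 {flen} {s} {e} {max(1, s - 2)} {min(plen, e + 2)} 0.95 -\n")


def _decoy_layout(plen: int, reversed_order: bool = False):
    lrr = (5, max(6, int(plen * 0.30)))
    tm = (int(plen * 0.38), int(plen * 0.38) + min(22, max(6, plen // 12)))
    kd = (int(plen * 0.55), plen - 2)
    if reversed_order:
        return {"lrr": kd, "tm": tm, "kd": lrr}
    return {"lrr": lrr, "tm": tm, "kd": kd}


def generate_evidence(
    manifest: dict,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    tm_disagree_rate: float = 0.0,
    seed: int = 17,
) -> dict[str, str]:
    """Emit KD/LRR domtblout, similarity and TM tables as text blobs.

    Returns ``{"kd", "lrr", "similarity", "tm_a", "tm_b"}`` and annotates
    the manifest with decoy classes and the expected identified set under
    the requested noise rates.  At zero rates the identification stage
    recovers the planted family exactly.
    """
    for r in (fn_rate, fp_rate, tm_disagree_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("noise rates must be in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    genes = manifest["genes"]
    family = manifest["family_genes"]
    background = sorted(g for g, r in genes.items() if not r["is_family"])

    decoys: dict[str, str] = {}
    pool = list(background)
    rng.shuffle(pool)
    n_decoys = min(len(_DECOY_CLASSES), len(pool))
    for cls in _DECOY_CLASSES[:n_decoys]:
        decoys[pool.pop()] = cls
    manifest["decoys"] = decoys

    kd_rows, lrr_rows, sim_rows = [], [], []
    tm_a_rows, tm_b_rows = [], []
    dropped_kd: list[str] = []

    def strong_e(lo=18, hi=40):
        return 10.0 ** -float(rng.integers(lo, hi))

    sim_subset = {g for g in family if rng.random() < 0.5}

    for g in family:
        rec = genes[g]
        plen = rec["protein_length"]
        kd_s, kd_e = rec["kd_span"]
        if rng.random() < fn_rate:
            dropped_kd.append(g)
        else:
            kd_rows.append(_domtbl_row(g, plen, "Pkinase", "PF00069.1", 264,
                                       strong_e(), kd_s, kd_e))
        for s, e in rec["lrr_spans"]:
            lrr_rows.append(_domtbl_row(g, plen, "LRR_8", "PF13855.1", 61,
                                        strong_e(), s, e))
        if g in sim_subset:
            ident = float(rng.uniform(55, 95))
            sim_rows.append(
                f"{g}\tREF_{rec['subfamily']}\t{ident:.1f}\t{plen}\t10\t1\t1\t"
                f"{plen}\t1\t{plen}\t{strong_e(25, 60):.2g}\t500.0\n"
            )
        tm_s, tm_e = rec["tm_span"]
        row = f"{g}\t{tm_s}\t{tm_e}\n"
        if rng.random() < tm_disagree_rate:
            (tm_a_rows if rng.random() < 0.5 else tm_b_rows).append(row)
        else:
            tm_a_rows.append(row)
            tm_b_rows.append(row)

    for g, cls in sorted(decoys.items()):
        plen = genes[g]["protein_length"]
        lay = _decoy_layout(plen, reversed_order=(cls == "bad_order"))
        if cls == "not_candidate":
            kd_rows.append(_domtbl_row(g, plen, "Pkinase", "PF00069.1", 264,
                                       strong_e(), *lay["kd"]))
        elif cls == "subthreshold":
            kd_rows.append(_domtbl_row(g, plen, "Pkinase", "PF00069.1", 264,
                                       1e-8, *lay["kd"]))
            lrr_rows.append(_domtbl_row(g, plen, "LRR_8", "PF13855.1", 61,
                                        1e-7, *lay["lrr"]))
            sim_rows.append(f"{g}\tREF_X\t45.0\t{plen}\t10\t1\t1\t{plen}\t1\t"
                            f"{plen}\t1e-30\t300.0\n")
        elif cls == "no_lrr":
            kd_rows.append(_domtbl_row(g, plen, "Pkinase", "PF00069.1", 264,
                                       strong_e(), *lay["kd"]))
            sim_rows.append(f"{g}\tREF_X\t70.0\t{plen}\t10\t1\t1\t{plen}\t1\t"
                            f"{plen}\t1e-40\t500.0\n")
            tm_a_rows.append(f"{g}\t{lay['tm'][0]}\t{lay['tm'][1]}\n")
        elif cls == "no_kd":
            lrr_rows.append(_domtbl_row(g, plen, "LRR_8", "PF13855.1", 61,
                                        strong_e(), *lay["lrr"]))
            sim_rows.append(f"{g}\tREF_X\t70.0\t{plen}\t10\t1\t1\t{plen}\t1\t"
                            f"{plen}\t1e-40\t500.0\n")
            tm_a_rows.append(f"{g}\t{lay['tm'][0]}\t{lay['tm'][1]}\n")
        elif cls == "no_tm":
            kd_rows.append(_domtbl_row(g, plen, "Pkinase", "PF00069.1", 264,
                                       strong_e(), *lay["kd"]))
            lrr_rows.append(_domtbl_row(g, plen, "LRR_8", "PF13855.1", 61,
                                        strong_e(), *lay["lrr"]))
        elif cls == "bad_order":
            kd_rows.append(_domtbl_row(g, plen, "Pkinase", "PF00069.1", 264,
                                       strong_e(), *lay["kd"]))
            lrr_rows.append(_domtbl_row(g, plen, "LRR_8", "PF13855.1", 61,
                                        strong_e(), *lay["lrr"]))
            tm_a_rows.append(f"{g}\t{lay['tm'][0]}\t{lay['tm'][1]}\n")

    if fp_rate > 0:
        for g in background:
            if g in decoys:
                continue
            if rng.random() < fp_rate:
                plen = genes[g]["protein_length"]
                kd_rows.append(_domtbl_row(
                    g, plen, "Pkinase", "PF00069.1", 264, strong_e(),
                    5, max(6, min(plen - 1, 270))))

    manifest["evidence"] = {
        "rates": {"fn": fn_rate, "fp": fp_rate,
                  "tm_disagree": tm_disagree_rate},
        "dropped_kd": sorted(dropped_kd),
        "expected_identified": sorted(set(family) - set(dropped_kd)),
        "similarity_subset": sorted(sim_subset),
    }
    tm_header = "protein_id\tstart\tend\n"
    return {
        "kd": _DOMTBL_HEADER + "".join(kd_rows) + "#\n",
        "lrr": _DOMTBL_HEADER + "".join(lrr_rows) + "#\n",
        "similarity": "".join(sim_rows),
        "tm_a": tm_header + "".join(tm_a_rows),
        "tm_b": tm_header + "".join(tm_b_rows),
    }


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _random_subtree(rng, leaves: list[str]) -> str:
    if len(leaves) == 1:
        return f"{leaves[0]}:{rng.uniform(0.02, 0.4):.4f}"
    k = int(rng.integers(1, len(leaves)))
    left = _random_subtree(rng, leaves[:k])
    right = _random_subtree(rng, leaves[k:])
    return f"({left},{right}):{rng.uniform(0.02, 0.4):.4f}"


def generate_tree(
    manifest: dict, misplacement_rate: float = 0.0, seed: int = 17
) -> tuple[str, pd.DataFrame]:
    """Newick string with per-subfamily clades plus an anchors table.

    Each subfamily clade holds two reference anchors and the family genes
    planted there; with ``misplacement_rate`` > 0 a leaf may be planted in
    another subfamily's clade (recorded in the manifest as the observed
    clade, alongside its true subfamily).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 2]).generate_state(1)[0])
    genes = manifest["genes"]
    subfamilies = list(manifest["subfamilies"])
    placement: dict[str, str] = {}
    misplaced: list[str] = []
    for g in manifest["family_genes"]:
        true_sf = genes[g]["subfamily"]
        if misplacement_rate > 0 and rng.random() < misplacement_rate:
            others = [s for s in subfamilies if s != true_sf]
            placement[g] = others[int(rng.integers(len(others)))]
            misplaced.append(g)
        else:
            placement[g] = true_sf

    anchors = []
    clades = []
    for sf in subfamilies:
        anchor_ids = [f"REF_{sf}_1", f"REF_{sf}_2"]
        anchors += [(a, sf) for a in anchor_ids]
        members = [g for g in manifest["family_genes"] if placement[g] == sf]
        leaves = anchor_ids + members
        rng.shuffle(leaves)
        clades.append(_random_subtree(rng, leaves))
    tree = clades[0]
    for clade in clades[1:]:
        tree = f"({tree},{clade}):{rng.uniform(0.05, 0.3):.4f}"
    newick = tree[:tree.rfind(":")] + ";\n"
    if not newick.startswith("("):
        newick = f"({tree});\n"
    anchors_df = pd.DataFrame(anchors, columns=["leaf_id", "subfamily"])
    manifest["tree"] = {
        "true_labels": {g: genes[g]["subfamily"]
                        for g in manifest["family_genes"]},
        "observed_clade": placement,
        "misplaced": sorted(misplaced),
        "misplacement_rate": misplacement_rate,
    }
    return newick, anchors_df


# ---------------------------------------------------------------------------
# promoters and expression
# ---------------------------------------------------------------------------

def naive_motif_count(seq: str, motif: str) -> int:
    """Sliding-window IUPAC occurrence count over both strands."""
    def count_one(s: str, m: str) -> int:
        if all(c in "ACGT" for c in m):  # concrete motif: C-speed scan
            c = start = 0
            while True:
                i = s.find(m, start)
                if i < 0:
                    return c
                c += 1
                start = i + 1
        n, k = len(s), len(m)
        c = 0
        for i in range(n - k + 1):
            if all(s[i + j] in IUPAC[m[j]] for j in range(k)):
                c += 1
        return c

    total = count_one(seq, motif)
    rc = reverse_complement(motif)
    if rc != motif:
        total += count_one(seq, rc)
    return total


def _concretize(rng, motif: str) -> str:
    """One concrete ACGT realization of an IUPAC motif."""
    return "".join(IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in motif)


def _plant_window(rng, catalog, elements: dict[str, int], length: int) -> str:
    """A background-clean window with exactly the requested occurrences."""
    by_id = {el.element_id: el for el in catalog}
    for _ in range(120):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if any(naive_motif_count(seq, el.motif) for el in catalog):
            continue
        placements: list[tuple[int, str]] = []
        taken: list[tuple[int, int]] = []
        ok = True
        for eid in sorted(elements):
            motif = by_id[eid].motif
            for _ in range(elements[eid]):
                inst = _concretize(rng, motif)
                if rng.random() < 0.5:
                    inst = reverse_complement(inst)
                placed = False
                for _try in range(60):
                    off = int(rng.integers(0, length - len(inst) + 1))
                    if all(off + len(inst) <= s or off >= e for s, e in taken):
                        taken.append((off, off + len(inst)))
                        placements.append((off, inst))
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        chars = list(seq)
        for off, inst in placements:
            chars[off:off + len(inst)] = inst
        out = "".join(chars)
        if all(naive_motif_count(out, by_id[eid].motif) == cnt
               for eid, cnt in elements.items()) and not any(
                   naive_motif_count(out, el.motif)
                   for el in catalog if el.element_id not in elements):
            return out
    raise RuntimeError("could not plant a clean promoter window")


def generate_promoters_and_expression(
    manifest: dict,
    genome: dict[str, str],
    catalog: list[CisElement],
    seed: int = 17,
    enriched_pair: tuple[str, str] | None = None,
    n_stress_groups: int = 4,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant motif occurrences in family promoters; build FPKM + DE tables.

    Returns (patched genome, development FPKM matrix, stress FPKM matrix,
    DE statistics table).  Promoter windows are re-rolled until they contain
    no background occurrence of any catalog motif, then planted occurrences
    are inserted and verified with a naive sliding-window scan, so manifest
    counts are exact.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 3]).generate_state(1)[0])
    genes = manifest["genes"]
    family = manifest["family_genes"]
    genome = dict(genome)
    length = manifest.get("promoter_length", 1500)

    if enriched_pair is None:
        sf = manifest["subfamilies"][-1]
        cats = sorted({el.category for el in catalog})
        enriched_pair = (sf, cats[0])
    enr_sf, enr_cat = enriched_pair
    enr_elements = [el for el in catalog if el.category == enr_cat]

    planted_counts: dict[str, dict[str, int]] = {}
    for g in family:
        rec = genes[g]
        chrom = rec["chromosome"]
        if rec["strand"] == "+":
            lo, hi = rec["start"] - length, rec["start"] - 1
        else:
            lo, hi = rec["end"] + 1, rec["end"] + length
        if lo < 1 or hi > len(genome[chrom]):
            continue  # contig edge; leave unplanted
        elements: dict[str, int] = {}
        n_el = int(rng.integers(1, 4))
        for idx in rng.choice(len(catalog), size=n_el, replace=False):
            elements[catalog[int(idx)].element_id] = int(rng.integers(1, 3))
        if rec["subfamily"] == enr_sf:
            el = enr_elements[0]
            elements[el.element_id] = max(elements.get(el.element_id, 0), 1)
        elif rng.random() < 0.85:
            for el in enr_elements:
                elements.pop(el.element_id, None)
        planted = _plant_window(rng, catalog, elements, length)
        seq = planted if rec["strand"] == "+" else reverse_complement(planted)
        s = genome[chrom]
        genome[chrom] = s[:lo - 1] + seq + s[hi:]
        planted_counts[g] = elements
    manifest["promoters"] = {
        "planted_counts": planted_counts,
        "enriched_pair": list(enriched_pair),
        "promoter_length": length,
    }

    # development matrix: two well-separated k-means clusters
    samples = ["fiber_5dpa", "fiber_10dpa", "fiber_20dpa", "fiber_25dpa",
               "ovule_1dpa", "ovule_3dpa", "ovule_10dpa", "ovule_20dpa"]
    fam_sorted = sorted(family)
    high = sorted(str(g) for g in rng.choice(fam_sorted, size=min(8, len(fam_sorted)),
                                             replace=False))
    rows, clusters = {}, {}
    for g in fam_sorted:
        mu = 2.2 if g in high else 0.3
        rows[g] = np.maximum(
            10.0 ** rng.normal(mu, 0.12, size=len(samples)) - 1.0, 0.0)
        clusters[g] = 1 if g in high else 2
    dev = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    dev = dev.round(3)
    dev.index.name = "gene_id"

    # stress matrix: n_stress_groups separated levels for the tree cut
    stress_samples = [f"{t}_{h}h" for t in ("cold", "heat", "peg", "salt")
                      for h in (1, 3, 6, 12)]
    level_mu = np.linspace(2.6, 0.2, n_stress_groups)
    stress_rows, stress_clusters = {}, {}
    for i, g in enumerate(fam_sorted):
        grp = i % n_stress_groups
        stress_rows[g] = np.maximum(
            10.0 ** rng.normal(level_mu[grp], 0.08,
                               size=len(stress_samples)) - 1.0, 0.0)
        stress_clusters[g] = grp + 1  # group 1 = highest level
    stress = pd.DataFrame.from_dict(stress_rows, orient="index",
                                    columns=stress_samples).round(3)
    stress.index.name = "gene_id"

    # DE statistics for the two infection contrasts
    contrasts = ["V991", "D07038"]
    de_both = sorted(str(g) for g in rng.choice(fam_sorted, size=min(6, len(fam_sorted)),
                                                replace=False))
    remaining = [g for g in fam_sorted if g not in de_both]
    de_single = sorted(str(g) for g in rng.choice(remaining, size=min(4, len(remaining)),
                                                  replace=False))
    de_rows = []
    for g in fam_sorted:
        for ci, contrast in enumerate(contrasts):
            if g in de_both:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                lfc = sign * float(rng.uniform(1.5, 4.0))
                fdr = float(rng.uniform(1e-6, 0.01))
            elif g in de_single and ci == 0:
                lfc = float(rng.uniform(1.5, 4.0))
                fdr = float(rng.uniform(1e-6, 0.01))
            else:
                lfc = float(rng.uniform(-0.8, 0.8))
                fdr = float(rng.uniform(0.1, 1.0))
            de_rows.append((g, contrast, round(lfc, 3), round(fdr, 5)))
    de = pd.DataFrame(de_rows,
                      columns=["gene_id", "contrast_id", "log2fc", "fdr"])
    manifest["expression"] = {
        "dev_clusters": clusters,
        "stress_clusters": stress_clusters,
        "de_expected_both": list(de_both),
        "de_expected_any": sorted(set(de_both) | set(de_single)),
        "contrasts": contrasts,
    }
    return genome, dev, stress, de


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def generate_bundle(
    outdir: str | os.PathLike,
    config: SimulationConfig | None = None,
    seed: int = 17,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    tm_disagree_rate: float = 0.0,
    misplacement_rate: float = 0.0,
    catalog: list[CisElement] | None = None,
) -> dict:
    """Write a complete fixture directory and return the manifest."""
    from .promoter import default_catalog

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = catalog or default_catalog()

    models, genome, proteins, manifest = generate_genome(config, seed)
    if models:
        evidence = generate_evidence(manifest, fn_rate, fp_rate,
                                     tm_disagree_rate, seed)
        newick, anchors = generate_tree(manifest, misplacement_rate, seed)
        genome, dev, stress, de = generate_promoters_and_expression(
            manifest, genome, catalog, seed)
    else:
        evidence = {"kd": "", "lrr": "", "similarity": "",
                    "tm_a": "protein_id\tstart\tend\n",
                    "tm_b": "protein_id\tstart\tend\n"}
        newick, anchors = "", pd.DataFrame(columns=["leaf_id", "subfamily"])
        dev = stress = pd.DataFrame()
        de = pd.DataFrame(columns=["gene_id", "contrast_id", "log2fc", "fdr"])

    write_gff3(models, outdir / "genes.gff3")
    write_fasta(genome, outdir / "genome.fa")
    write_fasta(proteins, outdir / "proteins.fa")
    (outdir / "kd.domtblout").write_text(evidence["kd"])
    (outdir / "lrr.domtblout").write_text(evidence["lrr"])
    (outdir / "similarity.tsv").write_text(evidence["similarity"])
    (outdir / "tm_a.tsv").write_text(evidence["tm_a"])
    (outdir / "tm_b.tsv").write_text(evidence["tm_b"])
    (outdir / "tree.nwk").write_text(newick)
    anchors.to_csv(outdir / "anchors.tsv", sep="\t", index=False)
    write_matrix(dev, outdir / "fpkm_development.tsv")
    write_matrix(stress, outdir / "fpkm_stress.tsv")
    de.to_csv(outdir / "de_stats.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
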