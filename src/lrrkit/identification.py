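"""LRR-RLK identification from three evidence streams.

An LRR-RLK is called when a protein (i) enters the candidate set either
through the profile-HMM route (a kinase-domain hit *and* an LRR hit, both at
E ≤ 1e-10) or through the similarity route (a hit against reference LRR-RLKs
at E ≤ 1e-5 with identity > 50%), and (ii) carries LRR, transmembrane (TM)
and kinase (KD) segments arranged LRR–TM–KD from N- to C-terminus.  A TM
segment is accepted when either of two independent predictors reports one.

Domain order is tested on span midpoints after merging overlapping spans of
the same class: the rightmost LRR midpoint must precede the leftmost TM
midpoint, which must precede the leftmost KD midpoint.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import DomainHit, PipelineConfig, TMSegment

__all__ = [
    "KD_FAMILIES",
    "LRR_FAMILIES",
    "DomainArchitecture",
    "IdentificationResult",
    "build_candidate_set",
    "call_tm",
    "validate_architecture",
    "identify_lrr_rlks",
    "run_identification",
]

#: Pfam families whose profile hits count as kinase-domain evidence.
KD_FAMILIES = frozenset({"PF00069", "PF07714"})

#: Pfam families whose profile hits count as LRR evidence.
LRR_FAMILIES = frozenset({
    "PF00560", "PF07723", "PF07725", "PF12799", "PF13306",
    "PF13516", "PF13855", "PF14580", "PF01816",
})


@dataclass
class DomainArchitecture:
    protein_id: str
    lrr_spans: list[tuple[int, int]]
    kd_spans: list[tuple[int, int]]
    tm_spans: list[tuple[int, int]]
    ordered_ok: bool = False


@dataclass
class IdentificationResult:
    protein_id: str
    is_lrr_rlk: bool
    candidate_route: str | None  # "hmm_both" | "similarity" | "both" | None
    rejection_reason: str | None  # first failing check, or None


def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting 1-based inclusive intervals."""
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_candidate_set(
    kd_hits: Sequence[DomainHit],
    lrr_hits: Sequence[DomainHit],
    sim_hits: Sequence[DomainHit],
    config: PipelineConfig | None = None,
) -> dict[str, str]:
    """Union of the HMM-both and similarity routes, keyed by protein id.

    Returns protein_id → route ("hmm_both", "similarity" or "both").
    E-value cutoffs are applied as ≤ for float safety; the identity cutoff
    is strictly >.
    """
    config = config or PipelineConfig()
    kd_ok = {h.protein_id for h in kd_hits
             if h.e_value <= config.hmm_evalue_max}
    lrr_ok = {h.protein_id for h in lrr_hits
              if h.e_value <= config.hmm_evalue_max}
    hmm_both = kd_ok & lrr_ok
    similar = {
        h.protein_id for h in sim_hits
        if h.e_value <= config.sim_evalue_max
        and h.identity_pct is not None
        and h.identity_pct > config.sim_identity_min
    }
    routes: dict[str, str] = {}
    for p in hmm_both | similar:
        if p in hmm_both and p in similar:
            routes[p] = "both"
        elif p in hmm_both:
            routes[p] = "hmm_both"
        else:
            routes[p] = "similarity"
    return routes


def call_tm(
    tm_tables: Sequence[Sequence[TMSegment]],
) -> tuple[dict[str, bool], dict[str, list[tuple[int, int]]]]:
    """Either-predictor TM consensus.

    A protein is TM-positive when at least one predictor reports at least one
    segment; the union of all predictors' segments is retained for the
    architecture-order check.
    """
    has_tm: dict[str, bool] = defaultdict(bool)
    segments: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for table in tm_tables:
        for seg in table:
            has_tm[seg.protein_id] = True
            segments[seg.protein_id].append((seg.start, seg.end))
    return dict(has_tm), {p: merge_intervals(v) for p, v in segments.items()}


def _midpoint(span: tuple[int, int]) -> float:
    return (span[0] + span[1]) / 2.0


def validate_architecture(
    protein_id: str,
    lrr_spans: Sequence[tuple[int, int]],
    kd_spans: Sequence[tuple[int, int]],
    tm_spans: Sequence[tuple[int, int]],
) -> DomainArchitecture:
    """Compute the LRR–TM–KD order flag from merged span midpoints.

    The architecture is returned even when invalid so that rejected proteins
    can be reported with their observed layout.
    """
    lrr = merge_intervals(lrr_spans)
    kd = merge_intervals(kd_spans)
    tm = merge_intervals(tm_spans)
    ordered = bool(lrr and kd and tm) and (
        max(_midpoint(s) for s in lrr)
        < min(_midpoint(s) for s in tm)
        < min(_midpoint(s) for s in kd)
    )
    return DomainArchitecture(protein_id, lrr, kd, tm, ordered)


def identify_lrr_rlks(
    candidates: Mapping[str, str],
    architectures: Mapping[str, DomainArchitecture],
    tm_calls: Mapping[str, bool],
    universe: Iterable[str] | None = None,
) -> list[IdentificationResult]:
    """Final LRR-RLK calls with the first failing check as rejection reason.

    Checks run in the order: candidate membership, LRR presence, KD presence,
    TM presence, domain order.  Results cover every protein in ``universe``
    (default: every protein appearing in any input), sorted by protein id.
    """
    if universe is None:
        universe = set(candidates) | set(architectures) | set(tm_calls)
    universe = sorted(universe)
    results = []
    for p in universe:
        route = candidates.get(p)
        arch = architectures.get(p)
        reason = None
        if route is None:
            reason = "not_candidate"
        elif arch is None or not arch.lrr_spans:
            reason = "no_lrr"
        elif not arch.kd_spans:
            reason = "no_kd"
        elif not tm_calls.get(p, False):
            reason = "no_tm"
        elif not arch.ordered_ok:
            reason = "bad_order"
        results.append(IdentificationResult(
            protein_id=p,
            is_lrr_rlk=reason is None,
            candidate_route=route,
            rejection_reason=reason,
        ))
    return results


def run_identification(
    kd_hits: Sequence[DomainHit],
    lrr_hits: Sequence[DomainHit],
    sim_hits: Sequence[DomainHit],
    tm_a: Sequence[TMSegment],
    tm_b: Sequence[TMSegment],
    config: PipelineConfig | None = None,
    confirmed_spans: Mapping[str, Mapping[str, list[tuple[int, int]]]] | None = None,
) -> tuple[list[IdentificationResult], dict[str, DomainArchitecture]]:
    """Wire the full identification stage together.

    Domain spans for the order check come from ``confirmed_spans``
    (protein_id → {"lrr": [...], "kd": [...]}) when provided — the
    post-confirmation table — otherwise from the threshold-passing HMM
    alignment coordinates.
    """
    config = config or PipelineConfig()
    routes = build_candidate_set(kd_hits, lrr_hits, sim_hits, config)
    tm_flags, tm_spans = call_tm([tm_a, tm_b])

    lrr_by_p: dict[str, list[tuple[int, int]]] = defaultdict(list)
    kd_by_p: dict[str, list[tuple[int, int]]] = defaultdict(list)
    if confirmed_spans is not None:
        for p, d in confirmed_spans.items():
            lrr_by_p[p] = list(d.get("lrr", []))
            kd_by_p[p] = list(d.get("kd", []))
    else:
        for h in lrr_hits:
            if h.e_value <= config.hmm_evalue_max:
                lrr_by_p[h.protein_id].append((h.ali_start, h.ali_end))
        for h in kd_hits:
            if h.e_value <= config.hmm_evalue_max:
                kd_by_p[h.protein_id].append((h.ali_start, h.ali_end))

    architectures = {
        p: validate_architecture(
            p, lrr_by_p.get(p, []), kd_by_p.get(p, []), tm_spans.get(p, [])
        )
        for p in set(lrr_by_p) | set(kd_by_p) | set(tm_spans)
    }
    roster = (
        {h.protein_id for h in kd_hits} | {h.protein_id for h in lrr_hits}
        | {h.protein_id for h in sim_hits}
        | {s.protein_id for s in tm_a} | {s.protein_id for s in tm_b}
    )
    results = identify_lrr_rlks(routes, architectures, tm_flags, roster)
    return results, architectures
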