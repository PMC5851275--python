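"""Composite (chimeric) gene calls via the triplet criterion.

A gene C is composite when two other genes A and B each align to a
substantial stretch of C (>= 30 aa), neither alignment explains C
full-length (mutual coverage < 0.8), and the two stretches barely overlap
(<= 20 aa) -- i.e. C looks like a fusion of two distinct components.
Hits from C's own homology family are excluded as evidence: paralogs
explain C in full, not piecewise.

Family-level calls then require strict majorities of members that are
composite and that carry >= 2 annotated domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

from .families import HomologyFamily, Thresholds, mutual_coverage, span_len
from .io_formats import ProteinRecord, SimilarityHit

Span = tuple[int, int]


class IncidentRecord(NamedTuple):
    """One HSP seen from the side of a focal gene (orientation-free)."""

    partner: str
    span: Span          # on the focal gene
    partner_span: Span  # on the partner
    pct_identity: float
    evalue: float
    bitscore: float
    coverage: float     # mutual coverage of the HSP


@dataclass(frozen=True)
class TripletEvidence:
    composite: str
    component_a: str
    component_b: str
    span_a: Span
    span_b: Span
    overlap_aa: int


def overlap_aa(a: Span, b: Span) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def incident_records(
    hits: Iterable[SimilarityHit],
    taxa: Mapping[str, ProteinRecord],
) -> dict[str, list[IncidentRecord]]:
    """Index HSPs by each endpoint.

    All-vs-all BLAST reports both orientations of a pair; the mirrored
    record is collapsed so each HSP is seen once per endpoint.  Works
    equally on tables that carry only one orientation.
    """
    seen: set[tuple] = set()
    out: dict[str, list[IncidentRecord]] = {}
    for h in hits:
        if h.query == h.subject:
            continue
        cov = mutual_coverage(h, taxa[h.query].length, taxa[h.subject].length)
        for focal, partner, span, pspan in (
            (h.query, h.subject, h.qspan, h.sspan),
            (h.subject, h.query, h.sspan, h.qspan),
        ):
            key = (focal, partner, span, pspan, h.evalue, h.bitscore)
            if key in seen:
                continue
            seen.add(key)
            out.setdefault(focal, []).append(
                IncidentRecord(partner, span, pspan, h.pct_identity,
                               h.evalue, h.bitscore, cov)
            )
    for records in out.values():
        records.sort(key=lambda r: (r.span, r.partner, r.partner_span))
    return out


def _candidate_records(
    gene: str,
    records: list[IncidentRecord],
    t: Thresholds,
    family_of: Mapping[str, str] | None,
) -> list[IncidentRecord]:
    """Records usable as component evidence on ``gene``."""
    fam = family_of.get(gene) if family_of is not None else None
    keep = []
    for r in records:
        if r.evalue >= t.evalue_max:
            continue
        if span_len(r.span) < t.triplet_min_span:
            continue
        if r.coverage >= t.mutual_cov_min:
            continue
        if fam is not None and family_of.get(r.partner) == fam:
            continue
        keep.append(r)
    return keep


def detect_triplet_composites(
    hits: Iterable[SimilarityHit],
    taxa: Mapping[str, ProteinRecord],
    t: Thresholds | None = None,
    family_of: Mapping[str, str] | None = None,
) -> dict[str, list[TripletEvidence]]:
    """All triplet evidence, keyed by composite gene.

    A triplet pairs two candidate records from *distinct* partner genes
    whose spans on the focal gene overlap by at most
    ``triplet_max_overlap`` aa.  (A, B) and (B, A) are the same evidence
    and are reported once, sorted by (composite, leftmost span start).
    """
    t = t or Thresholds()
    incident = incident_records(hits, taxa)
    out: dict[str, list[TripletEvidence]] = {}
    for gene in sorted(incident):
        cands = _candidate_records(gene, incident[gene], t, family_of)
        evidence: dict[tuple, TripletEvidence] = {}
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                a, b = cands[i], cands[j]
                if a.partner == b.partner:
                    continue
                ov = overlap_aa(a.span, b.span)
                if ov > t.triplet_max_overlap:
                    continue
                # canonical orientation: leftmost span first
                if (a.span, a.partner) > (b.span, b.partner):
                    a, b = b, a
                key = (a.partner, a.span, b.partner, b.span)
                if key not in evidence:
                    evidence[key] = TripletEvidence(
                        composite=gene, component_a=a.partner,
                        component_b=b.partner, span_a=a.span, span_b=b.span,
                        overlap_aa=ov,
                    )
        if evidence:
            out[gene] = sorted(
                evidence.values(),
                key=lambda e: (min(e.span_a[0], e.span_b[0]), e.span_a, e.span_b),
            )
    return out


def annotate_multidomain(
    domains: Mapping[str, list[tuple[str, Span]]]
) -> dict[str, bool]:
    """True iff a gene carries >= 2 annotated domain spans (any source)."""
    return {gene: len(spans) >= 2 for gene, spans in domains.items()}


@dataclass(frozen=True)
class CompositeFamilyCall:
    family_id: str
    fraction_composite: float
    fraction_multidomain: float
    is_composite_family: bool


def call_composite_families(
    families: Iterable[HomologyFamily],
    composite_flags: Mapping[str, object],
    multidomain_flags: Mapping[str, bool],
    t: Thresholds | None = None,
) -> list[CompositeFamilyCall]:
    """Family is composite iff both member fractions exceed the strict majority."""
    t = t or Thresholds()
    calls = []
    for fam in families:
        n = len(fam.members)
        fc = sum(1 for m in fam.members if composite_flags.get(m)) / n
        fm = sum(1 for m in fam.members if multidomain_flags.get(m, False)) / n
        calls.append(CompositeFamilyCall(
            family_id=fam.id,
            fraction_composite=fc,
            fraction_multidomain=fm,
            is_composite_family=(fc > t.majority and fm > t.majority),
        ))
    calls.sort(key=lambda c: c.family_id)
    return calls
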