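"""Decomposition of S-genes into components and origin assignment.

Every partial, non-family alignment onto an S-gene marks a *component
instance* (an interval plus the sequences supporting it).  Instances on one
composite are grouped by reciprocal 70% overlap into component families,
nested/overlapping families are merged to a fixpoint, and each family gets
an origin from the taxonomy of its ten best prokaryotic supporters:

* top 10 all bacterial -> BAC; all archaeal -> ARC;
* fewer than 10 prokaryotic supporters, or a mixed top 10 -> PROK;
* no prokaryotic supporter at all -> EUK.

Per homology family, the origin profile is the fraction of member genes
carrying at least one component of each origin; a deterministic rule (or,
for exploration, hierarchical clustering) turns profiles into the familiar
BAC-BAC / ARC-EUK / PROK-EUK ... labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import median_low
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .composites import IncidentRecord, Span, incident_records, overlap_aa
from .families import Thresholds, span_len
from .io_formats import ARCHAEA, BACTERIA, EUKARYOTE, ProteinRecord

ARC = "ARC"
BAC = "BAC"
PROK = "PROK"
EUK = "EUK"
ORIGINS = (EUK, ARC, BAC, PROK)

#: Small / low-complexity domains whose archaeal or bacterial signal is
#: treated as merely prokaryotic under the conservative reassignment.
SMALL_DOMAIN_LIST = (
    "LRR_4", "WD40", "LRR_RI", "ANK", "Kelch_1", "Kelch_2", "Kelch_3",
    "Kelch_4", "Kelch_5", "Kelch_6", "TPR", "TPR_1", "TPR_2", "PPR", "UBQ",
    "MORN", "FNI", "Ube1_repeat1", "Ubiquitin", "TF_Zn_Ribbon",
    "Zn-ribbon_TFIIS", "UBL", "RCC1", "Ube1_repeat2", "EFh", "Kelch", "FNIP",
    "TPR_10", "TPR_17", "Zpr1", "zf-ZPR1", "UBA_EF-Ts", "Ubox", "S1",
    "ZnF_C3H1", "DnaJ", "RING", "UBA_PLICs",
)


class Supporter(NamedTuple):
    subject: str
    domain_of_life: str
    bitscore: float
    evalue: float


@dataclass
class ComponentInstance:
    composite: str
    span: Span
    supporters: list[Supporter]  # sorted by descending bitscore


@dataclass
class ComponentFamily:
    id: str
    composite: str
    representative: Span
    members: list[ComponentInstance]
    origin: str | None = None

    @property
    def supporters(self) -> list[Supporter]:
        """Pooled supporters, one per subject (best bitscore), ranked."""
        best: dict[str, Supporter] = {}
        for inst in self.members:
            for s in inst.supporters:
                prev = best.get(s.subject)
                if prev is None or (s.bitscore, -s.evalue) > (prev.bitscore,
                                                              -prev.evalue):
                    best[s.subject] = s
        return sorted(best.values(),
                      key=lambda s: (-s.bitscore, s.evalue, s.subject))


def extract_component_instances(
    gene: str,
    hits_or_index,
    taxa: Mapping[str, ProteinRecord],
    t: Thresholds | None = None,
    family_of: Mapping[str, str] | None = None,
) -> list[ComponentInstance]:
    """Component instances on one composite gene.

    ``hits_or_index`` is either an iterable of SimilarityHit or a
    pre-built index from :func:`sgenes.composites.incident_records` (pass
    the index when processing many genes).  Qualifying records (E-value <
    cutoff, span >= 30 aa, mutual coverage < 0.8, partner outside the
    gene's own family) are grouped by identical span on the composite; one
    instance per span carries every supporting subject.
    """
    t = t or Thresholds()
    if isinstance(hits_or_index, dict):
        records: list[IncidentRecord] = hits_or_index.get(gene, [])
    else:
        records = incident_records(hits_or_index, taxa).get(gene, [])
    fam = family_of.get(gene) if family_of is not None else None
    by_span: dict[Span, dict[str, Supporter]] = {}
    for r in records:
        if r.evalue >= t.evalue_max:
            continue
        if span_len(r.span) < t.triplet_min_span:
            continue
        if r.coverage >= t.mutual_cov_min:
            continue
        if fam is not None and family_of.get(r.partner) == fam:
            continue
        sup = Supporter(r.partner, taxa[r.partner].domain_of_life,
                        r.bitscore, r.evalue)
        bucket = by_span.setdefault(r.span, {})
        prev = bucket.get(sup.subject)
        if prev is None or (sup.bitscore, -sup.evalue) > (prev.bitscore,
                                                          -prev.evalue):
            bucket[sup.subject] = sup
    out = []
    for span in sorted(by_span):
        sups = sorted(by_span[span].values(),
                      key=lambda s: (-s.bitscore, s.evalue, s.subject))
        out.append(ComponentInstance(gene, span, sups))
    return out


def _reciprocal_overlap(a: Span, b: Span, frac: float) -> bool:
    ov = overlap_aa(a, b)
    return ov > frac * span_len(a) and ov > frac * span_len(b)


def _representative(members: Sequence[ComponentInstance]) -> Span:
    # low median keeps coordinates integral and deterministic
    return (median_low(sorted(m.span[0] for m in members)),
            median_low(sorted(m.span[1] for m in members)))


def cluster_component_instances(
    instances: Sequence[ComponentInstance],
    t: Thresholds | None = None,
) -> list[ComponentFamily]:
    """Single-linkage grouping of instances on one composite.

    Two instances link when their spans overlap by more than 70% of *both*
    lengths.  Family ids are assigned by leftmost representative start.
    """
    t = t or Thresholds()
    if not instances:
        return []
    composite = instances[0].composite
    n = len(instances)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _reciprocal_overlap(instances[i].span, instances[j].span,
                                   t.component_overlap):
                parent[find(i)] = find(j)
    groups: dict[int, list[ComponentInstance]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(instances[i])
    fams = [
        ComponentFamily(id="", composite=composite,
                        representative=_representative(members),
                        members=sorted(members, key=lambda m: m.span))
        for members in groups.values()
    ]
    fams.sort(key=lambda f: f.representative)
    for k, fam in enumerate(fams, start=1):
        fam.id = f"{composite}:c{k}"
    return fams


def merge_component_families(
    families: Sequence[ComponentFamily],
    t: Thresholds | None = None,
) -> list[ComponentFamily]:
    """Merge overlapping/nested component families to a fixpoint.

    A pair merges when the representative of one is included by more than
    70% of the *smaller* representative's length in the other.  Pairs are
    examined in a deterministic order (descending member count, then
    leftmost start); representatives are recomputed after every merge.
    """
    t = t or Thresholds()
    fams = [replace(f, members=list(f.members)) for f in families]
    changed = True
    while changed:
        changed = False
        fams.sort(key=lambda f: (-len(f.members), f.representative, f.id))
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                a, b = fams[i], fams[j]
                small = min(span_len(a.representative),
                            span_len(b.representative))
                ov = overlap_aa(a.representative, b.representative)
                if ov > t.merge_inclusion * small:
                    a.members = sorted(a.members + b.members,
                                       key=lambda m: m.span)
                    a.representative = _representative(a.members)
                    del fams[j]
                    changed = True
                    break
            if changed:
                break
    fams.sort(key=lambda f: f.representative)
    composite = fams[0].composite if fams else ""
    for k, fam in enumerate(fams, start=1):
        fam.id = f"{composite}:c{k}"
    return fams


def assign_component_origin(
    component: ComponentFamily,
    t: Thresholds | None = None,
) -> str:
    """Origin from the top-10 prokaryotic supporters (see module docstring)."""
    t = t or Thresholds()
    prok = [s for s in component.supporters
            if s.domain_of_life in (ARCHAEA, BACTERIA)]
    if not prok:
        return EUK
    if len(prok) < t.top_k_hits:
        return PROK
    top = {s.domain_of_life for s in prok[: t.top_k_hits]}
    if top == {BACTERIA}:
        return BAC
    if top == {ARCHAEA}:
        return ARC
    return PROK


def assign_origins(
    components: Iterable[ComponentFamily],
    t: Thresholds | None = None,
) -> list[ComponentFamily]:
    out = []
    for cf in components:
        cf.origin = assign_component_origin(cf, t)
        out.append(cf)
    return out


def conservative_reassign(
    components: Iterable[ComponentFamily],
    domains: Mapping[str, list[tuple[str, Span]]],
    small_domain_list: Sequence[str] = SMALL_DOMAIN_LIST,
) -> list[ComponentFamily]:
    """Downgrade ARC/BAC calls on small, low-complexity domains to PROK.

    A component whose span overlaps an annotated domain from the list is
    too generic for a confident archaeal-vs-bacterial call.  EUK and PROK
    labels are left untouched, so the count of genes carrying eukaryotic
    components is invariant under this step.
    """
    watch = set(small_domain_list)
    out = []
    for cf in components:
        new_origin = cf.origin
        if cf.origin in (ARC, BAC):
            annotated = domains.get(cf.composite, [])
            if any(name in watch and overlap_aa(cf.representative, span) > 0
                   for name, span in annotated):
                new_origin = PROK
        out.append(replace(cf, origin=new_origin))
    return out


@dataclass
class OriginProfile:
    family_id: str
    ratios: dict[str, float] = field(default_factory=dict)
    label: str | None = None


def family_origin_profile(
    family_id: str,
    members: Iterable[str],
    components_by_gene: Mapping[str, Sequence[ComponentFamily]],
) -> OriginProfile:
    """Fraction of member genes with >= 1 component of each origin."""
    members = sorted(members)
    counts = {o: 0 for o in ORIGINS}
    for gene in members:
        origins = {cf.origin for cf in components_by_gene.get(gene, ())}
        for o in ORIGINS:
            if o in origins:
                counts[o] += 1
    n = len(members)
    return OriginProfile(
        family_id=family_id,
        ratios={o: counts[o] / n for o in ORIGINS},
    )


_PRECEDENCE = (ARC, PROK, BAC, EUK)


def _rule_label(ratios: Mapping[str, float], majority: float) -> str:
    above = [o for o in _PRECEDENCE if ratios.get(o, 0.0) > majority]
    if len(above) == 1:
        return f"{above[0]}-{above[0]}"
    if len(above) == 2:
        return f"{above[0]}-{above[1]}"
    return "OTHER"


def label_origin_profiles(
    profiles: Sequence[OriginProfile],
    method: str = "rule",
    n_clusters: int | None = None,
    t: Thresholds | None = None,
) -> list[OriginProfile]:
    """Attach cluster labels to origin profiles.

    ``rule`` (the deterministic default): the origins whose ratio exceeds
    the strict majority name the label (ARC before PROK before BAC before
    EUK; a single origin doubles as X-X; none or three-plus -> OTHER).
    ``hierarchical``: average-linkage Euclidean clustering of the 4-ratio
    vectors cut at ``n_clusters``, each cluster named by the rule applied
    to its mean profile.
    """
    t = t or Thresholds()
    if method == "rule":
        return [replace(p, label=_rule_label(p.ratios, t.majority))
                for p in profiles]
    if method != "hierarchical":
        raise ValueError(f"unknown labelling method {method!r}")
    if n_clusters is None or n_clusters < 1:
        raise ValueError("hierarchical labelling needs n_clusters >= 1")
    if n_clusters > len(profiles):
        raise ValueError(
            f"requested {n_clusters} clusters for {len(profiles)} profiles"
        )
    from scipy.cluster.hierarchy import fcluster, linkage

    x = np.array([[p.ratios[o] for o in ORIGINS] for p in profiles])
    if len(profiles) == 1:
        assign = np.array([1])
    else:
        z = linkage(x, method="average", metric="euclidean")
        assign = fcluster(z, t=n_clusters, criterion="maxclust")
    out = []
    for cluster_id in range(1, int(assign.max()) + 1):
        mask = assign == cluster_id
        mean = x[mask].mean(axis=0)
        name = _rule_label(dict(zip(ORIGINS, mean)), t.majority)
        for idx in np.nonzero(mask)[0]:
            out.append((idx, replace(profiles[idx],
                                     label=f"{name}:{cluster_id}")))
    out.sort(key=lambda pair: pair[0])
    return [p for _, p in out]
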