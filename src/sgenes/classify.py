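"""Classification of composite eukaryotic families by prokaryotic homology.

Composite, eukaryote-only families fall into three mutually exclusive
classes:

* ``PROK_FULL`` -- some member aligns full-length (mutual coverage >= 0.8)
  with a prokaryotic sequence: the fusion predates its acquisition, so the
  family is not a within-eukaryote chimera;
* ``EUK_INNOVATION`` -- no member shows any prokaryotic similarity below
  the E-value cutoff;
* ``S_GENE`` -- members show *partial* prokaryotic similarity only: a
  chimera assembled inside the eukaryotic lineage from at least one
  prokaryotic fragment.

A profile (HMM) search against a larger prokaryotic dataset can then
rescue or remove candidates: full-length profile matches demote S-genes to
``PROK_FULL``; partial matches promote apparent innovations to ``S_GENE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .families import HomologyFamily, Thresholds, mutual_coverage
from .io_formats import ProteinRecord, SimilarityHit, ValidationError

PROK_FULL = "PROK_FULL"
EUK_INNOVATION = "EUK_INNOVATION"
S_GENE = "S_GENE"
CLASS_LABELS = (PROK_FULL, EUK_INNOVATION, S_GENE)


@dataclass
class FamilyClassLabel:
    family_id: str
    label: str
    evidence: list[SimilarityHit] = field(default_factory=list)


@dataclass(frozen=True)
class ProfileHit:
    """One pre-filtered hmmsearch match of a family profile on a prokaryote."""

    family_id: str
    target: str
    evalue: float
    mutual_cov: float
    qspan: tuple[int, int] | None = None
    sspan: tuple[int, int] | None = None

    def __post_init__(self):
        if not (self.evalue < 1e-5):
            raise ValidationError(
                f"profile hit {self.family_id}/{self.target}: table must be "
                "pre-filtered at E-value < 1e-5"
            )


def prokaryotic_hits_by_gene(
    hits: Iterable[SimilarityHit],
    taxa: Mapping[str, ProteinRecord],
) -> dict[str, list[SimilarityHit]]:
    """Index hits with a prokaryotic partner by their eukaryotic endpoint."""
    out: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        q, s = taxa[h.query], taxa[h.subject]
        if q.is_eukaryote and s.is_prokaryote:
            out.setdefault(h.query, []).append(h)
        elif s.is_eukaryote and q.is_prokaryote:
            out.setdefault(h.subject, []).append(h)
    return out


def classify_family(
    family: HomologyFamily,
    prok_hits: Mapping[str, Sequence[SimilarityHit]],
    taxa: Mapping[str, ProteinRecord],
    t: Thresholds | None = None,
) -> FamilyClassLabel:
    """Assign one of the three class labels to a composite family.

    ``prok_hits`` maps member gene -> its hits against prokaryotic
    sequences (see :func:`prokaryotic_hits_by_gene`); the subject lengths
    must be resolvable through ``taxa``.
    """
    t = t or Thresholds()
    if not family.members:
        raise ValueError(f"family {family.id} has no members")
    full: list[SimilarityHit] = []
    partial: list[SimilarityHit] = []
    for member in sorted(family.members):
        for h in prok_hits.get(member, ()):  # may be empty
            if not (h.evalue < t.evalue_max):
                continue
            cov = mutual_coverage(h, taxa[h.query].length, taxa[h.subject].length)
            (full if cov >= t.mutual_cov_min else partial).append(h)
    if full:
        return FamilyClassLabel(family.id, PROK_FULL, evidence=full)
    if not partial:
        return FamilyClassLabel(family.id, EUK_INNOVATION)
    return FamilyClassLabel(family.id, S_GENE, evidence=partial)


@dataclass(frozen=True)
class Reclassification:
    family_id: str
    old_label: str
    new_label: str
    profile_hit: ProfileHit


def apply_profile_filter(
    labels: Sequence[FamilyClassLabel],
    profile_hits: Iterable[ProfileHit],
    t: Thresholds | None = None,
) -> tuple[list[FamilyClassLabel], list[Reclassification]]:
    """Apply the HMM-profile rescue/removal stage.

    * S_GENE with a full-length profile match (coverage >= 0.8) -> PROK_FULL.
    * EUK_INNOVATION with a full-length profile match -> PROK_FULL.
    * EUK_INNOVATION with only partial profile matches -> S_GENE.

    Idempotent for a fixed profile table.  Every change is logged.
    """
    t = t or Thresholds()
    by_family: dict[str, list[ProfileHit]] = {}
    known = {lab.family_id for lab in labels}
    for ph in profile_hits:
        if ph.family_id not in known:
            raise ValidationError(
                f"profile hit references unknown family {ph.family_id!r}"
            )
        by_family.setdefault(ph.family_id, []).append(ph)
    updated: list[FamilyClassLabel] = []
    log: list[Reclassification] = []
    for lab in labels:
        phits = sorted(by_family.get(lab.family_id, []),
                       key=lambda p: (-p.mutual_cov, p.evalue, p.target))
        new = lab.label
        trigger: ProfileHit | None = None
        full = [p for p in phits if p.mutual_cov >= t.mutual_cov_min]
        if lab.label == S_GENE and full:
            new, trigger = PROK_FULL, full[0]
        elif lab.label == EUK_INNOVATION and phits:
            if full:
                new, trigger = PROK_FULL, full[0]
            else:
                new, trigger = S_GENE, phits[0]
        if new != lab.label:
            log.append(Reclassification(lab.family_id, lab.label, new, trigger))
            updated.append(FamilyClassLabel(lab.family_id, new, lab.evidence))
        else:
            updated.append(lab)
    return updated, log


def apply_exclusions(
    labels: Sequence[FamilyClassLabel],
    excluded_ids: Iterable[str],
) -> tuple[list[FamilyClassLabel], list[str]]:
    """Drop curated exclusions (e.g. suspected eukaryote->prokaryote HGT).

    Exclusions are expert judgements supplied as a plain id list, never
    re-derived.  Returns surviving labels and the ids actually removed.
    """
    excluded = set(excluded_ids)
    kept = [lab for lab in labels if lab.family_id not in excluded]
    removed = sorted(lab.family_id for lab in labels
                     if lab.family_id in excluded)
    return kept, removed


def parse_profile_hits(path) -> list[ProfileHit]:
    """Columns: family, target, evalue, mutual_cov [, qstart qend sstart send]."""
    from .io_formats import _data_lines

    out = []
    for lineno, fields in _data_lines(path):
        if fields[0] in ("family", "family_id"):
            continue
        qspan = sspan = None
        if len(fields) >= 8:
            qspan = (int(fields[4]), int(fields[5]))
            sspan = (int(fields[6]), int(fields[7]))
        out.append(ProfileHit(
            family_id=fields[0], target=fields[1], evalue=float(fields[2]),
            mutual_cov=float(fields[3]), qspan=qspan, sspan=sspan,
        ))
    return out
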