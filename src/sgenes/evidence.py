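"""Independent evidence for gene fusion: operons, introns, targeting.

* Operon-like composites: two components of one composite supported by two
  *different* genes that sit in the same operon of the same prokaryotic
  genome -- the fused eukaryotic gene mirrors a pre-existing prokaryotic
  co-transcription unit.
* Conserved introns: an intron at the same alignment column in at least
  one Opimoda and one Diphoda member predates their split; an intron
  within 20 aa of a component border is consistent with intron-mediated
  fusion, one deep inside a component is not.
* Targeting: a family counts as organelle/secretory-targeted when a strict
  majority of members are predicted MITO, CHLORO or SIGNAL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .components import ComponentFamily
from .families import Thresholds
from .io_formats import DIPHODA, OPIMODA, ProteinRecord, ValidationError

BETWEEN_COMPONENTS = "BETWEEN_COMPONENTS"
WITHIN_COMPONENT = "WITHIN_COMPONENT"


@dataclass(frozen=True)
class OperonEvidence:
    family_id: str
    composite: str
    component_pair: tuple[str, str]
    gene_pair: tuple[str, str]
    genome: str
    operon: str


def detect_operon_like(
    components_by_gene: Mapping[str, Sequence[ComponentFamily]],
    operon_table: Iterable[tuple[str, str, str]],
    family_of: Mapping[str, str],
) -> list[OperonEvidence]:
    """All (composite, component pair, prokaryotic gene pair) evidence.

    Evidence is symmetric in the component pair and deduplicated; a family
    is operon-like iff it appears in at least one record.  Composites with
    a single component family can never qualify.
    """
    operons_of: dict[str, set[tuple[str, str]]] = {}
    for genome, operon, gene in operon_table:
        operons_of.setdefault(gene, set()).add((genome, operon))
    evidence: set[OperonEvidence] = set()
    for composite in sorted(components_by_gene):
        comps = components_by_gene[composite]
        if len(comps) < 2:
            continue
        fam = family_of.get(composite, "")
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                a, b = comps[i], comps[j]
                for sa in a.supporters:
                    sa_ops = operons_of.get(sa.subject)
                    if not sa_ops:
                        continue
                    for sb in b.supporters:
                        if sb.subject == sa.subject:
                            continue
                        sb_ops = operons_of.get(sb.subject)
                        if not sb_ops:
                            continue
                        for genome, operon in sorted(sa_ops & sb_ops):
                            if a.id <= b.id:
                                pair = (a.id, b.id)
                                genes = (sa.subject, sb.subject)
                            else:
                                pair = (b.id, a.id)
                                genes = (sb.subject, sa.subject)
                            evidence.add(OperonEvidence(
                                family_id=fam, composite=composite,
                                component_pair=pair, gene_pair=genes,
                                genome=genome, operon=operon,
                            ))
    return sorted(evidence, key=lambda e: (e.family_id, e.composite,
                                           e.component_pair, e.gene_pair,
                                           e.genome, e.operon))


def operon_like_families(evidence: Iterable[OperonEvidence]) -> set[str]:
    return {e.family_id for e in evidence}


def map_introns_to_alignment(
    msa: Mapping[str, str],
    introns: Mapping[str, Sequence[int]],
) -> dict[str, list[int]]:
    """Map ungapped intron positions to 1-based alignment columns.

    An intron after residue ``k`` maps to the column of residue ``k + 1``;
    an intron after the final residue maps to the sentinel column
    ``n_columns + 1``.  Positions beyond the sequence are errors, as is a
    gene absent from the alignment.
    """
    out: dict[str, list[int]] = {}
    for gene in introns:
        if gene not in msa:
            raise ValidationError(f"gene {gene!r} absent from the alignment")
        aligned = msa[gene]
        n_cols = len(aligned)
        # column of each ungapped residue
        residue_col: list[int] = [i + 1 for i, ch in enumerate(aligned)
                                  if ch != "-"]
        ungapped_len = len(residue_col)
        cols = []
        for pos in introns[gene]:
            if pos > ungapped_len:
                raise ValidationError(
                    f"{gene}: intron position {pos} beyond ungapped length "
                    f"{ungapped_len}"
                )
            cols.append(residue_col[pos] if pos < ungapped_len else n_cols + 1)
        out[gene] = cols
    return out


@dataclass(frozen=True)
class IntronCall:
    family_id: str
    column: int
    opimoda_gene: str
    diphoda_gene: str
    placement: str


def _near_border(pos: int, borders: Sequence[int], window: int) -> bool:
    return any(abs(pos - b) <= window for b in borders)


def component_borders(components: Sequence[ComponentFamily]) -> list[int]:
    """Start and end coordinates of each (merged) component span."""
    borders: set[int] = set()
    for cf in components:
        borders.update(cf.representative)
    return sorted(borders)


def conserved_introns(
    family_id: str,
    msa: Mapping[str, str],
    introns: Mapping[str, Sequence[int]],
    borders_by_gene: Mapping[str, Sequence[int]],
    taxa: Mapping[str, ProteinRecord],
    t: Thresholds | None = None,
    column_tolerance: int = 0,
) -> list[IntronCall]:
    """Shared-column intron pairs across the Opimoda/Diphoda divide.

    A call is emitted for every (Opimoda gene, Diphoda gene) pair with
    introns at the same alignment column (within ``column_tolerance``,
    default exact).  Placement is BETWEEN_COMPONENTS only when *both*
    introns fall within ``border_window`` aa of a component border in
    their own sequence coordinates; otherwise WITHIN_COMPONENT.
    """
    t = t or Thresholds()
    member_introns = {g: list(p) for g, p in introns.items() if g in msa}
    columns = map_introns_to_alignment(msa, member_introns)
    species_mg = {rec.species: rec.megagroup for rec in taxa.values()
                  if rec.is_eukaryote}

    def megagroup(gene: str) -> str | None:
        rec = taxa.get(gene)
        return species_mg.get(rec.species) if rec else None

    entries = []  # (gene, megagroup, column, ungapped position)
    for gene in sorted(member_introns):
        mg = megagroup(gene)
        if mg is None:
            continue
        for pos, col in zip(member_introns[gene], columns[gene]):
            entries.append((gene, mg, col, pos))
    calls: set[IntronCall] = set()
    for g_op, mg_op, col_op, pos_op in entries:
        if mg_op != OPIMODA:
            continue
        for g_di, mg_di, col_di, pos_di in entries:
            if mg_di != DIPHODA:
                continue
            if abs(col_op - col_di) > column_tolerance:
                continue
            both_near = (
                _near_border(pos_op, borders_by_gene.get(g_op, ()),
                             t.border_window)
                and _near_border(pos_di, borders_by_gene.get(g_di, ()),
                                 t.border_window)
            )
            calls.add(IntronCall(
                family_id=family_id,
                column=min(col_op, col_di),
                opimoda_gene=g_op,
                diphoda_gene=g_di,
                placement=BETWEEN_COMPONENTS if both_near else WITHIN_COMPONENT,
            ))
    return sorted(calls, key=lambda c: (c.column, c.opimoda_gene,
                                        c.diphoda_gene))


def family_targeting(
    targeting: Mapping[str, str],
    members: Iterable[str],
) -> tuple[bool, dict[str, float]]:
    """(family-is-targeted, per-location member fractions).

    Targeted iff the fraction of members predicted MITO, CHLORO or SIGNAL
    strictly exceeds one half; members without a prediction count against.
    """
    members = sorted(members)
    n = len(members)
    fractions = {loc: 0.0 for loc in ("MITO", "CHLORO", "SIGNAL", "OTHER")}
    n_targeted = 0
    for gene in members:
        loc = targeting.get(gene)
        if loc is None:
            continue
        fractions[loc] += 1.0 / n
        if loc in ("MITO", "CHLORO", "SIGNAL"):
            n_targeted += 1
    return n_targeted / n > 0.5, fractions
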