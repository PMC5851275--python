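"""Homology families from the all-vs-all similarity table.

Two sequences are joined when some hit between them clears three criteria
at once: E-value strictly below 1e-5, percent identity of at least 30, and
mutual coverage (the aligned span divided by sequence length, minimised
over the two partners) of at least 0.8.  Connected components of the
resulting undirected graph are the gene families; sequences with no
qualifying edge stand alone as singleton families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .io_formats import SimilarityHit, ProteinRecord


@dataclass(frozen=True)
class Thresholds:
    """Every tunable cutoff of the pipeline, with the published defaults.

    Comparisons marked strict in the docs really are strict (``<`` for the
    E-value, ``>`` for majorities and component overlaps); the others are
    inclusive.
    """

    evalue_max: float = 1e-5          # strict <
    identity_min: float = 30.0        # percent, inclusive >=
    mutual_cov_min: float = 0.8       # inclusive >=
    min_euk_species: int = 3
    majority: float = 0.5             # strict >
    triplet_min_span: int = 30        # aa
    triplet_max_overlap: int = 20     # aa
    component_overlap: float = 0.70   # strict >
    merge_inclusion: float = 0.70     # strict >
    top_k_hits: int = 10
    support_min: float = 85.0         # percent bootstrap
    border_window: int = 20           # aa around component borders
    n_resample: int = 100

    def __post_init__(self):
        for name in ("mutual_cov_min", "majority", "component_overlap",
                     "merge_inclusion"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("min_euk_species", "triplet_min_span", "triplet_max_overlap",
                     "top_k_hits", "border_window", "n_resample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class HomologyFamily:
    """A connected component of the homology graph, with taxonomy rollups."""

    id: str
    members: frozenset[str]
    species: frozenset[str]
    n_euk_species: int
    all_eukaryotic: bool

    def __len__(self) -> int:
        return len(self.members)


def span_len(span: tuple[int, int]) -> int:
    return span[1] - span[0] + 1


def mutual_coverage(hit: SimilarityHit, qlen: int, slen: int) -> float:
    """min(query-span / query length, subject-span / subject length)."""
    if qlen <= 0 or slen <= 0:
        raise ValueError("sequence lengths must be positive")
    return min(span_len(hit.qspan) / qlen, span_len(hit.sspan) / slen)


def hit_qualifies(hit: SimilarityHit, taxa: Mapping[str, ProteinRecord],
                  t: Thresholds) -> bool:
    """Does this HSP satisfy the family-edge criteria?"""
    if hit.query == hit.subject:
        return False
    if not (hit.evalue < t.evalue_max):
        return False
    if hit.pct_identity < t.identity_min:
        return False
    cov = mutual_coverage(hit, taxa[hit.query].length, taxa[hit.subject].length)
    return cov >= t.mutual_cov_min


def build_family_graph(hits: Iterable[SimilarityHit],
                       taxa: Mapping[str, ProteinRecord],
                       t: Thresholds | None = None) -> nx.Graph:
    """Undirected graph over every sequence in ``taxa``.

    An edge (A, B) is present iff at least one HSP between A and B (in
    either orientation) satisfies all three criteria on its own; HSPs are
    never chained, and multiple qualifying HSPs still give a single edge.
    Self-hits are ignored.
    """
    t = t or Thresholds()
    g = nx.Graph()
    g.add_nodes_from(taxa.keys())
    for hit in hits:
        if hit.query not in taxa or hit.subject not in taxa:
            raise KeyError(
                f"hit {hit.query}/{hit.subject} references an id absent from "
                "the taxon table"
            )
        if hit_qualifies(hit, taxa, t):
            g.add_edge(hit.query, hit.subject)
    return g


def extract_families(graph: nx.Graph,
                     taxa: Mapping[str, ProteinRecord]) -> list[HomologyFamily]:
    """One family per connected component, singletons included.

    The family id is the lexicographically smallest member id; the returned
    list is sorted by id, so output is deterministic.
    """
    fams = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        fam_id = min(members)
        species = frozenset(taxa[m].species for m in members)
        euk_species = {taxa[m].species for m in members if taxa[m].is_eukaryote}
        fams.append(HomologyFamily(
            id=fam_id,
            members=members,
            species=species,
            n_euk_species=len(euk_species),
            all_eukaryotic=all(taxa[m].is_eukaryote for m in members),
        ))
    fams.sort(key=lambda f: f.id)
    return fams


def select_candidate_families(families: Iterable[HomologyFamily],
                              taxa: Mapping[str, ProteinRecord],
                              t: Thresholds | None = None) -> list[HomologyFamily]:
    """Eukaryote-only families spanning at least ``min_euk_species`` species."""
    t = t or Thresholds()
    return [f for f in families
            if f.all_eukaryotic and f.n_euk_species >= t.min_euk_species]


def family_of_map(families: Iterable[HomologyFamily]) -> dict[str, str]:
    out: dict[str, str] = {}
    for fam in families:
        for m in fam.members:
            out[m] = fam.id
    return out
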