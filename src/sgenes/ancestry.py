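"""Presence/absence, Dollo parsimony and gene-tree vertical-descent checks.

Under Dollo parsimony a gene family is gained exactly once and afterwards
only lost.  With the gain fixed at the MRCA of the present leaves, the
minimal reconstruction places one loss on the root edge of every maximal
all-absent subtree below the gain; placing the gain any higher only adds
losses (a property the test suite verifies against brute force rather than
assuming).

Age classes follow the deepest split of the eukaryote tree: a family seen
on both sides of the Opimoda/Diphoda divide is EARLY, one confined to a
single supergroup is LINEAGE_SPECIFIC, anything in between INTERMEDIATE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .families import HomologyFamily, Thresholds
from .io_formats import DIPHODA, OPIMODA, ProteinRecord, ValidationError
from .tree import SpeciesTree, TreeNode

EARLY = "EARLY"
INTERMEDIATE = "INTERMEDIATE"
LINEAGE_SPECIFIC = "LINEAGE_SPECIFIC"

OLD = "OLD"
LIKELY_OLD = "LIKELY_OLD"
INCONCLUSIVE = "INCONCLUSIVE"


def build_presence_matrix(
    families: Iterable[HomologyFamily],
    taxa: Mapping[str, ProteinRecord],
    tree: SpeciesTree,
) -> pd.DataFrame:
    """Boolean families x species table over the tree's leaves."""
    leaves = sorted(tree.leaf_labels())
    fams = sorted(families, key=lambda f: f.id)
    rows = []
    for fam in fams:
        missing = fam.species - set(leaves)
        if missing:
            raise ValidationError(
                f"family {fam.id}: species {sorted(missing)} not in the tree"
            )
        rows.append([sp in fam.species for sp in leaves])
    return pd.DataFrame(rows, index=[f.id for f in fams], columns=leaves,
                        dtype=bool)


@dataclass
class DolloResult:
    family_id: str
    gain_node: str
    loss_edges: frozenset[str]  # each edge named by its child node label
    n_losses: int


def dollo_reconstruct(
    tree: SpeciesTree,
    presence: Mapping[str, bool],
    family_id: str = "",
) -> DolloResult:
    """Single-gain, minimal-loss reconstruction of one presence row.

    The gain sits at the MRCA of the present leaves; a loss is charged on
    the edge above every maximal subtree (below the gain) whose leaves are
    all absent.  Children of a polytomy are treated as simultaneous.
    """
    present = {sp for sp, flag in presence.items() if flag}
    if not present:
        raise ValueError(f"family {family_id or '?'}: all-absent presence row")
    gain = tree.mrca(present)
    losses: list[str] = []

    def walk(node: TreeNode) -> None:
        for child in node.children:
            if tree.leaf_labels(child.label) & present:
                walk(child)
            else:
                losses.append(child.label)

    walk(gain)
    return DolloResult(family_id=family_id, gain_node=gain.label,
                       loss_edges=frozenset(losses), n_losses=len(losses))


def dollo_all(tree: SpeciesTree, presence: pd.DataFrame) -> list[DolloResult]:
    return [dollo_reconstruct(tree, presence.loc[fam].to_dict(), fam)
            for fam in presence.index]


def age_class(
    presence: Mapping[str, bool],
    taxa_or_tree,
) -> str:
    """EARLY / INTERMEDIATE / LINEAGE_SPECIFIC from the present species.

    ``taxa_or_tree`` is either a decorated SpeciesTree or a taxon table;
    both can resolve a species to its supergroup and megagroup.
    """
    if isinstance(taxa_or_tree, SpeciesTree):
        sg_of = taxa_or_tree.supergroup_of
        mg_of = taxa_or_tree.megagroup_of
    else:
        sg_of, mg_of = {}, {}
        for rec in taxa_or_tree.values():
            if rec.is_eukaryote:
                sg_of[rec.species] = rec.supergroup
                mg_of[rec.species] = rec.megagroup
    present = [sp for sp, flag in presence.items() if flag]
    if not present:
        raise ValueError("age_class of an all-absent row")
    megagroups = {mg_of[sp] for sp in present}
    supergroups = {sg_of[sp] for sp in present}
    if OPIMODA in megagroups and DIPHODA in megagroups:
        return EARLY
    if len(supergroups) == 1:
        return LINEAGE_SPECIFIC
    return INTERMEDIATE


@dataclass
class GeneTreeVerdict:
    family_id: str
    verdict: str
    offending_partitions: list[frozenset[str]] = field(default_factory=list)


def _bipartitions(tree: SpeciesTree, support_min: float):
    """Resolved bipartitions as (smaller side, larger side) leaf-label sets."""
    all_leaves = tree.leaf_labels()
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        if node.support is None or node.support < support_min:
            continue
        side = tree.leaf_labels(node.label)
        other = all_leaves - side
        if not other:
            continue
        if len(side) <= len(other):
            yield side, frozenset(other)
        else:
            yield frozenset(other), side


def _mixes(side_a: frozenset[str], side_b: frozenset[str],
           group_of: Mapping[str, str]) -> bool:
    """True iff some group straddles the split and neither side is pure."""
    groups_a = {group_of[l] for l in side_a}
    groups_b = {group_of[l] for l in side_b}
    straddling = groups_a & groups_b
    if not straddling:
        return False
    return len(groups_a) > 1 and len(groups_b) > 1


def assess_gene_tree(
    gene_tree: SpeciesTree,
    supergroup_of: Mapping[str, str],
    megagroup_of: Mapping[str, str],
    t: Thresholds | None = None,
    family_id: str = "",
) -> GeneTreeVerdict:
    """Test whether a gene tree is compatible with vertical descent.

    Only bipartitions with bootstrap support >= ``support_min`` count as
    resolved; absent support means unresolved.  A resolved bipartition
    *mixes* supergroups when some supergroup has leaves on both sides and
    neither side is pure for a single supergroup.  Verdicts:

    * OLD -- no resolved bipartition mixes supergroups;
    * LIKELY_OLD -- mixtures exist but none joins Opimoda and Diphoda
      sequences on its smaller side (compatible with within-megagroup
      transfer or endosymbiotic exchange);
    * INCONCLUSIVE -- otherwise (deep transfer cannot be ruled out).
    """
    t = t or Thresholds()
    for leaf in gene_tree.leaves():
        if leaf.label not in supergroup_of or leaf.label not in megagroup_of:
            raise ValidationError(f"gene-tree leaf {leaf.label!r} unmapped")
    offending: list[frozenset[str]] = []
    deep_mix = False
    for small, large in _bipartitions(gene_tree, t.support_min):
        if _mixes(small, large, supergroup_of):
            offending.append(small)
            mgs = {megagroup_of[l] for l in small}
            if OPIMODA in mgs and DIPHODA in mgs:
                deep_mix = True
    if not offending:
        verdict = OLD
    elif not deep_mix:
        verdict = LIKELY_OLD
    else:
        verdict = INCONCLUSIVE
    offending.sort(key=lambda s: sorted(s))
    return GeneTreeVerdict(family_id=family_id, verdict=verdict,
                           offending_partitions=offending)
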