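"""A light rooted-tree structure for species trees and gene trees.

Newick parsing is delegated to dendropy; the wrapper adds the things the
pipeline needs everywhere: stable node labels (unlabelled internal nodes get
deterministic preorder names ``N1, N2, ...``), MRCA queries by leaf label,
and leaf decoration with supergroup/megagroup from the taxon table.
Polytomies are allowed and flagged.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Mapping

import dendropy

from .io_formats import DIPHODA, OPIMODA, ProteinRecord, ValidationError

log = logging.getLogger(__name__)


class TreeNode:
    __slots__ = ("label", "parent", "children", "support")

    def __init__(self, label: str, support: float | None = None):
        self.label = label
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label})"


class SpeciesTree:
    """Rooted tree with labelled nodes and species metadata on leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._by_label: dict[str, TreeNode] = {}
        self._leafset: dict[str, frozenset[str]] = {}
        self.has_polytomy = False
        self.supergroup_of: dict[str, str] = {}
        self.megagroup_of: dict[str, str] = {}
        self._index()

    # -- construction -----------------------------------------------------
    def _index(self) -> None:
        self._by_label.clear()
        self._leafset.clear()
        self.has_polytomy = False
        counter = 0
        for node in self.preorder():
            if not node.label:
                counter += 1
                node.label = f"N{counter}"
            if node.label in self._by_label:
                raise ValidationError(f"duplicate node label {node.label!r}")
            self._by_label[node.label] = node
            if len(node.children) > 2:
                self.has_polytomy = True
        for node in self.postorder():
            if node.is_leaf:
                self._leafset[node.label] = frozenset({node.label})
            else:
                self._leafset[node.label] = frozenset().union(
                    *(self._leafset[c.label] for c in node.children)
                )

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        root = _convert(dtree.seed_node)
        return cls(root)

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def decorate(self, taxa: Mapping[str, ProteinRecord]) -> None:
        """Attach supergroup/megagroup to leaves from a taxon table.

        Every leaf label must appear as a *species* of >= 1 eukaryotic
        record.  Logs a warning when the root does not separate Opimoda
        from Diphoda.
        """
        by_species: dict[str, ProteinRecord] = {}
        for rec in taxa.values():
            if rec.is_eukaryote:
                by_species.setdefault(rec.species, rec)
        for leaf in self.leaves():
            rec = by_species.get(leaf.label)
            if rec is None:
                raise ValidationError(
                    f"tree leaf {leaf.label!r} absent from the taxon table"
                )
            self.supergroup_of[leaf.label] = rec.supergroup  # type: ignore[assignment]
            self.megagroup_of[leaf.label] = rec.megagroup  # type: ignore[assignment]
        if len(self.root.children) >= 2:
            sides = [
                {self.megagroup_of[l] for l in self.leaf_labels(c.label)}
                for c in self.root.children
            ]
            clean = (
                len(self.root.children) == 2
                and sides[0] in ({OPIMODA}, {DIPHODA})
                and sides[1] in ({OPIMODA}, {DIPHODA})
                and sides[0] != sides[1]
            )
            if not clean:
                log.warning("species-tree root does not split Opimoda from Diphoda")
        if len(self.root.children) > 2:
            log.warning("species tree has a multifurcating (unrooted-style) root")

    # -- queries ----------------------------------------------------------
    def node(self, label: str) -> TreeNode:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self, label: str | None = None) -> frozenset[str]:
        node = self.root if label is None else self._by_label[label]
        return self._leafset[node.label]

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def mrca(self, leaf_labels: Iterable[str]) -> TreeNode:
        wanted = set(leaf_labels)
        if not wanted:
            raise ValueError("mrca of an empty leaf set")
        missing = wanted - self._leafset[self.root.label]
        if missing:
            raise ValidationError(f"leaves not in tree: {sorted(missing)}")
        node = self.root
        while True:
            containing = [
                c for c in node.children if wanted <= self._leafset[c.label]
            ]
            if len(containing) == 1:
                node = containing[0]
            else:
                return node

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.label}"

        return render(self.root) + ";"


def _convert(dnode) -> TreeNode:
    if dnode.taxon is not None:
        label = dnode.taxon.label
    else:
        label = dnode.label or ""
    support = None
    if dnode.child_nodes() and label:
        try:
            support = float(label)
        except ValueError:
            support = None
        else:
            # numeric internal labels are bootstrap supports, not names
            label = ""
    node = TreeNode(label, support=support)
    for child in dnode.child_nodes():
        node.add(_convert(child))
    return node


def parse_species_tree(path, taxa: Mapping[str, ProteinRecord]) -> SpeciesTree:
    """Read a rooted Newick species tree and decorate leaves from ``taxa``."""
    tree = SpeciesTree.from_file(path)
    tree.decorate(taxa)
    return tree


def parse_gene_tree(path) -> SpeciesTree:
    """Read a gene tree whose internal labels are bootstrap supports.

    Numeric internal labels become ``node.support`` and the nodes get
    generated ``N<k>`` labels so they can be referenced deterministically.
    """
    return SpeciesTree.from_file(path)
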