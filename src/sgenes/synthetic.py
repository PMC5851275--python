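"""Synthetic datasets with planted chimeric genes.

The generator emulates, at toy scale, the structure the pipeline is built
to dissect: prokaryotic genomes carry single-domain genes (some arranged
in operons); eukaryotic genomes carry

* *S-genes* -- composites concatenating 2-4 domain fragments of archaeal,
  bacterial and eukaryotic provenance, with no full-length prokaryotic
  homolog anywhere;
* *full-length transfers* -- composites whose exact fusion also exists as
  a prokaryotic gene, but only in an "extended" prokaryote set that is
  searched for classification and never enters the clustering dataset
  (mirroring the two-dataset design of large-scale surveys);
* *eukaryotic innovations* -- composites built solely from domains absent
  from prokaryotes;
* single-domain *donor* families providing the eukaryotic component
  signal.

Sequences evolve along the species tree by uniform random substitution at
a per-branch probability; there are no indels, so every planted span stays
exact and ground truth is unambiguous at interval resolution.  Similarity
hits are synthesised from the planted homology relations with closed-form
scores (bitscore = round(1.8 * L * identity), evalue = 10^(-bitscore/5),
capped at 1) -- artifact conventions for reproducibility, not claims about
any aligner.  Spurious noise hits always carry E-values >= 1e-3, so they
can never satisfy the family-edge criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    ARCHAEA,
    BACTERIA,
    DIPHODA,
    EUKARYOTE,
    OPIMODA,
    ProteinRecord,
    SimilarityHit,
    write_fasta,
    write_hit_table,
    write_taxon_table,
    write_tsv,
)
from .tree import SpeciesTree, TreeNode

AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

S_GENE = "S_GENE"
PROK_FULL = "PROK_FULL"
EUK_INNOVATION = "EUK_INNOVATION"
NON_COMPOSITE = "NON_COMPOSITE"

_OPIMODA_NAMES = ("Opisthokonta", "Amoebozoa", "Apusomonadida", "Breviatea")
_DIPHODA_NAMES = ("SAR", "Archaeplastida", "Discoba", "Metamonada")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset (defaults = the planted
    recovery experiment: 12 eukaryotes in 4 supergroups, 20 prokaryotic
    genomes, 30 S-genes, 10 transfers, 10 innovations, 5 operon fusions,
    5 conserved-intron families, divergence 0.1)."""

    seed: int = 42
    n_supergroups: int = 4
    species_per_supergroup: int = 3
    n_bacteria: int = 10
    n_archaea: int = 10
    domain_library_size: int = 120
    domain_length_range: tuple[int, int] = (60, 120)
    n_sgenes: int = 30
    n_full_transfers: int = 10
    n_innovations: int = 10
    n_operon_fusions: int = 5
    n_intron_families: int = 5
    n_euk_donor_domains: int = 12
    n_extended_genomes: int = 3
    divergence: float = 0.1
    hit_noise: float = 0.0

    def __post_init__(self):
        if self.n_supergroups < 2 or self.species_per_supergroup < 1:
            raise ValueError("need >= 2 supergroups with >= 1 species each")
        if min(self.n_bacteria, self.n_archaea) < 1:
            raise ValueError("need at least one genome per prokaryotic domain")
        if self.n_operon_fusions > self.n_sgenes:
            raise ValueError("n_operon_fusions cannot exceed n_sgenes")
        if self.n_intron_families > self.n_sgenes:
            raise ValueError("n_intron_families cannot exceed n_sgenes")
        if not (0.0 <= self.divergence < 0.5):
            raise ValueError("divergence must be in [0, 0.5) (saturation bound)")
        if not (0.0 <= self.hit_noise <= 1.0):
            raise ValueError("hit_noise must be a fraction in [0, 1]")
        lo, hi = self.domain_length_range
        if lo < 30 or hi < lo:
            raise ValueError("domain lengths must be >= 30 aa and ordered")
        if min(self.n_sgenes, self.n_full_transfers, self.n_innovations,
               self.n_operon_fusions) < 0:
            raise ValueError("family counts must be non-negative")


@dataclass
class SyntheticTruth:
    family_of: dict[str, str] = field(default_factory=dict)
    composite_genes: set[str] = field(default_factory=set)
    class_of_family: dict[str, str] = field(default_factory=dict)
    component_layout: dict[str, list[tuple[tuple[int, int], str]]] = field(
        default_factory=dict)
    gain_node: dict[str, str] = field(default_factory=dict)
    operon_derived: set[str] = field(default_factory=set)
    conserved_intron_families: set[str] = field(default_factory=set)


@dataclass
class GeneInfo:
    id: str
    species: str
    domain_of_life: str
    family: str
    seq: np.ndarray
    copies: list[tuple[str, tuple[int, int]]]  # (library domain, span)
    in_base: bool = True


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    tree: SpeciesTree
    genes: dict[str, GeneInfo]
    domain_side: dict[str, str]  # library domain -> BACTERIA/ARCHAEA/EUKARYOTE
    truth: SyntheticTruth

    def taxa(self, base_only: bool = True) -> dict[str, ProteinRecord]:
        out = {}
        for gid in sorted(self.genes):
            g = self.genes[gid]
            if base_only and not g.in_base:
                continue
            sg = mg = None
            if g.domain_of_life == EUKARYOTE:
                sg = g.species.rsplit("_sp", 1)[0]
                mg = OPIMODA if sg in _species_side(self.config)[0] else DIPHODA
            out[gid] = ProteinRecord(
                id=gid, species=g.species, domain_of_life=g.domain_of_life,
                length=len(g.seq), supergroup=sg, megagroup=mg,
            )
        return out

    def extended_taxa(self) -> dict[str, ProteinRecord]:
        out = {}
        for gid in sorted(self.genes):
            g = self.genes[gid]
            if g.in_base:
                continue
            out[gid] = ProteinRecord(
                id=gid, species=g.species, domain_of_life=g.domain_of_life,
                length=len(g.seq),
            )
        return out


# ---------------------------------------------------------------------------
# species tree


def _species_side(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    n_op = (config.n_supergroups + 1) // 2
    n_di = config.n_supergroups - n_op
    opi = [(_OPIMODA_NAMES[i] if i < len(_OPIMODA_NAMES) else f"OpiSG{i + 1}")
           for i in range(n_op)]
    dip = [(_DIPHODA_NAMES[i] if i < len(_DIPHODA_NAMES) else f"DipSG{i + 1}")
           for i in range(n_di)]
    return opi, dip


def _ladder(nodes: list[TreeNode], labels: list[str]) -> TreeNode:
    """Right-leaning ladder over ``nodes``; internal labels consumed in order."""
    if len(nodes) == 1:
        return nodes[0]
    top = TreeNode(labels.pop(0))
    top.add(nodes[0])
    top.add(_ladder(nodes[1:], labels))
    return top


def build_species_tree(config: SyntheticConfig) -> tuple[SpeciesTree,
                                                         dict[str, list[str]]]:
    opi, dip = _species_side(config)
    species_of: dict[str, list[str]] = {}

    def supergroup_clade(sg: str) -> TreeNode:
        species = [f"{sg}_sp{j + 1}" for j in range(config.species_per_supergroup)]
        species_of[sg] = species
        leaves = [TreeNode(sp) for sp in species]
        labels = [sg] + [f"{sg}_n{j + 2}" for j in range(len(leaves))]
        return _ladder(leaves, labels) if len(leaves) > 1 else leaves[0]

    def side_clade(name: str, sgs: list[str]) -> TreeNode:
        clades = [supergroup_clade(sg) for sg in sgs]
        if len(clades) == 1:
            return clades[0]
        labels = [name] + [f"{name}_n{j + 1}" for j in range(len(clades))]
        return _ladder(clades, labels)

    root = TreeNode("root")
    root.add(side_clade("Opimoda", opi))
    root.add(side_clade("Diphoda", dip))
    return SpeciesTree(root), species_of


# ---------------------------------------------------------------------------
# sequence evolution


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return AA[rng.integers(0, 20, size=length)]


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform substitution at per-site probability p (no indels)."""
    mask = rng.random(seq.size) < p
    out = seq.copy()
    k = int(mask.sum())
    if k:
        idx = np.searchsorted(AA, out[mask])
        out[mask] = AA[(idx + rng.integers(1, 20, size=k)) % 20]
    return out


def _evolve_family(tree: SpeciesTree, gain: str, present: set[str],
                   ancestor: np.ndarray, p: float,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Sequences at the present leaves, evolved edge-by-edge from the gain."""
    out: dict[str, np.ndarray] = {}
    node = tree.node(gain)

    def rec(n: TreeNode, seq: np.ndarray) -> None:
        if n.is_leaf:
            if n.label in present:
                out[n.label] = seq
            return
        for child in n.children:
            if tree.leaf_labels(child.label) & present:
                rec(child, _mutate(seq, p, rng))

    if node.is_leaf:
        out[node.label] = ancestor
    else:
        rec(node, ancestor)
    return out


# ---------------------------------------------------------------------------
# generation


def _draw_layout(rng: np.random.Generator, force_bac_pair: bool) -> list[str]:
    """Fragment origins for one S-gene: 2-4 fragments, >= 1 prokaryotic."""
    k = int(rng.integers(2, 5))
    if force_bac_pair:
        k = max(k, 2)
    while True:
        origins = [str(rng.choice(["BAC", "ARC", "EUK"], p=[0.45, 0.2, 0.35]))
                   for _ in range(k)]
        if force_bac_pair:
            origins[0] = origins[1] = "BAC"
        if any(o in ("BAC", "ARC") for o in origins):
            return origins


def _pick_gain(tree: SpeciesTree, pattern_item: str, sg_cycle: list[str],
               side_cycle: list[str], min_leaves: int) -> str:
    if pattern_item == "root":
        return tree.root.label
    if pattern_item == "side":
        label = side_cycle.pop(0)
        side_cycle.append(label)
        if label in tree and len(tree.leaf_labels(label)) >= min_leaves:
            return label
        return tree.root.label
    label = sg_cycle.pop(0)
    sg_cycle.append(label)
    if label in tree and len(tree.leaf_labels(label)) >= min_leaves:
        return label
    return tree.root.label


def _plant_loss(tree: SpeciesTree, gain: str, present: set[str],
                rng: np.random.Generator, min_present: int = 3) -> set[str]:
    """Drop one leaf if the gain node stays the MRCA and >= min_present remain."""
    if len(present) <= min_present:
        return present
    gain_node = tree.node(gain)
    candidates = []
    for leaf in sorted(present):
        remaining = present - {leaf}
        ok = sum(1 for c in gain_node.children
                 if tree.leaf_labels(c.label) & remaining) >= 2
        if ok:
            candidates.append(leaf)
    if not candidates:
        return present
    lost = candidates[int(rng.integers(0, len(candidates)))]
    return present - {lost}


def simulate_dataset(
    config: SyntheticConfig,
    outdir: str | Path | None = None,
) -> tuple[SyntheticDataset, SyntheticTruth]:
    """Generate the dataset (and write it under ``outdir`` when given).

    Deterministic for a fixed config: running twice produces byte-identical
    files.  Inconsistent configs fail before anything is written.
    """
    rng = np.random.default_rng(config.seed)
    tree, species_of = build_species_tree(config)
    opi_sgs, dip_sgs = _species_side(config)
    all_species = [sp for sg in opi_sgs + dip_sgs for sp in species_of[sg]]
    bacteria = [f"Bact{j + 1:02d}" for j in range(config.n_bacteria)]
    archaea = [f"Arch{j + 1:02d}" for j in range(config.n_archaea)]
    xgenomes = [f"XBac{j + 1:02d}" for j in range(config.n_extended_genomes)]

    # --- layouts -----------------------------------------------------------
    sg_ids = [f"sg{i + 1:03d}" for i in range(config.n_sgenes)]
    tr_ids = [f"tr{i + 1:03d}" for i in range(config.n_full_transfers)]
    in_ids = [f"in{i + 1:03d}" for i in range(config.n_innovations)]
    sg_layouts = [_draw_layout(rng, i < config.n_operon_fusions)
                  for i in range(config.n_sgenes)]
    tr_layouts = [[str(rng.choice(["BAC", "ARC"])), str(rng.choice(["BAC", "ARC"]))]
                  for _ in range(config.n_full_transfers)]
    in_layouts = [["EUK"] * int(rng.integers(2, 4))
                  for _ in range(config.n_innovations)]

    prok_needed = (sum(sum(1 for o in lay if o != "EUK") for lay in sg_layouts)
                   + 2 * config.n_full_transfers)
    if prok_needed + config.n_euk_donor_domains > config.domain_library_size:
        raise ValueError(
            f"domain_library_size {config.domain_library_size} too small: need "
            f"{prok_needed} prokaryotic + {config.n_euk_donor_domains} "
            "eukaryotic domains"
        )

    # --- domain library ----------------------------------------------------
    lo, hi = config.domain_length_range
    lib_len = {f"d{i + 1:03d}": int(rng.integers(lo, hi + 1))
               for i in range(config.domain_library_size)}
    lib_seq = {d: _random_seq(n, rng) for d, n in lib_len.items()}
    domain_names = sorted(lib_len)
    euk_pool = domain_names[-config.n_euk_donor_domains:]
    prok_free = iter(domain_names[:-config.n_euk_donor_domains])
    domain_side: dict[str, str] = {d: EUKARYOTE for d in euk_pool}

    def assign_domains(origins: list[str]) -> list[str]:
        out = []
        for o in origins:
            if o == "EUK":
                out.append(str(rng.choice(euk_pool)))
            else:
                d = next(prok_free)
                domain_side[d] = BACTERIA if o == "BAC" else ARCHAEA
                out.append(d)
        return out

    sg_domains = [assign_domains(lay) for lay in sg_layouts]
    tr_domains = [assign_domains(lay) for lay in tr_layouts]
    in_domains = [assign_domains(lay) for lay in in_layouts]

    # --- gains and presence ------------------------------------------------
    truth = SyntheticTruth()
    genes: dict[str, GeneInfo] = {}
    sg_cycle = list(opi_sgs + dip_sgs)
    side_cycle = [c.label for c in tree.root.children if not c.is_leaf]
    pattern = ["root", "sg", "root", "side", "root", "sg"]

    def spans_of(domains: list[str]) -> list[tuple[int, int]]:
        spans, pos = [], 1
        for d in domains:
            spans.append((pos, pos + lib_len[d] - 1))
            pos += lib_len[d]
        return spans

    def plant_family(fam: str, domains: list[str], origins: list[str] | None,
                     gain: str, allow_loss: bool, klass: str) -> None:
        present = set(tree.leaf_labels(gain))
        if allow_loss:
            present = _plant_loss(tree, gain, present, rng)
        ancestor = np.concatenate([lib_seq[d] for d in domains])
        leaf_seqs = _evolve_family(tree, gain, present, ancestor,
                                   config.divergence, rng)
        spans = spans_of(domains)
        truth.gain_node[fam] = gain
        truth.class_of_family[fam] = klass
        for sp in sorted(leaf_seqs):
            gid = f"{fam}_{sp}"
            genes[gid] = GeneInfo(
                id=gid, species=sp, domain_of_life=EUKARYOTE, family=fam,
                seq=leaf_seqs[sp], copies=list(zip(domains, spans)),
            )
            truth.family_of[gid] = fam
            if klass != NON_COMPOSITE:
                truth.composite_genes.add(gid)
                if origins is not None:
                    truth.component_layout[gid] = list(zip(spans, origins))

    # donor families: one per eukaryotic library domain, present everywhere
    for d in euk_pool:
        plant_family(f"eu_{d}", [d], None, tree.root.label,
                     allow_loss=False, klass=NON_COMPOSITE)

    for i, fam in enumerate(sg_ids):
        if i < config.n_intron_families:
            gain = tree.root.label
        else:
            gain = _pick_gain(tree, pattern[i % len(pattern)], sg_cycle,
                              side_cycle, min_leaves=3)
        plant_family(fam, sg_domains[i], sg_layouts[i], gain,
                     allow_loss=(gain == tree.root.label and i % 3 == 2),
                     klass=S_GENE)
        truth.class_of_family[fam] = S_GENE
    for i, fam in enumerate(tr_ids):
        gain = _pick_gain(tree, ["root", "side", "sg"][i % 3], sg_cycle,
                          side_cycle, min_leaves=3)
        plant_family(fam, tr_domains[i], tr_layouts[i], gain,
                     allow_loss=False, klass=PROK_FULL)
    for i, fam in enumerate(in_ids):
        gain = _pick_gain(tree, ["sg", "root", "side"][i % 3], sg_cycle,
                          side_cycle, min_leaves=3)
        plant_family(fam, in_domains[i], in_layouts[i], gain,
                     allow_loss=False, klass=EUK_INNOVATION)

    # --- prokaryotic genes (one copy per genome of the matching side) ------
    for d in sorted(domain_side):
        side = domain_side[d]
        if side == EUKARYOTE:
            continue
        fam = f"pk_{d}"
        truth.class_of_family[fam] = NON_COMPOSITE
        for genome in bacteria if side == BACTERIA else archaea:
            gid = f"{d}_{genome}"
            genes[gid] = GeneInfo(
                id=gid, species=genome, domain_of_life=side, family=fam,
                seq=_mutate(lib_seq[d], config.divergence, rng),
                copies=[(d, (1, lib_len[d]))],
            )
            truth.family_of[gid] = fam

    # --- extended prokaryote set: the fused full-length homologs -----------
    for i, fam in enumerate(tr_ids):
        fx = f"fx{i + 1:03d}"
        truth.class_of_family[fx] = NON_COMPOSITE
        domains = tr_domains[i]
        ancestor = np.concatenate([lib_seq[d] for d in domains])
        for genome in xgenomes:
            gid = f"{fx}_{genome}"
            genes[gid] = GeneInfo(
                id=gid, species=genome, domain_of_life=BACTERIA, family=fx,
                seq=_mutate(ancestor, config.divergence, rng),
                copies=list(zip(domains, spans_of(domains))), in_base=False,
            )
            truth.family_of[gid] = fx

    # --- operons -----------------------------------------------------------
    operons: list[tuple[str, str, str]] = []
    for i in range(config.n_operon_fusions):
        fam = sg_ids[i]
        bac_domains = [d for d, o in zip(sg_domains[i], sg_layouts[i])
                       if o == "BAC"][:2]
        genome = bacteria[i % len(bacteria)]
        op = f"op{i + 1:03d}"
        for d in bac_domains:
            operons.append((genome, op, f"{d}_{genome}"))
        truth.operon_derived.add(fam)
    # negative controls: unrelated gene pairs sharing an operon
    bg_sources = [(i, d) for i in range(config.n_operon_fusions,
                                        config.n_sgenes)
                  for d, o in zip(sg_domains[i], sg_layouts[i]) if o == "BAC"]
    for j in range(min(3, max(0, len(bg_sources) - 1))):
        (i1, d1), (i2, d2) = bg_sources[j], bg_sources[j + 1]
        if i1 == i2:
            continue
        genome = bacteria[0]
        operons.append((genome, f"bg{j + 1:02d}", f"{d1}_{genome}"))
        operons.append((genome, f"bg{j + 1:02d}", f"{d2}_{genome}"))

    # --- introns -----------------------------------------------------------
    introns: dict[str, list[int]] = {}

    def family_members(fam: str) -> list[str]:
        return sorted(g for g, f in truth.family_of.items() if f == fam)

    for i in range(config.n_intron_families):
        fam = sg_ids[i]
        border = spans_of(sg_domains[i])[0][1]  # junction after fragment 1
        pos = border + int(rng.integers(-10, 11))
        for gid in family_members(fam):
            introns.setdefault(gid, []).append(pos)
        truth.conserved_intron_families.add(fam)
    # negatives: shared introns deep inside a component
    for i in range(config.n_intron_families,
                   min(config.n_intron_families + 3, config.n_sgenes)):
        fam = sg_ids[i]
        spans = spans_of(sg_domains[i])
        frag = max(spans, key=lambda s: s[1] - s[0])
        pos = (frag[0] + frag[1]) // 2
        borders = sorted({b for s in spans for b in s})
        if min(abs(pos - b) for b in borders) <= 21:
            continue
        for gid in family_members(fam):
            introns.setdefault(gid, []).append(pos)
    # negative: an intron private to a single member
    idx = config.n_intron_families + 3
    if idx < config.n_sgenes:
        members = family_members(sg_ids[idx])
        if members:
            spans = spans_of(sg_domains[idx])
            introns.setdefault(members[0], []).append(
                (spans[0][0] + spans[0][1]) // 2)

    # --- targeting ---------------------------------------------------------
    targeting: dict[str, str] = {}
    mito_fams = {sg_ids[i] for i in range(config.n_sgenes) if i % 7 == 3}
    # some background (donor) families are targeted too, so family-level
    # enrichment tests have a non-degenerate comparison pool
    mito_fams |= {f"eu_{d}" for i, d in enumerate(euk_pool) if i % 4 == 1}
    for gid in sorted(genes):
        g = genes[gid]
        if g.domain_of_life != EUKARYOTE:
            continue
        targeting[gid] = "MITO" if g.family in mito_fams else "OTHER"

    dataset = SyntheticDataset(config=config, tree=tree, genes=genes,
                               domain_side=domain_side, truth=truth)
    base_hits, ext_hits = synth_hit_table(dataset, config, rng)

    if outdir is not None:
        _write_dataset(dataset, base_hits, ext_hits, operons, introns,
                       targeting, Path(outdir))
    dataset.operons = operons            # type: ignore[attr-defined]
    dataset.introns = introns            # type: ignore[attr-defined]
    dataset.targeting = targeting        # type: ignore[attr-defined]
    dataset.base_hits = base_hits        # type: ignore[attr-defined]
    dataset.extended_hits = ext_hits     # type: ignore[attr-defined]
    return dataset, truth


# ---------------------------------------------------------------------------
# hit synthesis


def _pair_hit(g1: GeneInfo, g2: GeneInfo, s1: tuple[int, int],
              s2: tuple[int, int]) -> list[SimilarityHit]:
    a = g1.seq[s1[0] - 1: s1[1]]
    b = g2.seq[s2[0] - 1: s2[1]]
    length = a.size
    mm = int(np.count_nonzero(a != b))
    ident = 1.0 - mm / length
    bitscore = round(1.8 * length * ident)
    evalue = min(1.0, 10.0 ** (-bitscore / 5.0))
    mk = lambda q, s, qs, ss: SimilarityHit(
        query=q.id, subject=s.id, pct_identity=round(100.0 * ident, 1),
        aln_len=length, mismatch=mm, gapopen=0, qstart=qs[0], qend=qs[1],
        sstart=ss[0], send=ss[1], evalue=evalue, bitscore=float(bitscore),
    )
    return [mk(g1, g2, s1, s2), mk(g2, g1, s2, s1)]


def synth_hit_table(
    dataset: SyntheticDataset,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimilarityHit], list[SimilarityHit]]:
    """Hits implied by the planted homology, plus optional seeded noise.

    Returns (base table, extended table).  The base table is the all-vs-all
    comparison of the clustering dataset: a full-length hit for every pair
    of genes in one planted family, and a per-domain-copy hit for every
    cross-family pair sharing a library domain.  The extended table holds
    eukaryotic queries against the extended prokaryote set (the full-length
    fused homologs of the transferred composites).  Both orientations of
    every pair are emitted, as an all-vs-all search would produce.

    With ``hit_noise`` > 0, that fraction of base-table records is dropped
    (each direction independently) and an equal number of short spurious
    records with E-value >= 1e-3 is added.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genes = dataset.genes
    base: list[SimilarityHit] = []
    ext: list[SimilarityHit] = []

    members: dict[str, list[str]] = {}
    for gid in sorted(genes):
        members.setdefault(genes[gid].family, []).append(gid)

    # full-length hits inside each planted family (clustering signal)
    for fam in sorted(members):
        ids = members[fam]
        if not genes[ids[0]].in_base:
            continue
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                g1, g2 = genes[ids[i]], genes[ids[j]]
                base.extend(_pair_hit(g1, g2, (1, g1.seq.size),
                                      (1, g2.seq.size)))

    # full-length hits between each transferred family and its fused
    # prokaryotic counterpart (classification signal, extended table)
    for fam in sorted(members):
        if not fam.startswith("fx"):
            continue
        tr = "tr" + fam[2:]
        for gid_t in members.get(tr, ()):  # eukaryotic copies
            for gid_x in members[fam]:
                gt, gx = genes[gid_t], genes[gid_x]
                ext.extend(_pair_hit(gt, gx, (1, gt.seq.size),
                                     (1, gx.seq.size)))

    # per-domain-copy hits across families (component / triplet signal)
    copies: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    for gid in sorted(genes):
        g = genes[gid]
        if not g.in_base:
            continue
        for d, span in g.copies:
            copies.setdefault(d, []).append((gid, span))
    for d in sorted(copies):
        entries = copies[d]
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                (id1, s1), (id2, s2) = entries[i], entries[j]
                g1, g2 = genes[id1], genes[id2]
                if g1.family == g2.family or id1 == id2:
                    continue
                base.extend(_pair_hit(g1, g2, s1, s2))

    if config.hit_noise > 0:
        n_drop = int(round(config.hit_noise * len(base)))
        if n_drop:
            drop = set(rng.choice(len(base), size=n_drop, replace=False).tolist())
            base = [h for k, h in enumerate(base) if k not in drop]
            base_ids = sorted({gid for gid in genes if genes[gid].in_base})
            for _ in range(n_drop):
                qi, si = rng.choice(len(base_ids), size=2, replace=False)
                q, s = genes[base_ids[qi]], genes[base_ids[si]]
                length = int(rng.integers(10, 26))
                length = min(length, q.seq.size, s.seq.size)
                qs = int(rng.integers(1, q.seq.size - length + 2))
                ss = int(rng.integers(1, s.seq.size - length + 2))
                evalue = 10.0 ** float(rng.uniform(-3, 0))
                pct = round(float(rng.uniform(20, 90)), 1)
                base.append(SimilarityHit(
                    query=q.id, subject=s.id, pct_identity=pct,
                    aln_len=length,
                    mismatch=int(round(length * (1 - pct / 100))), gapopen=0,
                    qstart=qs, qend=qs + length - 1,
                    sstart=ss, send=ss + length - 1,
                    evalue=evalue,
                    bitscore=float(round(-5 * math.log10(evalue))),
                ))

    key = lambda h: (h.query, h.subject, h.qstart, h.qend, h.sstart, h.send,
                     h.evalue)
    return sorted(base, key=key), sorted(ext, key=key)


# ---------------------------------------------------------------------------
# writing


def _write_dataset(dataset: SyntheticDataset, base_hits, ext_hits, operons,
                   introns, targeting, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    genes = dataset.genes
    truth = dataset.truth

    base_seqs = {gid: genes[gid].seq.tobytes().decode()
                 for gid in sorted(genes) if genes[gid].in_base}
    ext_seqs = {gid: genes[gid].seq.tobytes().decode()
                for gid in sorted(genes) if not genes[gid].in_base}
    write_fasta(base_seqs, outdir / "proteins.fasta")
    write_fasta(ext_seqs, outdir / "proteins_extended.fasta")
    write_taxon_table(dataset.taxa(base_only=True), outdir / "taxa.tsv")
    write_taxon_table(dataset.extended_taxa(), outdir / "taxa_extended.tsv")
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(dataset.tree.to_newick() + "\n")
    write_hit_table(base_hits, outdir / "hits.tsv")
    write_hit_table(ext_hits, outdir / "hits_extended.tsv")
    write_tsv(outdir / "domains.tsv", ["gene", "domain", "start", "end"],
              [(gid, d, s[0], s[1]) for gid in sorted(genes)
               for d, s in genes[gid].copies])
    write_tsv(outdir / "operons.tsv", ["genome", "operon", "gene"], operons)
    write_tsv(outdir / "introns.tsv", ["gene", "position"],
              [(gid, p) for gid in sorted(introns) for p in introns[gid]])
    write_tsv(outdir / "targeting.tsv", ["gene", "location"],
              sorted(targeting.items()))

    write_tsv(outdir / "truth" / "families.tsv", ["gene", "family"],
              sorted(truth.family_of.items()))
    write_tsv(outdir / "truth" / "composites.tsv", ["gene"],
              [(g,) for g in sorted(truth.composite_genes)])
    write_tsv(outdir / "truth" / "classes.tsv", ["family", "class"],
              sorted(truth.class_of_family.items()))
    write_tsv(outdir / "truth" / "layout.tsv",
              ["gene", "start", "end", "origin"],
              [(g, s[0], s[1], o) for g in sorted(truth.component_layout)
               for s, o in truth.component_layout[g]])
    write_tsv(outdir / "truth" / "gains.tsv", ["family", "gain_node"],
              sorted(truth.gain_node.items()))
    write_tsv(outdir / "truth" / "operon_families.tsv", ["family"],
              [(f,) for f in sorted(truth.operon_derived)])
    write_tsv(outdir / "truth" / "intron_families.tsv", ["family"],
              [(f,) for f in sorted(truth.conserved_intron_families)])
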