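"""Independent brute-force oracles and random-instance generators.

Everything here re-derives expected answers by enumeration or closed
form, sharing no code path with the implementations under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from sgenes.families import Thresholds
from sgenes.io_formats import (
    ARCHAEA,
    BACTERIA,
    EUKARYOTE,
    ProteinRecord,
    SimilarityHit,
)
from sgenes.tree import SpeciesTree, TreeNode

# ---------------------------------------------------------------------------
# family clustering


def closure_partition(hits, taxa, t: Thresholds) -> set[frozenset[str]]:
    """Partition of the taxa ids by naive transitive closure of edges."""
    groups = {gid: {gid} for gid in taxa}
    for h in hits:
        if h.query == h.subject:
            continue
        qlen, slen = taxa[h.query].length, taxa[h.subject].length
        cov = min((h.qend - h.qstart + 1) / qlen, (h.send - h.sstart + 1) / slen)
        if h.evalue < t.evalue_max and h.pct_identity >= t.identity_min \
                and cov >= t.mutual_cov_min:
            merged = groups[h.query] | groups[h.subject]
            for gid in merged:
                groups[gid] = merged
    return {frozenset(g) for g in groups.values()}


def random_hit_instance(rng: np.random.Generator, n_hits: int):
    """A random protein set + hit table with a mix of strong/weak hits."""
    n_prot = int(rng.integers(10, 60))
    taxa = {}
    for i in range(n_prot):
        length = int(rng.integers(50, 401))
        taxa[f"p{i:03d}"] = ProteinRecord(
            id=f"p{i:03d}", species=f"sp{i % 7}",
            domain_of_life=BACTERIA, length=length)
    ids = sorted(taxa)
    hits = []
    for _ in range(n_hits):
        q, s = (ids[int(rng.integers(0, n_prot))] for _ in range(2))
        qlen, slen = taxa[q].length, taxa[s].length
        if rng.random() < 0.5:  # strong: high coverage, maybe qualifying
            qa = int(rng.integers(1, max(2, int(qlen * 0.2))))
            sa = int(rng.integers(1, max(2, int(slen * 0.2))))
            qspan, sspan = (qa, qlen), (sa, slen)
        else:
            qa = int(rng.integers(1, qlen + 1))
            sa = int(rng.integers(1, slen + 1))
            qspan = (qa, int(rng.integers(qa, qlen + 1)))
            sspan = (sa, int(rng.integers(sa, slen + 1)))
        evalue = 10.0 ** float(rng.uniform(-20, 0))
        hits.append(SimilarityHit(
            query=q, subject=s,
            pct_identity=round(float(rng.uniform(10, 100)), 1),
            aln_len=qspan[1] - qspan[0] + 1, mismatch=0, gapopen=0,
            qstart=qspan[0], qend=qspan[1], sstart=sspan[0], send=sspan[1],
            evalue=evalue, bitscore=round(float(rng.uniform(20, 500)), 1),
        ))
    return hits, taxa


# ---------------------------------------------------------------------------
# triplet composites


def triplet_flags_bruteforce(hits, taxa, t: Thresholds,
                             family_of=None) -> set[str]:
    """Composite flags by exhaustive enumeration over ordered hit pairs."""
    views = []  # (focal, partner, span, coverage, evalue)
    for h in hits:
        if h.query == h.subject:
            continue
        qlen, slen = taxa[h.query].length, taxa[h.subject].length
        cov = min((h.qend - h.qstart + 1) / qlen, (h.send - h.sstart + 1) / slen)
        views.append((h.query, h.subject, (h.qstart, h.qend), cov, h.evalue))
        views.append((h.subject, h.query, (h.sstart, h.send), cov, h.evalue))
    flagged = set()
    for c1, p1, s1, cov1, e1 in views:
        for c2, p2, s2, cov2, e2 in views:
            if c1 != c2 or p1 == p2:
                continue
            if e1 >= t.evalue_max or e2 >= t.evalue_max:
                continue
            if (s1[1] - s1[0] + 1) < t.triplet_min_span:
                continue
            if (s2[1] - s2[0] + 1) < t.triplet_min_span:
                continue
            if cov1 >= t.mutual_cov_min or cov2 >= t.mutual_cov_min:
                continue
            if family_of is not None:
                fam = family_of.get(c1)
                if fam is not None and (family_of.get(p1) == fam
                                        or family_of.get(p2) == fam):
                    continue
            ov = min(s1[1], s2[1]) - max(s1[0], s2[0]) + 1
            if ov > t.triplet_max_overlap:
                continue
            flagged.add(c1)
    return flagged


def random_triplet_instance(rng: np.random.Generator):
    """Up to 50 proteins with partial/full hits of varied geometry."""
    n_prot = int(rng.integers(5, 51))
    taxa = {}
    for i in range(n_prot):
        dol = [EUKARYOTE, BACTERIA, ARCHAEA][int(rng.integers(0, 3))]
        rec = ProteinRecord(
            id=f"g{i:02d}", species=f"s{i}", domain_of_life=dol,
            length=int(rng.integers(80, 401)),
            supergroup="SAR" if dol == EUKARYOTE else None,
            megagroup="DIPHODA" if dol == EUKARYOTE else None)
        taxa[rec.id] = rec
    ids = sorted(taxa)
    hits = []
    for _ in range(int(rng.integers(20, 150))):
        q, s = (ids[int(rng.integers(0, n_prot))] for _ in range(2))
        qlen, slen = taxa[q].length, taxa[s].length
        qa = int(rng.integers(1, qlen + 1))
        qlen_span = int(rng.integers(20, 200))
        qspan = (qa, min(qlen, qa + qlen_span))
        sa = int(rng.integers(1, slen + 1))
        sspan = (sa, min(slen, sa + qlen_span))
        hits.append(SimilarityHit(
            query=q, subject=s,
            pct_identity=round(float(rng.uniform(20, 100)), 1),
            aln_len=qspan[1] - qspan[0] + 1, mismatch=0, gapopen=0,
            qstart=qspan[0], qend=qspan[1], sstart=sspan[0], send=sspan[1],
            evalue=10.0 ** float(rng.uniform(-15, 0)),
            bitscore=round(float(rng.uniform(20, 300)), 1),
        ))
    return hits, taxa


# ---------------------------------------------------------------------------
# Dollo parsimony


def random_rooted_tree(rng: np.random.Generator, n_leaves: int,
                       polytomy_prob: float = 0.25) -> SpeciesTree:
    nodes = [TreeNode(f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        k = 3 if (len(nodes) >= 3 and rng.random() < polytomy_prob) else 2
        idx = sorted(rng.choice(len(nodes), size=k, replace=False).tolist(),
                     reverse=True)
        parent = TreeNode("")
        for i in idx:
            parent.add(nodes.pop(i))
        nodes.append(parent)
    return SpeciesTree(nodes[0])


def dollo_min_losses_bruteforce(tree: SpeciesTree, present: set[str]) -> int:
    """Exhaustive minimum loss count over every single-gain placement."""
    best = None
    for gain in tree.preorder():
        below = tree.leaf_labels(gain.label)
        if not present <= below:
            continue
        absent = below - present
        # candidate loss edges: edges under the gain to all-absent subtrees
        candidates = []
        stack = list(gain.children)
        while stack:
            node = stack.pop()
            if not (tree.leaf_labels(node.label) & present):
                candidates.append(tree.leaf_labels(node.label))
            stack.extend(node.children)
        if not absent:
            best = 0 if best is None else min(best, 0)
            continue
        for r in range(1, len(candidates) + 1):
            if best is not None and r >= best:
                break
            found = False
            for combo in combinations(candidates, r):
                covered = frozenset().union(*combo)
                if covered == absent:
                    found = True
                    break
            if found:
                best = r if best is None else min(best, r)
                break
    return best


# ---------------------------------------------------------------------------
# resampling statistics


def exhaustive_zscore(observed: int, pool: list[bool], k: int) -> float:
    counts = [sum(combo) for combo in combinations(pool, k)]
    mean = sum(counts) / len(counts)
    var = sum((c - mean) ** 2 for c in counts) / len(counts)
    return (observed - mean) / var ** 0.5


def hypergeometric_zscore(observed: int, pool: list[bool], k: int) -> float:
    n_total, n_pos = len(pool), sum(pool)
    p = n_pos / n_total
    mean = k * p
    var = k * p * (1 - p) * (n_total - k) / (n_total - 1)
    return (observed - mean) / var ** 0.5


def pearson_chi2(table) -> float:
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


def bh_stepup(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted
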