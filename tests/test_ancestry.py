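import numpy as np
import pytest

from oracles import dollo_min_losses_bruteforce, random_rooted_tree
from sgenes.ancestry import (
    EARLY,
    INCONCLUSIVE,
    INTERMEDIATE,
    LIKELY_OLD,
    LINEAGE_SPECIFIC,
    OLD,
    age_class,
    assess_gene_tree,
    build_presence_matrix,
    dollo_reconstruct,
)
from sgenes.families import HomologyFamily
from sgenes.io_formats import ProteinRecord, ValidationError
from sgenes.tree import SpeciesTree, parse_species_tree


def euk(gid, species, supergroup, megagroup):
    return ProteinRecord(id=gid, species=species, domain_of_life="EUKARYOTE",
                         length=100, supergroup=supergroup,
                         megagroup=megagroup)


TAXA = {
    "gA": euk("gA", "A", "Opisthokonta", "OPIMODA"),
    "gB": euk("gB", "B", "Amoebozoa", "OPIMODA"),
    "gC": euk("gC", "C", "SAR", "DIPHODA"),
    "gD": euk("gD", "D", "Archaeplastida", "DIPHODA"),
}


def make_tree():
    tree = SpeciesTree.from_newick("((A,B)Opi,(C,D)Dip)root;")
    tree.decorate(TAXA)
    return tree


def fam(fid, members):
    species = frozenset(TAXA[m].species for m in members)
    return HomologyFamily(id=fid, members=frozenset(members), species=species,
                          n_euk_species=len(species), all_eukaryotic=True)


class TestSpeciesTree:
    def test_parse_and_decorate(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A,B),(C,D));\n")
        tree = parse_species_tree(path, TAXA)
        assert sorted(tree.leaf_labels()) == ["A", "B", "C", "D"]
        assert tree.megagroup_of["A"] == "OPIMODA"

    def test_unknown_leaf_is_error(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A,X),(C,D));\n")
        with pytest.raises(ValidationError, match="X"):
            parse_species_tree(path, TAXA)

    def test_polytomy_accepted_and_flagged(self):
        tree = SpeciesTree.from_newick("((A,B,C),D);")
        assert tree.has_polytomy

    def test_newick_round_trip(self):
        tree = make_tree()
        again = SpeciesTree.from_newick(tree.to_newick())
        assert again.to_newick() == tree.to_newick()


class TestPresenceMatrix:
    def test_rows_follow_membership(self):
        tree = make_tree()
        m = build_presence_matrix([fam("f1", {"gA", "gC"})], TAXA, tree)
        assert m.loc["f1"].tolist() == [True, False, True, False]

    def test_empty_family_set(self):
        m = build_presence_matrix([], TAXA, make_tree())
        assert m.empty

    def test_species_missing_from_tree_is_error(self):
        tree = SpeciesTree.from_newick("(A,B);")
        tree.decorate({k: TAXA[k] for k in ("gA", "gB")})
        with pytest.raises(ValidationError):
            build_presence_matrix([fam("f1", {"gA", "gC"})], TAXA, tree)


class TestDollo:
    def test_gain_at_mrca_no_losses(self):
        res = dollo_reconstruct(make_tree(),
                                {"A": True, "B": True, "C": False, "D": False})
        assert res.gain_node == "Opi" and res.n_losses == 0

    def test_disjoint_presence_charges_losses(self):
        res = dollo_reconstruct(make_tree(),
                                {"A": True, "B": False, "C": True, "D": False})
        assert res.gain_node == "root"
        assert res.loss_edges == {"B", "D"}

    def test_all_absent_is_error(self):
        with pytest.raises(ValueError):
            dollo_reconstruct(make_tree(), {s: False for s in "ABCD"})

    def test_reconstruction_reproduces_the_row(self):
        rng = np.random.default_rng(5)
        tree = random_rooted_tree(rng, 8)
        leaves = sorted(tree.leaf_labels())
        for _ in range(20):
            row = {l: bool(rng.random() < 0.5) for l in leaves}
            if not any(row.values()):
                continue
            res = dollo_reconstruct(tree, row)
            under_gain = tree.leaf_labels(res.gain_node)
            lost = frozenset().union(
                frozenset(),
                *(tree.leaf_labels(e) for e in res.loss_edges))
            assert {l for l in leaves if row[l]} == under_gain - lost

    @pytest.mark.parametrize("seed", range(5))
    def test_loss_count_is_the_single_gain_minimum(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(8):
            tree = random_rooted_tree(rng, int(rng.integers(3, 9)))
            leaves = sorted(tree.leaf_labels())
            row = {l: bool(rng.random() < 0.5) for l in leaves}
            if not any(row.values()):
                row[leaves[0]] = True
            res = dollo_reconstruct(tree, row)
            present = {l for l in leaves if row[l]}
            assert res.n_losses == dollo_min_losses_bruteforce(tree, present)


class TestAgeClass:
    def test_both_megagroups_is_early(self):
        assert age_class({"A": True, "C": True}, TAXA) == EARLY

    def test_two_supergroups_one_side_is_intermediate(self):
        assert age_class({"C": True, "D": True}, TAXA) == INTERMEDIATE

    def test_single_supergroup_is_lineage_specific(self):
        assert age_class({"C": True}, TAXA) == LINEAGE_SPECIFIC


SG = {"a1": "Opisthokonta", "a2": "Opisthokonta", "b1": "Amoebozoa",
      "b2": "Amoebozoa", "c1": "SAR", "c2": "SAR", "d1": "Archaeplastida",
      "d2": "Archaeplastida"}
MG = {k: ("OPIMODA" if v in ("Opisthokonta", "Amoebozoa") else "DIPHODA")
      for k, v in SG.items()}


class TestGeneTreeVerdicts:
    def assess(self, newick):
        return assess_gene_tree(SpeciesTree.from_newick(newick), SG, MG)

    def test_supergroup_pure_partitions_are_old(self):
        v = self.assess("(((a1,a2)95,(b1,b2)99)90,((c1,c2)95,(d1,d2)95)90);")
        assert v.verdict == OLD and not v.offending_partitions

    def test_unsupported_partitions_do_not_count(self):
        # a SAR leaf nests inside Opisthokonta, but with support below 85
        v = self.assess("(((a1,c1)50,(a2,b1)40)30,((c2,d1)20,(b2,d2)10)5);")
        assert v.verdict == OLD

    def test_mixing_confined_within_one_megagroup_is_likely_old(self):
        # resolved clade joins SAR and Archaeplastida splitting both: Diphoda-only mix
        v = self.assess("(((a1,a2)95,(b1,b2)95)90,((c1,d1)95,(c2,d2)95)90);")
        assert v.verdict == LIKELY_OLD
        assert v.offending_partitions

    def test_opimoda_diphoda_joined_on_small_side_is_inconclusive(self):
        v = self.assess("(((a1,c1)95,(a2,b1)90)90,((b2,c2)40,(d1,d2)95)90);")
        assert v.verdict == INCONCLUSIVE

    def test_unmapped_leaf_is_error(self):
        with pytest.raises(ValidationError):
            assess_gene_tree(SpeciesTree.from_newick("((a1,zz)95,(c1,d1)95);"),
                             SG, MG)
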