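import hashlib
from pathlib import Path

import numpy as np
import pytest

from sgenes.io_formats import parse_hit_table, parse_taxon_table
from sgenes.synthetic import SyntheticConfig, simulate_dataset
from sgenes.tree import SpeciesTree


def digest_tree(root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(root.rglob("*")) if p.is_file()}


class TestConfigValidation:
    def test_operon_fusions_bounded_by_sgenes(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_sgenes=2, n_operon_fusions=3)

    def test_divergence_saturation_bound(self):
        with pytest.raises(ValueError):
            SyntheticConfig(divergence=0.6)

    def test_domain_budget_checked_before_writing(self, tmp_path):
        cfg = SyntheticConfig(domain_library_size=10)
        with pytest.raises(ValueError, match="domain_library_size"):
            simulate_dataset(cfg, tmp_path / "out")
        assert not (tmp_path / "out").exists()


class TestDeterminism:
    def test_same_seed_twice_is_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_sgenes=4, n_full_transfers=1,
                              n_innovations=1, n_operon_fusions=1,
                              n_intron_families=1, n_euk_donor_domains=4,
                              domain_library_size=30)
        simulate_dataset(cfg, tmp_path / "a")
        simulate_dataset(cfg, tmp_path / "b")
        assert digest_tree(tmp_path / "a") == digest_tree(tmp_path / "b")


class TestPlantedStructure:
    def test_truth_counts_match_config(self, study_dataset):
        _, truth, _ = study_dataset
        by_class = {}
        for fam, cls in truth.class_of_family.items():
            by_class.setdefault(cls, set()).add(fam)
        assert len(by_class["S_GENE"]) == 30
        assert len(by_class["PROK_FULL"]) == 10
        assert len(by_class["EUK_INNOVATION"]) == 10
        assert len(truth.operon_derived) == 5
        assert len(truth.conserved_intron_families) == 5

    def test_sgene_layouts_have_a_prokaryotic_span(self, study_dataset):
        _, truth, _ = study_dataset
        for gene, layout in truth.component_layout.items():
            fam = truth.family_of[gene]
            if truth.class_of_family[fam] != "S_GENE":
                continue
            origins = [o for _, o in layout]
            assert any(o in ("ARC", "BAC") for o in origins)
            spans = [s for s, _ in layout]
            assert all(s1[1] < s2[0] for s1, s2 in zip(spans, spans[1:]))

    def test_files_parse_back(self, study_dataset):
        _, _, outdir = study_dataset
        taxa = parse_taxon_table(outdir / "taxa.tsv")
        hits = parse_hit_table(outdir / "hits.tsv")
        tree = SpeciesTree.from_file(outdir / "tree.nwk")
        assert len(tree.leaf_labels()) == 12
        assert all(h.query in taxa and h.subject in taxa for h in hits)

    def test_presence_follows_the_recorded_gain(self, study_dataset):
        dataset, truth, _ = study_dataset
        tree = dataset.tree
        for fam, gain in truth.gain_node.items():
            species = {g.species for g in dataset.genes.values()
                       if g.family == fam}
            assert species <= set(tree.leaf_labels(gain))
            assert tree.mrca(species).label == gain


class TestZeroDivergence:
    def test_orthologous_copies_are_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=2, divergence=0.0, n_sgenes=2,
                              n_full_transfers=1, n_innovations=1,
                              n_operon_fusions=1, n_intron_families=1,
                              n_euk_donor_domains=4, domain_library_size=20)
        dataset, truth = simulate_dataset(cfg)
        by_family = {}
        for g in dataset.genes.values():
            by_family.setdefault(g.family, []).append(g.seq)
        for fam, seqs in by_family.items():
            first = seqs[0]
            assert all(np.array_equal(first, s) for s in seqs[1:])


class TestHitSynthesis:
    def test_identical_copies_give_full_identity_hit(self, tmp_path):
        cfg = SyntheticConfig(seed=2, divergence=0.0, n_sgenes=2,
                              n_full_transfers=1, n_innovations=1,
                              n_operon_fusions=1, n_intron_families=1,
                              n_euk_donor_domains=4, domain_library_size=20)
        dataset, truth = simulate_dataset(cfg)
        same_family = [h for h in dataset.base_hits
                       if truth.family_of[h.query] == truth.family_of[h.subject]]
        assert same_family
        for h in same_family:
            assert h.pct_identity == 100.0
            assert h.qstart == h.sstart == 1

    def test_score_and_evalue_closed_forms(self, study_dataset):
        # a 100-aa overlap at 90% identity scores round(1.8*100*0.9) = 162
        # and E = 10^(-162/5) = 10^-32.4
        dataset, _, _ = study_dataset
        assert round(1.8 * 100 * 0.9) == 162
        for h in dataset.base_hits[:500]:
            expected_bits = round(1.8 * h.aln_len * (1 - h.mismatch / h.aln_len))
            assert h.bitscore == expected_bits
            assert h.evalue == pytest.approx(
                min(1.0, 10 ** (-h.bitscore / 5)), rel=1e-9)

    def test_noise_hits_fail_the_family_edge_threshold(self, tmp_path):
        cfg = SyntheticConfig(seed=3, hit_noise=0.1, n_sgenes=4,
                              n_full_transfers=1, n_innovations=1,
                              n_operon_fusions=1, n_intron_families=1,
                              n_euk_donor_domains=4, domain_library_size=30)
        noisy, truth = simulate_dataset(cfg)
        clean, _ = simulate_dataset(
            SyntheticConfig(**{**cfg.__dict__, "hit_noise": 0.0}))
        true_set = set(clean.base_hits)
        spurious = [h for h in noisy.base_hits if h not in true_set]
        assert spurious
        assert all(h.evalue >= 1e-3 for h in spurious)
        n_dropped = len(true_set) - len([h for h in noisy.base_hits
                                         if h in true_set])
        assert n_dropped == len(spurious)
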