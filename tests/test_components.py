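import numpy as np
import pytest

from sgenes.components import (
    ComponentFamily,
    ComponentInstance,
    Supporter,
    assign_component_origin,
    cluster_component_instances,
    conservative_reassign,
    extract_component_instances,
    family_origin_profile,
    label_origin_profiles,
    merge_component_families,
)
from sgenes.families import Thresholds
from sgenes.io_formats import ProteinRecord, SimilarityHit


def rec(gid, length, dol="BACTERIA"):
    kw = {}
    if dol == "EUKARYOTE":
        kw = dict(supergroup="SAR", megagroup="DIPHODA")
    return ProteinRecord(id=gid, species=f"sp_{gid}", domain_of_life=dol,
                         length=length, **kw)


def hit(q, s, qspan, sspan, evalue=1e-20, bitscore=100.0):
    return SimilarityHit(query=q, subject=s, pct_identity=80.0,
                         aln_len=qspan[1] - qspan[0] + 1, mismatch=0,
                         gapopen=0, qstart=qspan[0], qend=qspan[1],
                         sstart=sspan[0], send=sspan[1], evalue=evalue,
                         bitscore=bitscore)


def inst(span, supporters=()):
    return ComponentInstance("C", span, list(supporters))


class TestExtractInstances:
    taxa = {"C": rec("C", 300, "EUKARYOTE"), "p1": rec("p1", 140),
            "p2": rec("p2", 141), "e1": rec("e1", 140, "EUKARYOTE")}

    def test_two_partial_hits_give_two_instances(self):
        hits = [hit("p1", "C", (1, 140), (1, 140)),
                hit("p2", "C", (1, 141), (160, 300))]
        out = extract_component_instances("C", hits, self.taxa)
        assert [i.span for i in out] == [(1, 140), (160, 300)]
        assert out[0].supporters[0].domain_of_life == "BACTERIA"

    def test_full_length_hit_excluded(self):
        hits = [hit("p1", "C", (1, 140), (1, 280))]  # coverage 0.93
        assert extract_component_instances("C", hits, self.taxa) == []

    def test_eukaryote_only_span_has_no_prokaryotic_supporters(self):
        hits = [hit("e1", "C", (1, 140), (1, 140))]
        (one,) = extract_component_instances("C", hits, self.taxa)
        assert all(s.domain_of_life == "EUKARYOTE" for s in one.supporters)


class TestClustering:
    def test_high_reciprocal_overlap_groups(self):
        fams = cluster_component_instances([inst((100, 200)), inst((110, 210))])
        assert len(fams) == 1

    def test_low_overlap_stays_apart(self):
        fams = cluster_component_instances([inst((100, 200)), inst((180, 280))])
        assert len(fams) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_single_linkage(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        spans = []
        for _ in range(n):
            a = int(rng.integers(1, 400))
            spans.append((a, a + int(rng.integers(30, 150))))
        instances = [inst(s) for s in spans]
        got = cluster_component_instances(instances)
        # oracle: repeated merging of span sets until fixpoint
        t = Thresholds()
        groups = [{s} for s in spans]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    link = any(
                        (min(a[1], b[1]) - max(a[0], b[0]) + 1)
                        > t.component_overlap * (a[1] - a[0] + 1)
                        and (min(a[1], b[1]) - max(a[0], b[0]) + 1)
                        > t.component_overlap * (b[1] - b[0] + 1)
                        for a in groups[i] for b in groups[j])
                    if link:
                        groups[i] |= groups.pop(j)
                        changed = True
                        break
                if changed:
                    break
        expected = {frozenset(g) for g in groups}
        assert {frozenset(m.span for m in f.members) for f in got} == expected


class TestMerging:
    def fam(self, span, n_members=1):
        return ComponentFamily(id=f"C:{span}", composite="C",
                               representative=span,
                               members=[inst(span)] * n_members)

    def test_nested_families_merge(self):
        out = merge_component_families([self.fam((100, 200)),
                                        self.fam((120, 190))])
        assert len(out) == 1

    def test_small_inclusion_does_not_merge(self):
        out = merge_component_families([self.fam((100, 200)),
                                        self.fam((190, 300))])
        assert len(out) == 2

    def test_chained_merges_reach_fixpoint(self):
        # a ~ b and b ~ c but a !~ c directly: all three must coalesce
        out = merge_component_families([
            self.fam((100, 200)), self.fam((110, 210)), self.fam((120, 220))])
        assert len(out) == 1
        # fixpoint: no pair of survivors still satisfies the merge rule
        t = Thresholds()
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                a, b = out[i].representative, out[j].representative
                ov = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
                small = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
                assert not ov > t.merge_inclusion * small


def bac(i, score):
    return Supporter(f"b{i}", "BACTERIA", score, 1e-20)


def arc(i, score):
    return Supporter(f"a{i}", "ARCHAEA", score, 1e-20)


class TestOriginAssignment:
    def comp(self, supporters):
        return ComponentFamily(id="C:c1", composite="C",
                               representative=(1, 100),
                               members=[inst((1, 100), supporters)])

    def test_top_ten_all_bacterial(self):
        sups = [bac(i, 200 - i) for i in range(10)] + [arc(99, 50)]
        assert assign_component_origin(self.comp(sups)) == "BAC"

    def test_fewer_than_ten_prokaryotic_supporters(self):
        sups = [arc(i, 200 - i) for i in range(9)]
        assert assign_component_origin(self.comp(sups)) == "PROK"

    def test_mixed_top_ten(self):
        sups = [bac(i, 200 - i) for i in range(9)] + [arc(9, 150)] \
            + [bac(99, 50)]
        assert assign_component_origin(self.comp(sups)) == "PROK"

    def test_no_prokaryotic_supporters(self):
        sups = [Supporter("e1", "EUKARYOTE", 100, 1e-20)]
        assert assign_component_origin(self.comp(sups)) == "EUK"


class TestConservativeReassignment:
    def comp(self, origin, span=(1, 100)):
        return ComponentFamily(id="C:c1", composite="C", representative=span,
                               members=[inst(span)], origin=origin)

    @pytest.mark.parametrize("origin,domain,expected", [
        ("BAC", "WD40", "PROK"),
        ("ARC", "DnaJ", "PROK"),
        ("EUK", "EFh", "EUK"),     # EUK labels are never touched
        ("BAC", "PilZ", "BAC"),    # not on the small-domain list
    ])
    def test_reassignment_rules(self, origin, domain, expected):
        domains = {"C": [(domain, (40, 90))]}
        (out,) = conservative_reassign([self.comp(origin)], domains)
        assert out.origin == expected

    def test_non_overlapping_annotation_ignored(self):
        domains = {"C": [("WD40", (150, 220))]}
        (out,) = conservative_reassign([self.comp("BAC")], domains)
        assert out.origin == "BAC"


class TestOriginProfiles:
    def test_ratio_per_origin(self):
        comps = {
            "g1": [self.cf("BAC")], "g2": [self.cf("BAC"), self.cf("EUK")],
            "g3": [self.cf("BAC")], "g4": [self.cf("BAC"), self.cf("EUK")],
        }
        prof = family_origin_profile("f", ["g1", "g2", "g3", "g4"], comps)
        assert prof.ratios == {"EUK": 0.5, "ARC": 0.0, "BAC": 1.0, "PROK": 0.0}

    def cf(self, origin):
        return ComponentFamily(id="x", composite="g", representative=(1, 50),
                               members=[], origin=origin)

    def test_gene_without_components_contributes_nothing(self):
        prof = family_origin_profile("f", ["g1", "g2"],
                                     {"g1": [self.cf("ARC")]})
        assert prof.ratios["ARC"] == 0.5

    @pytest.mark.parametrize("ratios,label", [
        ({"BAC": 1.0, "EUK": 0.0, "ARC": 0.0, "PROK": 0.0}, "BAC-BAC"),
        ({"ARC": 0.9, "EUK": 0.8, "BAC": 0.0, "PROK": 0.0}, "ARC-EUK"),
        ({"PROK": 0.6, "BAC": 0.7, "EUK": 0.0, "ARC": 0.0}, "PROK-BAC"),
        ({"BAC": 0.3, "EUK": 0.3, "ARC": 0.3, "PROK": 0.3}, "OTHER"),
    ])
    def test_rule_labels(self, ratios, label):
        from sgenes.components import OriginProfile

        (out,) = label_origin_profiles([OriginProfile("f", ratios)])
        assert out.label == label

    def test_hierarchical_needs_enough_profiles(self):
        from sgenes.components import OriginProfile

        with pytest.raises(ValueError):
            label_origin_profiles([OriginProfile("f", {o: 0.0 for o in
                                                       "EUK ARC BAC PROK".split()})],
                                  method="hierarchical", n_clusters=2)
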