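"""Species/genus OTU assignment: single linkage, tree support, labelling."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refdb16s.otus import (
    OtuCluster,
    OtuPartition,
    assign_genus_otus,
    clade_support,
    cluster_species_otus,
    is_monophyletic,
    label_otu,
    otu_divergence_stats,
)
from refdb16s.records import ReferenceRecord
from refdb16s.tree import parse_newick

from conftest import make_family, stub_identity


def _recs(ids, **kw):
    return [ReferenceRecord(id=i, seq="ACGT" * 10, **kw) for i in ids]


class TestSpeciesClustering:
    def test_single_linkage_chain(self):
        """A-B and B-C above threshold pull A and C into one OTU even though
        A-C is below it."""
        fn = stub_identity({
            frozenset("AB"): 98.5,
            frozenset("BC"): 98.2,
            frozenset("AC"): 96.9,
        })
        part = cluster_species_otus(_recs("ABC"), identity_fn=fn)
        assert part.as_sets() == {frozenset("ABC")}

    def test_no_pair_above_threshold_gives_singletons(self):
        fn = stub_identity({
            frozenset(p): 96.0 for p in itertools.combinations("ABCD", 2)
        })
        part = cluster_species_otus(_recs("ABCD"), identity_fn=fn)
        assert part.as_sets() == {frozenset({c}) for c in "ABCD"}

    def test_boundary_inclusive_at_98(self):
        part = cluster_species_otus(
            _recs("AB"), identity_fn=stub_identity({frozenset("AB"): 98.0})
        )
        assert part.as_sets() == {frozenset("AB")}
        part = cluster_species_otus(
            _recs("AB"), identity_fn=stub_identity({frozenset("AB"): 97.9})
        )
        assert part.as_sets() == {frozenset("A"), frozenset("B")}

    def test_matches_connected_components_oracle(self, rng):
        """Random identity structure: partition equals networkx connected
        components of the thresholded identity graph."""
        for _ in range(10):
            ids = [f"R{i}" for i in range(12)]
            matrix = {
                frozenset(p): float(rng.uniform(95.0, 100.0))
                for p in itertools.combinations(ids, 2)
            }
            part = cluster_species_otus(
                _recs(ids), identity_fn=stub_identity(matrix)
            )
            g = nx.Graph()
            g.add_nodes_from(ids)
            g.add_edges_from(
                tuple(p) for p, v in matrix.items() if v >= 98.0
            )
            oracle = {frozenset(c) for c in nx.connected_components(g)}
            assert part.as_sets() == oracle

    def test_order_independent(self, rng):
        records = make_family(rng, 12, length=150, max_subs=6)
        part = cluster_species_otus(records)
        perm = [records[i] for i in rng.permutation(len(records))]
        assert cluster_species_otus(perm).as_sets() == part.as_sets()


class TestDivergenceStats:
    def test_pair_at_99_identity_is_1pct_divergence(self):
        part = OtuPartition(
            [OtuCluster("x", ("A", "B"), "species")], level="species"
        )
        per, glob = otu_divergence_stats(
            part, _recs("AB"), identity_fn=stub_identity({frozenset("AB"): 99.0})
        )
        assert glob.mean == pytest.approx(1.0)
        assert per["x"].sd == pytest.approx(0.0)

    def test_all_singletons_reported_absent(self):
        part = OtuPartition(
            [OtuCluster("a", ("A",), "species"), OtuCluster("b", ("B",), "species")],
            level="species",
        )
        per, glob = otu_divergence_stats(part, _recs("AB"), stub_identity({}))
        assert per == {} and glob is None

    def test_three_member_cluster_hand_average(self):
        """Pairwise identities {98.0, 98.5, 99.0} -> mean divergence
        (2.0 + 1.5 + 1.0)/3 = 1.5%."""
        fn = stub_identity({
            frozenset("AB"): 98.0,
            frozenset("AC"): 98.5,
            frozenset("BC"): 99.0,
        })
        part = OtuPartition(
            [OtuCluster("x", ("A", "B", "C"), "species")], level="species"
        )
        _, glob = otu_divergence_stats(part, _recs("ABC"), fn)
        assert glob.mean == pytest.approx(1.5)
        assert glob.max == pytest.approx(2.0)


class TestCladeSupport:
    def test_supported_clade(self):
        d = clade_support(parse_newick("((A,B)85,C);"), {"A", "B"})
        assert d.supported and d.bootstrap_support == 85.0

    def test_boundary_at_70(self):
        assert clade_support(parse_newick("((A,B)70,C);"), {"A", "B"}).supported
        assert not clade_support(parse_newick("((A,B)69,C);"), {"A", "B"}).supported

    def test_non_monophyletic_unsupported(self):
        d = clade_support(parse_newick("((A,C)90,B);"), {"A", "B"})
        assert not d.supported and d.bootstrap_support is None

    def test_unknown_leaf_is_error(self):
        with pytest.raises(KeyError):
            clade_support(parse_newick("((A,B),C);"), {"A", "Z"})


class TestMonophyly:
    @pytest.mark.parametrize(
        "newick,members,expected",
        [
            ("((A,B),C);", {"A", "B"}, True),
            ("((A,B),C);", {"A", "C"}, False),
            ("((A,B),(C,D));", {"C", "D"}, True),
            ("(A,B,(C,D));", {"A", "B"}, True),  # unrooted: bipartition side
            ("(A,B,(C,D));", {"A", "C"}, False),
        ],
    )
    def test_cases(self, newick, members, expected):
        assert is_monophyletic(parse_newick(newick), members) is expected


class TestGenusAssignment:
    def _species(self, labels):
        return OtuPartition(
            [OtuCluster(l, (l,), "species") for l in labels], level="species"
        )

    def test_sister_outside_named_genus_stays_unclassified(self):
        tree = parse_newick("((g1a,g1b),x);")
        part = self._species(["g1a", "g1b", "x"])
        genus = assign_genus_otus(
            tree, part,
            {"g1a": "Genus1", "g1b": "Genus1"},
            {l: l for l in ("g1a", "g1b", "x")},
        )
        by_label = {c.label: set(c.members) for c in genus.clusters}
        assert by_label["Genus1"] == {"g1a", "g1b"}
        assert any(l.startswith("unclassified") and m == {"x"}
                   for l, m in by_label.items())

    def test_attachment_that_restores_monophyly(self):
        tree = parse_newick("(((g1a,x),g1b),out);")
        part = self._species(["g1a", "g1b", "x", "out"])
        genus = assign_genus_otus(
            tree, part,
            {"g1a": "Genus1", "g1b": "Genus1"},
            {l: l for l in ("g1a", "g1b", "x", "out")},
        )
        by_label = {c.label: set(c.members) for c in genus.clusters}
        assert by_label["Genus1"] == {"g1a", "g1b", "x"}

    def test_matches_exhaustive_attachment_search(self, rng):
        """Planted 4-genus tree with one unnamed species per genus: the
        assignment equals exhaustive search over all single-genus
        attachments."""
        newick = ("(((a1,a2),ax)90,((b1,b2),bx)85,((c1,c2),cx)80,"
                  "((d1,d2),dx)75);")
        tree = parse_newick(newick)
        labels = [l for g in "abcd" for l in (f"{g}1", f"{g}2", f"{g}x")]
        part = self._species(labels)
        priors = {f"{g}{i}": f"Genus_{g}" for g in "abcd" for i in "12"}
        genus = assign_genus_otus(tree, part, priors, {l: l for l in labels})
        by_label = {c.label: set(c.members) for c in genus.clusters}
        # oracle: for each unnamed leaf, the unique genus whose seed set
        # plus the leaf is monophyletic
        for g in "abcd":
            fits = [
                h for h in "abcd"
                if tree.is_monophyletic({f"{h}1", f"{h}2", f"{g}x"})
            ]
            assert fits == [g]
            assert f"{g}x" in by_label[f"Genus_{g}"]

    def test_conflicting_prior_naming_flagged(self):
        """A prior genus interleaved with another cannot be monophyletic."""
        tree = parse_newick("(((a1,b1),a2),b2);")
        part = self._species(["a1", "a2", "b1", "b2"])
        genus = assign_genus_otus(
            tree, part,
            {"a1": "GA", "a2": "GA", "b1": "GB", "b2": "GB"},
            {l: l for l in ("a1", "a2", "b1", "b2")},
        )
        flags = {c.label: c.conflict for c in genus.clusters}
        assert flags["GA"] and flags["GB"]

    def test_nesting_invariant(self):
        tree = parse_newick("(((s1,s2),s3),(s4,s5));")
        part = self._species(["s1", "s2", "s3", "s4", "s5"])
        genus = assign_genus_otus(
            tree, part,
            {"s1": "G1", "s2": "G1", "s4": "G2", "s5": "G2"},
            {l: l for l in ("s1", "s2", "s3", "s4", "s5")},
        )
        species_sets = part.as_sets()
        for c in genus.clusters:
            for s in species_sets:
                assert s <= set(c.members) or not (s & set(c.members))


class TestLabelling:
    def test_single_named_member(self):
        recs = [ReferenceRecord(id="A", seq="ACGT", name="Rothia aeria")]
        assert label_otu(recs) == "Rothia aeria"

    def test_combination_name_alphabetical(self):
        """Indistinguishable mitis-group streptococci get one combination
        label joining the epithets alphabetically."""
        names = [
            "Streptococcus mitis",
            "Streptococcus pneumoniae",
            "Streptococcus infantis",
            "Streptococcus oralis",
        ]
        recs = [
            ReferenceRecord(id=f"S{i}", seq="ACGT", name=n)
            for i, n in enumerate(names)
        ]
        assert label_otu(recs) == "Streptococcus infantis/mitis/oralis/pneumoniae"

    def test_unnamed_cluster_uses_shared_lineage(self):
        recs = [
            ReferenceRecord(
                id="A", seq="ACGT", name="Lachnospiraceae sp.",
                lineage=("Bacteria", "Firmicutes", "Lachnospiraceae"),
            ),
            ReferenceRecord(
                id="B", seq="ACGT",
                lineage=("Bacteria", "Firmicutes", "Lachnospiraceae"),
            ),
        ]
        assert label_otu(recs) == "unclassified_Lachnospiraceae"
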