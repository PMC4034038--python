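import pytest

from ggfam.events import (
    count_duplications,
    label_events,
    reconcile_lca,
    root_by_parsimony,
)
from ggfam.trees import (
    Event,
    GeneTree,
    Node,
    SpeciesMap,
    parse_newick,
    resolve_polytomies,
    write_newick,
)


class TestNewick:
    def test_parse_small(self):
        t = parse_newick("((a,b),c);")
        assert sorted(t.leaf_labels()) == ["a", "b", "c"]
        assert t.is_binary()

    def test_roundtrip(self):
        for text in ["((a,b),c);", "((a,b),(c,d));", "((a:1,b:2):0.5,c:3);"]:
            assert write_newick(parse_newick(text)) == text

    def test_events_roundtrip_nhx(self):
        t = parse_newick("((A_g1,A_g2),B_g1);")
        label_events(t, SpeciesMap())
        text = write_newick(t, include_events=True)
        again = parse_newick(text)
        events = [n.event for n in again.postorder() if not n.is_leaf]
        assert events == [Event.DUPLICATION, Event.SPECIATION]

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((a,a),c);")

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("((a,b,c;")

    def test_resolve_polytomies(self):
        t = parse_newick("(a,b,c,d);")
        assert not t.is_binary()
        r = resolve_polytomies(t)
        assert r.is_binary() and sorted(r.leaf_labels()) == ["a", "b", "c", "d"]


class TestSpeciesMap:
    def test_default_prefix_pattern(self):
        assert SpeciesMap().resolve("ATH_g1") == "ATH"

    def test_table_wins(self):
        m = SpeciesMap(table={"x": "SPEC"})
        assert m.resolve("x") == "SPEC"
        with pytest.raises(KeyError):
            m.resolve("y")

    def test_tsv(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("g1\tA\ng2\tB\n")
        m = SpeciesMap.from_tsv(p)
        assert m.resolve("g1") == "A" and m.resolve("g2") == "B"


class TestLabelEvents:
    @pytest.mark.parametrize(
        "newick,expected",
        [
            # postorder internal events
            ("((A_g1,B_g1),(A_g2,B_g2));", ["S", "S", "D"]),
            ("((A_g1,A_g2),B_g1);", ["D", "S"]),
            # caterpillar, one species: duplications everywhere
            ("(((A_g1,A_g2),A_g3),A_g4);", ["D", "D", "D"]),
        ],
    )
    def test_species_overlap_rule(self, newick, expected):
        t = label_events(parse_newick(newick), SpeciesMap())
        got = [n.event.value for n in t.postorder() if not n.is_leaf]
        assert got == expected

    def test_child_swap_invariance(self):
        t = label_events(parse_newick("((A_g1,B_g1),(A_g2,C_g1));"), SpeciesMap())
        s = parse_newick("((A_g2,C_g1),(B_g1,A_g1));")
        label_events(s, SpeciesMap())
        assert sorted(n.event.value for n in t.postorder()) == sorted(
            n.event.value for n in s.postorder()
        )

    def test_unmapped_leaf_named(self):
        t = parse_newick("((A_g1,B_g1),c);")
        with pytest.raises(KeyError, match="'c'"):
            label_events(t, SpeciesMap(table={"A_g1": "A", "B_g1": "B"}))

    def test_polytomy_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            label_events(parse_newick("(A_g1,B_g1,C_g1);"), SpeciesMap())


class TestReconcileLCA:
    def make(self, gene, sp):
        g = parse_newick(gene)
        SpeciesMap().apply(g)
        return g, parse_newick(sp)

    def test_hand_traced_losses(self):
        # gene (A,C) vs species ((A,B),C): root speciation, one loss (B)
        g, s = self.make("(A_g1,C_g1);", "((A,B),C);")
        dups, losses, mapping = reconcile_lca(g, s)
        assert (dups, losses) == (0, 1)

    def test_root_duplication_no_losses(self):
        g, s = self.make("((A_g1,B_g1),(A_g2,B_g2));", "(A,B);")
        dups, losses, _ = reconcile_lca(g, s)
        assert (dups, losses) == (1, 0)

    def test_congruent_tree_zero_zero(self):
        g, s = self.make("((A_g1,B_g1),C_g1);", "((A,B),C);")
        assert reconcile_lca(g, s)[:2] == (0, 1 - 1)

    def test_missing_species_rejected(self):
        g, s = self.make("(A_g1,Z_g1);", "(A,B);")
        with pytest.raises(ValueError, match="'Z'"):
            reconcile_lca(g, s)

    def test_dup_counts_agree_with_overlap_on_congruent_families(self, species_tree_5, rng):
        from ggfam.simulate import FamilySimConfig, simulate_family

        for seed in range(20):
            fam = simulate_family(
                FamilySimConfig(species_tree=species_tree_5, dup_rate=0.3, loss_rate=0.0, seed=seed)
            )
            t = fam.gene_tree.copy()
            label_events(t)
            dups, _, _ = reconcile_lca(t, species_tree_5)
            assert dups == count_duplications(t)


class TestRooting:
    def test_quartet_internal_edge_wins(self, quartet_two_species):
        rooted, audit = root_by_parsimony(quartet_two_species)
        chosen = next(a for a in audit if a.chosen)
        assert chosen.edge_id == "A_g1,B_g1"
        assert chosen.dup_count == 1
        assert {a.dup_count for a in audit if not a.chosen} == {2}
        assert len(audit) == 5  # 2n-3 edges of an unrooted quartet

    def test_single_species_total_tie_breaks_deterministically(self):
        t = parse_newick("(((A_g1,A_g2),A_g3),A_g4);")
        rooted, audit = root_by_parsimony(t)
        assert {a.dup_count for a in audit} == {3}  # n-1 duplications everywhere
        chosen = [a for a in audit if a.chosen]
        assert len(chosen) == 1
        # balance tie-break: a 2|2 split beats any 1|3 split
        assert len(chosen[0].edge_id.split(",")) == 2
        again = root_by_parsimony(parse_newick("(((A_g1,A_g2),A_g3),A_g4);"))[1]
        assert [a.edge_id for a in again] == [a.edge_id for a in audit]

    def test_congruent_family_scores_zero(self, species_tree_5):
        g = parse_newick("((A_g1,B_g1),((C_g1,D_g1),E_g1));")
        rooted, audit = root_by_parsimony(g, species_tree=species_tree_5)
        chosen = next(a for a in audit if a.chosen)
        assert (chosen.dup_count, chosen.loss_count) == (0, 0)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError, match="3 leaves"):
            root_by_parsimony(parse_newick("(A_g1,B_g1);"))

    def test_rooted_output_is_binary_and_labeled(self, quartet_two_species):
        rooted, _ = root_by_parsimony(quartet_two_species)
        assert rooted.is_binary()
        assert all(
            n.event in (Event.DUPLICATION, Event.SPECIATION)
            for n in rooted.postorder()
            if not n.is_leaf
        )
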