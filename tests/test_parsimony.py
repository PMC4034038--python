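import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ggfam import datasets
from ggfam.parsimony import (
    ancestral_report,
    exact_null,
    fitch_parsimony,
    fitch_scores_bulk,
    n_distinct_assignments,
    permutation_test,
    read_states,
    write_states,
)
from ggfam.trees import parse_newick, write_newick

from .conftest import random_binary_tree
from .oracles import exhaustive_mpr_root_states, exhaustive_parsimony


class TestFitch:
    @pytest.mark.parametrize(
        "newick,states,score",
        [
            ("((t1,t2),(t3,t4));", {"t1": 1, "t2": 1, "t3": 2, "t4": 2}, 1),
            ("((t1,t2),(t3,t4));", {"t1": 1, "t2": 2, "t3": 1, "t4": 2}, 2),
            ("((t1,t2),(t3,t4));", {"t1": 1, "t2": 1, "t3": 1, "t4": 1}, 0),
        ],
    )
    def test_small_examples(self, newick, states, score):
        assert fitch_parsimony(parse_newick(newick), states).score == score

    def test_matches_exhaustive_oracle_on_random_trees(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 9))
            labels = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(labels, rng)
            states = {l: int(rng.integers(1, 5)) for l in labels}
            assert fitch_parsimony(tree, states).score == exhaustive_parsimony(tree, states)

    def test_root_mpr_set_matches_exhaustive(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 7))
            labels = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(labels, rng)
            states = {l: int(rng.integers(1, 4)) for l in labels}
            res = fitch_parsimony(tree, states)
            assert set(res.root_states) == exhaustive_mpr_root_states(tree, states)

    @given(st.permutations([1, 1, 2, 2, 3, 4]))
    @settings(deadline=None, max_examples=40)
    def test_state_relabeling_invariance(self, perm):
        tree = parse_newick("(((a,b),(c,d)),(e,f));")
        base = {l: s for l, s in zip("abcdef", [1, 1, 2, 2, 3, 4])}
        relabel = dict(zip(sorted(set(base.values())), [9, 5, 3, 1]))
        assert (
            fitch_parsimony(tree, base).score
            == fitch_parsimony(tree, {k: relabel[v] for k, v in base.items()}).score
        )

    def test_score_bounds(self, rng):
        for _ in range(20):
            labels = [f"t{i}" for i in range(8)]
            tree = random_binary_tree(labels, rng)
            states = {l: int(rng.integers(1, 4)) for l in labels}
            score = fitch_parsimony(tree, states).score
            assert len(set(states.values())) - 1 <= score <= len(labels) - 1

    def test_polytomy_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fitch_parsimony(parse_newick("(a,b,c);"), {"a": 1, "b": 1, "c": 2})

    def test_missing_tip_state_rejected(self):
        with pytest.raises(ValueError, match="b"):
            fitch_parsimony(parse_newick("((a,b),c);"), {"a": 1, "c": 2})

    def test_bulk_scorer_agrees_with_single(self, rng):
        labels = [f"t{i}" for i in range(10)]
        tree = random_binary_tree(labels, rng)
        mat = rng.integers(1, 6, size=(50, 10))
        bulk = fitch_scores_bulk(tree, mat, labels)
        singles = [
            fitch_parsimony(tree, dict(zip(labels, row))).score for row in mat
        ]
        assert bulk.tolist() == singles

    def test_agrees_with_phangorn(self, tmp_path):
        """Independent cross-check against R phangorn's Fitch scorer."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available")
        tree, states = datasets.load_atha_ggpps()
        (tmp_path / "t.nwk").write_text(write_newick(tree) + "\n")
        write_states(states, tmp_path / "s.tsv")
        rcode = """
        suppressMessages({library(ape); library(phangorn)})
        args <- commandArgs(trailingOnly=TRUE)
        tree <- read.tree(args[1])
        tab <- read.delim(args[2], stringsAsFactors=FALSE)
        states <- setNames(as.character(tab$state), tab$tip_label)
        m <- matrix(states[tree$tip.label], ncol=1,
                    dimnames=list(tree$tip.label, "c1"))
        pd <- phyDat(m, type="USER", levels=sort(unique(states)))
        cat(parsimony(tree, pd, method="fitch"))
        """
        out = subprocess.run(
            ["Rscript", "-e", rcode, str(tmp_path / "t.nwk"), str(tmp_path / "s.tsv")],
            capture_output=True,
            text=True,
            check=True,
        )
        assert int(out.stdout.strip()) == fitch_parsimony(tree, states).score


class TestAncestralReport:
    def test_uniform_states_unambiguous(self):
        tree = parse_newick("((a,b),(c,d));")
        res = fitch_parsimony(tree, {l: 3 for l in "abcd"})
        rep = ancestral_report(tree, res)
        assert not rep["ambiguous"].any()
        assert set(rep["states"]) == {"3"}

    def test_balanced_split_root_ambiguous(self):
        tree = parse_newick("((a,b),(c,d));")
        res = fitch_parsimony(tree, {"a": 1, "b": 1, "c": 2, "d": 2})
        assert res.root_states == frozenset({1, 2})
        rep = ancestral_report(tree, res).set_index("node")
        assert rep.loc["n2", "ambiguous"]

    def test_ggpps_root_state_is_ubiquitous(self):
        tree, states = datasets.load_atha_ggpps()
        res = fitch_parsimony(tree, states)
        assert res.root_states == frozenset({2})


class TestPermutation:
    def test_degenerate_multiset_p_one(self):
        tree = parse_newick("((a,b),(c,d));")
        res = permutation_test(tree, {l: 1 for l in "abcd"}, n=200, seed=3)
        assert res.observed == 0 and res.k == res.n and res.p == 1.0

    def test_printed_formula(self):
        # p = (1+k)/n
        tree, states = datasets.load_atha_ggpps()
        res = permutation_test(tree, states, n=500, seed=11)
        assert res.p == min(1.0, (1 + res.k) / res.n)
        alt = permutation_test(tree, states, n=500, seed=11, plus_one_denominator=True)
        assert alt.p == (1 + alt.k) / 501

    def test_same_seed_identical_null(self):
        tree, states = datasets.load_atha_ggpps()
        a = permutation_test(tree, states, n=300, seed=42)
        b = permutation_test(tree, states, n=300, seed=42)
        assert a.null_histogram == b.null_histogram and a.p == b.p

    def test_histogram_sums_to_n(self):
        tree, states = datasets.load_atha_ggpps()
        res = permutation_test(tree, states, n=777, seed=5)
        assert sum(res.null_histogram.values()) == 777

    def test_n_below_one_rejected(self):
        tree, states = datasets.load_atha_ggpps()
        with pytest.raises(ValueError):
            permutation_test(tree, states, n=0, seed=1)


class TestExactNull:
    def test_tiny_enumeration(self):
        tree = parse_newick("((a,b),c);")
        hist = exact_null(tree, {"a": 1, "b": 1, "c": 2})
        assert sum(hist.values()) == 3  # 3!/2! distinct assignments
        # the cherry (a,b) sharing state 1 costs 1; split arrangements cost... all cost 1
        assert hist == {1: 3}

    def test_minimum_is_states_minus_one(self):
        tree = parse_newick("((a,b),(c,d));")
        hist = exact_null(tree, {"a": 1, "b": 1, "c": 2, "d": 3})
        assert min(hist) == 2  # 3 distinct states

    def test_limit_enforced(self):
        tree, states = datasets.load_atha_ggpps()
        assert n_distinct_assignments(states) == 29_937_600
        with pytest.raises(ValueError, match="exceed"):
            exact_null(tree, states, limit=1000)

    def test_sampler_converges_to_exact_frequencies(self, rng):
        labels = [f"t{i}" for i in range(7)]
        tree = random_binary_tree(labels, rng)
        states = dict(zip(labels, [1, 1, 2, 2, 3, 3, 4]))
        hist = exact_null(tree, states)
        total = sum(hist.values())
        res = permutation_test(tree, states, n=20000, seed=7)
        for score, count in hist.items():
            p_exact = count / total
            se = np.sqrt(p_exact * (1 - p_exact) / res.n)
            p_hat = res.null_histogram.get(score, 0) / res.n
            assert abs(p_hat - p_exact) <= 4 * se + 1e-9


class TestStatesIO:
    def test_roundtrip(self, tmp_path):
        states = {"a": 1, "b/2": 5}
        write_states(states, tmp_path / "s.tsv")
        assert read_states(tmp_path / "s.tsv") == states
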