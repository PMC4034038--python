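"""Unordered-parsimony ancestral states and the permutation signal test.

Fitch's algorithm computes, for a strictly binary rooted tree with one
discrete character at the tips, the minimum number of unordered state
changes (all changes cost 1) and the set of most-parsimonious root states.
The bottom-up pass intersects child state sets (union + one step when the
intersection is empty); the top-down refinement of Swofford & Maddison
yields the full most-parsimonious reconstruction (MPR) set per node.

Phylogenetic signal is assessed by reshuffling the observed state multiset
uniformly among the tips ``n`` times, recomputing the score each time, and
reporting ``p = (1 + k) / n`` (capped at 1) where ``k`` counts replicates
with a score less than or equal to the observed one.  ``exact_null``
enumerates all distinct assignments instead, as an oracle for the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from pathlib import Path

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from ggfam.trees import GeneTree, Node

CharacterStates = dict[str, int]


def read_states(path: str | Path) -> CharacterStates:
    """Read a two-column TSV (tip_label, state); a header row is optional."""
    states: CharacterStates = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        if lineno == 1 and not parts[1].lstrip("-").isdigit():
            continue  # header
        states[parts[0]] = int(parts[1])
    return states


def write_states(states: CharacterStates, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tip_label\tstate\n")
        for tip, s in states.items():
            fh.write(f"{tip}\t{s}\n")


@dataclass
class FitchResult:
    score: int
    node_state_sets: dict[str, frozenset[int]]
    root_states: frozenset[int]


@dataclass
class PermutationResult:
    observed: int
    n: int
    k: int
    p: float
    seed: int
    null_histogram: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "n": self.n,
            "k": self.k,
            "p": self.p,
            "seed": self.seed,
            "null_histogram": {str(s): c for s, c in sorted(self.null_histogram.items())},
        }


def _check_tree_states(tree: GeneTree, states: CharacterStates) -> None:
    if not tree.is_binary():
        raise ValueError("Fitch parsimony requires a strictly binary tree "
                         "(resolve polytomies first)")
    missing = [l for l in tree.leaf_labels() if l not in states]
    if missing:
        raise ValueError(f"tips without a state: {missing}")


def fitch_parsimony(tree: GeneTree, states: CharacterStates) -> FitchResult:
    """Minimum-change score and per-node MPR state sets."""
    _check_tree_states(tree, states)
    ids = tree.node_ids()
    prelim: dict[int, frozenset[int]] = {}
    score = 0
    for node in tree.postorder():
        if node.is_leaf:
            prelim[id(node)] = frozenset([states[node.label]])
            continue
        a, b = (prelim[id(c)] for c in node.children)
        inter = a & b
        if inter:
            prelim[id(node)] = inter
        else:
            prelim[id(node)] = a | b
            score += 1

    # Swofford-Maddison downpass: final (MPR) sets
    final: dict[int, frozenset[int]] = {id(tree.root): prelim[id(tree.root)]}
    for node in tree.root.preorder():
        if node.is_leaf:
            continue
        fp = final[id(node)]
        for c in node.children:
            pc = prelim[id(c)]
            if c.is_leaf:
                final[id(c)] = pc
            elif pc & fp == fp:
                final[id(c)] = pc & fp
            else:
                ga, gb = (prelim[id(g)] for g in c.children)
                if ga & gb:
                    final[id(c)] = pc | (fp & (ga | gb))
                else:
                    final[id(c)] = pc | fp
    sets = {ids[k]: v for k, v in final.items()}
    return FitchResult(
        score=score, node_state_sets=sets, root_states=final[id(tree.root)]
    )


def _postorder_program(tree: GeneTree, tip_order: list[str]):
    """Compile the tree into (op, slot) instructions for the bulk scorer."""
    col = {t: i for i, t in enumerate(tip_order)}
    program = []  # (left_slot, right_slot, out_slot) over a register list
    slot_of: dict[int, int] = {}
    next_slot = len(tip_order)
    for node in tree.postorder():
        if node.is_leaf:
            slot_of[id(node)] = col[node.label]
        else:
            if len(node.children) != 2:
                raise ValueError("bulk Fitch scoring requires a binary tree")
            l, r = (slot_of[id(c)] for c in node.children)
            slot_of[id(node)] = next_slot
            program.append((l, r, next_slot))
            next_slot += 1
    return program, next_slot


def fitch_scores_bulk(
    tree: GeneTree, state_matrix: np.ndarray, tip_order: list[str]
) -> np.ndarray:
    """Fitch scores for many tip-state assignments at once.

    ``state_matrix`` is (replicates, n_tips), integer states in [0, 63],
    columns ordered as ``tip_order``.  Returns an int array of scores.
    """
    state_matrix = np.asarray(state_matrix)
    if state_matrix.ndim != 2 or state_matrix.shape[1] != len(tip_order):
        raise ValueError("state_matrix must be (replicates, n_tips)")
    if state_matrix.min() < 0 or state_matrix.max() > 63:
        raise ValueError("bulk scorer supports integer states in [0, 63]")
    program, n_slots = _postorder_program(tree, tip_order)
    regs: list[np.ndarray | None] = [None] * n_slots
    for i in range(len(tip_order)):
        regs[i] = np.uint64(1) << state_matrix[:, i].astype(np.uint64)
    score = np.zeros(state_matrix.shape[0], dtype=np.int64)
    for l, r, out in program:
        inter = regs[l] & regs[r]
        empty = inter == 0
        regs[out] = np.where(empty, regs[l] | regs[r], inter)
        score += empty
    return score


def permutation_test(
    tree: GeneTree,
    states: CharacterStates,
    n: int = 10000,
    seed: int = 0,
    plus_one_denominator: bool = False,
) -> PermutationResult:
    """Reshuffle the tip-state multiset among taxa and score each replicate.

    ``p = (1 + k) / n`` capped at 1.0, with ``k`` the number of replicates
    whose score is <= the observed score.  ``plus_one_denominator=True``
    switches to the conventional ``(1 + k) / (n + 1)`` estimator.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_tree_states(tree, states)
    tip_order = tree.leaf_labels()
    values = np.array([states[t] for t in tip_order])
    observed = int(fitch_scores_bulk(tree, values[None, :], tip_order)[0])
    rng = np.random.default_rng(seed)
    shuffled = rng.permuted(np.tile(values, (n, 1)), axis=1)
    scores = fitch_scores_bulk(tree, shuffled, tip_order)
    k = int((scores <= observed).sum())
    denom = n + 1 if plus_one_denominator else n
    p = min(1.0, (1 + k) / denom)
    uniq, counts = np.unique(scores, return_counts=True)
    return PermutationResult(
        observed=observed,
        n=n,
        k=k,
        p=p,
        seed=seed,
        null_histogram={int(s): int(c) for s, c in zip(uniq, counts)},
    )


def n_distinct_assignments(states: CharacterStates) -> int:
    values = list(states.values())
    total = factorial(len(values))
    for v in set(values):
        total //= factorial(values.count(v))
    return total


def exact_null(
    tree: GeneTree, states: CharacterStates, limit: int = 2_000_000
) -> dict[int, int]:
    """Exact score distribution over all distinct tip assignments.

    Enumerates every distinct permutation of the state multiset and scores
    it; frequencies sum to the multinomial count.  Errors when the
    enumeration would exceed ``limit`` (use :func:`permutation_test` then).
    """
    _check_tree_states(tree, states)
    total = n_distinct_assignments(states)
    if total > limit:
        raise ValueError(
            f"{total} distinct assignments exceed limit {limit}; "
            "sample with permutation_test instead"
        )
    tip_order = tree.leaf_labels()
    values = sorted(states[t] for t in tip_order)
    hist: dict[int, int] = {}
    chunk: list[list[int]] = []

    def flush():
        if not chunk:
            return
        scores = fitch_scores_bulk(tree, np.array(chunk), tip_order)
        for s, c in zip(*np.unique(scores, return_counts=True)):
            hist[int(s)] = hist.get(int(s), 0) + int(c)
        chunk.clear()

    for perm in multiset_permutations(values):
        chunk.append(perm)
        if len(chunk) >= 100_000:
            flush()
    flush()
    assert sum(hist.values()) == total
    return dict(sorted(hist.items()))


def ancestral_report(tree: GeneTree, result: FitchResult) -> pd.DataFrame:
    """Per-node table of MPR state sets; |set| > 1 is flagged ambiguous."""
    ids = tree.node_ids()
    rows = []
    for node in tree.postorder():
        ss = result.node_state_sets[ids[id(node)]]
        rows.append(
            {
                "node": ids[id(node)],
                "is_leaf": node.is_leaf,
                "states": ",".join(str(s) for s in sorted(ss)),
                "ambiguous": len(ss) > 1,
            }
        )
    return pd.DataFrame(rows, columns=["node", "is_leaf", "states", "ambiguous"])
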