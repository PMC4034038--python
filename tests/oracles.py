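"""Independent brute-force oracles used by the tests.

These deliberately avoid the implementation paths they check: alignment by
exhaustive enumeration of every global alignment; parsimony by exhaustive
minimization over all internal-node labelings.
"""

from __future__ import annotations

import itertools
from math import inf

import numpy as np

from ggfam.homology import ScoringMatrix
from ggfam.trees import GeneTree


def brute_force_align_score(a: str, b: str, matrix: ScoringMatrix) -> float:
    """Max score over every global alignment (affine: open + (L-1)*extend)."""
    best = -inf

    def rec(i: int, j: int, prev: str, acc: float):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + matrix.score(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "A", acc + (matrix.gap_extend if prev == "A" else matrix.gap_open))
        if j < len(b):
            rec(i, j + 1, "B", acc + (matrix.gap_extend if prev == "B" else matrix.gap_open))

    rec(0, 0, "", 0.0)
    return best


def _edge_changes(tree: GeneTree, labeling: dict[int, int]) -> int:
    changes = 0
    for node in tree.postorder():
        for c in node.children:
            if labeling[id(c)] != labeling[id(node)]:
                changes += 1
    return changes


def exhaustive_parsimony(tree: GeneTree, states: dict[str, int]) -> int:
    """Minimum changes over all internal labelings (vectorized enumeration)."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves()
    alphabet = sorted(set(states.values()))
    k, m = len(alphabet), len(internals)
    combos = np.array(list(itertools.product(range(k), repeat=m)))  # (k^m, m)
    idx = {id(n): i for i, n in enumerate(internals)}
    leaf_state = {id(l): alphabet.index(states[l.label]) for l in leaves}
    changes = np.zeros(len(combos), dtype=np.int64)
    for node in tree.postorder():
        if node.is_leaf:
            continue
        parent_col = combos[:, idx[id(node)]]
        for c in node.children:
            child_col = (
                np.full(len(combos), leaf_state[id(c)])
                if c.is_leaf
                else combos[:, idx[id(c)]]
            )
            changes += parent_col != child_col
    return int(changes.min())


def exhaustive_mpr_root_states(tree: GeneTree, states: dict[str, int]) -> set[int]:
    """States assignable to the root in at least one minimum-change labeling."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    alphabet = sorted(set(states.values()))
    best = None
    root_states: dict[int, int] = {}
    for combo in itertools.product(alphabet, repeat=len(internals)):
        labeling = {id(n): s for n, s in zip(internals, combo)}
        for l in tree.leaves():
            labeling[id(l)] = states[l.label]
        c = _edge_changes(tree, labeling)
        root_states[labeling[id(tree.root)]] = min(
            root_states.get(labeling[id(tree.root)], 10**9), c
        )
        best = c if best is None else min(best, c)
    return {s for s, c in root_states.items() if c == best}
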