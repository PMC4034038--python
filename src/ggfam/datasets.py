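"""Curated in-package dataset: the *A. thaliana* GGPPS paralog family.

The fixture encodes the twelve GGPPS paralogs of *Arabidopsis thaliana*
(GGPPS1-GGPPS12) with their developmental expression states.  The topology
is a transcription of the published paralog phylogeny reconstructed from
its textual description: GGPPS12 is the outermost paralog; GGPPS2+GGPPS11
and GGPPS3+GGPPS4 are WGD-derived sister pairs; GGPPS1 pairs with GGPPS8;
and the species-specific young paralogs GGPPS6, GGPPS7, GGPPS9 and GGPPS10
form a recent clade with GGPPS5 as its closest relative.

Expression states 1-8 discretize the developmental expression clusters:
GGPPS11 and GGPPS12 share the ubiquitous state 2; GGPPS5 and GGPPS8 share
one state (their profiles correlate above the clustering cutoff despite
sitting in distant clades); GGPPS9 and GGPPS10 share a clade-specific
state; GGPPS6 and GGPPS7 are measured by a single shared microarray
probeset (258121_s_at) and therefore carry one state.  The remaining
paralogs each occupy their own state.

``merged=True`` collapses the shared-probeset pair into a single
``GGPPS6/7`` terminal, as drawn in expression figures.
"""

from __future__ import annotations

from importlib import resources

from ggfam.parsimony import CharacterStates
from ggfam.trees import GeneTree, Node, parse_newick

MERGED_TIP = "GGPPS6/7"


def _data_text(name: str) -> str:
    return (resources.files("ggfam") / "data" / name).read_text()


def load_atha_ggpps(merged: bool = False) -> tuple[GeneTree, CharacterStates]:
    """The GGPPS paralog tree and expression states.

    By default the tree carries 12 tips (GGPPS1-GGPPS12, GGPPS6 and GGPPS7
    separate tips sharing one probeset-derived state).  With ``merged=True``
    the GGPPS6/GGPPS7 cherry collapses to one ``GGPPS6/7`` tip (11 tips).
    """
    tree = parse_newick(_data_text("atha_ggpps_tree.nwk"))
    states: CharacterStates = {}
    for line in _data_text("atha_ggpps_states.tsv").splitlines()[1:]:
        tip, state = line.split("\t")
        states[tip] = int(state)
    if merged:
        tree, states = _merge_cherry(tree, states, ("GGPPS6", "GGPPS7"), MERGED_TIP)
    return tree, states


def _merge_cherry(
    tree: GeneTree, states: CharacterStates, pair: tuple[str, str], new_label: str
) -> tuple[GeneTree, CharacterStates]:
    if states[pair[0]] != states[pair[1]]:
        raise ValueError("cannot merge tips with different states")
    out = tree.copy()
    for node in out.postorder():
        for i, c in enumerate(node.children):
            if (
                len(c.children) == 2
                and all(g.is_leaf for g in c.children)
                and {g.label for g in c.children} == set(pair)
            ):
                node.children[i] = Node(label=new_label, length=c.length)
    merged_states = {t: s for t, s in states.items() if t not in pair}
    merged_states[new_label] = states[pair[0]]
    return GeneTree(root=out.root), merged_states
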