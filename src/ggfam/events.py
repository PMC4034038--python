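"""Duplication/speciation inference and duplication-loss parsimony rooting.

Two complementary procedures:

* **Species overlap** — an internal node of a rooted gene tree is a
  duplication iff its two child subtrees share at least one species;
  otherwise it is a speciation.  No species phylogeny is assumed.
* **LCA reconciliation** — each gene-tree node maps to the last common
  ancestor (in a given species tree) of its descendant species; a node is a
  duplication iff it maps to the same species-tree node as one of its
  children, and gene losses are counted from the depth gaps along child
  edges.

Rooting tries every edge of the unrooted gene tree as a root position and
keeps the edge minimizing implied duplications (plus losses, when a species
tree is supplied).
"""

from __future__ import annotations

from dataclasses import dataclass

from ggfam.trees import Event, GeneTree, Node, SpeciesMap


def _species_set(node: Node, cache: dict[int, frozenset]) -> frozenset:
    if id(node) in cache:
        return cache[id(node)]
    if node.is_leaf:
        if node.species is None:
            raise ValueError(f"leaf {node.label!r} has no species assigned")
        s = frozenset([node.species])
    else:
        s = frozenset().union(*(_species_set(c, cache) for c in node.children))
    cache[id(node)] = s
    return s


def label_events(tree: GeneTree, species_map: SpeciesMap | None = None) -> GeneTree:
    """Label every internal node DUPLICATION or SPECIATION (species overlap).

    Mutates ``tree`` in place and returns it.  The tree must be strictly
    binary and every leaf must resolve to a species (via ``species_map`` or
    pre-assigned ``species`` attributes).
    """
    if species_map is not None:
        species_map.apply(tree)
    if not tree.is_binary():
        raise ValueError("species-overlap labeling requires a strictly binary tree")
    cache: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            node.event = Event.LEAF
            continue
        left, right = node.children
        overlap = _species_set(left, cache) & _species_set(right, cache)
        node.event = Event.DUPLICATION if overlap else Event.SPECIATION
    return tree


def count_duplications(tree: GeneTree) -> int:
    return sum(n.event is Event.DUPLICATION for n in tree.postorder())


def reconcile_lca(
    tree: GeneTree, species_tree: GeneTree
) -> tuple[int, int, dict[str, str]]:
    """LCA reconciliation of a rooted binary gene tree against a species tree.

    Returns ``(dup_count, loss_count, mapping)`` where ``mapping`` sends each
    gene-tree node id to the id of the species-tree node it maps to.  Losses
    are summed per child edge: for child ``c`` of ``v``,
    ``depth(M(c)) - depth(M(v)) - (0 if v is a duplication else 1)``.
    """
    if not tree.is_binary() or not species_tree.is_binary():
        raise ValueError("reconciliation requires binary trees")
    sp_parent: dict[int, Node | None] = {id(species_tree.root): None}
    sp_depth: dict[int, int] = {id(species_tree.root): 0}
    for n in species_tree.root.preorder():
        for c in n.children:
            sp_parent[id(c)] = n
            sp_depth[id(c)] = sp_depth[id(n)] + 1
    sp_leaf = {n.label: n for n in species_tree.leaves()}

    def lca(a: Node, b: Node) -> Node:
        ancestors = set()
        x = a
        while x is not None:
            ancestors.add(id(x))
            x = sp_parent[id(x)]
        x = b
        while id(x) not in ancestors:
            x = sp_parent[id(x)]
        return x

    gene_ids = tree.node_ids()
    sp_ids = species_tree.node_ids()
    mapping: dict[int, Node] = {}
    dup_count = 0
    loss_count = 0
    for node in tree.postorder():
        if node.is_leaf:
            if node.species is None:
                raise ValueError(f"leaf {node.label!r} has no species assigned")
            if node.species not in sp_leaf:
                raise ValueError(
                    f"species {node.species!r} (leaf {node.label!r}) missing "
                    "from the species tree"
                )
            mapping[id(node)] = sp_leaf[node.species]
            continue
        left, right = node.children
        m = lca(mapping[id(left)], mapping[id(right)])
        mapping[id(node)] = m
        is_dup = m is mapping[id(left)] or m is mapping[id(right)]
        if is_dup:
            dup_count += 1
        for c in (left, right):
            loss_count += sp_depth[id(mapping[id(c)])] - sp_depth[id(m)] - (
                0 if is_dup else 1
            )
    readable = {gene_ids[k]: sp_ids[id(v)] for k, v in mapping.items()}
    return dup_count, loss_count, readable


@dataclass
class RootingScore:
    edge_id: str
    dup_count: int
    loss_count: int
    chosen: bool = False

    @property
    def total(self) -> int:
        return self.dup_count + self.loss_count


def _unrooted_edges(tree: GeneTree):
    """Adjacency of the unrooted tree (degree-2 root suppressed) plus a
    deterministic, bipartition-sorted edge list."""
    t = tree.copy()
    nodes = {id(n): n for n in t.postorder()}
    adj: dict[int, set[int]] = {id(n): set() for n in t.postorder()}

    for n in t.postorder():
        for c in n.children:
            adj[id(n)].add(id(c))
            adj[id(c)].add(id(n))
    root = t.root
    if len(root.children) == 2:
        a, b = (id(c) for c in root.children)
        adj[a].discard(id(root))
        adj[b].discard(id(root))
        adj[a].add(b)
        adj[b].add(a)
        del adj[id(root)]
        del nodes[id(root)]

    def side_leaves(u: int, v: int) -> tuple[str, ...]:
        out = []
        stack = [(u, v)]
        while stack:
            x, parent = stack.pop()
            if nodes[x].is_leaf:
                out.append(nodes[x].label)
            for w in adj[x]:
                if w != parent:
                    stack.append((w, x))
        return tuple(sorted(out))

    edges = []
    seen = set()
    for u in adj:
        for v in adj[u]:
            key = frozenset((u, v))
            if key in seen:
                continue
            seen.add(key)
            left = side_leaves(u, v)
            right = side_leaves(v, u)
            small = min((len(left), left), (len(right), right))[1]
            edges.append((small, u, v, left, right))
    edges.sort(key=lambda e: (len(e[0]), e[0]))
    return nodes, adj, edges


def _root_at(nodes, adj, u: int, v: int) -> GeneTree:
    """Build the rooted tree for root position on edge (u, v)."""

    def min_leaf(x: int, parent: int) -> str:
        n = nodes[x]
        if n.is_leaf:
            return n.label
        return min(min_leaf(w, x) for w in adj[x] if w != parent)

    def build(x: int, parent: int) -> Node:
        n = nodes[x]
        kids = sorted((w for w in adj[x] if w != parent), key=lambda w: min_leaf(w, x))
        return Node(
            label=n.label if n.is_leaf else None,
            species=n.species,
            children=[build(w, x) for w in kids],
        )

    return GeneTree(root=Node(children=[build(u, v), build(v, u)]))


def root_by_parsimony(
    tree: GeneTree,
    species_map: SpeciesMap | None = None,
    species_tree: GeneTree | None = None,
) -> tuple[GeneTree, list[RootingScore]]:
    """Root a gene tree on the edge minimizing implied duplications (+ losses).

    Every edge of the unrooted tree is tried as a root position and scored by
    the species-overlap duplication count; when a species tree is supplied
    the LCA-reconciliation loss count is added.  Ties break by lowest
    duplication count, then lowest loss count, then smallest difference in
    leaf counts between the two sides of the root edge, then the canonical
    (bipartition-sorted) edge order.  Returns the winning rooted, labeled
    tree and the full audit list.
    """
    if tree.n_leaves < 3:
        raise ValueError("rooting needs at least 3 leaves")
    work = tree.copy()
    if species_map is not None:
        species_map.apply(work)
    else:
        for leaf in work.leaves():
            if leaf.species is None:
                leaf.species = SpeciesMap().resolve(leaf.label)
    nodes, adj, edges = _unrooted_edges(work)

    scored: list[tuple[RootingScore, GeneTree, int]] = []
    for idx, (small, u, v, left, right) in enumerate(edges):
        rooted = _root_at(nodes, adj, u, v)
        label_events(rooted)
        dups = count_duplications(rooted)
        losses = 0
        if species_tree is not None:
            dups, losses, _ = reconcile_lca(rooted, species_tree)
        score = RootingScore(edge_id=",".join(small), dup_count=dups, loss_count=losses)
        scored.append((score, rooted, abs(len(left) - len(right))))

    best = min(
        range(len(scored)),
        key=lambda i: (
            scored[i][0].dup_count,
            scored[i][0].loss_count,
            scored[i][2],
            i,
        ),
    )
    scored[best][0].chosen = True
    return scored[best][1], [s for s, _, _ in scored]
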