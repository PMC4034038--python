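"""Synthetic inputs with ground truth for every pipeline stage.

Four generators, all pure functions of (config, seed):

* :func:`simulate_family` — forward duplication-loss evolution of one gene
  lineage down a species tree (duplications as a Poisson process with rate
  λ per lineage per unit branch length, losses with rate μ; every surviving
  lineage bifurcates at each speciation).  Ground truth: per-node event
  labels, the true root edge of the unrooted gene tree, duplication and loss
  counts.
* :func:`simulate_architecture_set` — protein sequences with planted
  FARM/SARM/CxxxC/CxxxS motifs on a backbone that contains no D and no C,
  so planted truth is exact; optional point mutations (drawn from the full
  20-letter alphabet) outside motif spans can create spurious motifs.
* :func:`simulate_expression` — log2 expression with planted cluster
  structure: per-cluster center profiles drawn independently per sample,
  genes = center + Gaussian noise, clipped below at 0.
* :func:`simulate_characters` — a discrete character evolved down a tree:
  uniform root state, per-branch jump probability q to a uniformly chosen
  different state; full history and true change count recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ggfam.motifs import AMINO_ACIDS, ArchClass, ProteinSequence
from ggfam.trees import Event, GeneTree, Node
from ggfam.expression import ExpressionMatrix
from ggfam.parsimony import CharacterStates

# ---------------------------------------------------------------------------
# gene families by duplication-loss


@dataclass
class FamilySimConfig:
    species_tree: GeneTree  # binary, positive branch lengths
    dup_rate: float = 0.3
    loss_rate: float = 0.0
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        for n in self.species_tree.postorder():
            if n is not self.species_tree.root and (n.length is None or n.length <= 0):
                raise ValueError("species tree needs positive branch lengths")


@dataclass
class SimulatedFamily:
    gene_tree: GeneTree  # rooted, events set on internal nodes
    true_root_edge: frozenset[str]  # leaf bipartition: one side of the root edge
    n_dups: int
    n_losses: int

    @property
    def true_events(self) -> dict[str, Event]:
        ids = self.gene_tree.node_ids()
        return {
            ids[id(n)]: n.event
            for n in self.gene_tree.postorder()
            if not n.is_leaf
        }


class _Extinct(Exception):
    pass


def _evolve_branch(rng, node_spec: Node, t_remaining: float, cfg, counter, tally) -> Node | None:
    """One gene lineage evolving along the species-tree branch into
    ``node_spec``; returns the surviving (sub)tree or None."""
    lam, mu = cfg.dup_rate, cfg.loss_rate
    total = lam + mu
    t = rng.exponential(1.0 / total) if total > 0 else np.inf
    if t < t_remaining:
        if rng.random() < lam / total:  # duplication: two independent copies
            left = _evolve_branch(rng, node_spec, t_remaining - t, cfg, counter, tally)
            right = _evolve_branch(rng, node_spec, t_remaining - t, cfg, counter, tally)
            if left is None:
                return right
            if right is None:
                return left
            return Node(children=[left, right], event=Event.DUPLICATION, length=t)
        tally[0] += 1  # loss event: the lineage terminates here
        return None
    # reached the end of the species branch
    if node_spec.is_leaf:
        counter[node_spec.label] = counter.get(node_spec.label, 0) + 1
        return Node(
            label=f"{node_spec.label}_g{counter[node_spec.label]}",
            species=node_spec.label,
            event=Event.LEAF,
            length=t_remaining,
        )
    kids = []
    for child_spec in node_spec.children:
        sub = _evolve_branch(rng, child_spec, child_spec.length, cfg, counter, tally)
        if sub is not None:
            kids.append(sub)
    if not kids:
        return None
    if len(kids) == 1:  # the other side died out: splice through
        kids[0].length = (kids[0].length or 0.0) + t_remaining
        return kids[0]
    return Node(children=kids, event=Event.SPECIATION, length=t_remaining)


def simulate_family(cfg: FamilySimConfig) -> SimulatedFamily:
    """Evolve one ancestral gene lineage down the species tree.

    Retries (up to ``max_retries``) when the whole family goes extinct or
    fewer than 3 genes survive (an unrooted tree needs >= 3 leaves).
    """
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.max_retries):
        tally = [0]
        counter: dict[str, int] = {}
        root_spec = cfg.species_tree.root
        kids = []
        for child_spec in root_spec.children:
            sub = _evolve_branch(rng, child_spec, child_spec.length, cfg, counter, tally)
            if sub is not None:
                kids.append(sub)
        if not kids:
            continue
        root = kids[0] if len(kids) == 1 else Node(children=kids, event=Event.SPECIATION)
        if root.is_leaf:
            continue
        tree = GeneTree(root=root)
        if tree.n_leaves < 3:
            continue
        n_dups = sum(n.event is Event.DUPLICATION for n in tree.postorder())
        left_side = frozenset(root.children[0].leaf_labels())
        return SimulatedFamily(
            gene_tree=tree,
            true_root_edge=left_side,
            n_dups=n_dups,
            n_losses=tally[0],
        )
    raise RuntimeError(
        f"family extinct in {cfg.max_retries} attempts; lower loss_rate"
    )


# ---------------------------------------------------------------------------
# protein sequences with planted motif architectures

#: Backbone alphabet: the 20 amino acids minus D and C, so no spurious
#: aspartate-rich or cysteine motifs can arise outside the planted spans.
BACKBONE = sorted(AMINO_ACIDS - {"D", "C"})
_HYDRO = sorted("AVLIMFWP")
_ANY = sorted(AMINO_ACIDS - {"D", "C"})

#: Fixed, non-overlapping motif offsets used by the generator.
_LAYOUT = {"FARM": 10, "SARM": 40, "CC1": 60, "CC2": 80}
MIN_LENGTH = _LAYOUT["CC2"] + 5 + 5

_CLASS_MOTIFS: dict[ArchClass, list[str]] = {
    ArchClass.CANONICAL_GGPPS: ["FARM", "SARM", "CC1"],
    ArchClass.PH_PPPS: ["FARM", "SARM"],
    ArchClass.PH_GPS_GGPPS: ["FARM", "SARM", "CC1", "CS2"],
    ArchClass.PH_GPS: ["FARM", "SARM", "CC1", "CC2"],
    ArchClass.PH_SSUI: ["CC1", "CC2"],
    ArchClass.PH_SSUII: ["FARM", "CC1", "CC2"],
}


def _plant(rng, residues: list[str], motif: str) -> tuple[int, int]:
    if motif == "FARM":
        start = _LAYOUT["FARM"]
        pat = ["D", "D"] + [rng.choice(_ANY) for _ in range(4)] + ["D"]
    elif motif == "SARM":
        start = _LAYOUT["SARM"]
        pat = ["D", "D"] + [rng.choice(_ANY) for _ in range(2)] + ["D"]
    elif motif in ("CC1", "CC2"):
        start = _LAYOUT[motif]
        pat = ["C"] + [rng.choice(_HYDRO) for _ in range(3)] + ["C"]
    elif motif == "CS2":
        start = _LAYOUT["CC2"]
        pat = ["C"] + [rng.choice(_HYDRO) for _ in range(3)] + ["S"]
    else:
        raise AssertionError(motif)
    residues[start : start + len(pat)] = pat
    return start, start + len(pat)


def simulate_architecture_set(
    class_counts: dict[ArchClass, int],
    length: int = 120,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[ProteinSequence], pd.DataFrame]:
    """Generate proteins with planted motif architectures plus a truth table.

    At ``mutation_rate`` 0 the planted class is recovered exactly by the
    scanner.  Point mutations are applied outside motif spans, with the
    mutant residue drawn from the full 20-letter alphabet, so they can
    create spurious motifs but never destroy a planted one.
    """
    if length < MIN_LENGTH:
        raise ValueError(f"length must be >= {MIN_LENGTH} to host all motifs")
    if ArchClass.UNCLASSIFIED in class_counts:
        raise ValueError("cannot plant the UNCLASSIFIED class")
    rng = np.random.default_rng(seed)
    seqs: list[ProteinSequence] = []
    rows = []
    for klass in _CLASS_MOTIFS:  # deterministic enum order
        for i in range(class_counts.get(klass, 0)):
            residues = [str(rng.choice(BACKBONE)) for _ in range(length)]
            spans = [_plant(rng, residues, m) for m in _CLASS_MOTIFS[klass]]
            if mutation_rate > 0:
                in_motif = set()
                for s, e in spans:
                    in_motif.update(range(s, e))
                all_aa = sorted(AMINO_ACIDS)
                for pos in range(length):
                    if pos not in in_motif and rng.random() < mutation_rate:
                        residues[pos] = str(rng.choice(all_aa))
            sid = f"{klass.value}_{i + 1}"
            seqs.append(ProteinSequence(id=sid, residues="".join(residues)))
            rows.append(
                {
                    "sequence_id": sid,
                    "true_class": klass.value,
                    "motifs": ";".join(
                        f"{m}@{s}-{e}"
                        for m, (s, e) in zip(_CLASS_MOTIFS[klass], spans)
                    ),
                }
            )
    truth = pd.DataFrame(rows, columns=["sequence_id", "true_class", "motifs"])
    return seqs, truth


def write_fasta(seqs: list[ProteinSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}" + (f" {s.description}" if s.description else "") + "\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# expression matrices with planted clusters


@dataclass
class ExpressionSimConfig:
    n_clusters: int = 8
    genes_per_cluster: int = 2
    n_samples: int = 50
    center_mean: float = 7.0
    center_sd: float = 2.0
    within_noise_sd: float = 0.5
    detection_threshold: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.within_noise_sd <= 0:
            raise ValueError("within_noise_sd must be > 0")


def simulate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Planted-cluster log2 expression; returns (matrix, true labels 1..K)."""
    rng = np.random.default_rng(cfg.seed)
    centers = rng.normal(cfg.center_mean, cfg.center_sd, (cfg.n_clusters, cfg.n_samples))
    gene_ids, labels, rows = [], {}, []
    for c in range(cfg.n_clusters):
        for g in range(cfg.genes_per_cluster):
            gid = f"gene_c{c + 1}_{g + 1}"
            gene_ids.append(gid)
            labels[gid] = c + 1
            rows.append(
                np.clip(
                    centers[c] + rng.normal(0, cfg.within_noise_sd, cfg.n_samples),
                    0,
                    None,
                )
            )
    df = pd.DataFrame(
        np.array(rows),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"sample_{s + 1}" for s in range(cfg.n_samples)],
    )
    return (
        ExpressionMatrix(values=df, detection_threshold=cfg.detection_threshold),
        labels,
    )


# ---------------------------------------------------------------------------
# discrete characters on a tree


@dataclass
class CharacterSimConfig:
    tree: GeneTree
    k: int = 8
    q: float = 0.2  # per-branch change probability
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.q < 1:
            raise ValueError("q must be in [0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def simulate_characters(
    cfg: CharacterSimConfig,
) -> tuple[CharacterStates, dict[str, int], int]:
    """Evolve one discrete character down the tree.

    Returns (tip states, full node-state history, true change count).
    Parsimony on the tips is a lower bound on the true change count.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = cfg.tree.node_ids()
    history: dict[str, int] = {}
    n_changes = 0
    root_state = int(rng.integers(1, cfg.k + 1))

    def walk(node: Node, state: int):
        nonlocal n_changes
        history[ids[id(node)]] = state
        for c in node.children:
            s = state
            if rng.random() < cfg.q:
                others = [x for x in range(1, cfg.k + 1) if x != state]
                s = int(others[rng.integers(0, len(others))])
                n_changes += 1
            walk(c, s)

    walk(cfg.tree.root, root_state)
    tips = {l: history[l] for l in cfg.tree.leaf_labels()}
    return tips, history, n_changes
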