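"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/simulated/:
  proteins.faa + architecture_truth.tsv   planted motif architectures
  family_<i>.nwk + family_truth.tsv       duplication-loss gene families
  expression.tsv + expression_truth.tsv   planted expression clusters
  characters.tsv + characters_truth.json  a character evolved on the
                                          packaged GGPPS paralog tree
"""

import json
from pathlib import Path

import pandas as pd

from ggfam import datasets
from ggfam.motifs import ArchClass
from ggfam.simulate import (
    CharacterSimConfig,
    ExpressionSimConfig,
    FamilySimConfig,
    simulate_architecture_set,
    simulate_characters,
    simulate_expression,
    simulate_family,
    write_fasta,
)
from ggfam.parsimony import write_states
from ggfam.trees import parse_newick, write_newick

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)

# --- protein architectures: 20 sequences per class, light mutation noise
seqs, truth = simulate_architecture_set(
    {k: 20 for k in ArchClass if k is not ArchClass.UNCLASSIFIED},
    mutation_rate=0.02,
    seed=SEED,
)
write_fasta(seqs, OUT / "proteins.faa")
truth.to_csv(OUT / "architecture_truth.tsv", sep="\t", index=False)
print(f"wrote {len(seqs)} proteins across {truth['true_class'].nunique()} classes")

# --- gene families down a 5-species tree
species_tree = parse_newick("((A:1,B:1):1,((C:1,D:1):1,E:2):1);")
rows = []
for i in range(20):
    fam = simulate_family(
        FamilySimConfig(species_tree=species_tree, dup_rate=0.3, loss_rate=0.1, seed=SEED + i)
    )
    (OUT / f"family_{i}.nwk").write_text(
        write_newick(fam.gene_tree, include_events=True) + "\n"
    )
    rows.append(
        {"family": i, "n_leaves": fam.gene_tree.n_leaves,
         "n_dups": fam.n_dups, "n_losses": fam.n_losses}
    )
fam_truth = pd.DataFrame(rows)
fam_truth.to_csv(OUT / "family_truth.tsv", sep="\t", index=False)
print(
    f"wrote 20 families: {fam_truth['n_dups'].sum()} duplications, "
    f"{fam_truth['n_losses'].sum()} losses in total"
)

# --- expression with 8 planted clusters (the study's cluster count)
m, labels = simulate_expression(ExpressionSimConfig(seed=SEED))
m.values.to_csv(OUT / "expression.tsv", sep="\t")
pd.DataFrame(labels.items(), columns=["gene_id", "true_cluster"]).to_csv(
    OUT / "expression_truth.tsv", sep="\t", index=False
)
print(f"wrote expression matrix {m.values.shape} with 8 planted clusters")

# --- a discrete character on the packaged paralog tree
tree, _ = datasets.load_atha_ggpps()
tips, history, n_changes = simulate_characters(
    CharacterSimConfig(tree=tree, k=8, q=0.3, seed=SEED)
)
write_states(tips, OUT / "characters.tsv")
(OUT / "characters_truth.json").write_text(
    json.dumps({"true_changes": n_changes, "history": history}, indent=2) + "\n"
)
print(f"wrote simulated character with {n_changes} true changes")
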