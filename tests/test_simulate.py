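import numpy as np
import pytest

from ggfam.events import label_events
from ggfam.expression import cluster_profiles, pearson_distance
from ggfam.motifs import ArchClass, classify_architecture, find_motifs
from ggfam.parsimony import fitch_parsimony
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
from ggfam.trees import Event, parse_newick, write_newick
from ggfam.motifs import read_fasta


class TestFamily:
    def test_no_events_gives_congruent_tree(self, species_tree_5):
        fam = simulate_family(
            FamilySimConfig(species_tree=species_tree_5, dup_rate=0.0, loss_rate=0.0, seed=1)
        )
        assert fam.n_dups == 0 and fam.n_losses == 0
        assert sorted(fam.gene_tree.leaf_labels()) == [
            "A_g1", "B_g1", "C_g1", "D_g1", "E_g1",
        ]
        events = {n.event for n in fam.gene_tree.postorder() if not n.is_leaf}
        assert events == {Event.SPECIATION}

    def test_overlap_labeling_recovers_truth_at_zero_loss(self, species_tree_5):
        for seed in range(25):
            fam = simulate_family(
                FamilySimConfig(
                    species_tree=species_tree_5, dup_rate=0.4, loss_rate=0.0, seed=seed
                )
            )
            labeled = fam.gene_tree.copy()
            label_events(labeled)
            ids = labeled.node_ids()
            predicted = {
                ids[id(n)]: n.event for n in labeled.postorder() if not n.is_leaf
            }
            assert predicted == fam.true_events

    def test_fixed_seed_reproducible(self, species_tree_5):
        cfg = dict(species_tree=species_tree_5, dup_rate=0.5, loss_rate=0.2, seed=99)
        a = simulate_family(FamilySimConfig(**cfg))
        b = simulate_family(FamilySimConfig(**cfg))
        assert write_newick(a.gene_tree) == write_newick(b.gene_tree)
        assert a.n_losses == b.n_losses

    def test_duplications_scale_with_rate(self, species_tree_5):
        def mean_dups(rate, n=150):
            return np.mean(
                [
                    simulate_family(
                        FamilySimConfig(
                            species_tree=species_tree_5,
                            dup_rate=rate,
                            loss_rate=0.0,
                            seed=s,
                        )
                    ).n_dups
                    for s in range(n)
                ]
            )

        assert mean_dups(0.05) < mean_dups(0.6)

    def test_negative_rate_rejected(self, species_tree_5):
        with pytest.raises(ValueError):
            FamilySimConfig(species_tree=species_tree_5, dup_rate=-1)

    def test_extinction_errors_out(self, species_tree_5):
        with pytest.raises(RuntimeError, match="extinct"):
            simulate_family(
                FamilySimConfig(
                    species_tree=species_tree_5,
                    dup_rate=0.0,
                    loss_rate=50.0,
                    seed=0,
                    max_retries=5,
                )
            )


class TestArchitectures:
    def test_clean_plant_recovered_for_every_class(self):
        seqs, truth = simulate_architecture_set(
            {k: 4 for k in ArchClass if k is not ArchClass.UNCLASSIFIED}, seed=2
        )
        truth_map = dict(zip(truth["sequence_id"], truth["true_class"]))
        for s in seqs:
            got = classify_architecture(find_motifs(s))
            assert got.value == truth_map[s.id]

    def test_ssui_plant_structure(self):
        seqs, _ = simulate_architecture_set({ArchClass.PH_SSUI: 3}, seed=0)
        for s in seqs:
            hits = find_motifs(s)
            kinds = [h.kind.value for h in hits]
            assert kinds.count("CXXXC") == 2 and "FARM" not in kinds

    def test_mutated_recovery_rate_pinned(self):
        seqs, truth = simulate_architecture_set(
            {k: 20 for k in ArchClass if k is not ArchClass.UNCLASSIFIED},
            mutation_rate=0.02,
            seed=7,
        )
        truth_map = dict(zip(truth["sequence_id"], truth["true_class"]))
        rate = np.mean(
            [classify_architecture(find_motifs(s)).value == truth_map[s.id] for s in seqs]
        )
        assert rate >= 0.9  # regression floor measured once at this seed

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="length"):
            simulate_architecture_set({ArchClass.PH_PPPS: 1}, length=50)

    def test_fasta_roundtrip(self, tmp_path):
        seqs, _ = simulate_architecture_set({ArchClass.CANONICAL_GGPPS: 2}, seed=3)
        write_fasta(seqs, tmp_path / "x.faa")
        again = read_fasta(tmp_path / "x.faa")
        assert [(s.id, s.residues) for s in again] == [(s.id, s.residues) for s in seqs]


class TestExpression:
    def test_low_noise_recovery(self):
        m, labels = simulate_expression(
            ExpressionSimConfig(n_clusters=4, within_noise_sd=0.05, seed=1)
        )
        c = cluster_profiles(pearson_distance(m))
        assert c.n_clusters == 4
        partition = {}
        for g, lab in labels.items():
            partition.setdefault(c.assignment[g], set()).add(lab)
        assert all(len(v) == 1 for v in partition.values())

    def test_single_cluster(self):
        m, _ = simulate_expression(ExpressionSimConfig(n_clusters=1, seed=0))
        assert cluster_profiles(pearson_distance(m)).n_clusters == 1

    def test_values_clipped_at_zero(self):
        m, _ = simulate_expression(
            ExpressionSimConfig(center_mean=0.0, center_sd=3.0, seed=4)
        )
        assert (m.values.to_numpy() >= 0).all()

    def test_deterministic(self):
        a, _ = simulate_expression(ExpressionSimConfig(seed=8))
        b, _ = simulate_expression(ExpressionSimConfig(seed=8))
        assert a.values.equals(b.values)


class TestCharacters:
    def test_zero_rate_uniform_states(self, species_tree_5):
        tips, history, n_changes = simulate_characters(
            CharacterSimConfig(tree=species_tree_5, k=4, q=0.0, seed=1)
        )
        assert n_changes == 0 and len(set(tips.values())) == 1
        assert fitch_parsimony(species_tree_5, tips).score == 0

    def test_parsimony_is_lower_bound(self, species_tree_5):
        for seed in range(40):
            tips, _, n_changes = simulate_characters(
                CharacterSimConfig(tree=species_tree_5, k=6, q=0.4, seed=seed)
            )
            assert fitch_parsimony(species_tree_5, tips).score <= n_changes

    def test_invalid_q_rejected(self, species_tree_5):
        with pytest.raises(ValueError):
            CharacterSimConfig(tree=species_tree_5, q=1.0)
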