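import filecmp
from pathlib import Path

import numpy as np
import pytest

from viropan.synthetic_data import (
    DECOY_FAMILY,
    SimulationConfig,
    emit_hit_table,
    emit_proteomes,
    plant_clade_families,
    simulate_gene_content,
    simulate_tree,
    verify_truth,
    write_simulation,
)


class TestSimulateTree:
    def test_three_taxa_node_counts(self):
        tree = simulate_tree(3, seed=0)
        leaves = [n for n in tree.preorder_node_iter() if n.is_leaf()]
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 3 and len(internal) == 2

    def test_deterministic_per_seed(self):
        a = simulate_tree(18, seed=5).as_string(schema="newick")
        b = simulate_tree(18, seed=5).as_string(schema="newick")
        assert a == b

    def test_eighteen_taxa_binary_node_arithmetic(self):
        tree = simulate_tree(18, seed=1)
        nodes = list(tree.preorder_node_iter())
        assert sum(n.is_leaf() for n in nodes) == 18
        assert len(nodes) == 2 * 18 - 1

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="n_taxa"):
            simulate_tree(2, seed=0)


class TestGeneContent:
    def test_no_event_limit(self):
        cfg = SimulationConfig(n_taxa=6, n_families_root=20, gain_rate=0.0,
                               loss_rate=0.0, seed=3)
        tree = simulate_tree(6, 3)
        truth = simulate_gene_content(tree, cfg)
        root = truth.present_families(truth.root_label)
        for leaf in truth.leaf_labels():
            assert truth.present_families(leaf) == root
        assert all(g == l == 0 for g, l in truth.branch_events.values())

    def test_zero_loss_keeps_root_families_everywhere(self):
        cfg = SimulationConfig(n_taxa=8, n_families_root=30, gain_rate=0.1,
                               loss_rate=0.0, seed=4)
        truth = simulate_gene_content(simulate_tree(8, 4), cfg)
        root = truth.present_families(truth.root_label)
        for leaf in truth.leaf_labels():
            assert root <= truth.present_families(leaf)

    def test_ledger_replay_consistency(self):
        cfg = SimulationConfig(n_taxa=10, n_families_root=50, seed=9)
        truth = simulate_gene_content(simulate_tree(10, 9), cfg)
        verify_truth(truth)

    def test_event_rates_match_expectation_within_3_se(self):
        """Monte-Carlo check: pooled realized event frequency per
        opportunity, over 20 seeds, within 3 SE of 1 - exp(-rate)."""
        rate = 0.05
        p = 1.0 - np.exp(-rate)
        losses = gains = loss_opp = gain_opp = 0
        for seed in range(20):
            cfg = SimulationConfig(n_taxa=10, n_families_root=200,
                                   gain_rate=rate, loss_rate=rate, seed=seed)
            truth = simulate_gene_content(simulate_tree(10, seed), cfg)
            for node in truth.branch_gained:
                gains += len(truth.branch_gained[node])
                losses += len(truth.branch_lost[node])
                gain_opp += truth.gain_opportunities[node]
                loss_opp += truth.loss_opportunities[node]
        for events, opps in ((losses, loss_opp), (gains, gain_opp)):
            se = np.sqrt(p * (1 - p) / opps)
            assert abs(events / opps - p) < 3 * se

    def test_planted_families_keep_ledger_consistent(self):
        cfg = SimulationConfig(n_taxa=8, n_families_root=30, seed=2)
        tree = simulate_tree(8, 2)
        truth = simulate_gene_content(tree, cfg)
        clade = tree.seed_node.child_nodes()[0]
        fams = plant_clade_families(truth, clade.label, 2, kind="hallmark")
        anti = plant_clade_families(truth, clade.label, 2, kind="anti")
        verify_truth(truth)
        inside = {n.label for n in clade.preorder_iter() if n.is_leaf()}
        for f in fams:
            for leaf in truth.leaf_labels():
                assert (truth.ancestral_contents[leaf][f] == 1) == (leaf in inside)
        for f in anti:
            for leaf in truth.leaf_labels():
                assert (truth.ancestral_contents[leaf][f] == 1) == (leaf not in inside)


class TestProteomes:
    def test_zero_divergence_gives_identical_members(self):
        cfg = SimulationConfig(n_taxa=5, n_families_root=10,
                               within_family_divergence=0.0, seed=6)
        truth = simulate_gene_content(simulate_tree(5, 6), cfg)
        proteomes = emit_proteomes(truth, cfg)
        by_fam = {}
        for recs in proteomes.values():
            for r in recs:
                by_fam.setdefault(truth.protein_family[r.id], set()).add(r.residues)
        assert all(len(s) == 1 for s in by_fam.values())

    def test_absent_family_emits_no_protein(self, small_sim):
        cfg, truth, proteomes, _, _ = small_sim
        for taxon, recs in proteomes.items():
            fams = {truth.protein_family[r.id] for r in recs}
            assert fams == truth.present_families(taxon)

    def test_within_family_identity_exceeds_between(self, small_sim):
        cfg, truth, proteomes, _, _ = small_sim
        seqs = {r.id: r.residues for recs in proteomes.values() for r in recs}
        pids = sorted(seqs)

        def ident(a, b):
            sa, sb = seqs[a], seqs[b]
            n = min(len(sa), len(sb))
            return sum(x == y for x, y in zip(sa[:n], sb[:n])) / n

        within, between = [], []
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b = rng.choice(pids, 2, replace=False)
            fam_a, fam_b = truth.protein_family[a], truth.protein_family[b]
            (within if fam_a == fam_b else between).append(ident(a, b))
        if within and between:
            assert min(within) > max(between)

    def test_decoys_below_length_filter(self):
        cfg = SimulationConfig(n_taxa=4, n_families_root=10,
                               decoy_fraction=0.2, seed=8)
        truth = simulate_gene_content(simulate_tree(4, 8), cfg)
        proteomes = emit_proteomes(truth, cfg)
        decoys = [
            r for recs in proteomes.values() for r in recs
            if truth.protein_family[r.id] == DECOY_FAMILY
        ]
        assert decoys and all(len(r) < 100 for r in decoys)


class TestHitTable:
    def test_noise_free_hits_restricted_to_families(self, small_sim):
        cfg, truth, proteomes, allvall, _ = small_sim
        for h in allvall:
            if h.query_id != h.subject_id:
                assert (
                    truth.protein_family[h.query_id]
                    == truth.protein_family[h.subject_id]
                )

    def test_self_hits_and_identical_sequences_at_100(self, small_sim):
        cfg, truth, proteomes, allvall, _ = small_sim
        pids = {r.id for recs in proteomes.values() for r in recs}
        selfs = {h.query_id for h in allvall if h.query_id == h.subject_id}
        assert selfs == pids
        for h in allvall:
            if h.query_id == h.subject_id:
                assert h.pct_identity == 100.0

    def test_bit_score_increases_with_identity_at_fixed_length(self, small_sim):
        cfg, truth, proteomes, allvall, _ = small_sim
        by_len = {}
        for h in allvall:
            by_len.setdefault(h.aln_length, []).append(h)
        checked = 0
        for hits in by_len.values():
            hits = sorted(hits, key=lambda h: h.pct_identity)
            for a, b in zip(hits, hits[1:]):
                if b.pct_identity > a.pct_identity:
                    assert b.bit_score > a.bit_score
                    assert b.evalue < a.evalue
                    checked += 1
        assert checked > 0

    def test_spurious_hits_are_sub_threshold(self):
        cfg = SimulationConfig(n_taxa=6, n_families_root=30,
                               spurious_hit_rate=0.05, seed=11)
        truth = simulate_gene_content(simulate_tree(6, 11), cfg)
        proteomes = emit_proteomes(truth, cfg)
        hits = emit_hit_table(proteomes, truth, cfg)
        spurious = [
            h for h in hits
            if truth.protein_family[h.query_id] != truth.protein_family[h.subject_id]
        ]
        assert spurious
        for h in spurious:
            assert h.pct_identity < 20.0 and h.evalue > 1e-5


class TestDeterminism:
    def test_identical_config_gives_byte_identical_bundle(self, tmp_path):
        cfg = SimulationConfig(n_taxa=5, n_families_root=15,
                               spurious_hit_rate=0.02, seed=13)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_simulation(d1, cfg)
        write_simulation(d2, cfg)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel
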