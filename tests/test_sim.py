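"""Simulator: species trees, birth--death gene families, sequence evolution,
functional decay, and fixture round-trips."""

import math
import os

import numpy as np
import pytest

from lygevol import sim
from lygevol.trees import Tree, topologies_equal


class TestSpeciesTree:
    def test_two_species_is_an_ultrametric_cherry(self):
        t = sim.simulate_species_tree(2, 1.0, seed=1)
        assert len(t.leaves()) == 2
        assert t.is_binary()
        a, b = t.leaves()
        assert a.depth() == pytest.approx(b.depth())

    def test_deterministic_under_fixed_seed(self):
        a = sim.simulate_species_tree(8, 1.0, seed=7)
        b = sim.simulate_species_tree(8, 1.0, seed=7)
        assert a.to_newick() == b.to_newick()

    def test_rejects_fewer_than_two_species(self):
        with pytest.raises(ValueError):
            sim.simulate_species_tree(1, 1.0, seed=0)

    def test_yule_shape_frequencies_match_enumeration_at_n4(self):
        # under the Yule process all labelled histories are equiprobable, so
        # the balanced 4-leaf shape has probability exactly 1/3
        balanced = 0
        n = 1000
        for s in range(n):
            t = sim.simulate_species_tree(4, 1.0, seed=s)
            sizes = sorted(len(c.leaf_names()) for c in t.root.children)
            balanced += sizes == [2, 2]
        p_hat = balanced / n
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(p_hat - 1 / 3) < 4 * se

    def test_packaged_vertebrate_tree_is_valid(self):
        t = sim.vertebrate_species_tree()
        t.validate_species_tree()
        assert t.is_ultrametric(1e-6)
        assert "amniote_ancestor" in [n.name for n in t.preorder()]


class TestGeneFamily:
    def test_zero_rates_reproduce_species_tree(self):
        st = sim.simulate_species_tree(6, 1.0, seed=3)
        gt, history = sim.simulate_gene_family(st, 0.0, 0.0, seed=1)
        renamed = st.copy()
        for lf in renamed.leaves():
            lf.name += "_1"
        assert topologies_equal(renamed, gt)
        assert history.n_duplications == 0
        assert history.n_losses == 0

    def test_loss_only_gives_at_most_one_copy_per_species(self):
        st = sim.simulate_species_tree(6, 1.0, seed=3)
        for s in range(20):
            gt, history = sim.simulate_gene_family(st, 0.0, 0.5, seed=s)
            counts = {}
            for g, sp in getattr(gt, "leaf_map", {}).items():
                counts[sp] = counts.get(sp, 0) + 1
            assert all(c == 1 for c in counts.values())
            assert history.n_duplications == 0

    def test_gene_tree_lengths_are_time_consistent(self):
        st = sim.simulate_species_tree(6, 1.0, seed=3)
        depth = st.root.max_leaf_distance()
        for s in range(10):
            gt, _ = sim.simulate_gene_family(st, 0.3, 0.1, seed=s)
            if gt.root.is_leaf:
                continue
            for lf in gt.leaves():
                assert lf.depth() <= depth + 1e-9

    def test_copy_number_matches_birth_death_expectation(self):
        # single branch of length 2: E[N] = exp((lambda - mu) T)
        st = Tree.from_newick("(a:2.0,b:2.0)r;")
        lam, mu, T = 0.3, 0.1, 2.0
        counts = []
        for s in range(1000):
            gt, _ = sim.simulate_gene_family(st, lam, mu, seed=s)
            lm = getattr(gt, "leaf_map", {})
            counts.append(sum(1 for sp in lm.values() if sp == "a"))
        mean = np.mean(counts)
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(mean - math.exp((lam - mu) * T)) < 3 * se


class TestSequenceEvolution:
    def test_rate_zero_copies_root_sequence(self):
        st = sim.simulate_species_tree(4, 1.0, seed=2)
        gt, _ = sim.simulate_gene_family(st, 0.0, 0.0, seed=0)
        seqs = sim.evolve_sequences(gt, "ACDEFG", rate=0.0, seed=0)
        assert all(s == "ACDEFG" for s in seqs.values())

    def test_conserved_sites_frozen_at_factor_zero(self):
        st = sim.simulate_species_tree(4, 1.0, seed=2)
        gt, _ = sim.simulate_gene_family(st, 0.0, 0.0, seed=0)
        root = sim.DEFAULT_ROOT_SEQUENCE
        seqs = sim.evolve_sequences(
            gt, root, rate=2.0, conserved_sites=sim.DEFAULT_CATALYTIC_INDICES,
            conserved_rate_factor=0.0, seed=4,
        )
        for s in seqs.values():
            for i in sim.DEFAULT_CATALYTIC_INDICES:
                assert s[i] == root[i]

    def test_out_of_bounds_conserved_site_rejected(self):
        st = sim.simulate_species_tree(4, 1.0, seed=2)
        gt, _ = sim.simulate_gene_family(st, 0.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            sim.evolve_sequences(gt, "ACDE", 0.1, conserved_sites={10}, seed=0)

    def test_divergence_follows_20_state_poisson_expectation(self):
        # two leaves separated by total path 2t; p = (19/20)(1 - e^{-(20/19) 2t r})
        st = Tree.from_newick("(a:1.0,b:1.0)r;")
        gt, _ = sim.simulate_gene_family(st, 0.0, 0.0, seed=0)
        L = 2000
        rate = 0.2
        root = "".join(
            np.random.default_rng(5).choice(list(sim.AMINO_ACIDS), size=L)
        )
        seqs = sim.evolve_sequences(gt, root, rate=rate, seed=9)
        a, b = seqs.values()
        p_obs = sum(x != y for x, y in zip(a, b)) / L
        p_exp = (19 / 20) * (1 - math.exp(-(20 / 19) * 2 * rate))
        se = math.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 4 * se

    def test_bit_reproducible(self):
        st = sim.simulate_species_tree(5, 1.0, seed=2)
        gt, _ = sim.simulate_gene_family(st, 0.2, 0.05, seed=3)
        s1 = sim.evolve_sequences(gt, sim.DEFAULT_ROOT_SEQUENCE, 0.5, seed=11)
        s2 = sim.evolve_sequences(gt, sim.DEFAULT_ROOT_SEQUENCE, 0.5, seed=11)
        assert s1 == s2


class TestFunctionalDecay:
    def _family(self, seed, dup=0.25, loss=0.05):
        st = sim.simulate_species_tree(8, 1.0, seed=seed)
        gt, history = sim.simulate_gene_family(st, dup, loss, seed=seed)
        seqs = (
            sim.evolve_sequences(
                gt, sim.DEFAULT_ROOT_SEQUENCE, 0.3,
                conserved_sites=sim.DEFAULT_CATALYTIC_INDICES,
                conserved_rate_factor=0.0, seed=seed,
            )
            if not gt.root.is_leaf or gt.root.name != "empty"
            else {}
        )
        return sim.SimulatedFamily(
            species_tree=st, gene_tree=gt, history=history,
            leaf_map=dict(getattr(gt, "leaf_map", {})), sequences=seqs,
        )

    def test_zero_probabilities_change_nothing(self):
        fam = self._family(1)
        before = dict(fam.sequences)
        sim.inject_functional_decay(fam, 0.0, 0.0, seed=0)
        assert fam.sequences == before
        assert not any(fam.catalytic_decayed.values())
        assert all(fam.signal_present.values())

    def test_probability_one_with_single_duplication_degrades_one_daughter(self):
        # hand-built family: one duplication, two species, both daughters survive
        st = Tree.from_newick("(a:1.0,b:1.0)r;")
        gt = Tree.from_newick("((a_1:1.0,b_1:1.0):0.1,(a_2:1.0,b_2:1.0):0.1)d1;")
        gt.root.name = None
        inner = gt.root
        # name the duplication node as the simulator would
        dup = Tree.from_newick("((a_1:1.0,b_1:1.0):0.1,(a_2:1.0,b_2:1.0):0.1);")
        dup.root.name = "d1"
        fam = sim.SimulatedFamily(
            species_tree=st, gene_tree=dup, history=sim.EventHistory(),
            leaf_map={"a_1": "a", "b_1": "b", "a_2": "a", "b_2": "b"},
            sequences={g: sim.DEFAULT_ROOT_SEQUENCE for g in ["a_1", "b_1", "a_2", "b_2"]},
        )
        sim.inject_functional_decay(fam, 1.0, 1.0, seed=0)
        degraded = {g for g, v in fam.catalytic_decayed.items() if v}
        assert degraded in ({"a_1", "b_1"}, {"a_2", "b_2"})
        i73 = sim.DEFAULT_CATALYTIC_INDICES[0]
        for g in degraded:
            assert not fam.signal_present[g]
            assert fam.sequences[g][i73 - fam.signal_length] == "Q"
        for g in {"a_1", "b_1", "a_2", "b_2"} - degraded:
            assert fam.signal_present[g]
            assert fam.sequences[g][i73] == "E"

    def test_compensation_invariant_holds_exhaustively(self):
        # every species with a degraded copy retains an intact copy, in every
        # replicate, by construction
        for s in range(100):
            fam = self._family(s)
            sim.inject_functional_decay(fam, 0.5, 0.3, seed=s)
            for sp in set(fam.leaf_map.values()):
                copies = fam.copies_of(sp)
                if any(fam.catalytic_decayed[g] for g in copies):
                    assert any(not fam.catalytic_decayed[g] for g in copies)

    def test_rejects_bad_probability(self):
        fam = self._family(1)
        with pytest.raises(ValueError):
            sim.inject_functional_decay(fam, 1.5, 0.0, seed=0)


class TestFixtureIO:
    def test_round_trip(self, tmp_path):
        fam = sim.simulate_family(4)
        paths = sim.write_fixture(fam, tmp_path)
        back = sim.read_fixture(tmp_path)
        assert back.sequences == fam.sequences
        assert back.leaf_map == fam.leaf_map
        assert back.gene_tree.to_newick() == fam.gene_tree.to_newick()
        assert back.species_tree.to_newick() == fam.species_tree.to_newick()
        assert back.catalytic_decayed == fam.catalytic_decayed
        assert back.signal_present == fam.signal_present
        assert len(back.history.events) == len(fam.history.events)

    def test_fasta_headers_match_gene_tree_leaves(self, tmp_path):
        fam = sim.simulate_family(4)
        paths = sim.write_fixture(fam, tmp_path)
        from lygevol.align import read_fasta

        headers = set(read_fasta(paths["sequences"]))
        assert headers == set(fam.gene_tree.leaf_names())

    def test_event_table_counts_every_event(self, tmp_path):
        fam = sim.simulate_family(4)
        paths = sim.write_fixture(fam, tmp_path)
        import pandas as pd

        df = pd.read_csv(paths["events"], sep="\t")
        h = fam.history
        assert len(df) == len(h.events)
        assert (df["kind"] == "duplication").sum() == h.n_duplications
        assert (df["kind"] == "loss").sum() == h.n_losses
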