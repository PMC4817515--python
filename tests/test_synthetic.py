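"""Simulator: strain trees, gain/loss pangenomes, dataset emission."""

import json

import numpy as np
import pytest
from skbio import TreeNode

from pancog.core_model import read_fasta, write_newick
from pancog.synthetic import (
    ParameterError,
    SimulationParams,
    emit_dataset,
    load_dataset,
    simulate_dataset,
    simulate_pangenome,
    simulate_strain_tree,
)


# ---------------------------------------------------------------------------
# strain tree


class TestStrainTree:
    def test_cherry(self):
        t = simulate_strain_tree(2, seed=0)
        tips = list(t.tips())
        assert len(tips) == 2
        assert all(x.length > 0 for x in tips)

    def test_determinism(self):
        a = write_newick(simulate_strain_tree(7, seed=5))
        b = write_newick(simulate_strain_tree(7, seed=5))
        assert a == b

    def test_rejects_single_genome(self):
        with pytest.raises(ParameterError):
            simulate_strain_tree(1, seed=0)

    def test_pure_birth_depth_expectation(self):
        """Mean root-to-tip depth matches an independent Yule simulation."""
        n, reps = 10, 300

        def independent_mean_depth(seed):
            # waiting times only: depth = sum over k of Exp(1/k) epochs the
            # lineage lives through; every tip shares every epoch, so depth
            # = sum_{k=2}^{n-1} wait_k + final wait at k=n (the first epoch
            # precedes the root and carries no branch)
            r = np.random.default_rng(seed)
            total = 0.0
            for k in range(2, n):
                total += r.exponential(1 / k)
            total += r.exponential(1 / n)
            return total

        ours = np.mean([
            np.mean([t.accumulate_to_ancestor(t.root())
                     for t in simulate_strain_tree(n, seed=s).tips()])
            for s in range(reps)
        ])
        theirs = np.mean([independent_mean_depth(10_000 + s) for s in range(reps)])
        # both are Monte-Carlo means of the same expectation
        assert ours == pytest.approx(theirs, abs=0.12)

    def test_leaf_count_exact(self):
        for n in (2, 5, 17):
            assert sum(1 for _ in simulate_strain_tree(n, seed=1).tips()) == n


# ---------------------------------------------------------------------------
# pangenome simulation


def _flat_tree(n, length):
    """Balanced-ish manual tree with fixed branch lengths."""
    nodes = [TreeNode(name=f"G{i+1:02d}", length=length) for i in range(n)]
    while len(nodes) > 1:
        b = nodes.pop()
        a = nodes.pop()
        p = TreeNode(length=length)
        p.extend([a, b])
        nodes.append(p)
    root = nodes[0]
    root.length = None
    i = 0
    for node in root.preorder():
        if not node.is_tip():
            node.name = f"N{i}"
            i += 1
    return root


class TestPangenome:
    def test_no_accessory_genome(self):
        tree = simulate_strain_tree(5, seed=3)
        params = SimulationParams(n_genomes=5, n_core_root=30, gain_rate=0.0,
                                  loss_rate=0.0, subst_rate=0.01, seed=3,
                                  duplication_prob=0.0, mean_protein_len=80)
        prots, truth = simulate_pangenome(tree, params)
        matrix = truth.presence_matrix()
        assert matrix.n_families == 30
        assert len(matrix.core_family_ids()) == 30
        assert all(len(p) == 30 for p in prots)

    def test_zero_branch_lengths_identical_genomes(self):
        tree = _flat_tree(4, 0.0)
        params = SimulationParams(n_genomes=4, n_core_root=20, gain_rate=5.0,
                                  loss_rate=1.0, subst_rate=5.0, seed=1,
                                  duplication_prob=0.0, mean_protein_len=80)
        prots, _ = simulate_pangenome(tree, params)
        ref = sorted(g.protein_seq for g in prots[0].genes)
        for p in prots[1:]:
            assert sorted(g.protein_seq for g in p.genes) == ref

    def test_mean_families_matches_expectation(self):
        """Mean family count per leaf equals the branch-sum expectation."""
        tree = _flat_tree(10, 0.25)
        g, loss = 5.0, 0.2

        # independent enumeration: every leaf of the balanced tree carries
        # core families surviving its root path plus branch gains
        # discounted by the loss hazard over the remaining path
        expected = {}
        for leaf in tree.tips():
            path = []
            node = leaf
            while node.parent is not None:
                path.append(node)
                node = node.parent
            depth = sum(x.length for x in path)
            e = 40 * np.exp(-loss * depth)
            below = 0.0
            for x in path:
                below += x.length  # distance from x (gain point) down to leaf
                e += g * x.length * np.exp(-loss * (below - x.length))
            expected[leaf.name] = e

        reps = 150
        sums = {k: 0.0 for k in expected}
        for s in range(reps):
            params = SimulationParams(n_genomes=10, n_core_root=40, gain_rate=g,
                                      loss_rate=loss, subst_rate=0.0, seed=s,
                                      duplication_prob=0.0, hgt_fraction=0.0,
                                      mean_protein_len=60)
            prots, truth = simulate_pangenome(tree, params)
            for p in prots:
                sums[p.genome_id] += len({truth.family_of_gene[x.gene_id]
                                          for x in p.genes})
        for leaf, e in expected.items():
            assert sums[leaf] / reps == pytest.approx(e, rel=0.06)

    def test_dollo_consistency_of_truth(self, small_dataset):
        """Leaf possession exactly equals the gain-ancestor/no-loss rule."""
        proteomes, truth = small_dataset
        matrix = truth.presence_matrix()
        for fid in matrix.family_ids:
            for leaf in matrix.genome_ids:
                assert matrix.cells.loc[fid, leaf] == truth.leaf_possesses(fid, leaf)

    def test_seed_determinism(self):
        params = SimulationParams(n_genomes=4, n_core_root=15, seed=21,
                                  hgt_fraction=0.1, mean_protein_len=70)
        p1, t1 = simulate_dataset(params)
        p2, t2 = simulate_dataset(params)
        assert [(g.gene_id, g.protein_seq, g.nucleotide_seq)
                for p in p1 for g in p.genes] == \
               [(g.gene_id, g.protein_seq, g.nucleotide_seq)
                for p in p2 for g in p.genes]
        assert write_newick(t1.tree) == write_newick(t2.tree)

    def test_gain_rate_monotonicity(self):
        """Higher gain rate strictly increases mean pan-genome size."""
        def mean_pan(gain):
            sizes = []
            for s in range(8):
                params = SimulationParams(n_genomes=6, n_core_root=20,
                                          gain_rate=gain, loss_rate=0.2,
                                          subst_rate=0.0, seed=s,
                                          mean_protein_len=60)
                _, truth = simulate_dataset(params)
                sizes.append(truth.presence_matrix().n_families)
            return np.mean(sizes)

        assert mean_pan(4.0) > mean_pan(1.0)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            SimulationParams(n_genomes=1)
        with pytest.raises(ParameterError):
            SimulationParams(hgt_fraction=1.0)
        with pytest.raises(ParameterError):
            SimulationParams(alien_gc=0.0)
        with pytest.raises(ParameterError):
            SimulationParams(gain_rate=-1)


# ---------------------------------------------------------------------------
# emission / reload


@pytest.fixture(scope="module")
def tiny():
    params = SimulationParams(n_genomes=3, n_core_root=10, gain_rate=1.0,
                              loss_rate=0.1, subst_rate=0.01, seed=4,
                              hgt_fraction=0.1, mean_protein_len=70)
    return simulate_dataset(params)


class TestEmit:
    def test_file_inventory(self, tiny, tmp_path):
        prots, truth = tiny
        written = emit_dataset(prots, truth, tmp_path / "d")
        names = sorted(p.name for p in written)
        assert sum(n.endswith((".faa", ".fna")) for n in names) == 6
        assert "annotation.tsv" in names and "truth.json" in names

    def test_refuses_nonempty_dir(self, tiny, tmp_path):
        prots, truth = tiny
        out = tmp_path / "d"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            emit_dataset(prots, truth, out)
        emit_dataset(prots, truth, out, force=True)  # force overrides

    def test_reload_roundtrip(self, tiny, tmp_path):
        prots, truth = tiny
        emit_dataset(prots, truth, tmp_path / "d")
        prots2, truth2 = load_dataset(tmp_path / "d")
        orig = {g.gene_id: (g.protein_seq, g.nucleotide_seq)
                for p in prots for g in p.genes}
        back = {g.gene_id: (g.protein_seq, g.nucleotide_seq)
                for p in prots2 for g in p.genes}
        assert orig == back
        assert truth2.family_of_gene == truth.family_of_gene
        assert truth2.hgt_gene_ids == truth.hgt_gene_ids

    def test_truth_family_sizes_match_fasta(self, tmp_path):
        """Truth-table family sizes equal counts derived from the FASTAs."""
        for seed in range(20):
            params = SimulationParams(n_genomes=3, n_core_root=8, gain_rate=1.0,
                                      loss_rate=0.2, subst_rate=0.01, seed=seed,
                                      mean_protein_len=60)
            prots, truth = simulate_dataset(params)
            out = tmp_path / f"d{seed}"
            emit_dataset(prots, truth, out)
            payload = json.loads((out / "truth.json").read_text())
            fasta_genes = [r.id for f in sorted(out.glob("*.faa"))
                           for r in read_fasta(f, "protein")]
            sizes_from_fasta = {}
            for gid in fasta_genes:
                fam = payload["family_of_gene"][gid]
                sizes_from_fasta[fam] = sizes_from_fasta.get(fam, 0) + 1
            truth_sizes = {}
            for gid, fam in truth.family_of_gene.items():
                truth_sizes[fam] = truth_sizes.get(fam, 0) + 1
            assert sizes_from_fasta == truth_sizes
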