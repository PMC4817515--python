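"""Dollo-parsimony gain/loss reconstruction and per-node summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from pancog.core_model import AnnotationTable, PresenceAbsenceMatrix, parse_newick
from pancog.gainloss import (
    DolloReconstruction,
    GainLossThresholds,
    dollo_reconstruct,
    family_labels_by_majority,
    node_acquisition_summary,
)


def _name(tree):
    i = 0
    for node in tree.preorder():
        if not node.is_tip():
            node.name = f"N{i}"
            i += 1
    return tree


def _matrix(patterns, genomes):
    """patterns: family -> iterable of possessing genomes."""
    df = pd.DataFrame(False, index=sorted(patterns), columns=genomes)
    for fam, who in patterns.items():
        for g in who:
            df.loc[fam, g] = True
    return PresenceAbsenceMatrix(df)


@pytest.fixture()
def five_leaf_tree():
    return _name(parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);"))


class TestDolloBasics:
    def test_family_in_all_leaves_gains_at_root(self, five_leaf_tree):
        m = _matrix({"f": "ABCDE"}, list("ABCDE"))
        recon = dollo_reconstruct(five_leaf_tree, m)
        assert recon.gain_node["f"] == five_leaf_tree.root().name
        assert recon.loss_nodes["f"] == []

    def test_single_leaf_family_gains_on_terminal_branch(self, five_leaf_tree):
        m = _matrix({"f": "C"}, list("ABCDE"))
        recon = dollo_reconstruct(five_leaf_tree, m)
        assert recon.gain_node["f"] == "C"
        assert recon.loss_nodes["f"] == []

    def test_loss_in_one_subtree(self, five_leaf_tree):
        # present in A, B, C, E: gained at root, lost on D's branch
        m = _matrix({"f": "ABCE"}, list("ABCDE"))
        recon = dollo_reconstruct(five_leaf_tree, m)
        assert recon.gain_node["f"] == five_leaf_tree.root().name
        assert recon.loss_nodes["f"] == ["D"]

    def test_unnamed_internal_nodes_accepted(self):
        """NJ/midpoint trees come without internal names; reconstruction
        names them internally instead of failing."""
        t = parse_newick("(((A:1,B:1):1,C:1):0.5,(D:1,E:1):0.5);")
        m = _matrix({"f": "ABCE"}, list("ABCDE"))
        recon = dollo_reconstruct(t, m)
        assert len(recon.loss_nodes["f"]) == 1

    def test_unrooted_tree_rejected(self):
        t = _name(parse_newick("(A:1,B:1,C:1);"))
        with pytest.raises(ValueError, match="unrooted"):
            dollo_reconstruct(t, _matrix({"f": "AB"}, list("ABC")))

    def test_leaf_mismatch_rejected(self, five_leaf_tree):
        with pytest.raises(ValueError, match="leaf set"):
            dollo_reconstruct(five_leaf_tree, _matrix({"f": "XY"}, list("XY")))

    def test_family_order_invariance(self, five_leaf_tree, rng):
        patterns = {f"f{i}": [g for g in "ABCDE" if rng.random() < 0.6] or ["A"]
                    for i in range(20)}
        m1 = _matrix(patterns, list("ABCDE"))
        shuffled = dict(reversed(list(patterns.items())))
        m2 = _matrix(shuffled, list("ABCDE"))
        r1 = dollo_reconstruct(five_leaf_tree, m1)
        r2 = dollo_reconstruct(five_leaf_tree, m2)
        assert r1.gain_node == r2.gain_node
        assert r1.loss_nodes == r2.loss_nodes


# ---------------------------------------------------------------------------
# exhaustive optimality


def _all_shapes(n):
    """One representative rooted binary tree per shape with <= n leaves."""
    def shapes(k):
        if k == 1:
            return [("leaf",)]
        out = []
        seen = set()
        for left in range(1, k // 2 + 1):
            for ls in shapes(left):
                for rs in shapes(k - left):
                    key = tuple(sorted([ls, rs]))
                    if key not in seen:
                        seen.add(key)
                        out.append(("node", ls, rs))
        return out

    trees = []
    for k in range(2, n + 1):
        for s in shapes(k):
            counter = itertools.count()

            def build(sh):
                if sh[0] == "leaf":
                    return TreeNode(name=f"L{next(counter)}", length=1.0)
                node = TreeNode(length=1.0)
                node.extend([build(sh[1]), build(sh[2])])
                return node

            t = build(s)
            t.length = None
            trees.append(_name(t))
    return trees


def _min_losses_bruteforce(tree, possessing):
    """Exhaustive search over (gain node, loss-edge set) single-gain
    assignments reproducing the presence pattern."""
    leaves = [t.name for t in tree.tips()]
    nodes = list(tree.preorder())
    paths = {}
    for leaf in tree.tips():
        path = []
        node = leaf
        while node is not None:
            path.append(node.name)
            node = node.parent
        paths[leaf.name] = path

    best = None
    for gain in nodes:
        under = {t.name for t in gain.tips()} or {gain.name}
        if not possessing <= under:
            continue
        # losses only make sense below the gain node
        sub_edges = [n.name for n in gain.preorder() if n is not gain]
        for k in range(0, len(sub_edges) + 1):
            if best is not None and k >= best:
                break
            for combo in itertools.combinations(sub_edges, k):
                losses = set(combo)
                ok = True
                for leaf in leaves:
                    path = paths[leaf]
                    if gain.name not in path:
                        has = False
                    else:
                        upto = path[: path.index(gain.name) + 1]
                        has = not (losses & set(upto))
                    if has != (leaf in possessing):
                        ok = False
                        break
                if ok:
                    best = k
                    break
            if best == k:
                break
    return best


class TestDolloOptimality:
    def test_exhaustive_over_shapes_and_patterns(self):
        """Loss counts equal the exhaustive single-gain minimum for every
        tree shape with <= 6 leaves and every non-empty presence pattern."""
        for tree in _all_shapes(6):
            leaves = [t.name for t in tree.tips()]
            for r in range(1, len(leaves) + 1):
                for possessing in itertools.combinations(leaves, r):
                    m = _matrix({"f": possessing}, leaves)
                    recon = dollo_reconstruct(tree, m)
                    brute = _min_losses_bruteforce(tree, set(possessing))
                    assert len(recon.loss_nodes["f"]) == brute

    def test_conservation_at_every_node(self, five_leaf_tree, rng):
        patterns = {f"f{i}": [g for g in "ABCDE" if rng.random() < 0.5] or ["B"]
                    for i in range(30)}
        m = _matrix(patterns, list("ABCDE"))
        recon = dollo_reconstruct(five_leaf_tree, m)
        summary = node_acquisition_summary(recon)
        assert (summary["n_acquired"] + summary["n_inherited"]
                == summary["n_present"]).all()


# ---------------------------------------------------------------------------
# per-node summaries and labels


class TestSummaries:
    def test_everything_acquired_at_root(self, five_leaf_tree):
        m = _matrix({f"f{i}": "ABCDE" for i in range(4)}, list("ABCDE"))
        recon = dollo_reconstruct(five_leaf_tree, m)
        summary = node_acquisition_summary(recon)
        root = five_leaf_tree.root().name
        assert summary.loc[root, "n_acquired"] == 4
        assert (summary.drop(index=root)["n_acquired"] == 0).all()
        assert (summary.drop(index=root)["n_inherited"] == 4).all()

    def test_gh13_root_family_in_breakdowns(self, five_leaf_tree):
        """A GH13 family gained at the root and never lost shows up in the
        root's acquired breakdown and every descendant's inherited one."""
        m = _matrix({"amy": "ABCDE", "other": "AB"}, list("ABCDE"))
        recon = dollo_reconstruct(five_leaf_tree, m)
        summary = node_acquisition_summary(
            recon, {"amy": "GH13", "other": "hypothetical"})
        root = five_leaf_tree.root().name
        assert summary.loc[root, "acquired:GH13"] == 1
        for node in summary.index.drop(root):
            assert summary.loc[node, "inherited:GH13"] == 1

    def test_label_majority_vote_and_ties(self):
        fams = {"f1": ["a", "b", "c"], "f2": ["d", "e"]}
        ann = AnnotationTable({"a": "GH13", "b": "GH13", "c": "GH43",
                               "d": "GH25", "e": "GH23"})
        labels = family_labels_by_majority(fams, ann)
        assert labels == {"f1": "GH13", "f2": "ambiguous"}

    def test_per_label_counts_sum_to_totals(self, five_leaf_tree, rng):
        patterns = {f"f{i}": [g for g in "ABCDE" if rng.random() < 0.5] or ["C"]
                    for i in range(25)}
        m = _matrix(patterns, list("ABCDE"))
        labels = {f: rng.choice(["GH13", "GH43", "hypothetical"])
                  for f in patterns}
        recon = dollo_reconstruct(five_leaf_tree, m)
        summary = node_acquisition_summary(recon, labels)
        acq_cols = [c for c in summary.columns if c.startswith("acquired:")]
        inh_cols = [c for c in summary.columns if c.startswith("inherited:")]
        assert (summary[acq_cols].sum(axis=1) == summary["n_acquired"]).all()
        assert (summary[inh_cols].sum(axis=1) == summary["n_inherited"]).all()

    def test_truth_gains_recovered_when_identifiable(self, small_dataset):
        """Reconstructed gain branches equal the simulator's recorded gains
        whenever the Dollo identifiability condition holds (the recorded
        gain node is still the MRCA of the surviving possessing leaves)."""
        _, truth = small_dataset
        matrix = truth.presence_matrix()
        recon = dollo_reconstruct(truth.tree, matrix)
        checked = 0
        for fid in matrix.family_ids:
            possessing = set(matrix.genomes_with(fid))
            true_gain = truth.tree.find(truth.gain_branch[fid])
            under = {t.name for t in true_gain.tips()} or {true_gain.name}
            mrca_is_gain = (possessing <= under) and all(
                possessing & ({t.name for t in c.tips()} or {c.name})
                for c in true_gain.children) if true_gain.children else (
                possessing == under)
            if mrca_is_gain:
                checked += 1
                assert recon.gain_node[fid] == truth.gain_branch[fid]
        assert checked > 0

    def test_thresholds_type_validation(self):
        with pytest.raises(ValueError):
            GainLossThresholds(pid_min=0.0)
        assert GainLossThresholds().pid_min == 0.50
        assert GainLossThresholds().cov_min == 0.50
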