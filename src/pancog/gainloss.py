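"""Dollo-parsimony reconstruction of gene-family gain and loss.

Under Dollo parsimony a family is gained exactly once and may be lost
repeatedly.  On a rooted strain tree the unique loss-minimal single-gain
reconstruction places the gain on the branch into the most recent common
ancestor of the possessing leaves, and one loss on the branch into every
maximal subtree below it that contains no possessing leaf.  Per-node
summaries (families acquired on the branch into the node vs families
inherited from the parent) can be broken down by functional label, e.g.
to trace the acquisition history of glycosyl-hydrolase (GH) families.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from skbio import TreeNode

from .core_model import AnnotationTable, PresenceAbsenceMatrix

__all__ = [
    "GainLossThresholds",
    "DolloReconstruction",
    "dollo_reconstruct",
    "node_acquisition_summary",
    "family_labels_by_majority",
]


@dataclass(frozen=True)
class GainLossThresholds:
    """Looser clustering cutoffs used to build the gain/loss family set
    (distinct from the 30%/80% pan-genome thresholds): 50% identity over
    at least 50% of both protein sequences."""

    pid_min: float = 0.50
    cov_min: float = 0.50

    def __post_init__(self) -> None:
        if not (0 < self.pid_min <= 1 and 0 < self.cov_min <= 1):
            raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class DolloReconstruction:
    tree: TreeNode
    gain_node: dict[str, str]            # family -> node whose incoming branch gains it
    loss_nodes: dict[str, list[str]]     # family -> nodes whose incoming branch loses it
    present: dict[str, set[str]]         # node name -> families present at the node
    acquired: dict[str, set[str]]        # node name -> families gained on the branch into it

    def inherited(self, node_name: str) -> set[str]:
        return self.present[node_name] - self.acquired[node_name]

    @property
    def total_losses(self) -> int:
        return sum(len(v) for v in self.loss_nodes.values())


def dollo_reconstruct(tree: TreeNode, matrix: PresenceAbsenceMatrix
                      ) -> DolloReconstruction:
    """Loss-minimal single-gain reconstruction of every family in *matrix*.

    The tree must be rooted (bifurcating root) and its leaf names must
    equal the matrix's genome IDs.  Families absent from every genome are
    rejected (the matrix type already enforces this).
    """
    root = tree.root()
    if len(root.children) != 2:
        raise ValueError(
            "tree is unrooted (root has != 2 children); root it first, e.g. "
            "with phylo.root_tree(tree, 'midpoint')")
    if any(n.name is None for n in tree.non_tips(include_self=True)):
        tree = tree.copy()
        i = 0
        for node in tree.preorder():
            if node.name is None:
                node.name = f"node{i}"
                i += 1
    leaves = {t.name for t in tree.tips()}
    if leaves != set(matrix.genome_ids):
        raise ValueError("tree leaf set does not match matrix genome set")

    # postorder leaf sets per node
    leafset: dict[str, frozenset[str]] = {}
    postorder = list(tree.postorder())
    for node in postorder:
        if node.is_tip():
            leafset[node.name] = frozenset([node.name])
        else:
            leafset[node.name] = frozenset().union(
                *(leafset[c.name] for c in node.children))

    gain_node: dict[str, str] = {}
    loss_nodes: dict[str, list[str]] = {}
    present: dict[str, set[str]] = {n.name: set() for n in postorder}
    acquired: dict[str, set[str]] = {n.name: set() for n in postorder}

    for fid in matrix.family_ids:
        possessing = frozenset(matrix.genomes_with(fid))
        # gain = MRCA of possessing leaves: smallest leafset covering them
        gain = min(
            (n for n in postorder if leafset[n.name] >= possessing),
            key=lambda n: len(leafset[n.name]),
        )
        gain_node[fid] = gain.name
        acquired[gain.name].add(fid)
        losses: list[str] = []
        stack = [gain]
        while stack:
            node = stack.pop()
            if leafset[node.name] & possessing:
                present[node.name].add(fid)
                stack.extend(node.children)
            else:
                losses.append(node.name)  # maximal empty subtree: one loss
        loss_nodes[fid] = sorted(losses)

    return DolloReconstruction(tree, gain_node, loss_nodes, present, acquired)


def family_labels_by_majority(families: dict[str, list[str]],
                              annotation: AnnotationTable) -> dict[str, str]:
    """Propagate gene labels to families by majority vote; ties are
    labelled "ambiguous" and counted separately downstream."""
    out: dict[str, str] = {}
    for fid, members in families.items():
        votes = Counter(annotation[g] for g in members)
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            out[fid] = "ambiguous"
        else:
            out[fid] = top[0][0]
    return out


def node_acquisition_summary(recon: DolloReconstruction,
                             family_labels: dict[str, str] | None = None
                             ) -> pd.DataFrame:
    """Per-node table of acquired vs inherited family counts.

    With *family_labels*, adds per-label acquired/inherited breakdowns
    (columns ``acquired:<label>``, ``inherited:<label>``); per-label
    counts sum to the totals, and acquired + inherited = present holds at
    every node.
    """
    rows = []
    for node in recon.tree.preorder():
        name = node.name
        acq = recon.acquired[name]
        inh = recon.inherited(name)
        row: dict[str, object] = {
            "node": name,
            "is_leaf": node.is_tip(),
            "n_present": len(recon.present[name]),
            "n_acquired": len(acq),
            "n_inherited": len(inh),
        }
        if family_labels is not None:
            for prefix, fams in (("acquired", acq), ("inherited", inh)):
                for label, cnt in sorted(Counter(
                        family_labels.get(f, "unlabeled") for f in fams).items()):
                    row[f"{prefix}:{label}"] = cnt
        rows.append(row)
    df = pd.DataFrame(rows).fillna(0)
    breakdown = [c for c in df.columns if ":" in c]
    df[breakdown] = df[breakdown].astype(int)
    return df.set_index("node")
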