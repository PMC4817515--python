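"""Distance-based phylogenomics: the core-genome supertree and the
gene-content (pan-genome) tree.

The supertree distance pools p-distances over all aligned columns of the
single-copy core families (equivalent to concatenating the alignments)
and applies the Poisson correction d = -ln(1 - p).  The pan-genome tree
uses 1 - Jaccard similarity of the family presence/absence profiles.
Trees are built with neighbor joining and can be rooted at the midpoint
or on a named outgroup leaf.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj
from skbio import TreeNode

from .core_model import PresenceAbsenceMatrix, Proteome
from .clustering import GeneFamilySet
from .homology import ScoringScheme, DEFAULT_SCORING, align_global

__all__ = [
    "core_sequence_distances",
    "presence_absence_distances",
    "neighbor_joining",
    "root_tree",
]


def core_sequence_distances(families: GeneFamilySet, proteomes: list[Proteome],
                            scoring: ScoringScheme = DEFAULT_SCORING,
                            family_ids: list[str] | None = None) -> DistanceMatrix:
    """Poisson-corrected distances from pooled single-copy core alignments.

    For every single-copy core family the two members of each genome pair
    are globally aligned (end-gap-free); p is the mismatch fraction over
    all aligned columns pooled across families, and d = -ln(1 - p).
    """
    genome_ids = families.genome_ids
    if len(genome_ids) < 3:
        raise ValueError("need at least three genomes")
    fids = family_ids if family_ids is not None else families.core_family_ids(single_copy=True)
    if not fids:
        raise ValueError("no single-copy core families available")
    seq_of = {g.gene_id: g.protein_seq for p in proteomes for g in p.genes}

    member: dict[tuple[str, str], str] = {}
    for fid in fids:
        for gene in families.families[fid]:
            member[(fid, families.genome_of[gene])] = seq_of[gene]

    n = len(genome_ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        cols = mism = 0
        for fid in fids:
            a = member[(fid, genome_ids[i])]
            b = member[(fid, genome_ids[j])]
            if a == b:
                cols += len(a)
                continue
            matched, _ident, mm = align_global(a, b, scoring)
            cols += matched
            mism += mm
        p = mism / cols if cols else 0.0
        if p >= 1.0:
            raise ValueError(
                f"p-distance >= 1 between {genome_ids[i]} and {genome_ids[j]}; "
                "Poisson correction undefined")
        d[i, j] = d[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(d, ids=genome_ids)


def presence_absence_distances(matrix: PresenceAbsenceMatrix) -> DistanceMatrix:
    """Gene-content distance: 1 - Jaccard similarity of family sets."""
    ids = matrix.genome_ids
    if len(ids) < 3:
        raise ValueError("need at least three genomes")
    cells = matrix.cells.to_numpy().astype(bool)
    if (cells.sum(axis=0) == 0).any():
        raise ValueError("a genome has an empty family set")
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = cells[:, i], cells[:, j]
        inter = np.logical_and(a, b).sum()
        union = np.logical_or(a, b).sum()
        d[i, j] = d[j, i] = 1.0 - inter / union
    return DistanceMatrix(d, ids=ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining; negative branch lengths are clamped to
    zero with a warning."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch lengths to 0")
    return tree


def root_tree(tree: TreeNode, root_at: str = "midpoint") -> TreeNode:
    """Root an unrooted NJ tree at the midpoint or on a named leaf."""
    if root_at == "midpoint":
        rooted = tree.root_at_midpoint()
    else:
        try:
            out = tree.find(root_at)
        except Exception as exc:
            raise ValueError(f"outgroup label {root_at!r} not in tree") from exc
        # bisect the branch above the outgroup so the root is binary
        rooted = tree.root_at(out, above=True)
    return rooted
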