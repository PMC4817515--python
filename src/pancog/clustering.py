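"""Markov clustering of the similarity graph into gene families (COGs),
and their classification into core / accessory / truly-unique.

MCL alternates expansion (matrix power) and inflation (entrywise power
plus column renormalisation) on a column-stochastic matrix built from the
edge weights, until the matrix stops changing; clusters are read off the
nonzero structure of the converged (doubly idempotent) matrix.  Families
present in every genome are core; families confined to one genome are
unique and their member genes are the strain's truly unique genes (TUGs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .core_model import PresenceAbsenceMatrix, Proteome
from .homology import (
    SimilarityGraph,
    SimilarityThresholds,
    ScoringScheme,
    DEFAULT_SCORING,
    align_local,
    candidate_pairs,
)

__all__ = [
    "MCLParams",
    "GeneFamilySet",
    "mcl_cluster",
    "classify_families",
    "unique_core_genes",
]


@dataclass(frozen=True)
class MCLParams:
    inflation: float = 1.5
    expansion: int = 2
    pruning_epsilon: float = 1e-6
    max_iter: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1 or self.expansion < 2 or self.max_iter < 1:
            raise ValueError("invalid MCL parameters")


class MCLConvergenceWarning(UserWarning):
    pass


def mcl_cluster(sim: SimilarityGraph | "object", params: MCLParams = MCLParams()
                ) -> dict[str, list[str]]:
    """Partition the genes of a similarity graph into families.

    Accepts a :class:`SimilarityGraph` or a bare ``networkx.Graph`` with
    ``weight`` edge attributes.  Self-loops with weight equal to each
    node's maximum incident weight are added before normalisation (the
    usual loop-shadowing choice, keeping the iteration well-behaved for
    bit-score weights).  Output is deterministic for a fixed node set.

    Returns ``family_id -> sorted member gene IDs`` with families numbered
    by their lexicographically smallest member.
    """
    graph = sim.graph if isinstance(sim, SimilarityGraph) else sim
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    rows, cols, vals = [], [], []
    maxw = np.zeros(n)
    for u, v, w in graph.edges(data="weight", default=1.0):
        if u == v:
            continue
        w = float(max(w, 0.0))
        i, j = idx[u], idx[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        maxw[i] = max(maxw[i], w)
        maxw[j] = max(maxw[j], w)
    loops = np.where(maxw > 0, maxw, 1.0)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loops)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    M = _normalize_columns(M)
    converged = False
    for _ in range(params.max_iter):
        prev = M.copy()
        # expansion
        P = M
        for _e in range(params.expansion - 1):
            P = P @ M
        # inflation + pruning
        P = P.power(params.inflation)
        P.data[P.data < params.pruning_epsilon] = 0.0
        P.eliminate_zeros()
        M = _normalize_columns(P)
        diff = abs(M - prev)
        if diff.nnz == 0 or diff.max() < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; returning the "
                      "current partition", MCLConvergenceWarning)

    # clusters = connected components of the converged matrix's support
    support = M + M.T
    n_comp, labels = connected_components(support, directed=False)
    members: dict[int, list[str]] = {}
    for node, lab in zip(nodes, labels):
        members.setdefault(int(lab), []).append(node)
    clusters = sorted((sorted(m) for m in members.values()), key=lambda m: m[0])
    return {f"FAM{i:05d}": m for i, m in enumerate(clusters)}


def _normalize_columns(M: sp.csr_matrix) -> sp.csr_matrix:
    col_sums = np.asarray(M.sum(axis=0)).ravel()
    col_sums[col_sums == 0] = 1.0
    D = sp.diags(1.0 / col_sums)
    return (M @ D).tocsr()


# ---------------------------------------------------------------------------
# family classification


@dataclass
class GeneFamilySet:
    """Clustered gene families with core/accessory/unique classification."""

    families: dict[str, list[str]]
    genome_of: dict[str, str]
    genome_ids: list[str]
    classification: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.classification:
            for fid, members in self.families.items():
                genomes = {self.genome_of[g] for g in members}
                if genomes == set(self.genome_ids):
                    self.classification[fid] = "core"
                elif len(genomes) == 1:
                    self.classification[fid] = "unique"
                else:
                    self.classification[fid] = "accessory"

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_of_gene(self) -> dict[str, str]:
        return {g: fid for fid, members in self.families.items() for g in members}

    def count(self, kind: str) -> int:
        return sum(1 for c in self.classification.values() if c == kind)

    @property
    def pan_size(self) -> int:
        return self.n_families

    @property
    def core_size(self) -> int:
        return self.count("core")

    def core_family_ids(self, single_copy: bool = False) -> list[str]:
        """Core families; with *single_copy*, restrict to the strict
        reading of exactly one member per genome."""
        out = []
        for fid, members in self.families.items():
            if self.classification[fid] != "core":
                continue
            if single_copy:
                counts = pd.Series([self.genome_of[g] for g in members]).value_counts()
                if (counts != 1).any() or len(counts) != len(self.genome_ids):
                    continue
            out.append(fid)
        return sorted(out)

    def tug_counts(self) -> dict[str, int]:
        """Per-genome number of genes in families unique to that genome."""
        tugs = {g: 0 for g in self.genome_ids}
        for fid, members in self.families.items():
            if self.classification[fid] == "unique":
                tugs[self.genome_of[members[0]]] += len(members)
        return tugs

    def tug_gene_ids(self) -> set[str]:
        return {g for fid, members in self.families.items()
                if self.classification[fid] == "unique" for g in members}

    def presence_absence(self) -> PresenceAbsenceMatrix:
        fams = sorted(self.families)
        counts = pd.DataFrame(0, index=fams, columns=self.genome_ids)
        for fid, members in self.families.items():
            for g in members:
                counts.loc[fid, self.genome_of[g]] += 1
        return PresenceAbsenceMatrix(counts > 0, counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [(fid, g, self.genome_of[g], self.classification[fid])
                for fid, members in sorted(self.families.items()) for g in members]
        return pd.DataFrame(rows, columns=["family_id", "gene_id", "genome_id",
                                           "classification"])


def classify_families(families: dict[str, list[str]],
                      proteomes: list[Proteome]) -> GeneFamilySet:
    """Attach core/accessory/unique labels to a clustering partition.

    Core means at least one member in every genome (the multi-copy-
    permitting reading); the strict single-copy core is available from
    :meth:`GeneFamilySet.core_family_ids`.
    """
    genome_of: dict[str, str] = {}
    for prot in proteomes:
        if len(prot.genes) == 0:
            raise ValueError(f"genome {prot.genome_id} has no genes")
        for g in prot.genes:
            genome_of[g.gene_id] = prot.genome_id
    clustered = {g for members in families.values() for g in members}
    if clustered != set(genome_of):
        raise ValueError("families do not partition the input gene set")
    return GeneFamilySet(families, genome_of, sorted(p.genome_id for p in proteomes))


# ---------------------------------------------------------------------------
# species-unique core genes


def unique_core_genes(ingroup: GeneFamilySet, ingroup_proteomes: list[Proteome],
                      outgroup_proteomes: list[Proteome],
                      thresholds: SimilarityThresholds = SimilarityThresholds(),
                      scoring: ScoringScheme = DEFAULT_SCORING,
                      ) -> tuple[list[str], int]:
    """Core families with no above-threshold hit in any outgroup proteome.

    Returns ``(unique_core_family_ids, n_core_shared_with_outgroup)``.
    """
    if not outgroup_proteomes:
        raise ValueError("outgroup must be non-empty")
    seq_of = {g.gene_id: g.protein_seq for p in ingroup_proteomes for g in p.genes}
    out_seqs = {f"OUT::{g.gene_id}": g.protein_seq
                for p in outgroup_proteomes for g in p.genes}
    db_size = sum(len(s) for s in out_seqs.values())

    core = ingroup.core_family_ids()
    core_genes = {g for fid in core for g in ingroup.families[fid]}
    pool = {g: seq_of[g] for g in core_genes}
    pool.update(out_seqs)
    cand = candidate_pairs(pool)

    hit_fams: set[str] = set()
    fam_of = ingroup.family_of_gene()
    for u, v in sorted(cand):
        u_out, v_out = u.startswith("OUT::"), v.startswith("OUT::")
        if u_out == v_out:
            continue
        gene, out = (v, u) if u_out else (u, v)
        fid = fam_of[gene]
        if fid in hit_fams:
            continue
        hit = align_local(pool[gene], pool[out], scoring, db_size=db_size,
                          query_id=gene, subject_id=out)
        if thresholds.passes(hit):
            hit_fams.add(fid)
    unique = sorted(set(core) - hit_fams)
    return unique, len(hit_fams)
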