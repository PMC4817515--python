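"""All-vs-all protein similarity, bidirectional best hits, and fragment ANI.

Edges of the similarity graph follow the classic comparative-genomics
cutoff: E-value below 1e-4 and at least 30% identity over at least 80% of
BOTH protein sequences.  Alignment is Smith-Waterman (BLOSUM62, affine
gaps) via Biopython's C pairwise aligner; a shared-4-mer prefilter keeps
the all-vs-all pass tractable without affecting edges above the identity
floor.  E-values use the Karlin-Altschul formula with gapped BLOSUM62
parameters and database size equal to the total residue count of the
proteome set.

ANI is the fragment method: the query genome is cut into consecutive
1020-nt pieces, each aligned glocally (both strands) against the subject;
fragments passing 30% identity / 70% coverage contribute their identity,
and the reported value is the mean of the two directions, in percent.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .core_model import Proteome

__all__ = [
    "SimilarityThresholds",
    "SimilarityHit",
    "ANIParams",
    "ScoringScheme",
    "align_local",
    "align_global",
    "candidate_pairs",
    "build_similarity_graph",
    "SimilarityGraph",
    "bidirectional_best_hits",
    "compute_ani",
    "ANIUndefinedError",
]


@dataclass(frozen=True)
class SimilarityThresholds:
    """Edge criteria for the ortholog-graph construction."""

    e_max: float = 1e-4
    pid_min: float = 0.30
    cov_min: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.pid_min <= 1 and 0 < self.cov_min <= 1 and self.e_max > 0):
            raise ValueError("thresholds out of range")

    def passes(self, hit: "SimilarityHit") -> bool:
        return (hit.evalue <= self.e_max and hit.identity >= self.pid_min
                and min(hit.cov_query, hit.cov_subject) >= self.cov_min)


@dataclass(frozen=True)
class ScoringScheme:
    """Protein scoring: substitution matrix plus affine gap penalties.

    A gap of length k costs ``gap_open + (k-1) * gap_extend``.
    Karlin-Altschul (lambda, K) are the standard gapped values for
    BLOSUM62 11/1 and are used for any scheme's E-values (pid/cov
    dominate edge decisions; the E-value only needs calibrated ranking).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def make_aligner(self, mode: str = "local") -> PairwiseAligner:
        # aligner construction (substitution-matrix load) dominates short
        # alignments, so reuse one instance per (scheme, mode)
        cached = _ALIGNER_CACHE.get((self, mode))
        if cached is not None:
            return cached
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(self.matrix_name)
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        aligner.mode = "global" if mode == "end_gap_free" else mode
        if mode == "end_gap_free":
            for attr in ("open_end_insertion_score", "extend_end_insertion_score",
                         "open_end_deletion_score", "extend_end_deletion_score"):
                setattr(aligner, attr, 0.0)
        _ALIGNER_CACHE[(self, mode)] = aligner
        return aligner

    def bit_score(self, raw: float) -> float:
        return (self.ka_lambda * raw - math.log(self.ka_k)) / math.log(2.0)

    def evalue(self, raw: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bit_score(raw))


@dataclass
class SimilarityHit:
    """One pairwise local alignment summarised for graph construction.

    ``full_stats`` is False for score-only hits: pairs whose raw score is
    already below the E-value ceiling cannot become edges, so their
    identity/coverage are not computed (reported as 0).
    """

    query_id: str
    subject_id: str
    score: float          # bit score
    raw_score: float
    identity: float       # identical columns / alignment columns
    cov_query: float
    cov_subject: float
    evalue: float
    full_stats: bool = True


class ANIUndefinedError(RuntimeError):
    """No genome fragment passed the ANI identity/coverage filters."""


@dataclass(frozen=True)
class ANIParams:
    fragment_len: int = 1020
    frag_pid_min: float = 0.30
    frag_cov_min: float = 0.70

    def __post_init__(self) -> None:
        if self.fragment_len < 100:
            raise ValueError("fragment_len must be >= 100")


_ALIGNER_CACHE: dict[tuple["ScoringScheme", str], PairwiseAligner] = {}

DEFAULT_SCORING = ScoringScheme()


# ---------------------------------------------------------------------------
# pairwise alignment


def _alignment_stats(alignment) -> tuple[float, int, int, int, int, int]:
    """identity plus aligned spans (query start/end, subject start/end)."""
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / columns if columns else 0.0
    t_blocks, q_blocks = alignment.aligned
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    return identity, columns, t_start, t_end, q_start, q_end


def align_local(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING,
                db_size: int | None = None,
                query_id: str = "query", subject_id: str = "subject"
                ) -> SimilarityHit:
    """Optimal Smith-Waterman local alignment of proteins *a* (query) and
    *b* (subject); identity and per-sequence coverages are computed on the
    optimal alignment (ties broken deterministically by the aligner's
    first reported path)."""
    if not a or not b:
        raise ValueError("align_local requires non-empty sequences")
    aligner = scoring.make_aligner("local")
    alignments = aligner.align(a, b)
    raw = alignments.score
    if raw <= 0:
        return SimilarityHit(query_id, subject_id, scoring.bit_score(0.0), 0.0,
                             0.0, 0.0, 0.0, math.inf)
    best = alignments[0]
    identity, _cols, a_start, a_end, b_start, b_end = _alignment_stats(best)
    n = db_size if db_size is not None else len(b)
    return SimilarityHit(
        query_id, subject_id,
        score=scoring.bit_score(raw), raw_score=float(raw),
        identity=identity,
        cov_query=(a_end - a_start) / len(a),
        cov_subject=(b_end - b_start) / len(b),
        evalue=scoring.evalue(raw, len(a), n),
    )


def align_global(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING):
    """End-gap-free global alignment; returns (n_matched_columns,
    n_identical, n_mismatch) over columns where both sequences align."""
    aligner = scoring.make_aligner("end_gap_free")
    best = aligner.align(a, b)[0]
    counts = best.counts()
    matched = counts.identities + counts.mismatches
    return matched, counts.identities, counts.mismatches


# ---------------------------------------------------------------------------
# prefilter + graph


def candidate_pairs(seqs: dict[str, str], k: int = 4, min_shared: int = 4,
                    max_bucket: int = 500) -> set[tuple[str, str]]:
    """Gene pairs sharing at least *min_shared* distinct k-mers.

    A cheap inverted-index prefilter before full dynamic programming;
    k-mers occurring in more than *max_bucket* genes are treated as
    low-complexity and skipped.
    """
    ids = sorted(seqs)
    index: dict[str, list[int]] = defaultdict(list)
    for gi, gid in enumerate(ids):
        s = seqs[gid]
        for kmer in {s[i:i + k] for i in range(len(s) - k + 1)}:
            index[kmer].append(gi)
    counts: Counter[tuple[int, int]] = Counter()
    for members in index.values():
        if len(members) < 2 or len(members) > max_bucket:
            continue
        counts.update(itertools.combinations(members, 2))
    return {(ids[i], ids[j]) for (i, j), c in counts.items() if c >= min_shared}


class SimilarityGraph:
    """Thresholded, weighted protein similarity graph plus raw hit lists.

    Nodes are gene IDs (every input gene, including singletons); edges
    carry the alignment bit score as weight.  The raw per-pair hits (also
    the sub-threshold ones among candidate pairs) are retained for
    best-hit bookkeeping.
    """

    def __init__(self, graph: nx.Graph, hits: list[SimilarityHit],
                 genome_of: dict[str, str], thresholds: SimilarityThresholds):
        self.graph = graph
        self.hits = hits
        self.genome_of = genome_of
        self.thresholds = thresholds

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        return self.graph.edges(data="weight")

    def best_hits(self) -> dict[str, dict[str, SimilarityHit]]:
        """gene -> target genome -> best hit (score desc, evalue asc,
        lexicographically smallest partner as final tie-break)."""
        best: dict[str, dict[str, SimilarityHit]] = defaultdict(dict)

        def consider(gene: str, partner: str, hit: SimilarityHit) -> None:
            tgt = self.genome_of[partner]
            if tgt == self.genome_of[gene]:
                return
            cur = best[gene].get(tgt)
            key = (-hit.score, hit.evalue, partner)
            if cur is None:
                best[gene][tgt] = hit
                return
            cur_partner = cur.subject_id if cur.query_id == gene else cur.query_id
            cur_key = (-cur.score, cur.evalue, cur_partner)
            if key < cur_key:
                best[gene][tgt] = hit
        for hit in self.hits:
            consider(hit.query_id, hit.subject_id, hit)
            consider(hit.subject_id, hit.query_id, hit)
        return best


def build_similarity_graph(proteomes: list[Proteome],
                           thresholds: SimilarityThresholds = SimilarityThresholds(),
                           scoring: ScoringScheme = DEFAULT_SCORING,
                           prefilter_k: int = 4, prefilter_min_shared: int = 4,
                           keep_within_genome: bool = True) -> SimilarityGraph:
    """All-vs-all comparison of every protein against all other proteins.

    An edge (u, v) exists iff the optimal local alignment satisfies all
    three thresholds; the weight is the bit score.  Self-edges are
    excluded; within-genome (paralog) edges are retained by default, as
    needed for paralog-aware family clustering.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    seqs: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    for prot in proteomes:
        for g in prot.genes:
            if g.gene_id in seqs:
                raise ValueError(f"duplicate gene ID across proteomes: {g.gene_id}")
            seqs[g.gene_id] = g.protein_seq
            genome_of[g.gene_id] = prot.genome_id
    db_size = sum(len(s) for s in seqs.values())

    graph = nx.Graph()
    for gid in seqs:
        graph.add_node(gid, genome=genome_of[gid])

    # lossless prescreen: an edge needs evalue <= e_max, i.e. a raw score
    # of at least s_min for the shortest query; below it a score-only hit
    # suffices (kept for best-hit bookkeeping)
    aligner = scoring.make_aligner("local")
    min_len = min(len(s) for s in seqs.values())
    s_min = (math.log(scoring.ka_k * min_len * db_size / thresholds.e_max)
             / scoring.ka_lambda)

    hits: list[SimilarityHit] = []
    for u, v in sorted(candidate_pairs(seqs, k=prefilter_k,
                                       min_shared=prefilter_min_shared)):
        if not keep_within_genome and genome_of[u] == genome_of[v]:
            continue
        raw = aligner.score(seqs[u], seqs[v])
        if raw < s_min:
            hits.append(SimilarityHit(
                u, v, scoring.bit_score(raw), float(raw), 0.0, 0.0, 0.0,
                scoring.evalue(raw, len(seqs[u]), db_size), full_stats=False))
            continue
        hit = align_local(seqs[u], seqs[v], scoring, db_size=db_size,
                          query_id=u, subject_id=v)
        hits.append(hit)
        if thresholds.passes(hit) and (keep_within_genome
                                       or genome_of[u] != genome_of[v]):
            graph.add_edge(u, v, weight=hit.score, identity=hit.identity)
    return SimilarityGraph(graph, hits, genome_of, thresholds)


def bidirectional_best_hits(sim: SimilarityGraph) -> set[frozenset[str]]:
    """Ortholog pairs (a in G1, b in G2) where each is the other's best hit
    in the partner genome."""
    best = sim.best_hits()
    pairs: set[frozenset[str]] = set()
    for gene, per_genome in best.items():
        for tgt, hit in per_genome.items():
            partner = hit.subject_id if hit.query_id == gene else hit.query_id
            back = best.get(partner, {}).get(sim.genome_of[gene])
            if back is None:
                continue
            back_partner = (back.subject_id if back.query_id == partner
                            else back.query_id)
            if back_partner == gene:
                pairs.add(frozenset((gene, partner)))
    return pairs


# ---------------------------------------------------------------------------
# ANI

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _fragments(seqs: dict[str, str], fragment_len: int) -> list[str]:
    frags = []
    for seq in seqs.values():
        for i in range(0, len(seq) - fragment_len + 1, fragment_len):
            frags.append(seq[i:i + fragment_len])
        if len(seq) < fragment_len and len(seq) >= 100:
            frags.append(seq)
    return frags


def _one_direction(query: dict[str, str], subject: dict[str, str],
                   params: ANIParams) -> tuple[float, int]:
    targets = [s for s in subject.values()]
    targets += [reverse_complement(s) for s in subject.values()]
    identities = []
    for frag in _fragments(query, params.fragment_len):
        kmax = int(len(frag) * (1 - params.frag_pid_min)) + 1
        best = None
        for t in targets:
            res = edlib.align(frag, t, mode="HW", task="distance", k=kmax)
            d = res["editDistance"]
            if d >= 0 and (best is None or d < best):
                best = d
                if best == 0:
                    break
        if best is None:
            continue
        identity = 1.0 - best / len(frag)
        # glocal alignment consumes the whole fragment, so fragment
        # coverage is complete whenever the subject can host it
        if identity >= params.frag_pid_min:
            identities.append(identity)
    if not identities:
        return math.nan, 0
    return float(np.mean(identities)), len(identities)


def compute_ani(genome_a: dict[str, str], genome_b: dict[str, str],
                params: ANIParams = ANIParams()) -> tuple[float, int]:
    """Average nucleotide identity between two assemblies, in percent.

    Returns ``(ani_percent, n_fragments_used)`` where the value is the
    mean of the A->B and B->A directions.  Raises
    :class:`ANIUndefinedError` when no fragment passes the filters in
    either direction.
    """
    if not genome_a or not genome_b:
        raise ValueError("both assemblies must be non-empty")
    ab, n_ab = _one_direction(genome_a, genome_b, params)
    ba, n_ba = _one_direction(genome_b, genome_a, params)
    vals = [v for v in (ab, ba) if not math.isnan(v)]
    if not vals:
        raise ANIUndefinedError("no fragment passed the ANI filters")
    return float(np.mean(vals)) * 100.0, n_ab + n_ba
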