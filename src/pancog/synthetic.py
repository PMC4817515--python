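"""Synthetic strain-pangenome generator with known truth.

Emulates the structure a strain-level comparative analysis assumes: a
clonal strain tree (pure-birth), a core of gene families present at the
root, accessory families gained exactly once on a branch and lost
repeatedly below it (Dollo-compatible by construction), per-branch protein
sequence divergence, strain-unique genes, and horizontally transferred
genes with atypical nucleotide composition.  Every dataset carries a
complete truth table (tree, family memberships, gain/loss branches, HGT
gene IDs) so downstream stages can be scored exactly.

Sequences evolve by i.i.d. per-site amino-acid substitution; codons are
drawn once at family birth from a GC-parameterised codon table and are
inherited down the tree, redrawn only at substituted sites, so nucleotide
divergence tracks protein divergence.  HGT genes are generated de novo
with codons drawn at an alien GC, giving the composition screen an
unambiguous positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .core_model import (
    GeneRecord,
    Proteome,
    PresenceAbsenceMatrix,
    parse_newick,
    write_fasta,
    write_newick,
    write_annotation_table,
    read_fasta,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Standard genetic code, organised as amino acid -> synonymous codons.
CODONS_BY_AA: dict[str, list[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
STOP_CODONS = ["TAA", "TAG", "TGA"]

GH_LABEL_POOL = ["GH13", "GH43", "GH23", "GH25", "GH3", "GH42", "GH36", "GH2"]


class ParameterError(ValueError):
    pass


@dataclass
class SimulationParams:
    """Knobs of the pangenome simulator.

    gain_rate is the expected number of new families per unit branch
    length; loss_rate the per-family loss hazard per unit branch length;
    subst_rate the per-site amino-acid substitution hazard.  hgt_fraction
    of each leaf's genes are replaced by de-novo genes whose codons are
    drawn at alien_gc instead of native_gc.
    """

    n_genomes: int = 12
    n_core_root: int = 400
    gain_rate: float = 3.0
    loss_rate: float = 0.3
    subst_rate: float = 0.01
    mean_protein_len: int = 300
    hgt_fraction: float = 0.0
    native_gc: float = 0.60
    alien_gc: float = 0.45
    duplication_prob: float = 0.02
    gh_label_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ParameterError("n_genomes must be >= 2")
        if min(self.gain_rate, self.loss_rate, self.subst_rate) < 0:
            raise ParameterError("rates must be >= 0")
        if not 0 <= self.hgt_fraction < 1:
            raise ParameterError("hgt_fraction must be in [0, 1)")
        for gc in (self.native_gc, self.alien_gc):
            if not 0 < gc < 1:
                raise ParameterError("GC fractions must be in (0, 1)")
        if self.n_core_root < 0 or self.mean_protein_len < 30:
            raise ParameterError("n_core_root >= 0 and mean_protein_len >= 30 required")


@dataclass
class SimulationTruth:
    """Complete ground truth of one simulated dataset."""

    tree: TreeNode
    family_of_gene: dict[str, str]
    gain_branch: dict[str, str]
    loss_branches: dict[str, list[str]]
    hgt_gene_ids: set[str]
    family_labels: dict[str, str]
    gene_coordinates: dict[str, list]  # gene_id -> [genome_id, start, end]
    params: SimulationParams

    def genomes(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def presence_matrix(self) -> PresenceAbsenceMatrix:
        """Leaf x family incidence tallied from the emitted genes."""
        import pandas as pd

        genomes = self.genomes()
        fams = sorted(set(self.family_of_gene.values()))
        counts = pd.DataFrame(0, index=fams, columns=genomes)
        for gene, fam in self.family_of_gene.items():
            counts.loc[fam, self.gene_coordinates[gene][0]] += 1
        return PresenceAbsenceMatrix(counts > 0, counts)

    def leaf_possesses(self, family_id: str, leaf_name: str) -> bool:
        """Dollo possession rule: gain node is an ancestor and no loss lies
        on the gain-to-leaf path."""
        gain = self.gain_branch[family_id]
        losses = set(self.loss_branches.get(family_id, ()))
        node = self.tree.find(leaf_name)
        path_names = []
        while node is not None:
            path_names.append(node.name)
            node = node.parent
        if gain not in path_names:
            return False
        # nodes from the leaf up to (excluding) the gain node
        on_path = path_names[: path_names.index(gain)] + [gain]
        return not (losses & set(on_path))


# ---------------------------------------------------------------------------
# strain tree


def simulate_strain_tree(n_genomes: int, seed: int, birth_rate: float = 1.0) -> TreeNode:
    """Pure-birth (Yule) strain tree with *n_genomes* leaves.

    Returns a rooted binary tree with strictly positive branch lengths,
    leaves named ``G01..``, internal nodes ``N0..`` in preorder.  The same
    seed yields a byte-identical Newick string.
    """
    if n_genomes < 2:
        raise ParameterError("n_genomes must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    pending = {id(root): 0.0}
    active = [root]
    while len(active) < n_genomes:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            pending[id(node)] += wait
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.length = None if parent.parent is None else pending.pop(id(parent))
        left, right = TreeNode(), TreeNode()
        parent.extend([left, right])
        for child in (left, right):
            pending[id(child)] = 0.0
        active.extend([left, right])
    tail = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = pending.pop(id(node)) + tail
    _name_nodes(root)
    return root


def _name_nodes(root: TreeNode) -> None:
    n_leaves = sum(1 for _ in root.tips())
    width = max(2, len(str(n_leaves)))
    leaf_i = internal_i = 0
    for node in root.preorder():
        if node.is_tip():
            leaf_i += 1
            node.name = f"G{leaf_i:0{width}d}"
        else:
            node.name = f"N{internal_i}"
            internal_i += 1


# ---------------------------------------------------------------------------
# sequence machinery


def codon_weights(gc: float) -> dict[str, np.ndarray]:
    """Per-amino-acid codon sampling weights under a base-composition model
    with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    out = {}
    for aa, codons in CODONS_BY_AA.items():
        w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
        out[aa] = w / w.sum()
    return out


@dataclass
class _FamilyState:
    protein: np.ndarray  # uint8 indices into AMINO_ACIDS
    codons: list[str]
    copies: int = 1


def _new_family_state(length: int, weights: dict[str, np.ndarray],
                      rng: np.random.Generator) -> _FamilyState:
    prot = rng.integers(0, 20, size=length).astype(np.uint8)
    codons = [
        CODONS_BY_AA[AMINO_ACIDS[a]][rng.choice(len(weights[AMINO_ACIDS[a]]),
                                                p=weights[AMINO_ACIDS[a]])]
        for a in prot
    ]
    return _FamilyState(prot, codons)


def _evolve(state: _FamilyState, branch_length: float, subst_rate: float,
            weights: dict[str, np.ndarray], rng: np.random.Generator) -> _FamilyState:
    p_sub = 1.0 - np.exp(-subst_rate * branch_length)
    prot = state.protein.copy()
    codons = list(state.codons)
    hits = np.nonzero(rng.random(len(prot)) < p_sub)[0]
    for i in hits:
        new_aa = int(rng.integers(0, 19))
        if new_aa >= prot[i]:
            new_aa += 1  # uniform over the 19 other residues
        prot[i] = new_aa
        aa = AMINO_ACIDS[new_aa]
        w = weights[aa]
        codons[i] = CODONS_BY_AA[aa][rng.choice(len(w), p=w)]
    return _FamilyState(prot, codons, state.copies)


# ---------------------------------------------------------------------------
# pangenome simulation


def simulate_pangenome(tree: TreeNode, params: SimulationParams
                       ) -> tuple[list[Proteome], SimulationTruth]:
    """Evolve gene families along *tree* and emit one proteome per leaf.

    Root families are present at the root; on every branch, new families
    arise as a Poisson draw with mean ``gain_rate * branch_length``, and
    each family present at the parent is lost with probability
    ``1 - exp(-loss_rate * branch_length)``.  Each leaf then has
    ``hgt_fraction`` of its genes replaced by de-novo alien-composition
    genes (which form their own single-leaf families in the truth table).
    """
    rng = np.random.default_rng(params.seed)
    native_w = codon_weights(params.native_gc)
    alien_w = codon_weights(params.alien_gc)

    fam_counter = 0
    gain_branch: dict[str, str] = {}
    loss_branches: dict[str, list[str]] = {}
    family_labels: dict[str, str] = {}

    def new_family(node_name: str) -> str:
        nonlocal fam_counter
        fid = f"F{fam_counter:05d}"
        fam_counter += 1
        gain_branch[fid] = node_name
        loss_branches[fid] = []
        if rng.random() < params.gh_label_fraction:
            family_labels[fid] = GH_LABEL_POOL[int(rng.integers(len(GH_LABEL_POOL)))]
        else:
            family_labels[fid] = "hypothetical"
        return fid

    def draw_len() -> int:
        return max(60, int(rng.poisson(params.mean_protein_len)))

    root_state: dict[str, _FamilyState] = {}
    for _ in range(params.n_core_root):
        fid = new_family(tree.name)
        root_state[fid] = _new_family_state(draw_len(), native_w, rng)

    # preorder traversal carrying per-node family states
    states: dict[str, dict[str, _FamilyState]] = {tree.name: root_state}
    leaf_states: dict[str, dict[str, _FamilyState]] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_state = states[node.parent.name]
        b = node.length
        child_state: dict[str, _FamilyState] = {}
        p_loss = 1.0 - np.exp(-params.loss_rate * b)
        for fid in sorted(parent_state):
            if rng.random() < p_loss:
                loss_branches[fid].append(node.name)
                continue
            st = _evolve(parent_state[fid], b, params.subst_rate, native_w, rng)
            if rng.random() < params.duplication_prob:
                st.copies += 1
            child_state[fid] = st
        n_gain = rng.poisson(params.gain_rate * b)
        for _ in range(n_gain):
            fid = new_family(node.name)
            child_state[fid] = _new_family_state(draw_len(), native_w, rng)
        if node.is_tip():
            leaf_states[node.name] = child_state
        else:
            states[node.name] = child_state

    # assemble proteomes with HGT replacement
    family_of_gene: dict[str, str] = {}
    hgt_gene_ids: set[str] = set()
    gene_coordinates: dict[str, list] = {}
    proteomes: list[Proteome] = []
    for leaf in sorted(leaf_states):
        entries: list[tuple[str, _FamilyState]] = []
        for fid in sorted(leaf_states[leaf]):
            st = leaf_states[leaf][fid]
            for _ in range(st.copies):
                entries.append((fid, st))
        n_genes = len(entries)
        n_hgt = int(round(params.hgt_fraction * n_genes))
        hgt_idx = set(rng.choice(n_genes, size=n_hgt, replace=False).tolist()) if n_hgt else set()
        # a family whose every copy is HGT-replaced is absent from this
        # leaf: record the replacement as a loss on the terminal branch so
        # the truth table stays Dollo-consistent
        surviving = {fid for i, (fid, _st) in enumerate(entries) if i not in hgt_idx}
        for fid in sorted({fid for i, (fid, _st) in enumerate(entries)
                           if i in hgt_idx} - surviving):
            loss_branches[fid].append(leaf)
        genes: list[GeneRecord] = []
        pos = 0
        hgt_counter = 0
        for i, (fid, st) in enumerate(entries):
            gid = f"{leaf}_{i:04d}"
            if i in hgt_idx:
                st = _new_family_state(draw_len(), alien_w, rng)
                fid = f"H{leaf}_{hgt_counter:03d}"
                hgt_counter += 1
                gain_branch[fid] = leaf
                loss_branches[fid] = []
                family_labels[fid] = "hypothetical"
                hgt_gene_ids.add(gid)
                codon_w = alien_w
            else:
                codon_w = native_w
            prot = "".join(AMINO_ACIDS[a] for a in st.protein)
            stop = STOP_CODONS[int(rng.choice(3, p=_stop_weights(codon_w)))]
            nt = "".join(st.codons) + stop
            start, end = pos, pos + len(nt)
            pos = end
            genes.append(GeneRecord(gid, leaf, prot, nt, start, end, "+",
                                    functional_label=family_labels[fid]))
            family_of_gene[gid] = fid
            gene_coordinates[gid] = [leaf, start, end]
        assembly = {"%s_contig1" % leaf: "".join(g.nucleotide_seq for g in genes)}
        proteomes.append(Proteome(leaf, genes, assembly))

    truth = SimulationTruth(tree, family_of_gene, gain_branch, loss_branches,
                            hgt_gene_ids, family_labels, gene_coordinates, params)
    return proteomes, truth


def _stop_weights(weights_like: dict[str, np.ndarray]) -> np.ndarray:
    # stop codons share the base-composition model of the coding table
    ref = weights_like["F"]  # TTT/TTC weights encode (1-gc) vs gc at pos 3
    gc = float(ref[1] / (ref[0] + ref[1]))
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in STOP_CODONS])
    return w / w.sum()


def simulate_dataset(params: SimulationParams
                     ) -> tuple[list[Proteome], SimulationTruth]:
    """Convenience wrapper: tree + pangenome from a single parameter set.

    Tree and sequence randomness derive from ``params.seed`` (offset
    streams, both below 2**31)."""
    tree = simulate_strain_tree(params.n_genomes, seed=params.seed % (2**31))
    return simulate_pangenome(tree, params)


# ---------------------------------------------------------------------------
# dataset emission / reload


def emit_dataset(proteomes: list[Proteome], truth: SimulationTruth,
                 out_dir: str | Path, force: bool = False) -> list[Path]:
    """Write per-genome protein + assembly FASTA, the annotation TSV and the
    truth JSON.  Refuses a non-empty output directory unless *force*."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    labels: dict[str, str] = {}
    for prot in proteomes:
        faa = out / f"{prot.genome_id}.faa"
        write_fasta(prot.genes, faa, kind="protein")
        fna = out / f"{prot.genome_id}.fna"
        from .core_model import FastaRecord

        write_fasta([FastaRecord(name, name, seq)
                     for name, seq in prot.assembly_seqs.items()], fna)
        written.extend([faa, fna])
        for g in prot.genes:
            labels[g.gene_id] = g.functional_label or "unlabeled"
    ann = out / "annotation.tsv"
    write_annotation_table(labels, ann)
    truth_path = out / "truth.json"
    payload = {
        "tree_newick": write_newick(truth.tree),
        "family_of_gene": truth.family_of_gene,
        "gain_branch": truth.gain_branch,
        "loss_branches": truth.loss_branches,
        "hgt_gene_ids": sorted(truth.hgt_gene_ids),
        "family_labels": truth.family_labels,
        "gene_coordinates": truth.gene_coordinates,
        "params": asdict(truth.params),
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    written.extend([ann, truth_path])
    return written


def load_dataset(in_dir: str | Path) -> tuple[list[Proteome], SimulationTruth]:
    """Reload a dataset written by :func:`emit_dataset`."""
    src = Path(in_dir)
    payload = json.loads((src / "truth.json").read_text())
    truth = SimulationTruth(
        tree=parse_newick(payload["tree_newick"]),
        family_of_gene=payload["family_of_gene"],
        gain_branch=payload["gain_branch"],
        loss_branches={k: list(v) for k, v in payload["loss_branches"].items()},
        hgt_gene_ids=set(payload["hgt_gene_ids"]),
        family_labels=payload["family_labels"],
        gene_coordinates=payload["gene_coordinates"],
        params=SimulationParams(**payload["params"]),
    )
    proteomes = []
    for faa in sorted(src.glob("*.faa")):
        gid = faa.stem
        assembly = {r.id: r.seq for r in read_fasta(src / f"{gid}.fna", alphabet="dna")}
        genes = []
        for rec in read_fasta(faa, alphabet="protein"):
            genome, start, end = truth.gene_coordinates[rec.id]
            contig = next(iter(assembly.values()))
            genes.append(GeneRecord(rec.id, gid, rec.seq, contig[start:end],
                                    start, end, "+",
                                    functional_label=truth.family_labels[
                                        truth.family_of_gene[rec.id]]))
        proteomes.append(Proteome(gid, genes, assembly))
    return proteomes, truth
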