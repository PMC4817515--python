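# Methods

This note documents the models and procedures pancog implements, the
defaults and why they were chosen, what the bundled simulator does and
does not emulate, and the numerical choices that affect results.

## Similarity search and gene families

Protein pairs are aligned with Smith–Waterman local alignment (BLOSUM62,
affine gaps; a gap of length k costs 11 + (k−1)·1 by default). E-values
use the Karlin–Altschul formula E = K·m·n·e^(−λS) with the standard
gapped BLOSUM62 parameters (λ = 0.267, K = 0.041) and database size n =
total residues of the proteome set. The E-value is a calibrated ranking
device here: edge decisions are dominated by the identity and coverage
thresholds (defaults 30% identity over ≥ 80% of both sequences,
E ≤ 1e-4), which is why one (λ, K) pair is used for every scoring
variant.

Two performance devices keep the all-vs-all pass tractable at desk
scale, neither of which changes the edge set:

- a shared-4-mer prefilter (default: ≥ 4 distinct shared 4-mers;
  k-mers occurring in > 500 sequences are treated as low-complexity
  and skipped). Its recall against a no-prefilter run is asserted in
  the test-suite at the divergence levels the package targets. Pairs
  below ~40% identity can drop out of the candidate set; the floor is a
  parameter (`prefilter_min_shared=1` disables the loss in practice).
- a lossless raw-score prescreen: a pair whose optimal score cannot
  reach the E-value ceiling is recorded as a score-only hit (kept for
  best-hit bookkeeping) without computing the traceback.

Within-genome (paralog) hits are retained by default and enter
clustering; a flag removes them.

MCL is implemented directly (sparse expansion/inflation with pruning at
1e-6, convergence when the iterate changes by < 1e-8, 200-iteration
cap with a warning on non-convergence). Self-loops are set to each
node's maximum incident weight, the usual loop-shadowing choice that
keeps the iteration well behaved for bit-score weights. Clusters are
the connected components of the converged matrix's support, which makes
the output invariant to node relabelling. Inflation defaults to 1.5,
the conventional coarse setting for ortholog graphs; it is exposed as a
parameter.

"Core" is read as ≥ 1 member in every genome (multi-copy allowed); the
stricter exactly-one-member reading is available
(`core_family_ids(single_copy=True)`) and is what the supertree stage
uses, since concatenation needs one sequence per genome. TUG counts are
taken from the post-clustering matrix and are independent of HGT status;
the two screens report their overlap separately.

## Pan/core profiles and openness

Enumerating all genome orderings is factorial; profiles are exact
(full enumeration) when G! fits in the ordering budget (default 1000,
so G ≤ 6) and otherwise use seeded random permutations, an unbiased
estimator of the same means. Monotonicity (pan non-decreasing, core
non-increasing) is asserted per ordering, not just on means.

The openness verdict is a fitted criterion, not a hypothesis test: the
pan curve is fitted by least squares on log–log axes to P(n) = κ·nᵞ and
the per-step novelty to Heaps' law N(n) = k·n^(−α) (excluding n = 1,
where "novelty" is an entire genome). Open means γ ≥ γ_open (default
0.05) or α ≤ 1. The thresholds are parameters because the field's usage
is qualitative ("the trend line has not plateaued"); the defaults mark
a pan curve still growing at a few percent per genome-doubling as open.

## Trees

Maximum-likelihood inference is deliberately out of scope; the claims
this package supports (strain clustering, outlier lineages) are
topological, and distance methods preserve them. The supertree distance
pools mismatches over all aligned columns of all single-copy core
families (equivalent to concatenating the per-family alignments), then
applies the Poisson correction d = −ln(1−p); pairwise global alignments
are end-gap-free and use the same scoring scheme as the search stage, so
there is a single source of scoring truth. p ≥ 1 raises an error naming
the pair. The gene-content tree is 1 − Jaccard on family sets.

Neighbor joining is the canonical Q-matrix algorithm (via scikit-bio);
negative branch lengths are clamped to zero with a warning. On additive
matrices the reconstruction is exact, which the test-suite checks to
1e-9 on random trees of 5–20 leaves. Rooting is midpoint or outgroup
(the branch above the outgroup leaf is bisected so the root is binary).

## Dollo gain/loss

For a family present in leaf set S of a rooted tree, the loss-minimal
single-gain reconstruction is: gain on the branch into MRCA(S), one
loss on the branch into every maximal subtree of MRCA(S) containing no
member of S. Optimality is verified in the tests by exhaustive search
over all (gain node, loss-edge set) assignments for every tree shape
with ≤ 6 leaves and every presence pattern. Per-node summaries satisfy
acquired + inherited = present at every node; functional labels
propagate from genes to families by majority vote, with ties labelled
"ambiguous" and counted separately. The gain/loss stage accepts any
rooted tree; unnamed internal nodes (as produced by NJ) are named
deterministically on a copy. The looser 50%/50% identity/coverage
clustering thresholds used for gain/loss family sets are kept distinct
from the 30%/80% pan-genome thresholds.

## ANI

Fragment ANI: the query assembly is cut into consecutive 1020-nt
fragments; each is aligned in glocal (infix) mode against every subject
contig and its reverse complement (edit distance via edlib), giving
identity = 1 − d/L, exact under substitution-only divergence. Fragments
pass at ≥ 30% identity; because the whole fragment is consumed in infix
mode, the 70% fragment-coverage criterion is satisfied by construction
whenever the subject can host the fragment — a deliberate simplification
that matches the fragment-ANI formulation at the divergence levels where
ANI is meaningful (> 80%). The reported value is the mean of the two
directions; "no fragment passed" is an explicit error, never a silent 0.
Contigs shorter than one fragment are used whole when ≥ 100 nt.

## HGT screen

The screen is a transparent composition test, not an HMM segmentation
or a phylogenetic donor search. Signals per gene: (i) atypicality — the
mean per-codon log-likelihood ratio of the gene's own synonymous codon
distribution (pseudocount 0.5) against the genome-wide one (raw
frequencies, clamped at 1e-3 for codons unseen genome-wide);
single-codon amino acids carry no signal and are skipped; (ii) GC3
deviation from the genome. Both are standardized by their null moments
and summed.

Calibration: 2000 null genes are simulated from the genome's own
profile — amino acids at the genome's marginal usage, codons at its
synonymous frequencies, lengths resampled from the genome's own gene
lengths (score variance scales with length) — and the flag threshold is
the 95th percentile of the combined score (a 5% false-positive budget).
Because real genes can be slightly over-dispersed relative to this
idealised null, the per-genome threshold is the larger of the null
quantile and a robust empirical quantile of the genome's own score bulk
(median + scaled IQR, insensitive to a minority of true aliens in the
upper tail). A single refinement pass re-estimates the background from
unflagged genes — but only when the first pass flags clearly more than
the budget (> 1.5× the 5% rate), since refining a clean genome would
just excise and re-flag the null tail. Genes shorter than 300 nt are
never flagged. Explicit thresholds switch to the raw-scale rule
(atypicality OR GC3 deviation beyond the given cutoffs).

The mobilome fraction this screen reports is tool-specific by nature;
published figures produced with HMM- or database-driven detectors are
not comparable numbers, and reproducing them is a non-goal. What the
package validates is the procedure — flag, fraction, overlap with
TUGs — against synthetic truth.

## The simulator

The generator produces what the analysis assumes: a pure-birth (Yule,
rate 1) strain tree; `n_core_root` families present at the root; gains
as Poisson(g·ℓ) per branch of length ℓ; per-family loss with hazard
1 − e^(−l·ℓ); i.i.d. per-site amino-acid substitution with hazard
1 − e^(−s·ℓ); optional per-branch family duplication (default 0.02) to
exercise paralog handling; and HGT genes replacing a fraction of each
leaf's genes, generated de novo with codons drawn at an alien GC
(default 0.45 vs native 0.60, a 0.15 offset). Codons are drawn at
family birth from a GC-parameterised codon table and inherited down the
tree, redrawn only at substituted sites, so nucleotide divergence tracks
protein divergence; assemblies are the concatenated coding sequences
(one contig per genome). A family whose every copy is HGT-replaced at a
leaf records a loss on that terminal branch, keeping the truth table
Dollo-consistent by construction. All randomness flows from one seed;
datasets are byte-reproducible.

What it does not emulate — and therefore what green tests do not show
about real data: intergenic DNA, operon and synteny structure,
rearrangements and inversions, rate heterogeneity across sites or
lineages, indels inside genes, homologous recombination between
lineages, and HGT between the simulated strains themselves (aliens are
de novo). Family identities are also well separated by construction
(unrelated families share no ancestry), so clustering at the default
thresholds is easier than on real proteomes with multi-domain proteins
and remote homology.

Reference study conditions used by the test-suite and the acceptance
script: 12 genomes with 400 root families, gain 3 and loss 0.3 per unit
branch length and 1% per-site substitution for family recovery; 12
genomes with 10% HGT genes at a 0.15 GC3 offset for the screen; trees of
5–20 leaves for NJ exactness; all tree shapes with ≤ 6 leaves times all
presence patterns for Dollo optimality; 6 genomes for exhaustive
ordering enumeration. These sizes were chosen as the smallest at which
each property is sharply testable (exact enumeration still feasible,
Monte-Carlo noise well below the asserted tolerances).

## Known limitations

- The E-value is calibrated for ranking, not for absolute accuracy
  across scoring schemes.
- The k-mer prefilter bounds sensitivity below ~40% identity; for
  remote-homology use-cases lower `prefilter_min_shared` (at quadratic
  cost) or supply an external hit list.
- Concatenation-based supertrees assume congruent gene histories; no
  per-gene trees or support values are computed.
- The HGT screen detects compositional atypicality only; ameliorated
  transfers and same-composition donors are invisible to it.
- ANI on simulator output reflects coding-sequence divergence only,
  since assemblies have no intergenic DNA.
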