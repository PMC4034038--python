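# Methods

This note documents the models, defaults and numerical choices behind
`ggfam`, and what the synthetic-data tests do and do not establish.

## Motif architecture classification

Trans-prenyltransferase function tracks four short motifs: FARM
(`D D x x x x D`), SARM (`D D x x D`), and the subunit-interaction motifs
CxxxC and its single-substitution variant CxxxS (`C h h h C/S`, h
hydrophobic). The scanner matches these literally; the "any amino acid"
positions accept the 20 standard residues but never `X`, so unknown
residues cannot create evidence. The hydrophobic alphabet defaults to
{A, V, L, I, M, F, W, P} and is a parameter: sources describing the CxxxC
spacer say only "hydrophobic", and alternative conventions (e.g. including
G or excluding P) move the boundary of what counts as a hit.

Overlap resolution is deterministic: within each motif kind, windows are
claimed greedily left to right; kinds are prioritized FARM > SARM > CxxxC >
CxxxS and a later kind may not overlap an already-claimed span. This
prevents the first five positions of a FARM from double-counting as a SARM.
In real polyprenyl synthases FARM and SARM lie far apart, so the rule only
matters for adversarial inputs.

Class assignment is a pure function of presence/absence counts, evaluated
top-down (first match wins): FARM∧SARM∧≥2 CxxxC → ph-GPS;
FARM∧SARM∧1 CxxxC∧≥1 CxxxS → ph-GPS/GGPPS; FARM∧SARM∧1 CxxxC →
canonical GGPPS; FARM∧SARM∧0 CxxxC → ph-PPPS; no aspartate motifs∧≥2
CxxxC → ph-SSUI; FARM only∧≥2 CxxxC → ph-SSUII; anything else is
UNCLASSIFIED. A "mutated SARM" is operationalized purely as absence of a
SARM match — no alignment to a reference is attempted.

## Homology screening

Scores are optimal global alignments under an affine gap model (Gotoh
three-state recursion, provided by Biopython's `PairwiseAligner`) with the
classic PAM250 log-odds matrix, whose entries are in Dayhoff units (tens of
log10 odds). Gap costs default to open −10, extend −1, with the convention
that a gap run of length L costs `open + (L − 1) · extend`. `X` scores 0
against everything. The exact scoring parameters behind published
"Dayhoff score" thresholds are generally not recoverable, so all of matrix,
gap costs and threshold are exposed; the threshold rule is strict
(score > 130 to *every* query) because "exceed" reads as strict, with an
`inclusive` flag for ≥.

The test suite checks the aligner against a brute-force oracle that
enumerates every global alignment (exhaustively for all sequence pairs of
length ≤ 4 over a 3-letter alphabet, and property-based beyond), and
against structural invariants (symmetry, suffix additivity).

## Duplication/speciation labeling and rooting

The species-overlap rule labels an internal node a duplication iff the
species sets of its two child subtrees intersect; it assumes no species
phylogeny. LCA reconciliation, used when a species tree is available, maps
each gene-tree node to the LCA of its children's images; a node is a
duplication iff it maps to the same species-tree node as one of its
children, and each child edge contributes
`depth(M(child)) − depth(M(node)) − (0 if duplication else 1)` losses.

Rooting tries every edge of the unrooted tree (a degree-2 root in the input
is suppressed first). Without a species tree the score is the duplication
count alone and losses are reported as 0 — the output records which mode
ran. With a species tree the score is duplications + losses. Published
descriptions of duplication-loss rooting alongside species-tree-free event
inference leave ambiguous whether losses entered the rooting step; both
modes are provided rather than guessing intent. Ties break by lowest
duplication count, then lowest loss count, then the most balanced root
split, then a canonical edge order (edges sorted by the label set of their
smaller side); determinism is required for reproducible audits. Trees must
be strictly binary; an explicit resolver binarizes polytomies
deterministically (first-two grouping) when asked.

## Expression states

Input matrices are log2 scale, genes × samples. The detection floor is
2.5 log2 units, read literally as "below 2.5 is not detectable": exactly
2.5 counts as detected. The mask is computed and reported but does not
remove values from correlations — exclusion would change correlations in a
way the upstream analysis did not describe.

Probesets shared between near-identical transcripts (e.g. the single
probeset reporting both *GGPPS6* and *GGPPS7*) are collapsed by an explicit
merge map; merged rows must carry identical values, and the merged gene is
labeled "A/B" style.

Distance is d = 1 − r (Pearson over all samples), so the published cluster
cutoff r = 0.65 is the cut height h = 0.35 exactly. Clustering is
agglomerative; linkage defaults to complete (the historical default of the
R `hclust` environment this style of analysis comes from) and is exposed.
The dendrogram is cut keeping merges *strictly* below h, making r = 0.65
the largest correlation that still separates two profiles. Cluster ids are
numbered by first member in input order; each cluster is one character
state.

## Ancestral states and the permutation test

Fitch's algorithm on a strictly binary rooted tree gives the minimum number
of unordered state changes; the Swofford–Maddison downpass yields the full
most-parsimonious state set per node (checked exhaustively against
enumeration of all internal labelings on small trees, and against R
phangorn's independent implementation).

The permutation test reshuffles the observed tip-state multiset uniformly
among taxa (sampling tip orderings, so duplicate states make some
permutations coincide — that is the intended null), scores each of n
replicates, and reports p = (1 + k)/n capped at 1.0, where k counts
replicates with score ≤ observed. This is the printed form of the
estimator; it can exceed 1 before capping and is slightly anti-conservative
relative to the conventional (1 + k)/(n + 1), which is available behind a
flag. The generator is NumPy's seeded PCG64; every report records the seed.
`exact_null` enumerates all distinct assignments (bounded by a limit) as an
oracle for the sampler.

### The GGPPS paralog fixture

The packaged worked example encodes the twelve *A. thaliana* GGPPS paralogs.
The topology is a transcription of the published paralog phylogeny from its
textual description (GGPPS12 outermost; cherries GGPPS2+11, GGPPS3+4,
GGPPS1+8, GGPPS6+7, GGPPS9+10; GGPPS5 sister to the young
GGPPS6/7/9/10 clade; divergence order following the dated chronogram).
Because the drawn figure admits minor rearrangements, all 105 arrangements
of the five narrative-constrained clades were checked: every one gives the
same observed score (7), the same null support ({7,8,9,10}) and exact
P(score ≤ 7) between 0.0093 and 0.0095, so the residual ambiguity does not
affect any reported number. For the shipped topology, exact enumeration of
all 29,937,600 distinct state assignments gives P(score ≤ 7) = 1/105
≈ 0.0095 and a Fitch root set of exactly the ubiquitous state 2.

Two encodings are available: the 12-taxon form (GGPPS6 and GGPPS7 as
separate tips sharing the probeset-derived state), which reproduces the
published statistics (observed 7, null 7–10, p ≈ 0.008–0.010), and an
11-tip form with a merged `GGPPS6/7` terminal. Under the merged encoding
the state multiset has only three duplicated states and the reshuffling
null changes qualitatively (P(score ≤ 7) = 1/15, null maximum 9 — for
*every* candidate topology), so the 12-taxon encoding is the one consistent
with the published permutation analysis and is the default.

## Synthetic-data generators

All generators are pure functions of (config, seed).

* **Families**: one ancestral lineage evolves forward down a binary species
  tree with positive branch lengths; duplications arrive per lineage as a
  Poisson process with rate λ (default 0.3 events per unit length), losses
  with rate μ (default 0); every surviving lineage bifurcates at each
  speciation; extinct subtrees are pruned and pass-through nodes spliced.
  At μ = 0 the surviving tree's recorded events are exactly recoverable by
  species overlap — the basis of the exactness test. With losses, inferred
  duplications can undercount truth when a duplication's witnesses die out.
* **Architectures**: backbones are drawn from the 18-letter alphabet
  excluding D and C, so planted motif truth is exact rather than
  probabilistic; motifs sit at fixed non-overlapping offsets (minimum
  length 90). Point mutations (outside motif spans, drawn from the full
  alphabet) can create spurious motifs, giving a controlled noise knob.
* **Expression**: default 8 clusters × 2 genes × 50 samples, cluster
  centers i.i.d. N(7, 2²) per sample, within-cluster noise SD 0.5 log2,
  values clipped at 0. These defaults mirror the scale of a
  developmental-atlas analysis (8 clusters over a dozen genes, detection
  floor 2.5) while keeping between-cluster correlations near 0 and
  within-cluster correlations ≈ 0.94, so the h = 0.35 cut is exercised with
  a realistic margin rather than trivially.
* **Characters**: root state uniform on 1..k; along each branch the state
  jumps with probability q to a uniformly chosen different state. The true
  change count upper-bounds the parsimony score on every replicate.

What passing synthetic tests does *not* show: real microarray data have
correlated noise, probe effects and replicate structure that the expression
generator omits; real protein families evolve by substitution processes the
architecture generator does not model (motifs are planted, not evolved);
and real gene trees carry phylogenetic error, whereas simulated families
are known without error. The tests establish correctness of the algorithms
under their stated models, not robustness to violations of those models.

## Calibration choices in the acceptance tests

The type-I-error check for the permutation test runs 500 replicates of
i.i.d. uniform tip states (no signal) at n = 2000 reshuffles and asks that
P(p ≤ 0.05) lie in [0.03, 0.08]. The replicates use 200-tip trees with a
3-state character: the parsimony score is integer-valued, so on small trees
(e.g. the 12-paralog scale) the null distribution is so coarse that the
achievable rejection rate sits near 0.02–0.03 — the test is valid but
strongly conservative. The larger design keeps the null score distribution
fine-grained enough to probe the estimator's nominal behavior; the observed
rate there is ≈ 0.04.

Problem sizes throughout the suite (200 simulated families, 200 random
trees for the parsimony oracle, exhaustive alignment pairs up to length 4,
100 clustering replicates) were chosen as the smallest sizes at which the
checked properties are exercised across the relevant structural variety.

## Known limitations

* Alignment is exact but O(len²) per pair with no seeding/indexing; the
  screen is meant for hundreds, not millions, of candidates.
* Reconciliation and rooting assume binary trees; polytomies must be
  resolved explicitly and the resolution is arbitrary (flagged in output).
* The permutation test's p has resolution 1/n and is conservative for very
  discrete score distributions (see above).
* The shipped paralog fixture is a transcription; branch lengths are not
  part of it, and analyses that need them (e.g. molecular dating) are out
  of scope.
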