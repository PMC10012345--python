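# Methods

`grnsb` assesses gene-regulatory-network (GRN) inference output the way the
networks themselves demand: rank-based statistics against an explicit pair
universe, gold standards engineered to match what each tool class can
actually infer, and global-topology comparison for the structure that rank
statistics cannot see. This note records the models, conventions, and the
design choices that were genuinely open.

## Gold-standard engineering

Curated bacterial GRNs mix gene nodes with regulatory protein complexes.
Because expression-based inference can only recover gene–gene interactions,
complex nodes are projected onto their constituent genes (every incident
edge is replaced by one edge per constituent, duplicates collapsed), and
genes without expression data are removed, since no method could ever
predict their interactions.

Co-expression tools do not infer regulation; they detect co-variation, and
genes regulated by the same transcription factor (TF) co-vary. A regulon —
a TF with its target set — therefore induces a clique of co-regulated
genes. `expand_coregulation` unions those cliques over all regulons into an
undirected co-regulation gold standard. The TF joins its own clique only
when it is autoregulated (it is then one of its own targets and enters as
an ordinary member); overlapping regulons contribute each unordered pair
once, and no self-edges are produced. The expression filter can be applied
before expansion (default: a gene with no data can never be scored) or
after (`--expand-first`), since either reading of the upstream pipeline is
defensible; both orders are exposed and tested.

## Rank-based assessment

The universe of candidate interactions is, by default, every ordered
(regulator, target) pair over the considered genes, self-pairs included —
autoregulation is real, and target–target predictions by co-expression
tools must be countable as false positives. Gold-standard pairs inside the
universe are the positives P; everything else is negative. Predicted pairs
outside the universe are dropped and logged.

Conventions, all tie-aware:

- **Trimming.** Lists longer than the expected size of the complete GRN
  (configured per organism, e.g. 12,000 or 16,000 interactions) are cut at
  that size. A tie block straddling the boundary is kept whole: a
  score-based cutoff cannot meaningfully split equal scores.
- **Ranking.** Entries sharing a score form one tie block and receive the
  mean of their positional ranks. Every universe pair absent from a list
  ranks right after the last listed one (L+1), so longer lists penalize
  their missing interactions more.
- **AUPR** is the trapezoidal area of the precision–recall curve swept one
  tie block at a time (all members of a block enter together), anchored on
  the left at (recall 0, precision of the first block), and **not**
  extrapolated past the recall the trimmed list actually reaches. Against a
  very large positive set (the co-regulation gold standard) truncated AUPR
  values are therefore small in absolute terms; they remain comparable
  across methods, which is the quantity of interest.
- **AUROC** is the tie-corrected Mann–Whitney statistic over the whole
  universe, with all unranked pairs sharing the position just past the
  list's end. Placing a common rank on that block and scoring ties as 1/2
  is algebraically the mid-rank treatment, which is how it is computed.
- **MCC / F1** summarize the trimmed list taken as a whole; degenerate
  denominators yield 0 by convention (logged). MCC is the right summary for
  the extreme P/N imbalance of GRNs and for unscored (rank-free)
  predictions.
- **Direction.** Undirected co-expression output assessed against a
  directed gold standard must first be symmetrized (each pair duplicated in
  both orientations, self-pairs once); assessing anything against the
  undirected co-regulation gold standard ignores direction (orientations
  collapse to the better-ranked one).

Regulon-level assessment compares, per gold-standard TF, the predicted and
true target sets as binary vectors over the universe's target set, scored
with MCC/F1 and reported against kout/kmax (the TF's out-degree over the
network maximum) to separate local from global regulators.

## Community integration and dominance

The community network scores every universe pair by its mean rank across
methods (Borda count), missing pairs contributing L+1 per method. Lower
mean rank is better; the stored score is the negated mean rank so the
non-increasing-score invariant holds. Exact mean-rank ties are ordered
lexicographically for reproducibility — tie-aware assessment still sees
them as one block, so the tie-break never affects a metric. The integrated
list is trimmed to the expected complete-GRN size.

Selective communities are all size-r subsets of the n methods. A tool's
dominance at size r is the fraction of the C(n−1, r−1) subsets containing
it whose community AUPR strictly exceeds the all-inclusive community's
("outperforming" reads as strict; ties are not wins). The table reports
per-r values and leaves any aggregation across r to the caller.

## Structural profiles

Thirteen normalized global properties form each network's profile:
regulator, self-regulation, maximum-out-connectivity and giant-component
fractions (counts over n); density × regulator fraction; three triad-motif
densities; average clustering; diameter and average path length over n−2
(the longest path a shortcut-free network could have, computed on the
undirected projection of the giant weakly-connected component); and the
log–log R² of the degree distribution P(k) and the clustering-by-degree
curve C(k) (zero values excluded; fewer than 3 usable points leaves the
statistic undefined and the property is dropped from clustering for all
networks, logged).

Motif classes are exact induced patterns, mutually exclusive by
construction: a feedforward loop is exactly {A→B, A→C, B→C}; the complex
variant adds B→A (the two regulators regulate each other); a 3-feedback
loop is exactly a directed 3-cycle and is counted only when all three
members are TFs. Counts are normalized by the motif potential
n!/(n−r)! · (TFn/n)^TFm with r = 3 and TFm = 2 (feedforward variants) or 3
(feedback loops). The ordered-triple convention of the potential makes the
normalized values comparative rather than absolute, which is how they are
used. Undirected networks are viewed as reciprocal-arc digraphs for the
direction-dependent properties; exact-pattern matching then correctly
assigns purely symmetric graphs zero directed motifs.

Profiles are min–max scaled per property across networks (constant columns
to 0) and clustered with Ward's method, either directly on the scaled rows
or on the rows of their pairwise Pearson-correlation matrix
("correlation-ward"). The number of connected components is reported in the
profile but excluded from the clustering vector.

## D-value dissimilarity

Two networks are compared as undirected simple graphs (self-loops dropped —
distance semantics; the projection is logged) through

D = w1·√(J(μ1,μ2)/log 2) + w2·|√NND₁ − √NND₂|
  + (w3/2)·(√(J(c1,c2)/log 2) + √(J(c1′,c2′)/log 2)),

with weights (0.45, 0.45, 0.1) by default. μ is the network-average
shortest-path-length distribution (per-node rows over bins 1…n−1 plus a
dedicated disconnected bin; rows sum to 1). NND, the network node
dispersion, is the Jensen–Shannon divergence of the per-node rows
normalized by log(d+1) for a connected graph of diameter d, or log(d+2)
when any pair is disconnected, keeping NND ≤ 1. c and c′ are the sorted
alpha-centrality distributions of the graph and its complement: the
solution of x = (1/n)·A·x + e with e = deg/(n−1), sorted, scaled by 1/n²,
with the residual mass appended as a final bin. Distributions of different
lengths are zero-padded before their final bins. D is symmetric,
permutation-invariant, and bounded in [0, 1].

Numerical note: the square root of a Jensen–Shannon divergence near zero
amplifies machine-epsilon entropy noise to ~1e−8, so identity checks
(D between a graph and its relabeling) hold to 1e−6 rather than exactly.

The pairwise D-value matrix is clustered by the same Pearson-then-Ward
recipe used for profiles.

## Synthetic fixtures

The generators make every stage testable without external data; they are
pure functions of (spec, seed).

- `generate_grn`: directed scale-free GRN. TF out-degree quotas follow a
  Pareto tail with the requested exponent (default 2.0, the classic GRN
  out-degree regime), rescaled by largest-remainder rounding so the edge
  count is hit exactly; targets are uniform; TFs autoregulate with
  probability `p_self` (default 0.1, the order observed in bacterial
  GRNs). Defaults (500 genes, 50 TFs — a 10% TF fraction, 1,500 edges)
  give the sparse, hub-dominated shape of curated bacterial networks at a
  size every test can afford.
- `generate_prediction`: each list position is a true pair with
  probability `precision` (independent Bernoulli, so realized precision is
  exactly binomial — what the planted-recovery checks assume), otherwise a
  decoy sampled without replacement. Style `caus` draws truths from the
  directed edges and decoys from TF-source non-edges (mirroring tools that
  receive a TF list); style `coex` is undirected, drawing truths from the
  co-regulation expansion and decoys from arbitrary unordered non-pairs.
  Scores decrease strictly except that adjacent entries share a score with
  probability `tie_fraction`.
- `snowball_sample`: link tracing over the undirected projection (a
  directed traversal from a hub would miss co-regulators), seeded at the
  highest-total-degree node, admitting nodes wave by wave — within a wave
  by descending degree, then lexicographically, the deterministic
  tie-break chosen here — up to the cutoff (default 198 nodes). The
  induced directed subgraph is returned.
- `generate_family`: "caus-like" members are the scale-free GRNs above;
  "coex-like" members partition the genes (shuffled) into co-regulated
  groups of 4–8 and union their cliques — near-total connectivity, high
  clustering, modest maximum degree.

What the fixtures do **not** emulate: expression data and its noise,
indirect-correlation artifacts, curation bias in real gold standards, or
tool-specific score distributions. Passing tests therefore demonstrate that
the assessment machinery is correct and discriminating under controlled
conditions, not that any particular inference tool is good on real data.

## Problem sizes used in the shipped checks

The automated checks run at sizes a single CPU handles comfortably while
keeping the statistics meaningful: enumeration-oracle agreement on 100
random ≤30-pair universes; planted precision pooled over 200 seeds of
length-1,200 lists (exact binomial 99% interval); motif counting against
brute force on 100 random ≤30-node digraphs; D-value axioms on 50 random
pairs and oracle equivalence (1e−9) on 10 small pairs; family separation
with 10+10 networks of 60 genes over 100 replicates; and the
directionality preference on a 400-gene, 80-TF gold standard over 100
seeds at planted precision 0.5. The one check requiring the curated
E. coli gold standard loads it from `data/` or the network and fails
otherwise rather than silently skipping.

## Known limitations

- Gene identifiers are opaque strings; no synonym resolution.
- Effect signs (activation/repression) are read and carried but ignored by
  every metric; the right weighting of sign agreement is an open question.
- Whether published AUROC analyses ranked only listed pairs or the whole
  universe is rarely stated; the whole-universe L+1 convention used here
  is the literal reading of the integration rules and is flagged in
  reports.
- Regulon-level true-negative counts use the universe's target set; a
  gold-standard-only gene set would shift MCC for sparsely covered TFs.
- The D-value's alpha-centrality step inverts a dense n×n system and the
  complement graph is dense by construction, so the measure is intended
  for networks up to a few thousand nodes.
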