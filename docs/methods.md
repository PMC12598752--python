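# Methods

This note records the modelling assumptions, parameter choices and known
limitations of `cofracnet`, in the order the pipeline runs.

## Elution preprocessing

Missing intensities are imputed to zero and rows that are entirely zero are
dropped (their ids are kept on the returned matrix). Each surviving profile
is divided by its row sum, so a profile is a discrete elution distribution
over the measured fractions; the row-sum contract is enforced to 1e-9.
Normalization strictly precedes padding: profiles are then zero-padded on
the right to a common length (default 200 fractions) so experiments with 27
to 61 fractions can share one model, and the appended zeros cannot dilute
the unit row sums. Padding never truncates — a profile longer than the
target is an error. Peak detection, replicate alignment and peptide-level
protein inference are out of scope; the input is assumed to be a
protein-level quantification matrix.

## Sequence encoding (FCGR)

The chaos game walks a point from the origin toward the vertex of each
successive residue, `p_k = p_{k-1} + s·(V(r_k) − p_{k-1})`, with the 20
canonical amino acids placed in alphabetical order at evenly spaced vertices
of the unit circle starting at angle 0, counterclockwise. This vertex
convention is not universal across CGR implementations; it is fixed and
documented here so encodings are reproducible within this package. The
contraction factor defaults to 0.863271, which keeps the attractors of
distinct residue suffixes from overlapping at resolution 16. Trajectory
points are histogrammed on a 16×16 grid over [−1, 1]² (half-open cells, the
last cell closed, so every point lands in exactly one bin), flattened
row-major to 256 values and divided by the maximum bin count. Normalizing
per protein rather than globally keeps vectors comparable across sequence
lengths. Non-canonical symbols (X, U, B, Z, *) have no vertex and are
dropped before encoding; a sequence that becomes empty is an error naming
the protein.

## Pair labels

Same-complex pairs are positive; pairs whose proteins are both catalog
members but share no complex are negative; everything else observed is
"experimental" (unlabeled, scored at prediction time). Because proteins can
belong to several complexes, sharing a complex takes precedence over
spanning two — otherwise the two definitions would contradict each other. A
nominal positive is relabeled negative when the two normalized, un-padded
profiles never co-elute: the per-fraction product must exceed 0.01 strictly,
and a tie at exactly 0.01 relabels. Negatives are down-sampled uniformly at
random (seeded, without replacement) to a 1:1 ratio before fold assignment;
folds are disjoint over the balanced set and experimental pairs never enter
them.

## Classifier

The network is implemented directly in numpy with analytic gradients —
the architecture is small enough that a framework adds nothing, and a
self-contained implementation keeps every arithmetic step inspectable and
seeded. Design points worth recording:

- **Residual placement.** The raw input row is added to every filter
  channel *after* the convolution's ReLU. Adding before the nonlinearity is
  equally defensible; after-ReLU keeps the identity path fully linear.
- **Pair symmetrization.** The pair feature is the elementwise absolute
  difference of the two protein representations (and of the two raw input
  rows). Plain subtraction is order-dependent while interaction labels are
  symmetric; the absolute difference makes score(i,j) = score(j,i) an exact
  identity rather than a training-time hope. Signed differences remain
  available behind `symmetrize="signed"` for experimentation.
- **Embedding.** One trainable row per protein, the width of the FCGR
  vector, initialized uniformly in [−0.01, 0.01]. The small initialization
  plus the fact that CF-MS enters by concatenation (not addition) keeps the
  elution signal dominant early in training while the embeddings absorb
  complex-level structure through backpropagation. Cross-dataset co-training
  disables the embedding (its rows are tied to one protein universe),
  down-samples every training pair list to the smallest set, and interleaves
  minibatches round-robin.
- **Optimization.** Binary cross-entropy, Adam (lr 1e-3), inverted dropout
  0.2 on the hidden FC activations, weight decay 1e-4 on convolution and FC
  weights. Kernel width 5 (odd, so the 'same' convolution is
  length-preserving, which the residual add requires), 32 filters by
  default, FC widths tapering geometrically to a single sigmoid unit. None
  of these four values is canonical; they are configuration, recorded in
  every run manifest.
- **Problem sizes.** The packaged worked example and acceptance run use a
  compact configuration (8 filters, FC head (64, 16, 1), 60 epochs) chosen
  so a full 5-fold run on the default synthetic study (200 proteins, 20
  complexes, ~500 balanced pairs) completes in minutes on one CPU while
  recovering the planted signal cleanly.

A non-finite training loss raises immediately with the epoch index rather
than continuing to corrupt the parameters.

## Clustering

The scored edge list keeps edges strictly above 0.5 (configurable); nodes
left without neighbors are dropped. Both smoothing matrices are computed
from this same floored adjacency. The Markov-cluster step follows standard
conventions: self-loops added once up front, column-stochastic
normalization, matrix-power expansion 2, elementwise inflation 2,
renormalization, exactly three iterations with no convergence test. The
topological overlap step reads "the 2.5th power" as an elementwise power
(soft thresholding): an elementwise power keeps weights in [0, 1], which the
overlap formula requires, whereas a matrix power would not. The TOM diagonal
is set to 1 (self-overlap), since rows subsequently feed cosine distances.

The dynamic tree cut is implemented in-package: a Ward dendrogram of the
cosine distance matrix is cut at the midpoint of the largest gap between
successive merge heights (the gap down to zero is excluded, since on
unstructured data it would shred everything into singletons); clusters are
re-cut recursively up to `deep_split` additional levels, each recursion
requiring a dominant local gap (≥ 30% of the local dendrogram height) and a
local height of at least 5% of the top-level dendrogram, so tight
homogeneous groups are not subdivided; finally clusters below the minimum
size (3) are absorbed into the retained cluster at smallest mean distance.
`deep_split` defaults to 3 with 2 recommended for small datasets (the
packaged pipeline uses 2). Clusters at or above 100 members are re-split on
the submatrix of the blend that produced them, with a recursion cap of 10
levels; truly unsplittable oversized clusters raise rather than pass
through. Merging repeatedly unions the highest-scoring pair with overlap
score strictly above 0.25, breaking ties lexicographically on sorted member
tuples so the result is independent of input order; a tie at exactly 0.25
does not merge.

## Evaluation

- **Classification.** A score equal to the 0.5 threshold classifies
  negative. MCC returns 0 with a warning when any denominator factor is
  zero. AUC is the rank-based (Mann–Whitney) area under the full ROC curve.
- **Composite score.** Overlap fraction counts predicted clusters whose
  overlap score with some reference complex strictly exceeds 0.25; Sn and
  PPV are the standard complex-wise/cluster-wise maxima over the member
  overlap count matrix; the maximum matching ratio uses an optimal (not
  greedy) maximum-weight one-to-one assignment, divided by the number of
  reference complexes. Components lie in [0, 1], the sum in [0, 3].
- **GO similarity.** Wang-style S-value propagation with edge weights
  `1/(c + nc(n)) + d`, c = 0.67, d = 0.4 (is_a) / 0.3 (part_of). The child
  count `nc` is evaluated at the ancestor being scored, over all of its
  children in the full ontology (not only those inside the term's ancestor
  closure) — the closest reading of "total number of child nodes". Gene
  similarity is the best-match average over the two term sets; a cluster's
  score is the mean over pairs of annotated genes, with unannotated genes
  excluded and logged, computed separately per ontology namespace.
- **Colocalization.** Largest per-compartment member count divided by the
  number of members *with* assignments; unannotated members do not enter
  the denominator.
- **Null models.** The random-clustering null redraws every predicted
  cluster as a uniform size-matched sample of the clustered proteins and
  recomputes the composite score (add-one-corrected empirical p). The
  size-matched bootstrap draws, per replicate, one background score of
  matching size per observed cluster and compares the observed per-cluster
  scores against the null-distribution mean with a one-sample t-test.

## Saliency

The attribution for a scored pair is the absolute gradient of the sigmoid
output with respect to the two assembled input rows, averaged over the two
proteins (the reduction across the pair is a package choice; one map per
pair is the target). Padded CF-MS positions are excluded from region means —
their input is constant zero. Before categorization each map is min–max
normalized to [0, 1] so the ±0.1 band is a fraction of the map's dynamic
range rather than an absolute gradient magnitude, which would depend on
model scale; the band comparison itself is strict on both sides. Per
category, maps are summed and min–max normalized; a constant sum returns
zeros with a warning.

## Synthetic data

The generator plants exactly the structure the pipeline assumes: each
complex draws a Gaussian elution apex (members jittered by `apex_jitter`
fractions, sd `peak_sd`, random amplitude in [0.5, 2]), background proteins
draw independent apexes; additive Gaussian noise is clipped at zero and
cells go missing independently. Complex members share a fixed 8-mer motif
inserted at a random position with probability `motif_share`; sequences are
otherwise uniform over the 20 canonical residues. Each complex maps to one
GO leaf of a seeded toy ontology (members also receive random noise terms)
and one subcellular compartment. Defaults — 200 proteins, 40 fractions, 20
complexes of 3–8 members, peak sd 1.5, jitter 0.5, 5% noise, 5%
missingness — describe a small but realistic study and are the conditions
under which the packaged worked example runs.

What the generator does **not** emulate: mass-spectrometer intensity
distributions (iBAQ dynamic range, peptide-level variation), correlated
missingness, multi-peak profiles from moonlighting proteins or degradation,
overlapping complex membership, and homology between sequences beyond the
planted motif. Passing tests on this generator therefore demonstrate that
the machinery is correct and that the pipeline recovers planted structure
under its own assumptions — not that real-data performance will match.
A genuine ambiguity the generator does contain: two complexes can draw
nearby apexes, making their cross-pairs nearly indistinguishable from
positives on elution alone; the trainable embedding is what allows the
classifier to separate such pairs, mirroring its intended role.

## Known limitations

- The dynamic tree cut is a largest-gap implementation, not a port of the
  full dynamic hybrid algorithm; on dendrograms without clear gap structure
  its cuts are heuristic (the hybrid reassignment stage absorbs fragments).
- MCL and TOM are dense-matrix implementations, adequate to a few thousand
  nodes; very large interactomes would need sparse variants.
- GOGO-style similarity is recomputed per term pair without cross-call
  caching; for large ontologies and big clusters this is the slow path.
- The classifier's embedding ties the model to one protein universe;
  transfer across datasets requires the embedding-free variant.
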